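# Methods

This note documents the models, conventions and numerical choices behind
`glenoid_oam`, and what the synthetic phantoms do and do not establish about
real CT data.

## Coordinate and sign conventions

All coordinates are physical millimetres; voxel indexing is 0-based with the
centre of voxel `(i, j, k)` at `origin + spacing * (i, j, k)`. For a right
shoulder, `+x` runs ventral → dorsal, `+y` caudal → cranial and `+z` medial →
lateral; left shoulders are the mirror image in `x`. Storing coordinates in
millimetres (never voxel indices) keeps every operation independent of
spacing and makes anisotropic grids safe.

The scapular plane is spanned by the spine-root midpoint, the glenoid centre
and the inferior scapular angle. The *coronal* measurement plane is the
scapular plane itself, and the *transversal* measurement plane contains the
spine axis and is perpendicular to the scapular plane — the analytic reading
of angle measurement on a scapula-aligned multiplanar reconstruction.

Both raw angles are measured against the **medial** spine ray (glenoid centre
→ spine root): γ against the caudally-oriented glenoid height line A→B
projected into the coronal plane, δ against the dorsally-oriented width line
C→D projected into the transversal plane. With these orientations, superior
inclination yields γ > 90° (α = γ − 90° > 0) and retroversion yields δ < 90°
(β = δ − 90° < 0) on both sides, which fixes the sign conventions
deterministically. How a *negative* (inferior) inclination should interact
with the "measured in caudal direction" rule is not anatomically settled;
this implementation simply lets γ drop below 90°, which is one consistent
reading. Angles are computed at full precision and rounded to 0.1° only in
output tables.

## Phantom construction

A phantom contains a flat scapular blade (spine length 100 mm, inferior-angle
drop 90 mm by default — representative adult dimensions), an elliptical
glenoid block (height 36 mm > width 26 mm) whose articular surface is a
concave elliptic paraboloid of depth 2.5 mm, a subchondral plate of constant
thickness 2 mm at 800 HU, trabecular bone at 300 HU, soft tissue at 40 HU,
and a humeral-head sphere cap (radius 24 mm, half-angle 55°) separated by a
4 mm joint space. With `volume_shape=None` the generator computes the
smallest grid that contains the anatomy; otherwise a grid too small for the
anatomy raises a sizing error (checked exactly: no bone voxel may touch the
boundary shell).

Ground-truth angles are imposed by rotating the rim point set and fossa about
the glenoid centre: an in-plane (inclination) rotation about the scapular
normal followed by a version rotation about the cranio-caudal axis. Because
the outer version rotation scales the coronal projection of the height line
by cos(β), the inner rotation angle is pre-compensated
(θ = atan(tan α / cos β)) so that the *measured* angles equal the requested
ones to machine precision on the continuous landmarks. The landmark set
returned with the volume is snapped to voxel centres, emulating image-picked
landmarks; at 0.6 mm spacing this injects up to ≈1.3° of quantisation error
into the recovered angles (RMS ≈ 0.44° over the inclination × version grid),
and the recovered version is effectively quantised in steps of
atan(spacing/width) ≈ 1.3°.

### Mineralisation bump field

Density maxima are modelled as isotropic Gaussian bumps added to the plate,
with σ = 25 % of glenoid width and peak 1400 HU. Bump placement encodes the
pattern labels, in fossa coordinates (p dorsal, q cranial, semi-axes a, b):

| labels | bumps (relative amplitude) |
|---|---|
| central / central_ant_gt_post | (−0.18 a, +0.18 b) |
| central / posterior | (+0.22 a, +0.18 b) |
| central / even | (0, +0.18 b) |
| cranial or caudal × anterior or posterior | (±0.55 a, ±0.55 b) |
| single-axis labels (other axis even) | ±0.70 of the active semi-axis |
| diagonal (vertical even) | (−0.55 a, +0.55 b) and (+0.55 a, −0.55 b), equal |
| diagonal (vertical cranial/caudal) | same positions, weaker bump scaled 0.72 |
| even / even | none |

The offsets were chosen so that the high-density region each bump produces
(the disc where plate + bump clears the bin-7 cutoff of 1033 HU) lands
decisively on the intended side of every classifier threshold: quadrant
centroids (≈0.42 of the semi-axes) leave the central-zone fraction straddling
the 0.40 physiological threshold and make labels unrecoverable, hence the
larger offsets. Physiological ("central") labels keep a small offset because
the classifier requires a ≥0.10 half-imbalance before it can call a pattern
central at all. The true size and amplitude of mineralisation maxima in vivo
are not quantitatively established; all of these are configuration, not
biology.

Four label pairs are mutually contradictory under the classifier and are
rejected by the generator: (cranial, central_ant_gt_post), (caudal,
central_ant_gt_post), (central, anterior) and (central, diagonal). The
central-zone fraction is one statistic shared by both axes: a physiological
label on either axis demands it at or above the threshold while a
cranial/caudal/anterior/diagonal label demands it below, so no density field
can satisfy both. The generator's contract is therefore the 16 realizable
pairs, over which label recovery is ≥95 % noise-free and ≥80 % at 50 HU
additive noise (criteria measured at 20 phantoms per pair).

OA features are rendered literally: an exostosis as a bone sphere of the
requested height beyond the caudal rim, sclerosis as a +150 HU plate boost,
erosion as a plate defect in the cranial-dorsal quadrant. Sclerosis deliberately
confounds the density map (it enlarges the supra-threshold region), which is
physically sensible but means pattern-recovery guarantees hold only for
sclerosis-free phantoms.

### Cohort sampling

`generate_cohort` draws per-shoulder angles from normal distributions clipped
to the observed cohort ranges (inclination mean 8.4°, SD 4.9°, clipped to
[0.5°, 19.8°]; version mean −5.2°, SD 4.2°, clipped to [−15.9°, 3.8°]),
pattern labels and OA grades at the observed cohort frequencies, and a
10 : 9 female : male donor ratio. All draws come from a single seeded
generator in a fixed per-specimen field order, so cohorts are bitwise
reproducible. An optional `pattern_rule` assigns labels deterministically
from the angles (physiological inside a given range, different outside),
which is how concordance-recovery experiments construct their ground truth;
an explicit `values` list replaces the normal draw where discrete,
boundary-avoiding angle sets are needed.

## CT-OAM numerical choices

* Bone segmentation is exact thresholding, 300 ≤ HU ≤ 2000.
* The articular surface is extracted as a height field over the rim plane:
  for each pixel of a regular grid (pixel = min voxel spacing) a ray marches
  from lateral to medial in steps of ¼ of the minimum spacing, sampling the
  mask with trilinear interpolation; the surface is the most lateral
  bone-entering crossing at or below the rim plane (crossings above it belong
  to the humeral head), refined by linear interpolation of the 0.5 level.
  Normals come from the height-field gradient and point into the bone;
  gradients at the validity border are damped to zero. The patch is
  triangulated two triangles per grid cell; its area agrees with the analytic
  paraboloid area to better than 10 %.
* The MIP samples HU trilinearly along the inward normal over [0, depth] at
  ¼-spacing steps; depth defaults to 3 mm. A ray leaving the volume marks its
  pixel invalid rather than failing. Map values are non-decreasing in depth
  by construction.
* Colour bins: six equal-width bins across [200, 1200] HU plus two open
  tails, lower edges inclusive, ordered violet (lowest) → black (highest).
  The high-density cutoff for pattern statistics is bin 7, i.e. HU ≥ 1033⅓
  (configurable); the central zone is the ellipse with semi-axes 50 % of the
  fossa's; both choices are conventions, not measurements.
* Classification thresholds: a half-imbalance below τ_e = 0.10 reads as
  "even"; a central-zone fraction of at least τ_c = 0.40 (with the required
  imbalance) as physiological; otherwise the larger half wins. "Diagonal" —
  the two largest quadrant fractions forming a diagonally opposite pair, each
  ≥ 0.30 — is tested *before* the even rule, since a diagonal pattern
  balances both half splits; with all fractions equal the diagonal test fails
  and the pattern is even, so the precedence is unambiguous.
* On piecewise-constant phantoms the MIP agrees with an exhaustive
  voxel-centre slab-max oracle to ≤1 HU at every valid pixel. Where the HU
  field varies across a voxel (Gaussian bumps) or the surface curves strongly
  (the rim ring of the fossa), interpolated ray maxima and voxel-centre
  maxima legitimately differ by O(gradient × voxel), so oracle equivalence is
  asserted on laterally-uniform slabs and on the interior of curved fossae.

## Grading conventions

A Kellgren–Lawrence row is satisfied if *any* of its criteria is met at the
stated severity, and the sub-score is the highest satisfied row — the
reproducible reading for mixed presentations. Samilson–Prieto intervals are
closed on the printed bounds: 0 / (0, 3) / [3, 7] / (7, ∞) mm. The Larsen
ladder distinguishes its middle rows by destruction severity (early vs medium
to severe), with erosion contributing at both levels. All three sub-scores,
the total and the grade are monotone under single-feature worsening
(exhaustively tested). The Outerbridge cartilage grade is carried as an
unscored annotation: it is a dissection finding outside the radiological
score.

## Reporting conventions

Percentages round half-up (not banker's rounding) to 1 decimal for
38- and 19-denominated tables and to whole percent for the sex-specific
values. Grouped-grade rows are emitted in both conventions — recomputed from
summed counts *and* as the sum of already-rounded per-grade percentages —
because clinical tables typically print the latter (13.2 + 21.1 = 34.3 while
13/38 = 34.2). The concordance rule, range search (1° grid, inclination
[0, 20]°, version [−16, +4]°, ties broken by the narrower range then the
lower bound) and margin-expansion report operate purely on counts, so their
outputs recompute exactly from the records.

Pooling left and right shoulders of the same donors mixes per-side and
bilateral counting in ways that are easy to misread; the reports here emit
per-side counts and percentages and leave any pooling to the reader.

## Problem sizes

The test suite and the acceptance script run phantoms with a compact scapula
(spine 30 mm, inferior-angle drop 28 mm, humeral radius 22 mm) wherever the
blade itself is not under test, keeping hundreds of phantom generations
affordable; angle-recovery studies use the full-size default geometry because
quantisation error scales with the landmark lever arms. Pattern-recovery
rates are measured at 20 phantoms per label pair in the suite and 10 per pair
in the acceptance script.

## Limitations

* Phantoms are geometric idealisations: no scanner physics (beam hardening,
  dose modulation, partial-volume blur beyond trilinear sampling), no
  cartilage, no anatomically realistic scapula blade. Passing recovery tests
  demonstrates the correctness of the measurement chain, not its accuracy on
  clinical scans.
* Landmarks are inputs; automatic landmark detection on real anatomy is out
  of scope, as is DICOM series reading.
* The OA score is computed from annotated features, not detected from the
  image; the phantom renders only exostosis, sclerosis and erosion visually.
* Humeral-head density maps are not computed (the glenoid is the quantitative
  object).
* Inferential statistics are out of scope; the cohort analysis is
  descriptive.
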