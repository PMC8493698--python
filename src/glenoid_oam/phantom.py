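"""Synthetic shoulder CT phantoms with known ground truth.

Every downstream stage (angle measurement, CT-OAM mapping, pattern
classification, OA grading, cohort analysis) is exercised on phantoms built
here, because real donor scans are not distributable.  A phantom contains:

* a flat scapular blade whose spine-root and inferior-angle landmarks are
  placed analytically,
* a shallow concave elliptical glenoid fossa whose rim extremes A (cranial),
  B (caudal), C (ventral), D (dorsal) are rotated about the glenoid centre so
  that the continuous-geometry inclination and version equal the requested
  angles exactly,
* a subchondral plate of constant thickness under the fossa surface at
  ``base_plate_hu`` plus an additive Gaussian mineralisation bump field whose
  placement encodes the requested distribution-pattern labels,
* a humeral head sphere cap separated by the joint space, and
* optional osteoarthritis features (rim exostosis, sclerosis, erosion).

Axis convention (right shoulder): ``+x`` ventral -> dorsal, ``+y`` caudal ->
cranial, ``+z`` medial -> lateral; left shoulders are mirrored in ``x``.
Ground-truth angles are imposed by the rotation ``R = R_y(-s*beta) R_x(-incl)``
about the glenoid centre (``s = +1`` right, ``-1`` left), which is exactly
inverted by the angle-measurement convention in :mod:`glenoid_oam.geometry`.

Some vertical/horizontal label pairs are mutually contradictory under the
quadrant classifier (a physiological horizontal label requires a dominant
central zone while a cranial/caudal vertical label forbids one, and vice
versa); :func:`generate_phantom` rejects those pairs.  See
``CONTRADICTORY_PATTERN_PAIRS`` and docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from ._utils import rotation_about_axis
from .errors import SizingError, ValidationError
from .io import LandmarkSet, Volume
from .oa_grading import (
    Destruction,
    Erosion,
    JointSpace,
    Osteophytes,
    RadiologicFeatures,
    Sclerosis,
    composite_score,
)

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "generate_landmarks",
    "voxelised_landmarks",
    "generate_cohort",
    "iter_cohort",
    "CohortResult",
    "Specimen",
    "VERTICAL_PATTERNS",
    "HORIZONTAL_PATTERNS",
    "CONTRADICTORY_PATTERN_PAIRS",
    "REALIZABLE_PATTERN_PAIRS",
    "DEFAULT_DISTRIBUTIONS",
]

VERTICAL_PATTERNS = ("central", "cranial", "caudal", "even")
HORIZONTAL_PATTERNS = ("central_ant_gt_post", "anterior", "posterior", "diagonal", "even")

#: Label pairs that no mineralisation field can satisfy simultaneously under
#: the quadrant classifier: the central-zone fraction is a single statistic
#: shared by both axes, and physiological labels require it above the
#: threshold while cranial/caudal/anterior/diagonal labels require it below.
CONTRADICTORY_PATTERN_PAIRS = frozenset(
    {
        ("cranial", "central_ant_gt_post"),
        ("caudal", "central_ant_gt_post"),
        ("central", "anterior"),
        ("central", "diagonal"),
    }
)

REALIZABLE_PATTERN_PAIRS = tuple(
    (v, h)
    for v in VERTICAL_PATTERNS
    for h in HORIZONTAL_PATTERNS
    if (v, h) not in CONTRADICTORY_PATTERN_PAIRS
)

_PERIPHERAL_OFFSET = 0.55  # semi-axis fraction for cranial/caudal/ant/post bumps
_CENTRAL_OFFSET = 0.18  # fraction of the semi-axis for "central" labels


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic shoulder; defaults emulate the study setup.

    Angles are in degrees (inclination positive = superior; version negative =
    retroversion), lengths in mm, densities in HU.  ``volume_shape=None``
    auto-computes the smallest grid containing the modelled anatomy.
    """

    voxel_spacing: Tuple[float, float, float] = (0.6, 0.6, 0.6)
    volume_shape: Optional[Tuple[int, int, int]] = None
    laterality: str = "right"
    glenoid_height: float = 36.0
    glenoid_width: float = 26.0
    humeral_head_radius: float = 24.0
    inclination_deg: float = 8.4
    version_deg: float = -5.2
    pattern_vertical: str = "central"
    pattern_horizontal: str = "central_ant_gt_post"
    peak_hu: float = 1400.0
    base_plate_hu: float = 800.0
    trabecular_hu: float = 300.0
    soft_tissue_hu: float = 40.0
    plate_thickness: float = 2.0
    joint_space: float = 4.0
    exostosis_height: float = 0.0
    sclerosis: bool = False
    erosion: bool = False
    noise_sd: float = 0.0
    seed: int = 0
    # secondary geometry (anatomically representative defaults)
    fossa_depth: float = 2.5
    block_depth: float = 10.0
    spine_length: float = 100.0
    inferior_angle_drop: float = 90.0
    cap_half_angle_deg: float = 55.0
    sclerosis_boost_hu: float = 150.0

    def __post_init__(self):
        sp = np.asarray(self.voxel_spacing, dtype=float)
        if sp.shape != (3,) or np.any(sp <= 0):
            raise ValidationError("voxel_spacing must be three positive values")
        if self.laterality not in ("left", "right"):
            raise ValidationError("laterality must be 'left' or 'right'")
        if not (self.glenoid_height > self.glenoid_width > 0):
            raise ValidationError("require glenoid_height > glenoid_width > 0")
        if not (self.peak_hu > self.base_plate_hu > self.trabecular_hu > self.soft_tissue_hu):
            raise ValidationError(
                "require peak_hu > base_plate_hu > trabecular_hu > soft_tissue_hu"
            )
        if not -10.0 <= self.inclination_deg <= 25.0:
            raise ValidationError("inclination_deg outside supported range [-10, 25]")
        if not -20.0 <= self.version_deg <= 10.0:
            raise ValidationError("version_deg outside supported range [-20, 10]")
        if self.pattern_vertical not in VERTICAL_PATTERNS:
            raise ValidationError(f"pattern_vertical must be one of {VERTICAL_PATTERNS}")
        if self.pattern_horizontal not in HORIZONTAL_PATTERNS:
            raise ValidationError(
                f"pattern_horizontal must be one of {HORIZONTAL_PATTERNS}"
            )
        if (self.pattern_vertical, self.pattern_horizontal) in CONTRADICTORY_PATTERN_PAIRS:
            raise ValidationError(
                f"pattern pair ({self.pattern_vertical}, {self.pattern_horizontal}) is "
                "contradictory under the quadrant classifier; see "
                "CONTRADICTORY_PATTERN_PAIRS"
            )
        for name in ("plate_thickness", "joint_space", "humeral_head_radius",
                     "fossa_depth", "block_depth", "spine_length",
                     "inferior_angle_drop"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.exostosis_height < 0:
            raise ValidationError("exostosis_height must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    @property
    def spacing(self) -> np.ndarray:
        return np.asarray(self.voxel_spacing, dtype=float)


@dataclass(frozen=True)
class GroundTruth:
    """Exact continuous-geometry truth of a generated phantom."""

    true_inclination_deg: float
    true_version_deg: float
    true_pattern_vertical: str
    true_pattern_horizontal: str
    true_features: RadiologicFeatures
    landmarks: LandmarkSet  # continuous (un-voxelised) coordinates, mm
    spine_axis: np.ndarray
    superior_axis: np.ndarray
    ventral_axis: np.ndarray
    bump_centres: Tuple[Tuple[float, float, float], ...]  # (p, q, amplitude frac)
    spec: PhantomSpec

    def expected_labels(self) -> Tuple[str, str]:
        """Generating labels in the classifier's vocabulary."""
        v = ("physiological_central" if self.true_pattern_vertical == "central"
             else self.true_pattern_vertical)
        h = ("physiological_central_ant_gt_post"
             if self.true_pattern_horizontal == "central_ant_gt_post"
             else self.true_pattern_horizontal)
        return v, h


def _bump_config(spec: PhantomSpec) -> List[Tuple[float, float, float]]:
    """Bump centres ``(p, q)`` in mm and relative amplitudes for the labels.

    ``p`` is the in-fossa ventral->dorsal coordinate (dorsal positive), ``q``
    caudal->cranial.  Pure cranial/caudal/anterior/posterior labels put the
    bump well into the named quadrant (0.55 of the semi-axis, far enough out
    that the central-zone fraction stays clearly below the classifier
    threshold); labels that must keep the central zone dominant use small
    offsets instead; diagonal pairs use two opposite bumps with amplitudes
    weighted by the vertical label.
    """
    a = spec.glenoid_width / 2.0
    b = spec.glenoid_height / 2.0
    C = _PERIPHERAL_OFFSET
    o = _CENTRAL_OFFSET
    v, h = spec.pattern_vertical, spec.pattern_horizontal
    if h == "diagonal":
        amp_cv, amp_cd = {"even": (1.0, 1.0), "cranial": (1.0, 0.72),
                          "caudal": (0.72, 1.0)}[v]
        return [(-C * a, C * b, amp_cv), (C * a, -C * b, amp_cd)]
    if v == "even" and h == "even":
        return []
    # a bump acting on a single axis sits closer to the fossa centre than one
    # pushed into a corner quadrant, so it gets a larger offset to keep the
    # central-zone fraction low
    Cv = C if h != "even" else 0.70
    Ch = C if v != "even" else 0.70
    qc = {"central": o * b, "cranial": Cv * b, "caudal": -Cv * b, "even": 0.0}[v]
    if v == "central" and h == "posterior":
        pc = 0.22 * a
    else:
        pc = {"central_ant_gt_post": -o * a, "anterior": -Ch * a,
              "posterior": Ch * a, "even": 0.0}[h]
    return [(pc, qc, 1.0)]


def _cap_reach(direction: np.ndarray, inward: np.ndarray, r: float,
               half_angle_deg: float) -> float:
    """Max extent of a spherical cap (radius r, axis ``inward``) along a unit
    direction, measured from the sphere centre."""
    psi = math.degrees(math.acos(float(np.clip(np.dot(direction, inward), -1, 1))))
    # solid sector: the apex (sphere centre) bounds the reach from below
    return max(0.0, r * math.cos(math.radians(max(0.0, psi - half_angle_deg))))


def _geometry(spec: PhantomSpec) -> Dict[str, np.ndarray]:
    """Continuous landmark/axis construction; gc placed inside the grid."""
    s = 1.0 if spec.laterality == "right" else -1.0
    # The version rotation is applied after the in-plane inclination rotation,
    # so the scapular-plane projection of the height line sees its inclination
    # scaled by cos(version); pre-compensate the inner angle so the projected
    # (measured) inclination equals the requested value exactly.
    theta = math.degrees(
        math.atan(
            math.tan(math.radians(spec.inclination_deg))
            / math.cos(math.radians(spec.version_deg))
        )
    )
    R = rotation_about_axis([0, 1, 0], -s * spec.version_deg) @ rotation_about_axis(
        [1, 0, 0], -theta
    )
    dorsal = R @ np.array([s, 0.0, 0.0])
    cranial = R @ np.array([0.0, 1.0, 0.0])
    lateral = R @ np.array([0.0, 0.0, 1.0])  # outward fossa normal

    a = spec.glenoid_width / 2.0
    b = spec.glenoid_height / 2.0
    r_h = spec.humeral_head_radius
    theta = spec.cap_half_angle_deg
    inward = -lateral  # cap axis: faces the glenoid

    surf_center_offset = -spec.fossa_depth  # fossa bottom along lateral from gc
    hc_offset = surf_center_offset + spec.joint_space + r_h  # humeral centre

    margin = 2.0 + float(np.max(spec.spacing))
    # extents of the humeral cap from the glenoid centre, per signed axis
    cap_ext = {}
    for axis, e in (("x", [1, 0, 0]), ("y", [0, 1, 0]), ("z", [0, 0, 1])):
        e = np.asarray(e, dtype=float)
        cap_ext[f"+{axis}"] = hc_offset * float(np.dot(lateral, e)) + _cap_reach(
            e, inward, r_h, theta
        )
        cap_ext[f"-{axis}"] = -hc_offset * float(np.dot(lateral, e)) + _cap_reach(
            -e, inward, r_h, theta
        )

    half_x = max(a, b * 0.2, cap_ext["+x"], cap_ext["-x"], spec.exostosis_height + a)
    up_y = max(b, cap_ext["+y"]) + (spec.exostosis_height or 0.0)
    down_y = spec.inferior_angle_drop
    up_z = max(cap_ext["+z"], 0.0)
    down_z = spec.spine_length + spec.block_depth

    need_ext = np.array(
        [2 * (half_x + margin), up_y + down_y + 2 * margin, up_z + down_z + 2 * margin]
    )
    if spec.volume_shape is None:
        shape = tuple(int(math.ceil(need_ext[i] / spec.spacing[i])) for i in range(3))
    else:
        shape = tuple(int(n) for n in spec.volume_shape)
        ext = spec.spacing * np.asarray(shape)
        if np.any(ext + 1e-9 < need_ext):
            raise SizingError(
                f"volume_shape {shape} (extent {tuple(np.round(ext, 1))} mm) cannot "
                f"contain the modelled anatomy (needs {tuple(np.round(need_ext, 1))} mm)"
            )
    ext = spec.spacing * np.asarray(shape)
    gc = np.array(
        [ext[0] / 2.0, ext[1] - margin - up_y, ext[2] - margin - up_z]
    )

    lm = {
        "glenoid_center": gc,
        "rim_A": gc + b * cranial,
        "rim_B": gc - b * cranial,
        "rim_C": gc - a * dorsal,
        "rim_D": gc + a * dorsal,
        "spine_root": gc - spec.spine_length * np.array([0.0, 0.0, 1.0]),
    }
    lm["inferior_angle"] = lm["spine_root"] - spec.inferior_angle_drop * np.array(
        [0.0, 1.0, 0.0]
    )
    hc = gc + hc_offset * lateral
    rim_dist = r_h * math.cos(math.radians(theta))
    rim_rad = r_h * math.sin(math.radians(theta))
    lm["uppermost_A"] = hc + inward * rim_dist + rim_rad * cranial
    lm["lowest_B"] = hc + inward * rim_dist - rim_rad * cranial
    lm["anterior_F"] = hc + inward * rim_dist - rim_rad * dorsal
    lm["posterior_E"] = hc + inward * rim_dist + rim_rad * dorsal

    return {
        "landmarks": lm,
        "dorsal": dorsal,
        "cranial": cranial,
        "lateral": lateral,
        "gc": gc,
        "hc": hc,
        "shape": np.asarray(shape),
        "a": a,
        "b": b,
        "spine_axis": np.array([0.0, 0.0, 1.0]),
        "superior_axis": np.array([0.0, 1.0, 0.0]),
        "ventral_axis": np.array([-s, 0.0, 0.0]),
    }


def _features_from_spec(spec: PhantomSpec) -> RadiologicFeatures:
    return RadiologicFeatures(
        exostosis_height_mm=spec.exostosis_height,
        sclerosis=Sclerosis.SOME if spec.sclerosis else Sclerosis.NONE,
        erosion=Erosion.PRESENT if spec.erosion else Erosion.NONE,
    )


def generate_landmarks(spec: PhantomSpec) -> Tuple[LandmarkSet, GroundTruth]:
    """Continuous landmarks and ground truth without voxelising a volume."""
    g = _geometry(spec)
    continuous = LandmarkSet(points=dict(g["landmarks"]), laterality=spec.laterality)
    gt = GroundTruth(
        true_inclination_deg=spec.inclination_deg,
        true_version_deg=spec.version_deg,
        true_pattern_vertical=spec.pattern_vertical,
        true_pattern_horizontal=spec.pattern_horizontal,
        true_features=_features_from_spec(spec),
        landmarks=continuous,
        spine_axis=g["spine_axis"],
        superior_axis=g["superior_axis"],
        ventral_axis=g["ventral_axis"],
        bump_centres=tuple(_bump_config(spec)),
        spec=spec,
    )
    return continuous, gt


def _snap_to_grid(point: np.ndarray, spacing: np.ndarray, shape: np.ndarray) -> np.ndarray:
    idx = np.round(point / spacing)
    idx = np.clip(idx, 0, shape - 1)
    return idx * spacing


def voxelised_landmarks(spec: PhantomSpec) -> Tuple[LandmarkSet, GroundTruth]:
    """Landmarks snapped to the phantom's voxel grid, without voxelising HU.

    Identical to the landmark set returned by :func:`generate_phantom` (same
    grid, same snapping), at a fraction of the cost; used for angle-recovery
    studies over many phantoms.
    """
    g = _geometry(spec)
    continuous, gt = generate_landmarks(spec)
    snapped = LandmarkSet(
        points={
            name: _snap_to_grid(pt, spec.spacing, g["shape"])
            for name, pt in continuous.points.items()
        },
        laterality=spec.laterality,
    )
    return snapped, gt


def generate_phantom(
    spec: PhantomSpec, features: Optional[RadiologicFeatures] = None
) -> Tuple[Volume, LandmarkSet, GroundTruth]:
    """Build one phantom: HU volume, voxel-snapped landmarks, ground truth.

    The returned :class:`LandmarkSet` is snapped to voxel centres, emulating
    landmarks picked on the image; exact continuous coordinates live in
    ``GroundTruth.landmarks``.  ``features`` optionally replaces the
    ground-truth radiological features derived from the spec's OA dials (the
    volume rendering still follows the spec).
    """
    g = _geometry(spec)
    shape = g["shape"]
    sp = spec.spacing
    gc, hc = g["gc"], g["hc"]
    dorsal, cranial, lateral = g["dorsal"], g["cranial"], g["lateral"]
    a, b = g["a"], g["b"]
    d0, t = spec.fossa_depth, spec.plate_thickness

    xs = (np.arange(shape[0], dtype=np.float32) * sp[0])[:, None, None]
    ys = (np.arange(shape[1], dtype=np.float32) * sp[1])[None, :, None]
    zs = (np.arange(shape[2], dtype=np.float32) * sp[2])[None, None, :]

    def coord(axis_vec: np.ndarray, center: np.ndarray) -> np.ndarray:
        return (
            (xs - center[0]) * np.float32(axis_vec[0])
            + (ys - center[1]) * np.float32(axis_vec[1])
            + (zs - center[2]) * np.float32(axis_vec[2])
        )

    p = coord(dorsal, gc)
    q = coord(cranial, gc)
    s = coord(lateral, gc)

    e = (p / np.float32(a)) ** 2 + (q / np.float32(b)) ** 2
    in_ellipse = e <= 1.0
    s_surf = np.float32(-d0) * (1.0 - e)
    plate = in_ellipse & (s <= s_surf) & (s > s_surf - np.float32(t))
    block = (
        in_ellipse
        & (s <= s_surf - np.float32(t))
        & (s > s_surf - np.float32(t + spec.block_depth))
    )

    lm = g["landmarks"]
    blade = (
        (np.abs(xs - gc[0]) <= 1.5)
        & (ys >= lm["inferior_angle"][1])
        & (ys <= gc[1] + b)
        & (zs >= lm["spine_root"][2] - 2.0)
        & (zs <= gc[2] - (d0 + t + spec.block_depth + 1.0))
    )
    blade = np.broadcast_to(blade, tuple(shape)).copy()

    hu = np.full(tuple(shape), np.float32(spec.soft_tissue_hu), dtype=np.float32)
    hu[blade] = spec.trabecular_hu
    hu[block] = spec.trabecular_hu

    plate_hu = np.float32(spec.base_plate_hu) + (
        np.float32(spec.sclerosis_boost_hu) if spec.sclerosis else np.float32(0.0)
    )
    bumps = _bump_config(spec)
    if bumps:
        sigma = 0.25 * spec.glenoid_width
        amp = spec.peak_hu - spec.base_plate_hu
        pv, qv = p[plate], q[plate]
        field = np.zeros_like(pv)
        for pc, qc, frac in bumps:
            field += np.float32(amp * frac) * np.exp(
                -(((pv - np.float32(pc)) ** 2 + (qv - np.float32(qc)) ** 2)
                  / np.float32(2 * sigma**2))
            )
        hu[plate] = plate_hu + field
    else:
        hu[plate] = plate_hu

    if spec.erosion:
        er = plate & (
            (p - np.float32(0.5 * a)) ** 2 + (q - np.float32(0.5 * b)) ** 2
            <= np.float32((0.3 * a) ** 2)
        )
        hu[er] = spec.soft_tissue_hu
        plate = plate & ~er

    # humeral head: sphere cap facing the glenoid, cortical shell + trabecular core
    dist = np.sqrt(coord([1, 0, 0], hc) ** 2 + coord([0, 1, 0], hc) ** 2
                   + coord([0, 0, 1], hc) ** 2)
    along = -coord(lateral, hc)  # component towards the glenoid
    cos_cap = np.float32(math.cos(math.radians(spec.cap_half_angle_deg)))
    cap = (dist <= spec.humeral_head_radius) & (along >= dist * cos_cap)
    shell = cap & (dist >= spec.humeral_head_radius - t)
    hu[cap & ~shell] = spec.trabecular_hu
    hu[shell] = spec.base_plate_hu

    exo = None
    if spec.exostosis_height > 0:
        centre = lm["rim_B"] - (spec.exostosis_height / 2.0) * cranial
        exo = (
            coord([1, 0, 0], centre) ** 2
            + coord([0, 1, 0], centre) ** 2
            + coord([0, 0, 1], centre) ** 2
        ) <= np.float32((spec.exostosis_height / 2.0) ** 2)
        hu[exo] = spec.base_plate_hu

    bone = blade | block | plate | cap
    if exo is not None:
        bone = bone | exo
    edge = np.zeros(tuple(shape), dtype=bool)
    edge[0, :, :] = edge[-1, :, :] = True
    edge[:, 0, :] = edge[:, -1, :] = True
    edge[:, :, 0] = edge[:, :, -1] = True
    if np.any(bone & edge):
        raise SizingError(
            "modelled anatomy touches the volume boundary; enlarge volume_shape"
        )

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu += rng.normal(0.0, spec.noise_sd, size=hu.shape).astype(np.float32)

    volume = Volume(voxels=hu, spacing=sp, origin=np.zeros(3),
                    laterality=spec.laterality)

    continuous, gt = generate_landmarks(spec)
    if features is not None:
        gt = replace(gt, true_features=features)
    snapped = LandmarkSet(
        points={
            name: _snap_to_grid(pt, sp, shape) for name, pt in continuous.points.items()
        },
        laterality=spec.laterality,
    )
    return volume, snapped, gt


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class Specimen:
    donor: str
    sex: str
    side: str
    spec: PhantomSpec
    ground_truth: GroundTruth
    landmarks: LandmarkSet  # voxel-snapped
    volume: Optional[Volume] = None


@dataclass
class CohortResult:
    specimens: List[Specimen]
    table: pd.DataFrame


#: Sampling distributions emulating the study population: angle means/SDs and
#: observed ranges, pattern frequencies and OA-grade frequencies as reported
#: for the 19-donor, 38-shoulder cohort.
DEFAULT_DISTRIBUTIONS: Dict[str, object] = {
    "inclination": {"mean": 8.4, "sd": 4.9, "lo": 0.5, "hi": 19.8},
    "version": {"mean": -5.2, "sd": 4.2, "lo": -15.9, "hi": 3.8},
    "pattern_vertical_probs": {"central": 23 / 38, "cranial": 10 / 38, "caudal": 5 / 38},
    "pattern_horizontal_probs": {
        "central_ant_gt_post": 16 / 38,
        "posterior": 18 / 38,
        "anterior": 1 / 38,
        "diagonal": 1 / 38,
        "even": 2 / 38,
    },
    "grade_probs": {"0": 11 / 38, "I": 9 / 38, "II": 5 / 38, "III": 8 / 38, "IV": 5 / 38},
    "female_fraction": 10 / 19,
}

_GRADE_TOTALS = {"0": (0,), "I": (1, 2), "II": (3, 4), "III": (5, 7), "IV": (8, 9)}


def _features_for_grade(grade: str, rng: np.random.Generator) -> RadiologicFeatures:
    """Sample a feature set whose composite score lands in the given grade."""
    lo, hi = _GRADE_TOTALS[grade][0], _GRADE_TOTALS[grade][-1]
    total = int(rng.integers(lo, hi + 1))
    kl = min(3, total)
    rem = total - kl
    sam = min(3, rem)
    lar = total - kl - sam
    height = {0: 0.0, 1: 2.0, 2: 5.0, 3: 8.0}[sam]
    feats = RadiologicFeatures(
        osteophytes=Osteophytes(kl),
        joint_space=JointSpace(kl),
        sclerosis=Sclerosis(min(2, max(0, kl - 1))),
        exostosis_height_mm=height,
        erosion=Erosion.PRESENT if lar >= 1 else Erosion.NONE,
        destruction=Destruction(lar),
    )
    assert composite_score(feats).grade == grade
    return feats


def _sample_clipped(rng: np.random.Generator, dist: Dict[str, object]) -> float:
    """Draw an angle: either from an explicit ``values`` list, or from a
    normal distribution clipped to the observed range."""
    if "values" in dist:
        values = list(dist["values"])  # type: ignore[arg-type]
        if not values:
            raise ValidationError("distribution 'values' list is empty")
        return float(rng.choice(values))
    if dist["lo"] > dist["hi"]:  # type: ignore[operator]
        raise ValidationError("distribution range is empty (lo > hi)")
    return float(np.clip(rng.normal(dist["mean"], dist["sd"]), dist["lo"], dist["hi"]))


def _patterns_from_rule(incl: float, vers: float, rule: Dict[str, object]) -> Tuple[str, str]:
    """Assign pattern labels consistently with angle ranges.

    A shoulder whose angle lies inside the rule's physiological range gets the
    physiological label on that axis; outside, a different label.  Labels are
    chosen so every produced pair is realizable by the generator.  With
    ``basis: "measured"`` the rule is applied to the angles measured from the
    voxel-snapped landmarks rather than the continuous ground truth, so the
    pattern/angle separation is exact with respect to downstream analysis.
    """
    inc_max = float(rule.get("inclination_max", 10.0))
    v_lo, v_hi = rule.get("version_range", (-8.0, -4.0))
    in_i = 0.0 <= incl <= inc_max
    in_v = float(v_lo) <= vers <= float(v_hi)
    if in_i and in_v:
        return "central", "central_ant_gt_post"
    if in_i:
        return "central", ("posterior" if vers < v_lo else "even")
    if in_v:
        return "even", "central_ant_gt_post"
    v = "cranial" if incl > inc_max else "caudal"
    return v, ("posterior" if vers < v_lo else "even")


def _sample_patterns(rng: np.random.Generator, dists: Dict[str, object]) -> Tuple[str, str]:
    vp: Dict[str, float] = dict(dists["pattern_vertical_probs"])  # type: ignore[arg-type]
    hp: Dict[str, float] = dict(dists["pattern_horizontal_probs"])  # type: ignore[arg-type]
    if not vp or not hp:
        raise ValidationError("pattern probability tables must be non-empty")
    vnames = sorted(vp)
    v = str(rng.choice(vnames, p=np.array([vp[k] for k in vnames]) / sum(vp.values())))
    allowed = {k: w for k, w in hp.items() if (v, k) not in CONTRADICTORY_PATTERN_PAIRS}
    hnames = sorted(allowed)
    weights = np.array([allowed[k] for k in hnames], dtype=float)
    h = str(rng.choice(hnames, p=weights / weights.sum()))
    return v, h


def iter_cohort(
    n: int,
    spec_distributions: Optional[Dict[str, object]] = None,
    seed: int = 0,
    base_spec: Optional[PhantomSpec] = None,
    make_volumes: bool = True,
):
    """Yield ``Specimen`` records for ``n`` donors (left and right shoulders).

    Deterministic given ``seed``: all random draws come from one generator in
    a fixed per-specimen field order (inclination, version, patterns, grade,
    noise seed).
    """
    if n < 1:
        raise ValidationError("cohort size n must be >= 1")
    dists = dict(DEFAULT_DISTRIBUTIONS)
    if spec_distributions:
        dists.update(spec_distributions)
    base = base_spec if base_spec is not None else PhantomSpec()
    rng = np.random.default_rng(seed)
    n_female = int(round(float(dists["female_fraction"]) * n))
    gp: Dict[str, float] = dict(dists["grade_probs"])  # type: ignore[arg-type]
    gnames = sorted(gp)
    gweights = np.array([gp[k] for k in gnames], dtype=float)
    gweights = gweights / gweights.sum()
    for d in range(n):
        donor = f"D{d + 1:02d}"
        sex = "female" if d < n_female else "male"
        for side in ("left", "right"):
            incl = _sample_clipped(rng, dists["inclination"])  # type: ignore[arg-type]
            vers = _sample_clipped(rng, dists["version"])  # type: ignore[arg-type]
            rule = dists.get("pattern_rule")
            if rule is not None:
                rule_i, rule_v = incl, vers
                if rule.get("basis", "true") == "measured":  # type: ignore[union-attr]
                    from . import geometry

                    probe = replace(base, laterality=side,
                                    inclination_deg=round(incl, 6),
                                    version_deg=round(vers, 6))
                    probe_lm, _ = voxelised_landmarks(probe)
                    rule_i = geometry.inclination_angle(probe_lm).alpha_deg
                    rule_v = geometry.version_angle(probe_lm).beta_deg
                v, h = _patterns_from_rule(rule_i, rule_v, rule)  # type: ignore[arg-type]
                _sample_patterns(rng, dists)  # keep the draw order stable
            else:
                v, h = _sample_patterns(rng, dists)
            grade = str(rng.choice(gnames, p=gweights))
            feats = _features_for_grade(grade, rng)
            noise_seed = int(rng.integers(0, 2**31 - 1))
            spec = replace(
                base,
                laterality=side,
                inclination_deg=round(incl, 6),
                version_deg=round(vers, 6),
                pattern_vertical=v,
                pattern_horizontal=h,
                exostosis_height=feats.exostosis_height_mm,
                sclerosis=feats.sclerosis > Sclerosis.NONE,
                erosion=feats.erosion > Erosion.NONE,
                seed=noise_seed,
            )
            if make_volumes:
                volume, snapped, gt = generate_phantom(spec, features=feats)
            else:
                volume = None
                continuous, gt = generate_landmarks(spec)
                gt = replace(gt, true_features=feats)
                shape = _geometry(spec)["shape"]
                snapped = LandmarkSet(
                    points={
                        name: _snap_to_grid(pt, spec.spacing, shape)
                        for name, pt in continuous.points.items()
                    },
                    laterality=side,
                )
            yield Specimen(
                donor=donor, sex=sex, side=side, spec=spec,
                ground_truth=gt, landmarks=snapped, volume=volume,
            )


def generate_cohort(
    n: int,
    spec_distributions: Optional[Dict[str, object]] = None,
    seed: int = 0,
    base_spec: Optional[PhantomSpec] = None,
    keep_volumes: bool = True,
) -> CohortResult:
    """Generate a full synthetic cohort: ``2 n`` shoulders plus a truth table.

    With ``keep_volumes=False`` only landmarks and ground truth are built
    (volumes are regenerable from each specimen's spec), which keeps large
    cohorts cheap.
    """
    specimens = list(
        iter_cohort(n, spec_distributions, seed, base_spec, make_volumes=keep_volumes)
    )
    rows = []
    for sp in specimens:
        score = composite_score(sp.ground_truth.true_features)
        rows.append(
            {
                "donor": sp.donor,
                "sex": sp.sex,
                "side": sp.side,
                "true_inclination_deg": sp.ground_truth.true_inclination_deg,
                "true_version_deg": sp.ground_truth.true_version_deg,
                "pattern_vertical": sp.ground_truth.true_pattern_vertical,
                "pattern_horizontal": sp.ground_truth.true_pattern_horizontal,
                "kl": score.kl_points,
                "samilson": score.samilson_points,
                "larsen": score.larsen_points,
                "total": score.total,
                "grade": score.grade,
            }
        )
    return CohortResult(specimens=specimens, table=pd.DataFrame(rows))
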