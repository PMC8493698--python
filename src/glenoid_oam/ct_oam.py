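"""CT-osteoabsorptiometry: subchondral mineralisation mapping of the glenoid.

The chain is: threshold the volume to bone (``segment_bone``), extract the
lateral-facing articular surface of the glenoid within the rim quadrilateral
(``extract_articular_surface``), project the maximal HU found within a fixed
depth below each surface point onto the surface (``subchondral_mip``),
false-colour encode the map into the conventional 8 ordered bins
(``false_colour_encode``), and summarise/classify the distribution of
high-density pixels by quadrants (``quadrant_summary`` / ``classify_pattern``).

The density map is parameterised on the rim plane: ``u`` runs ventral ->
dorsal (dorsal positive), ``v`` caudal -> cranial, with the glenoid centre at
the origin.  Because the axes are anatomical, maps of left and right shoulders
are directly comparable (left maps are implicitly mirrored).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.ndimage import map_coordinates

from ._utils import unit
from .errors import ExtractionError, ValidationError
from .geometry import ScapularFrame
from .io import LandmarkSet, Volume

__all__ = [
    "BoneMask",
    "SurfacePatch",
    "DensityMap",
    "QuadrantSummary",
    "PatternLabel",
    "segment_bone",
    "extract_articular_surface",
    "subchondral_mip",
    "false_colour_encode",
    "quadrant_summary",
    "classify_pattern",
    "compute_density_map",
    "save_density_map",
    "render_density_map",
    "HU_EDGES",
    "COLOUR_NAMES",
]

#: Interior bin edges: six equal-width bins across [200, 1200] HU plus the two
#: open tails gives the conventional 8 colour bins.
HU_EDGES = tuple(200.0 + i * (1000.0 / 6.0) for i in range(7))
COLOUR_NAMES = (
    "violet", "blue", "dark green", "bright green", "yellow", "orange", "red", "black",
)
#: Matplotlib-friendly palette, bin 1 (lowest HU) .. bin 8 (highest).
COLOUR_HEX = (
    "#7f00ff", "#0040ff", "#006400", "#40ff40", "#ffff00", "#ff9900", "#ff0000",
    "#000000",
)

VERTICAL_LABELS = ("physiological_central", "cranial", "caudal", "even")
HORIZONTAL_LABELS = (
    "physiological_central_ant_gt_post", "anterior", "posterior", "diagonal", "even",
)
QUADRANTS = ("cranial_ventral", "cranial_dorsal", "caudal_ventral", "caudal_dorsal")
_DIAGONAL_PAIRS = (
    frozenset(("cranial_ventral", "caudal_dorsal")),
    frozenset(("cranial_dorsal", "caudal_ventral")),
)


@dataclass
class BoneMask:
    """Binary bone segmentation of a volume with the HU window used."""

    mask: np.ndarray
    lo: float
    hi: float
    spacing: np.ndarray
    origin: np.ndarray

    @property
    def count(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass
class SurfacePatch:
    """Triangulated articular surface as a height field over the rim plane."""

    vertices: np.ndarray  # (N, 3) mm
    inward_normals: np.ndarray  # (N, 3) unit, pointing into the bone
    faces: np.ndarray  # (M, 3) vertex indices
    uv: np.ndarray  # (N, 2) parameter coords of each vertex
    u_coords: np.ndarray  # (nu,) grid u values (dorsal positive)
    v_coords: np.ndarray  # (nv,) grid v values (cranial positive)
    valid: np.ndarray  # (nu, nv) bool
    vertex_index: np.ndarray  # (nu, nv) int, -1 where invalid
    u_axis: np.ndarray  # unit vector, ventral -> dorsal
    v_axis: np.ndarray  # unit vector, caudal -> cranial
    normal_axis: np.ndarray  # unit vector, nominal outward (lateral)
    origin: np.ndarray  # glenoid centre, mm
    half_extents: Tuple[float, float]  # (a, b): rim half width / half height
    laterality: str = "unknown"

    @property
    def area_mm2(self) -> float:
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return float(np.linalg.norm(cross, axis=1).sum() / 2.0)


@dataclass
class DensityMap:
    """Subchondral maximum-intensity projection over the articular surface."""

    values: np.ndarray  # (nu, nv) HU, nan where invalid
    valid: np.ndarray  # (nu, nv) bool
    u_coords: np.ndarray
    v_coords: np.ndarray
    depth_mm: float
    half_extents: Tuple[float, float]
    laterality: str = "unknown"
    colour_bins: Optional[np.ndarray] = None  # (nu, nv) int in 1..8, 0 invalid
    hu_edges: Tuple[float, ...] = HU_EDGES


@dataclass(frozen=True)
class QuadrantSummary:
    """Distribution of high-density pixels over the articular surface."""

    quadrant_fractions: Dict[str, float]
    central_fraction: float
    half_fractions: Dict[str, float]  # cranial/caudal/ventral/dorsal
    cutoff_hu: float
    n_high: int
    no_maxima: bool


@dataclass(frozen=True)
class PatternLabel:
    vertical: str
    horizontal: str
    overall_physiological: bool

    def __post_init__(self):
        if self.vertical not in VERTICAL_LABELS:
            raise ValidationError(f"vertical label {self.vertical!r} invalid")
        if self.horizontal not in HORIZONTAL_LABELS:
            raise ValidationError(f"horizontal label {self.horizontal!r} invalid")
        expected = (
            self.vertical == "physiological_central"
            and self.horizontal == "physiological_central_ant_gt_post"
        )
        if self.overall_physiological != expected:
            raise ValidationError(
                "overall_physiological must hold exactly when both axes are physiological"
            )


def segment_bone(volume: Volume, lo: float = 300.0, hi: float = 2000.0) -> BoneMask:
    """Threshold segmentation of bone: ``lo <= HU <= hi``."""
    if not lo < hi:
        raise ValidationError("segmentation window requires lo < hi")
    mask = (volume.voxels >= lo) & (volume.voxels <= hi)
    if not mask.any():
        warnings.warn(
            f"bone segmentation [{lo}, {hi}] HU selected no voxels", stacklevel=2
        )
    return BoneMask(
        mask=mask, lo=float(lo), hi=float(hi),
        spacing=volume.spacing.copy(), origin=volume.origin.copy(),
    )


def _rim_frame(landmarks: LandmarkSet):
    """Anatomical in-fossa axes from the rim extremes."""
    h_vec = landmarks["rim_A"] - landmarks["rim_B"]  # caudal -> cranial
    w_vec = landmarks["rim_D"] - landmarks["rim_C"]  # ventral -> dorsal
    u_axis = unit(w_vec)
    v_axis = unit(h_vec - np.dot(h_vec, u_axis) * u_axis)  # keeps cranial sign
    n_axis = unit(np.cross(u_axis, v_axis))
    # orient the ray axis outward (lateral): away from the spine root
    if np.dot(n_axis, landmarks["glenoid_center"] - landmarks["spine_root"]) < 0:
        n_axis = -n_axis
    a = float(np.linalg.norm(w_vec)) / 2.0
    b = float(np.linalg.norm(h_vec)) / 2.0
    return u_axis, v_axis, n_axis, a, b


def _sample_grid(arr: np.ndarray, points_mm: np.ndarray, spacing: np.ndarray,
                 origin: np.ndarray, fill: float = 0.0):
    """Trilinear sampling at physical points; returns values and in-bounds flags."""
    idx = (points_mm - origin) / spacing  # (..., 3)
    nx, ny, nz = arr.shape
    inb = (
        (idx[..., 0] >= 0) & (idx[..., 0] <= nx - 1)
        & (idx[..., 1] >= 0) & (idx[..., 1] <= ny - 1)
        & (idx[..., 2] >= 0) & (idx[..., 2] <= nz - 1)
    )
    coords = np.moveaxis(idx, -1, 0)
    vals = map_coordinates(arr, coords, order=1, mode="constant", cval=fill)
    return vals, inb


def extract_articular_surface(
    mask: BoneMask,
    landmarks: LandmarkSet,
    pixel_mm: Optional[float] = None,
    search_above_mm: float = 1.2,
    search_below_mm: float = 8.0,
) -> SurfacePatch:
    """Extract the lateral-facing glenoid surface within the rim quadrilateral.

    For every pixel of a regular grid on the rim plane, a ray is marched from
    lateral to medial; the surface is the highest bone-entering crossing that
    does not lie above the rim plane (which excludes the humeral head).  The
    patch is returned as a triangulated height field with inward unit normals.
    """
    if not mask.mask.any():
        raise ExtractionError("bone mask is empty; no articular surface to extract")
    u_axis, v_axis, n_axis, a, b = _rim_frame(landmarks)
    gc = landmarks["glenoid_center"]
    step = 0.25 * float(np.min(mask.spacing))
    px = float(pixel_mm) if pixel_mm is not None else float(np.min(mask.spacing))

    nu = max(4, int(round(2 * a / px)))
    nv = max(4, int(round(2 * b / px)))
    u = (np.arange(nu) + 0.5) * px - a
    v = (np.arange(nv) + 0.5) * px - b

    s_hi = float(search_above_mm)
    s_lo = -float(search_below_mm)
    n_steps = int(np.ceil((s_hi - s_lo) / step)) + 1
    svals = s_hi - np.arange(n_steps) * step  # lateral -> medial

    U, V = np.meshgrid(u, v, indexing="ij")
    base = gc + U[..., None] * u_axis + V[..., None] * v_axis  # (nu, nv, 3)
    pts = base[:, :, None, :] + svals[None, None, :, None] * n_axis
    maskf = mask.mask.astype(np.float32)
    vals, inb = _sample_grid(maskf, pts, mask.spacing, mask.origin, fill=0.0)
    vals = np.where(inb, vals, 0.0)

    inside = vals >= 0.5
    entering = inside[:, :, 1:] & ~inside[:, :, :-1]  # crossing while marching medially
    # exclude crossings above the rim plane (humeral head side)
    s_margin = 0.75 * float(np.max(mask.spacing))
    cross_s = svals[1:]  # s of the first inside sample of each crossing
    allowed = entering & (cross_s[None, None, :] <= s_margin)

    any_cross = allowed.any(axis=2)
    first = np.argmax(allowed, axis=2)  # first (most lateral) allowed crossing
    # sub-step refinement: linear interpolation of the 0.5 level
    i0 = first
    i1 = first + 1
    f0 = np.take_along_axis(vals, i0[..., None], axis=2)[..., 0]
    f1 = np.take_along_axis(vals, i1[..., None], axis=2)[..., 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(f1 > f0, (0.5 - f0) / (f1 - f0), 0.5)
    frac = np.clip(frac, 0.0, 1.0)
    height = svals[i0] - frac * step

    ellipse = (U / a) ** 2 + (V / b) ** 2 <= 1.0
    valid = any_cross & ellipse
    if not valid.any():
        raise ExtractionError(
            "no bone boundary found within the rim region; cannot extract surface"
        )
    height = np.where(valid, height, np.nan)

    # normals from the height-field gradient (central differences on valid pixels)
    hu_grad = np.zeros_like(height)
    hv_grad = np.zeros_like(height)
    hfill = np.where(valid, height, 0.0)
    gu, gv = np.gradient(hfill, px, px)
    hu_grad = np.where(valid, gu, 0.0)
    hv_grad = np.where(valid, gv, 0.0)
    # damp gradients at the border of validity, where differences are unreliable
    core = valid.copy()
    core[1:, :] &= valid[:-1, :]
    core[:-1, :] &= valid[1:, :]
    core[:, 1:] &= valid[:, :-1]
    core[:, :-1] &= valid[:, 1:]
    hu_grad = np.where(core, hu_grad, 0.0)
    hv_grad = np.where(core, hv_grad, 0.0)

    outward = (
        -hu_grad[..., None] * u_axis - hv_grad[..., None] * v_axis
        + np.ones_like(height)[..., None] * n_axis
    )
    outward /= np.linalg.norm(outward, axis=-1, keepdims=True)
    inward = -outward

    vertex_index = np.full((nu, nv), -1, dtype=int)
    ii, jj = np.nonzero(valid)
    vertex_index[ii, jj] = np.arange(ii.size)
    vertices = base[ii, jj] + height[ii, jj, None] * n_axis
    normals = inward[ii, jj]
    uv = np.stack([U[ii, jj], V[ii, jj]], axis=1)

    faces = _grid_faces(vertex_index)

    return SurfacePatch(
        vertices=vertices,
        inward_normals=normals,
        faces=faces,
        uv=uv,
        u_coords=u,
        v_coords=v,
        valid=valid,
        vertex_index=vertex_index,
        u_axis=u_axis,
        v_axis=v_axis,
        normal_axis=n_axis,
        origin=np.asarray(gc, dtype=float),
        half_extents=(a, b),
        laterality=landmarks.laterality,
    )


def _grid_faces(vertex_index: np.ndarray) -> np.ndarray:
    """Two triangles per fully-valid grid cell."""
    v00 = vertex_index[:-1, :-1]
    v10 = vertex_index[1:, :-1]
    v01 = vertex_index[:-1, 1:]
    v11 = vertex_index[1:, 1:]
    ok = (v00 >= 0) & (v10 >= 0) & (v01 >= 0) & (v11 >= 0)
    t1 = np.stack([v00[ok], v10[ok], v11[ok]], axis=1)
    t2 = np.stack([v00[ok], v11[ok], v01[ok]], axis=1)
    if t1.size == 0:
        return np.zeros((0, 3), dtype=int)
    return np.concatenate([t1, t2], axis=0)


def subchondral_mip(
    volume: Volume,
    surface: SurfacePatch,
    depth: float = 3.0,
    step: Optional[float] = None,
) -> DensityMap:
    """Maximum HU along the inward normal over ``[0, depth]`` mm per pixel.

    Sampling is trilinear at a step of a quarter of the minimum voxel spacing
    (or ``step``); a pixel whose ray leaves the volume is marked invalid.
    """
    if depth <= 0:
        raise ValidationError("projection depth must be positive")
    if step is None:
        step = 0.25 * float(np.min(volume.spacing))
    n_steps = max(2, int(np.floor(depth / step)) + 1)
    ts = np.linspace(0.0, depth, n_steps)

    pts = (
        surface.vertices[:, None, :]
        + ts[None, :, None] * surface.inward_normals[:, None, :]
    )
    arr = np.asarray(volume.voxels, dtype=np.float32)
    vals, inb = _sample_grid(arr, pts, volume.spacing, volume.origin, fill=np.nan)
    ray_ok = inb.all(axis=1)
    vmax = vals.max(axis=1)

    nu, nv = surface.valid.shape
    values = np.full((nu, nv), np.nan)
    valid = np.zeros((nu, nv), dtype=bool)
    ii, jj = np.nonzero(surface.valid)
    values[ii, jj] = np.where(ray_ok, vmax, np.nan)
    valid[ii, jj] = ray_ok
    return DensityMap(
        values=values,
        valid=valid,
        u_coords=surface.u_coords,
        v_coords=surface.v_coords,
        depth_mm=float(depth),
        half_extents=surface.half_extents,
        laterality=surface.laterality,
    )


def false_colour_encode(dmap: DensityMap, edges: Tuple[float, ...] = HU_EDGES) -> DensityMap:
    """Assign the 8 ordered colour bins (1 = violet/lowest .. 8 = black/highest).

    Bins are half-open with the lower edge inclusive: HU < 200 is bin 1,
    HU >= 1200 is bin 8.
    """
    edges_arr = np.asarray(edges, dtype=float)
    if edges_arr.ndim != 1 or np.any(np.diff(edges_arr) <= 0):
        raise ValidationError("edges must be strictly increasing")
    vals = np.where(dmap.valid, dmap.values, 0.0)
    bins = 1 + np.searchsorted(edges_arr, vals, side="right")
    bins = np.where(dmap.valid, bins, 0).astype(int)
    return replace(dmap, colour_bins=bins, hu_edges=tuple(edges_arr))


def quadrant_summary(
    dmap: DensityMap,
    frame: Optional[ScapularFrame] = None,
    min_bin: int = 7,
) -> QuadrantSummary:
    """Fractions of high-density pixels per quadrant, halves and central zone.

    High density means colour bin >= ``min_bin`` (default 7, i.e. HU at or
    above the penultimate edge).  The quadrant axes are the map's anatomical
    parameterisation (``frame`` is accepted for API symmetry; the map already
    carries the anatomical axes of the surface it was projected from).
    """
    del frame
    if dmap.colour_bins is None:
        dmap = false_colour_encode(dmap)
    cutoff = float(dmap.hu_edges[min_bin - 2]) if min_bin >= 2 else -np.inf
    high = dmap.valid & (dmap.colour_bins >= min_bin)
    n_high = int(np.count_nonzero(high))

    U, V = np.meshgrid(dmap.u_coords, dmap.v_coords, indexing="ij")
    a, b = dmap.half_extents
    if n_high == 0:
        zero_q = {q: 0.0 for q in QUADRANTS}
        return QuadrantSummary(
            quadrant_fractions=zero_q,
            central_fraction=0.0,
            half_fractions={"cranial": 0.0, "caudal": 0.0, "ventral": 0.0, "dorsal": 0.0},
            cutoff_hu=cutoff,
            n_high=0,
            no_maxima=True,
        )
    ventral = U < 0
    cranial = V > 0
    quad_masks = {
        "cranial_ventral": cranial & ventral,
        "cranial_dorsal": cranial & ~ventral,
        "caudal_ventral": ~cranial & ventral,
        "caudal_dorsal": ~cranial & ~ventral,
    }
    qf = {name: float(np.count_nonzero(high & m)) / n_high for name, m in quad_masks.items()}
    central = (U / (0.5 * a)) ** 2 + (V / (0.5 * b)) ** 2 <= 1.0
    cf = float(np.count_nonzero(high & central)) / n_high
    hf = {
        "cranial": qf["cranial_ventral"] + qf["cranial_dorsal"],
        "caudal": qf["caudal_ventral"] + qf["caudal_dorsal"],
        "ventral": qf["cranial_ventral"] + qf["caudal_ventral"],
        "dorsal": qf["cranial_dorsal"] + qf["caudal_dorsal"],
    }
    return QuadrantSummary(
        quadrant_fractions=qf,
        central_fraction=cf,
        half_fractions=hf,
        cutoff_hu=cutoff,
        n_high=n_high,
        no_maxima=False,
    )


def classify_pattern(
    summary: QuadrantSummary,
    tau_even: float = 0.10,
    tau_central: float = 0.40,
    diagonal_min: float = 0.30,
) -> PatternLabel:
    """Classify the mineralisation distribution on both anatomical axes.

    Vertical: "even" when cranial and caudal halves differ by less than
    ``tau_even``; otherwise physiological (predominantly central) when the
    central-zone fraction reaches ``tau_central``; otherwise the larger half.
    Horizontal: "diagonal" when the two largest quadrant fractions form a
    diagonally opposite pair, each at least ``diagonal_min`` (tested first,
    since a diagonal pattern balances both half splits); then the same
    even / physiological (with anterior >= posterior) / larger-half ladder.
    """
    if summary.no_maxima:
        return PatternLabel(vertical="even", horizontal="even",
                            overall_physiological=False)
    hf = summary.half_fractions
    cf = summary.central_fraction

    if abs(hf["cranial"] - hf["caudal"]) < tau_even:
        vertical = "even"
    elif cf >= tau_central:
        vertical = "physiological_central"
    else:
        vertical = "cranial" if hf["cranial"] > hf["caudal"] else "caudal"

    qf = summary.quadrant_fractions
    order = sorted(qf, key=qf.get, reverse=True)
    top_pair = frozenset(order[:2])
    if top_pair in _DIAGONAL_PAIRS and all(qf[name] >= diagonal_min for name in top_pair):
        horizontal = "diagonal"
    elif abs(hf["ventral"] - hf["dorsal"]) < tau_even:
        horizontal = "even"
    elif cf >= tau_central and hf["ventral"] >= hf["dorsal"]:
        horizontal = "physiological_central_ant_gt_post"
    else:
        horizontal = "anterior" if hf["ventral"] > hf["dorsal"] else "posterior"

    overall = (
        vertical == "physiological_central"
        and horizontal == "physiological_central_ant_gt_post"
    )
    return PatternLabel(
        vertical=vertical, horizontal=horizontal, overall_physiological=overall
    )


def compute_density_map(
    volume: Volume,
    landmarks: LandmarkSet,
    depth: float = 3.0,
    lo: float = 300.0,
    hi: float = 2000.0,
    pixel_mm: Optional[float] = None,
) -> DensityMap:
    """Convenience chain: segment -> surface -> MIP -> colour encode."""
    mask = segment_bone(volume, lo=lo, hi=hi)
    surface = extract_articular_surface(mask, landmarks, pixel_mm=pixel_mm)
    dmap = subchondral_mip(volume, surface, depth=depth)
    return false_colour_encode(dmap)


def save_density_map(dmap: DensityMap, path_prefix) -> Tuple[Path, Path]:
    """Persist a map as a CSV value grid plus a JSON metadata sidecar."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = prefix.with_suffix(".csv")
    np.savetxt(csv_path, dmap.values, delimiter=",", fmt="%.2f")
    meta = {
        "depth_mm": dmap.depth_mm,
        "hu_edges": list(dmap.hu_edges),
        "u_coords_mm": [float(x) for x in dmap.u_coords],
        "v_coords_mm": [float(x) for x in dmap.v_coords],
        "half_extents_mm": [float(x) for x in dmap.half_extents],
        "laterality": dmap.laterality,
    }
    json_path = prefix.with_suffix(".json")
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")
    return csv_path, json_path


def render_density_map(dmap: DensityMap, path) -> Path:
    """Render the 8-colour false-colour map to a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    if dmap.colour_bins is None:
        dmap = false_colour_encode(dmap)
    cmap = ListedColormap(COLOUR_HEX)
    norm = BoundaryNorm(np.arange(0.5, 9.5), cmap.N)
    fig, ax = plt.subplots(figsize=(4, 5))
    shown = np.where(dmap.valid, dmap.colour_bins, np.nan)
    ax.imshow(
        shown.T,
        origin="lower",
        cmap=cmap,
        norm=norm,
        extent=(
            float(dmap.u_coords[0]), float(dmap.u_coords[-1]),
            float(dmap.v_coords[0]), float(dmap.v_coords[-1]),
        ),
    )
    ax.set_xlabel("u (ventral → dorsal, mm)")
    ax.set_ylabel("v (caudal → cranial, mm)")
    ax.set_title(f"CT-OAM density map ({dmap.laterality})")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
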