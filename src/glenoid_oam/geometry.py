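"""Scapular frame, glenoid angles and joint-surface morphometry.

The measurement convention follows the 3D multiplanar-reconstruction reading of
the Friedman-axis family of methods:

* The **scapular plane** is defined by the midpoint of the scapular spine
  root, the glenoid centre, and the inferior scapular angle.
* The **spine axis** runs from the spine root to the glenoid centre.
* Inclination: the raw angle ``gamma`` is measured in the scapular (coronal)
  plane between the caudally-oriented glenoid height line (rim A -> rim B) and
  the medially-oriented spine ray; ``alpha = gamma - 90``.  Positive alpha is
  superior inclination.
* Version: the raw angle ``delta`` is measured in the transversal plane (the
  plane containing the spine axis, perpendicular to the scapular plane)
  between the dorsally-oriented glenoid width line (rim C -> rim D) and the
  medial spine ray; ``beta = delta - 90``.  Negative beta is retroversion,
  positive anteversion, on both sides.

Angles are computed at full precision; ``round_deg`` gives the 0.1-degree
reporting resolution used in output tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import round_half_up, unit
from .errors import DegenerateGeometryError, ValidationError
from .io import HUMERAL_LANDMARKS, LandmarkSet

__all__ = [
    "ScapularFrame",
    "AngleMeasurement",
    "scapular_frame",
    "inclination_angle",
    "version_angle",
    "glenoid_size",
    "humeral_head_size",
    "angle_table",
]

_COLLINEAR_TOL = 1e-8


@dataclass(frozen=True)
class ScapularFrame:
    """Orthonormal anatomical frame derived from the scapular plane.

    ``spine_axis`` points from the spine root towards the glenoid centre
    (medial -> lateral), ``superior_axis`` lies in the scapular plane pointing
    cranially, and ``ventral_axis`` is the scapular-plane normal oriented so
    that it is anatomically ventral for the given laterality.
    """

    spine_axis: np.ndarray
    superior_axis: np.ndarray
    ventral_axis: np.ndarray
    origin: np.ndarray  # glenoid centre
    laterality: str

    def __post_init__(self):
        for name in ("spine_axis", "superior_axis", "ventral_axis"):
            v = getattr(self, name)
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValidationError(f"{name} is not a unit vector")
        G = np.stack([self.spine_axis, self.superior_axis, self.ventral_axis])
        if np.max(np.abs(G @ G.T - np.eye(3))) > 1e-9:
            raise ValidationError("frame axes are not orthonormal")

    @property
    def plane_normal(self) -> np.ndarray:
        return self.ventral_axis


@dataclass(frozen=True)
class AngleMeasurement:
    """A raw projected angle and its derived glenoid angle (degrees)."""

    gamma_deg: float = np.nan  # raw coronal angle (inclination measurement)
    alpha_deg: float = np.nan  # inclination = gamma - 90
    delta_deg: float = np.nan  # raw transversal angle (version measurement)
    beta_deg: float = np.nan  # version = delta - 90
    laterality: str = "unknown"

    def round_deg(self, decimals: int = 1) -> "AngleMeasurement":
        vals = {
            f: round_half_up(getattr(self, f), decimals)
            for f in ("gamma_deg", "alpha_deg", "delta_deg", "beta_deg")
            if np.isfinite(getattr(self, f))
        }
        return AngleMeasurement(laterality=self.laterality, **vals)


def scapular_frame(landmarks: LandmarkSet) -> ScapularFrame:
    """Build the scapular anatomical frame from the three plane landmarks."""
    sr = landmarks["spine_root"]
    gc = landmarks["glenoid_center"]
    ia = landmarks["inferior_angle"]
    v_spine = gc - sr
    v_inf = ia - sr
    cross = np.cross(v_spine, v_inf)
    scale = np.linalg.norm(v_spine) * np.linalg.norm(v_inf)
    if scale == 0 or np.linalg.norm(cross) < _COLLINEAR_TOL * scale:
        raise DegenerateGeometryError(
            "spine_root, glenoid_center and inferior_angle are collinear; "
            "the scapular plane is undefined"
        )
    spine = unit(v_spine)
    # In-plane cranial direction: perpendicular component of (spine_root -
    # inferior_angle), i.e. pointing away from the inferior angle.
    w = -v_inf
    sup = unit(w - np.dot(w, spine) * spine)
    normal = unit(np.cross(spine, sup))
    if landmarks.laterality == "left":
        ventral = -normal
    else:
        # right-shoulder convention; "unknown" is treated as right
        ventral = normal
    return ScapularFrame(
        spine_axis=spine,
        superior_axis=sup,
        ventral_axis=ventral,
        origin=np.asarray(gc, dtype=float),
        laterality=landmarks.laterality,
    )


def _projected_raw_angle(line_vec: np.ndarray, frame: ScapularFrame,
                         plane_normal: np.ndarray, what: str) -> float:
    """Angle (deg, in (0, 180)) between a projected line vector and the medial
    spine ray ``-spine_axis``."""
    v = line_vec - np.dot(line_vec, plane_normal) * plane_normal
    nrm = np.linalg.norm(v)
    if nrm < 1e-9 * max(np.linalg.norm(line_vec), 1.0):
        raise DegenerateGeometryError(
            f"{what} line is perpendicular to its measurement plane; "
            "projected direction is degenerate"
        )
    c = np.clip(np.dot(v / nrm, -frame.spine_axis), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def inclination_angle(landmarks: LandmarkSet) -> AngleMeasurement:
    """Glenoid inclination: alpha = gamma - 90 (positive = superior)."""
    frame = scapular_frame(landmarks)
    ab = landmarks["rim_B"] - landmarks["rim_A"]  # cranial -> caudal
    gamma = _projected_raw_angle(ab, frame, frame.ventral_axis, "glenoid height (A-B)")
    return AngleMeasurement(
        gamma_deg=gamma, alpha_deg=gamma - 90.0, laterality=landmarks.laterality
    )


def version_angle(landmarks: LandmarkSet) -> AngleMeasurement:
    """Glenoid ante-/retroversion: beta = delta - 90 (negative = retroversion)."""
    frame = scapular_frame(landmarks)
    cd = landmarks["rim_D"] - landmarks["rim_C"]  # ventral -> dorsal
    delta = _projected_raw_angle(cd, frame, frame.superior_axis, "glenoid width (C-D)")
    return AngleMeasurement(
        delta_deg=delta, beta_deg=delta - 90.0, laterality=landmarks.laterality
    )


def glenoid_size(landmarks: LandmarkSet) -> tuple:
    """Glenoid height |A-B| and width |C-D| in mm."""
    height = float(np.linalg.norm(landmarks["rim_A"] - landmarks["rim_B"]))
    width = float(np.linalg.norm(landmarks["rim_C"] - landmarks["rim_D"]))
    return height, width


def humeral_head_size(landmarks: LandmarkSet) -> tuple:
    """Humeral head (height, width, depth) in mm from the articular landmarks.

    Height is the chord from the uppermost to the lowest articular point,
    depth the chord from the most anterior to the most posterior point, and
    width the extent of that chord perpendicular to the height axis.
    """
    missing = [n for n in HUMERAL_LANDMARKS if n not in landmarks]
    if missing:
        raise ValidationError(f"missing humeral landmark(s): {', '.join(missing)}")
    a, b = landmarks["uppermost_A"], landmarks["lowest_B"]
    f, e = landmarks["anterior_F"], landmarks["posterior_E"]
    hvec = a - b
    if np.linalg.norm(hvec) == 0:
        raise ValidationError("humeral landmarks uppermost_A and lowest_B coincide")
    height = float(np.linalg.norm(hvec))
    depth = float(np.linalg.norm(f - e))
    h_unit = hvec / height
    fe = f - e
    width = float(np.linalg.norm(fe - np.dot(fe, h_unit) * h_unit))
    return height, width, depth


def angle_table(measurements, decimals: int = 1) -> pd.DataFrame:
    """Assemble per-specimen angle rows into the reporting table.

    ``measurements`` is an iterable of dicts with keys ``id``, ``side``,
    ``landmarks`` (a LandmarkSet); angles and sizes are computed here and
    rounded to the reporting resolution.
    """
    rows = []
    for m in measurements:
        lm = m["landmarks"]
        inc = inclination_angle(lm)
        ver = version_angle(lm)
        height, width = glenoid_size(lm)
        rows.append(
            {
                "id": m["id"],
                "side": m.get("side", lm.laterality),
                "gamma": round_half_up(inc.gamma_deg, decimals),
                "alpha": round_half_up(inc.alpha_deg, decimals),
                "delta": round_half_up(ver.delta_deg, decimals),
                "beta": round_half_up(ver.beta_deg, decimals),
                "height": round_half_up(height, decimals),
                "width": round_half_up(width, decimals),
            }
        )
    return pd.DataFrame(rows)
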