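"""Volumes, landmark sets and their on-disk formats.

All physical coordinates are in millimetres.  A :class:`Volume` keeps its voxel
grid in ``(x, y, z)`` axis order with the physical position of voxel
``(i, j, k)`` at ``origin + spacing * (i, j, k)`` (voxel centres, 0-based).
Supported image formats are NIfTI-1 (``.nii``/``.nii.gz``) and MetaImage
(``.mha``/``.mhd``); DICOM series are out of scope and expected to be converted
upstream.  Landmarks are stored as a flat JSON object ``{name: [x, y, z]}`` in
millimetres, with an optional ``"laterality"`` key.

Anatomical axis convention (right shoulder): ``+x`` runs ventral to dorsal,
``+y`` caudal to cranial, ``+z`` medial to lateral; left shoulders are the
mirror image in ``x``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict

import numpy as np
import SimpleITK as sitk

from .errors import FormatError, ValidationError

__all__ = [
    "Volume",
    "LandmarkSet",
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
    "SCAPULAR_LANDMARKS",
    "HUMERAL_LANDMARKS",
]

SCAPULAR_LANDMARKS = (
    "spine_root",
    "glenoid_center",
    "inferior_angle",
    "rim_A",  # most cranial point of the glenoid rim
    "rim_B",  # most caudal
    "rim_C",  # most ventral
    "rim_D",  # most dorsal
)
HUMERAL_LANDMARKS = ("uppermost_A", "lowest_B", "anterior_F", "posterior_E")

_IMAGE_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


@dataclass
class Volume:
    """A 3D Hounsfield-unit voxel grid with physical spacing and origin."""

    voxels: np.ndarray  # (nx, ny, nz) HU
    spacing: np.ndarray  # mm per axis, shape (3,)
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    laterality: str = "unknown"  # left | right | unknown

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxels.ndim != 3:
            raise ValidationError("voxels must be a 3D array")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValidationError("spacing must be three strictly positive values")
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("voxels contain non-finite HU values")
        if self.laterality not in ("left", "right", "unknown"):
            raise ValidationError(f"laterality {self.laterality!r} not in left/right/unknown")

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical size of the grid (voxel-centre span plus one spacing)."""
        return self.spacing * np.asarray(self.voxels.shape)

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        return self.origin + self.spacing * np.asarray(index, dtype=float)

    def physical_to_index(self, point: np.ndarray) -> np.ndarray:
        return (np.asarray(point, dtype=float) - self.origin) / self.spacing


@dataclass
class LandmarkSet:
    """Named anatomical points in physical millimetres.

    Required scapular points: spine root midpoint, glenoid centre, inferior
    angle, and the four glenoid rim extremes A (cranial), B (caudal),
    C (ventral), D (dorsal).  Humeral articular landmarks are optional.
    """

    points: Dict[str, np.ndarray]
    laterality: str = "unknown"

    def __post_init__(self) -> None:
        pts = {}
        for name, p in self.points.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ValidationError(f"landmark {name!r} must be a finite 3-vector")
            pts[name] = p
        self.points = pts
        missing = [n for n in SCAPULAR_LANDMARKS if n not in pts]
        if missing:
            raise ValidationError(f"missing required landmark(s): {', '.join(missing)}")
        names = list(SCAPULAR_LANDMARKS)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if np.array_equal(pts[a], pts[b]):
                    raise ValidationError(f"landmarks {a!r} and {b!r} coincide")
        if self.laterality not in ("left", "right", "unknown"):
            raise ValidationError(f"laterality {self.laterality!r} not in left/right/unknown")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return name in self.points

    @property
    def has_humeral(self) -> bool:
        return all(n in self.points for n in HUMERAL_LANDMARKS)

    def with_laterality(self, laterality: str) -> "LandmarkSet":
        return replace(self, points=dict(self.points), laterality=laterality)


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _IMAGE_SUFFIXES):
        raise FormatError(
            f"unsupported image format for {path}: expected one of {_IMAGE_SUFFIXES}"
        )


def read_volume(path, laterality: str = "unknown") -> Volume:
    """Read a NIfTI or MetaImage volume.

    Laterality is not representable in either header, so it is supplied by the
    caller (default ``"unknown"``).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    _check_suffix(path)
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # SimpleITK raises bare RuntimeError
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise FormatError(f"{path}: expected a 3D volume, got {img.GetDimension()}D")
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    if np.any(spacing <= 0):
        raise FormatError(f"{path}: non-positive voxel spacing {tuple(spacing)}")
    # SimpleITK arrays come back (z, y, x); store as (x, y, z).
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return Volume(
        voxels=arr,
        spacing=spacing,
        origin=np.asarray(img.GetOrigin(), dtype=float),
        laterality=laterality,
    )


def write_volume(volume: Volume, path) -> Path:
    """Write a volume as NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd)."""
    path = Path(path)
    _check_suffix(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.voxels.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    sitk.WriteImage(img, str(path))
    return path


def read_landmarks(path) -> LandmarkSet:
    """Read a landmark JSON file ``{name: [x, y, z] mm, ..., "laterality": ...}``."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such landmark file: {path}")
    try:
        with open(path) as fh:
            raw = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"cannot parse landmark JSON {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: landmark JSON must be an object keyed by name")
    laterality = raw.pop("laterality", "unknown")
    return LandmarkSet(points={k: np.asarray(v, dtype=float) for k, v in raw.items()},
                       laterality=laterality)


def write_landmarks(landmarks: LandmarkSet, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload: Dict[str, object] = {
        name: [float(c) for c in p] for name, p in landmarks.points.items()
    }
    payload["laterality"] = landmarks.laterality
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
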