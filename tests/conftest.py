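"""Shared fixtures: compact phantom geometry, hand-built slab phantoms, and
the brute-force slab-max oracle for the subchondral MIP."""

from __future__ import annotations

import numpy as np
import pytest

from glenoid_oam.io import LandmarkSet, Volume

#: Compact scapula geometry: full anatomy, shrunk blade/spine so volumes stay
#: small and fast while every stage still runs end to end.
SMALL_GEOMETRY = dict(
    spine_length=30.0,
    inferior_angle_drop=28.0,
    humeral_head_radius=22.0,
)


@pytest.fixture(scope="session")
def small_geometry():
    return dict(SMALL_GEOMETRY)


def make_slab_phantom(shape=(32, 32, 32), spacing=0.6, tilt_deg=0.0, bump=False):
    """A hand-built laterally-uniform slab phantom (synthetic stand-in for a
    flat articular surface): soft tissue above, an 800 HU plate 2 mm thick,
    trabecular bone below; optionally tilted about the x axis, optionally with
    a buried 1400 HU block.  Returns (Volume, LandmarkSet)."""
    shape = tuple(shape)
    sp = np.full(3, float(spacing))
    idx = np.indices(shape).astype(np.float64)
    X = idx[0] * sp[0]
    Y = idx[1] * sp[1]
    Z = idx[2] * sp[2]
    ext = sp * np.asarray(shape)
    cx, cy = ext[0] / 2.0, ext[1] / 2.0
    t = np.radians(tilt_deg)
    n = np.array([0.0, -np.sin(t), np.cos(t)])  # plate normal (tilted about x)
    # signed offset along the plate normal, measured from the volume centre
    z0 = ext[2] / 2.0
    off = (Y - cy) * n[1] + (Z - z0) * n[2]
    hu = np.full(shape, 40.0, dtype=np.float32)
    hu[off < -1.0] = 300.0
    hu[(off >= -1.0) & (off <= 1.0)] = 800.0
    if bump:
        # laterally bounded block inside the plate
        blk = (
            (off >= -1.0) & (off <= 0.0)
            & (np.abs(X - cx) <= 1.2) & (np.abs(Y - cy) <= 1.2)
        )
        hu[blk] = 1400.0
    vol = Volume(hu, sp, laterality="right")

    centre = np.array([cx, cy, z0])
    surf = centre + 1.0 * n  # top of the plate along the normal
    e_u = np.array([1.0, 0.0, 0.0])
    e_v = np.cross(n, e_u)  # in-plane cranial direction
    a = ext[0] / 2.0 - 2.5
    b = ext[1] / 2.0 - 2.5
    lm = LandmarkSet(
        points={
            "glenoid_center": surf,
            "rim_A": surf + b * e_v,
            "rim_B": surf - b * e_v,
            "rim_C": surf - a * e_u,
            "rim_D": surf + a * e_u,
            "spine_root": surf - 8.0 * n,
            "inferior_angle": surf - 8.0 * n - 6.0 * e_v,
        },
        laterality="right",
    )
    return vol, lm


@pytest.fixture
def slab_phantom():
    return make_slab_phantom


def mip_bruteforce(volume: Volume, surface, depth: float):
    """Independent oracle for the subchondral MIP: for each valid surface
    pixel, the exhaustive max over all voxel centres lying within ``depth``
    along the pixel's inward normal and within the pixel's square footprint
    perpendicular to it.  Returns an (nu, nv) array (nan where no voxel
    qualifies or the pixel is invalid)."""
    arr = np.asarray(volume.voxels, dtype=float)
    sp = volume.spacing
    centres = (np.indices(arr.shape).reshape(3, -1).T * sp) + volume.origin
    vals = arr.reshape(-1)
    # restrict to voxels near the patch to keep the exhaustive pass affordable
    lo = surface.vertices.min(axis=0) - (depth + 2.0)
    hi = surface.vertices.max(axis=0) + (depth + 2.0)
    near = np.all((centres >= lo) & (centres <= hi), axis=1)
    centres, vals = centres[near], vals[near]
    px = float(np.min(sp))
    out = np.full(surface.valid.shape, np.nan)
    ii, jj = np.nonzero(surface.valid)
    for i, j in zip(ii, jj):
        k = surface.vertex_index[i, j]
        d = centres - surface.vertices[k]
        t = d @ surface.inward_normals[k]
        perp = d - np.outer(t, surface.inward_normals[k])
        sel = (t >= 0) & (t <= depth) & (np.abs(perp).max(axis=1) <= px / 2 + 1e-6)
        if sel.any():
            out[i, j] = vals[sel].max()
    return out
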