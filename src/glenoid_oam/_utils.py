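"""Small numeric helpers shared across modules."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (the convention of printed clinical tables).

    numpy/python round half to even, which cannot reproduce e.g. 21.05 -> 21.1.
    """
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, n: int, decimals: int = 1) -> float:
    if n <= 0:
        raise ValueError("percentage denominator must be positive")
    return round_half_up(100.0 * count / n, decimals)


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise ValueError("cannot normalise a zero vector")
    return v / nrm


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about a unit axis (Rodrigues)."""
    a = unit(axis)
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = a
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]], dtype=float)
    return np.eye(3) + s * K + (1 - c) * (K @ K)
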