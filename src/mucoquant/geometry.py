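"""Shared planar geometry helpers.

Conventions used throughout the package
---------------------------------------
Pixel coordinates are 0-based ``(row, col)``.  Angles are measured in degrees
from the +column (horizontal) axis toward the +row axis and, for undirected
axes, folded into ``[0, 180)``.  Under these conventions the unit vector of an
axis at angle ``theta`` is ``(drow, dcol) = (sin(theta), cos(theta))``.
"""

from __future__ import annotations

import numpy as np


def axis_unit_vector(orientation_deg: float) -> np.ndarray:
    """Unit vector ``(drow, dcol)`` of an axis at ``orientation_deg``."""
    t = np.deg2rad(orientation_deg)
    return np.array([np.sin(t), np.cos(t)])


def fold_axis_angle(angle_deg: float) -> float:
    """Map an axis angle to the canonical range [0, 180)."""
    return float(np.mod(angle_deg, 180.0))


def acute_angle_to_axis(vec_row: float, vec_col: float, orientation_deg: float) -> float:
    """Acute angle in degrees between a vector and an undirected axis.

    Returns a value in ``[0, 90]``; 0 means the vector is parallel to the
    axis, 90 perpendicular.  Raises ``ValueError`` for a zero vector.
    """
    norm = float(np.hypot(vec_row, vec_col))
    if norm == 0.0:
        raise ValueError("angle undefined for a zero-length vector")
    u = axis_unit_vector(orientation_deg)
    cosang = abs(vec_row * u[0] + vec_col * u[1]) / norm
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


def ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    orientation_deg: float,
) -> np.ndarray:
    """Boolean mask of a filled ellipse.

    Parameters
    ----------
    shape
        Output array shape (rows, cols).
    center
        Ellipse center ``(row, col)``.
    semi_axes
        ``(a, b)`` semi-major and semi-minor axis lengths in pixels.
    orientation_deg
        Major-axis angle per the package convention.
    """
    a, b = semi_axes
    if a <= 0 or b <= 0:
        raise ValueError("semi-axes must be positive")
    rows, cols = np.ogrid[0 : shape[0], 0 : shape[1]]
    dr = rows - center[0]
    dc = cols - center[1]
    t = np.deg2rad(orientation_deg)
    # coordinates along the major (u) and minor (v) axes
    u = dc * np.cos(t) + dr * np.sin(t)
    v = -dc * np.sin(t) + dr * np.cos(t)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def sample_unit_disk(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform samples from the closed unit disk, shape ``(n, 2)``.

    Rejection sampling from the enclosing square; acceptance rate pi/4.
    """
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        cand = rng.uniform(-1.0, 1.0, size=(2 * (n - filled) + 8, 2))
        ok = cand[(cand**2).sum(axis=1) <= 1.0]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out
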