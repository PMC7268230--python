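"""Fiber geometry primitives: resampling, length, flipping and the MDF distance.

All streamline comparison in the package happens between fibers resampled to a
fixed number of equidistant points (``K = 21``).  The minimum average
direct-flip (MDF) distance between two such polylines ``a`` and ``b`` is

    d_direct(a, b)  = (1/K) * sum_i ||a_i - b_i||
    d_flipped(a, b) = d_direct(a, b^F)          (b^F: reversed point order)
    MDF(a, b)       = min(d_direct, d_flipped)

where ``||.||`` is the Euclidean norm.  Taking the minimum over the reversed
correspondence makes the distance invariant to the arbitrary storage
direction of tractography streamlines.
"""

from __future__ import annotations

import numpy as np

#: Number of equidistant points every fiber is resampled to.
K_POINTS = 21


class DegenerateFiberError(ValueError):
    """Raised when a polyline has no extent (zero total arc length)."""


def fiber_length(points: np.ndarray) -> float:
    """Polyline length: sum of Euclidean distances between adjacent points.

    Parameters
    ----------
    points : (n, 3) array
        Ordered polyline vertices in mm, ``n >= 2``.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise ValueError("a fiber needs at least 2 points")
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def flip_fiber(points: np.ndarray) -> np.ndarray:
    """Reverse the point order of a fiber (storage-direction flip)."""
    return np.asarray(points)[::-1].copy()


def resample_fiber(points: np.ndarray, k: int = K_POINTS) -> np.ndarray:
    """Resample a polyline to ``k`` points at equal cumulative arc length.

    Linear interpolation along the source polyline; the first and last output
    points equal the source endpoints exactly.

    Raises
    ------
    DegenerateFiberError
        If the polyline has zero total length.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2 or points.shape[1] != 3:
        raise ValueError("polyline must be an (n>=2, 3) array")
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    total = seg.sum()
    if total <= 0.0:
        raise DegenerateFiberError("zero-length polyline cannot be resampled")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, k)
    out = np.empty((k, 3))
    for d in range(3):
        out[:, d] = np.interp(targets, cum, points[:, d])
    out[0] = points[0]
    out[-1] = points[-1]
    return out


def resample_fibers(fibers, k: int = K_POINTS) -> np.ndarray:
    """Resample a sequence of polylines into a stacked ``(n, k, 3)`` array."""
    return np.stack([resample_fiber(f, k) for f in fibers]) if len(fibers) else np.empty((0, k, 3))


def mdf_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum average direct-flip distance between two equal-length fibers (mm)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"point-count mismatch: {a.shape} vs {b.shape}")
    direct = np.linalg.norm(a - b, axis=1).mean()
    flipped = np.linalg.norm(a - b[::-1], axis=1).mean()
    return float(min(direct, flipped))


def mdf_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise MDF between two stacks of resampled fibers.

    Parameters
    ----------
    A : (n, k, 3) array
    B : (m, k, 3) array

    Returns
    -------
    (n, m) array of MDF distances in mm.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    diff = A[:, None, :, :] - B[None, :, :, :]
    direct = np.linalg.norm(diff, axis=3).mean(axis=2)
    diff_f = A[:, None, :, :] - B[None, :, ::-1, :]
    flipped = np.linalg.norm(diff_f, axis=3).mean(axis=2)
    return np.minimum(direct, flipped)


def orient_fibers(fibers: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Flip every fiber whose direct mean distance to ``reference`` exceeds
    its flipped mean distance; returns a co-oriented copy.
    """
    fibers = np.asarray(fibers, dtype=float)
    direct = np.linalg.norm(fibers - reference[None], axis=2).mean(axis=1)
    flipped = np.linalg.norm(fibers - reference[None, ::-1], axis=2).mean(axis=1)
    out = fibers.copy()
    mask = direct > flipped
    out[mask] = out[mask, ::-1]
    return out


def mean_fiber(fibers: np.ndarray) -> np.ndarray:
    """Pointwise mean of flip-aligned fibers; reference is the first member."""
    fibers = np.asarray(fibers, dtype=float)
    if fibers.shape[0] == 0:
        raise ValueError("cannot average an empty set of fibers")
    return orient_fibers(fibers, fibers[0]).mean(axis=0)
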