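"""Raster-geometry helpers shared across modules.

Conventions: masks are 2D boolean pixel grids; coordinates are (row, col),
0-based, with pixel centers at integer positions. Physical lengths are in
micrometres and are obtained by multiplying pixel distances by the pixel
size.
"""

from __future__ import annotations

import hashlib

import numpy as np


def mask_hash(mask: np.ndarray) -> str:
    """Stable content hash of a boolean mask (used as a cache key)."""
    m = np.ascontiguousarray(np.asarray(mask, dtype=bool))
    h = hashlib.sha1()
    h.update(np.asarray(m.shape, dtype=np.int64).tobytes())
    h.update(np.packbits(m).tobytes())
    return h.hexdigest()


def mask_area_um2(mask: np.ndarray, pixel_size: float) -> float:
    return float(np.count_nonzero(mask)) * pixel_size**2


def equivalent_radius_um(mask: np.ndarray, pixel_size: float) -> float:
    """Radius of the circle with the same area as the mask, sqrt(A/pi)."""
    return float(np.sqrt(mask_area_um2(mask, pixel_size) / np.pi))


def mask_centroid(mask: np.ndarray) -> np.ndarray:
    rc = np.argwhere(mask)
    if rc.size == 0:
        raise ValueError("empty mask has no centroid")
    return rc.mean(axis=0)


def points_in_mask(coords: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Boolean membership of sub-pixel points: a point belongs to the pixel
    it rounds to."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    rc = np.rint(coords).astype(int)
    ok = (
        (rc[:, 0] >= 0)
        & (rc[:, 0] < mask.shape[0])
        & (rc[:, 1] >= 0)
        & (rc[:, 1] < mask.shape[1])
    )
    inside = np.zeros(len(coords), dtype=bool)
    inside[ok] = mask[rc[ok, 0], rc[ok, 1]]
    return inside


def sample_uniform_in_mask(
    mask: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n points uniform over mask pixels with sub-pixel jitter.

    Jitter stays strictly within (-0.5, 0.5) so every point rounds back to
    the pixel it was drawn from, keeping containment exact.
    """
    pix = np.argwhere(mask)
    if pix.shape[0] == 0:
        if n == 0:
            return np.empty((0, 2), dtype=float)
        raise ValueError("cannot sample points from an empty mask")
    idx = rng.integers(0, pix.shape[0], size=n)
    jitter = rng.uniform(-0.499, 0.499, size=(n, 2))
    return pix[idx].astype(float) + jitter


def ray_boundary_distance(
    mask: np.ndarray,
    origin,
    direction,
    coarse_step: float = 0.5,
    tol: float = 0.01,
) -> float:
    """Distance (pixels) from `origin` to the mask boundary along `direction`.

    Marches along the ray in coarse steps until it leaves the mask, then
    bisects the crossing to `tol`. `origin` must lie inside the mask.
    """
    origin = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    norm = float(np.hypot(d[0], d[1]))
    if norm == 0:
        raise ValueError("direction vector must be non-zero")
    d = d / norm
    if not points_in_mask(origin, mask)[0]:
        raise ValueError("ray origin lies outside the mask")
    t_max = float(np.hypot(*mask.shape)) + 1.0
    t_lo = 0.0
    t_hi = None
    t = coarse_step
    while t <= t_max:
        if not points_in_mask(origin + t * d, mask)[0]:
            t_hi = t
            break
        t_lo = t
        t += coarse_step
    if t_hi is None:  # pathological: ray never exits within the field
        return t_lo
    while t_hi - t_lo > tol:
        mid = 0.5 * (t_lo + t_hi)
        if points_in_mask(origin + mid * d, mask)[0]:
            t_lo = mid
        else:
            t_hi = mid
    return 0.5 * (t_lo + t_hi)
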