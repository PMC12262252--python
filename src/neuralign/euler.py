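"""Brute-force Euler (rotation + translation) pre-alignment.

Large whole-body motion is removed before non-rigid registration by a grid
search over in-plane rotation and translation, scored by global normalized
cross-correlation (NCC) of 4x-downsampled maximum-intensity projections,
followed by a search over the axial shift scored by full-3D NCC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import ConfigurationError, DegenerateInputError
from .volumes import CentroidList, EulerTransform


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Global zero-normalized cross-correlation, in [-1, 1].

    ``ncc(X, X) == 1`` for any nonconstant ``X``; the value is symmetric in
    its arguments and invariant to affine intensity rescaling of either one.

    Raises
    ------
    DegenerateInputError
        If either argument has zero variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    da = a - a.mean()
    db = b - b.mean()
    va = np.mean(da * da)
    vb = np.mean(db * db)
    if va == 0 or vb == 0:
        raise DegenerateInputError("zero-variance input to NCC")
    return float(np.mean(da * db) / np.sqrt(va * vb))


def _ncc_or_none(a, b):
    try:
        return ncc(a, b)
    except DegenerateInputError:
        return None


@dataclass(frozen=True)
class EulerGrid:
    """Search ranges and steps for the brute-force grid.

    Angles are in degrees; ``dxy_range`` / ``dxy_step`` are expressed at the
    downsampled scale (multiply by ``downsample`` for full-resolution
    voxels); ``dz`` is in voxels.  ``dxy_range=None`` defaults to a quarter
    of each downsampled dimension.
    """

    theta_range: tuple[float, float] = (-180.0, 180.0)
    theta_step: float = 2.0
    dxy_range: tuple[int, int] | None = None
    dxy_step: int = 2
    dz_range: tuple[int, int] = (-8, 8)
    dz_step: int = 1
    downsample: int = 4

    def thetas(self) -> np.ndarray:
        lo, hi = self.theta_range
        out = np.arange(lo, hi, self.theta_step, dtype=float)
        if out.size == 0:
            raise ConfigurationError("empty rotation grid")
        return out

    def shifts(self, limit: int) -> np.ndarray:
        if self.dxy_range is None:
            lo, hi = -limit, limit
        else:
            lo, hi = self.dxy_range
        out = np.arange(lo, hi + 1, self.dxy_step, dtype=int)
        if out.size == 0:
            raise ConfigurationError("empty translation grid")
        return out

    def dzs(self) -> np.ndarray:
        lo, hi = self.dz_range
        out = np.arange(lo, hi + 1, self.dz_step, dtype=int)
        if out.size == 0:
            raise ConfigurationError("empty axial grid")
        return out


def block_mean_downsample(img: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downsample a 2-D image, zero-padding to a full block."""
    if factor == 1:
        return np.asarray(img, dtype=float)
    x, y = img.shape
    px = (-x) % factor
    py = (-y) % factor
    img = np.pad(np.asarray(img, dtype=float), ((0, px), (0, py)))
    x, y = img.shape
    return img.reshape(x // factor, factor, y // factor, factor).mean(axis=(1, 3))


def _rotate2d(img: np.ndarray, theta_deg: float) -> np.ndarray:
    """Rotate a 2-D (x, y) image about its geometric center, CCW from +z."""
    if theta_deg == 0:
        return np.asarray(img, dtype=float)
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    center = (np.array(img.shape) - 1) / 2
    # output q reads input R^-1 (q - c) + c
    rot_inv = np.array([[c, s], [-s, c]])
    offset = center - rot_inv @ center
    return ndimage.affine_transform(
        np.asarray(img, dtype=float), rot_inv, offset=offset, order=1, cval=0.0
    )


def _shift_with_zeros(img: np.ndarray, shift) -> np.ndarray:
    """Translate an array by integer voxels, filling exposed regions with 0."""
    out = np.zeros_like(img)
    src = []
    dst = []
    for s, size in zip(shift, img.shape):
        s = int(s)
        src.append(slice(max(0, -s), min(size, size - s)))
        dst.append(slice(max(0, s), min(size, size + s)))
    if all(sl.stop > sl.start for sl in src):
        out[tuple(dst)] = img[tuple(src)]
    return out


def apply_euler(obj, t: EulerTransform, shape=None):
    """Apply an Euler transform to an image, ROI volume, or centroid list.

    Every z-slice is transformed by the same in-plane rotation + translation
    and the stack is then shifted by ``dz``.  Intensity volumes use linear
    interpolation, ROI volumes nearest-neighbor (both zero-filled), and
    centroid lists the exact analytic point map (``shape`` of the parent
    grid is required to locate the rotation center).
    """
    if isinstance(obj, CentroidList):
        if shape is None:
            raise ValueError("grid shape is required to transform centroids")
        return apply_euler_centroids(obj, t, shape)
    vol = np.asarray(obj)
    is_roi = np.issubdtype(vol.dtype, np.integer)
    order = 0 if is_roi else 1
    th = np.deg2rad(t.theta)
    c, s = np.cos(th), np.sin(th)
    center = (np.array(vol.shape[:2]) - 1) / 2
    rot_inv = np.array([[c, s], [-s, c]])
    offset = center - rot_inv @ center - rot_inv @ np.array([t.dx, t.dy])
    out = np.empty_like(vol, dtype=vol.dtype if is_roi else float)
    for z in range(vol.shape[2]):
        out[:, :, z] = ndimage.affine_transform(
            vol[:, :, z].astype(float),
            rot_inv,
            offset=offset,
            order=order,
            cval=0.0,
        ).astype(out.dtype)
    if t.dz:
        out = _shift_with_zeros(out, (0, 0, int(round(t.dz))))
    return out


def transform_points(points: np.ndarray, t: EulerTransform, shape) -> np.ndarray:
    """Exact analytic Euler point map for (N, 3) coordinates on a grid."""
    points = np.asarray(points, dtype=float)
    th = np.deg2rad(t.theta)
    c, s = np.cos(th), np.sin(th)
    center = (np.asarray(shape[:2], dtype=float) - 1) / 2
    rot = np.array([[c, -s], [s, c]])
    out = points.copy()
    out[:, :2] = (points[:, :2] - center) @ rot.T + center + np.array([t.dx, t.dy])
    out[:, 2] = points[:, 2] + t.dz
    return out


def apply_euler_centroids(
    centroids: CentroidList, t: EulerTransform, shape
) -> CentroidList:
    """Euler-transform the valid rows of a centroid list; pads untouched."""
    return centroids.replace_points(transform_points(centroids.points, t, shape))


def euler_grid_search(
    fixed: np.ndarray, moving: np.ndarray, grid: EulerGrid = EulerGrid()
) -> tuple[EulerTransform, dict]:
    """Brute-force Euler registration of ``moving`` onto ``fixed``.

    In-plane rotation and translation are searched on 4x block-mean
    downsampled z-maximum-intensity projections by maximizing NCC; the best
    in-plane transform is then applied to the full volume and the axial
    shift ``dz`` maximizing full-3D NCC is searched.  Deterministic given
    the grid; ties break toward the earlier grid point.

    Returns the transform and a report dict with the achieved in-plane and
    3-D NCC scores.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving shapes differ")

    f = grid.downsample
    fixed_mip = block_mean_downsample(fixed.max(axis=2), f)
    moving_mip = block_mean_downsample(moving.max(axis=2), f)
    limit = max(1, min(fixed_mip.shape) // 4)
    shifts = grid.shifts(limit)

    best = (-np.inf, 0.0, 0, 0)  # score, theta, dx_ds, dy_ds
    for theta in grid.thetas():
        rotated = _rotate2d(moving_mip, theta)
        for dx in shifts:
            for dy in shifts:
                score = _ncc_or_none(
                    fixed_mip, _shift_with_zeros(rotated, (dx, dy))
                )
                if score is not None and score > best[0]:
                    best = (score, theta, int(dx), int(dy))
    if not np.isfinite(best[0]):
        raise DegenerateInputError("no valid in-plane candidate (constant images)")

    score_xy, theta, dx_ds, dy_ds = best
    inplane = EulerTransform(theta, dx_ds * f, dy_ds * f, 0)
    moved = apply_euler(moving, inplane)

    best_z = (-np.inf, 0)
    for dz in grid.dzs():
        score = _ncc_or_none(fixed, _shift_with_zeros(moved, (0, 0, int(dz))))
        if score is not None and score > best_z[0]:
            best_z = (score, int(dz))
    transform = EulerTransform(theta, dx_ds * f, dy_ds * f, best_z[1])
    return transform, {"ncc_inplane_mip": score_xy, "ncc_3d": best_z[0]}
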