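"""Dense displacement fields (DDFs) and their application.

A DDF is an ``(X, Y, Z, 3)`` array of per-voxel displacements in voxels,
defining the coordinate transformation from fixed-image coordinates to
moving-image coordinates: voxel ``p`` of the fixed grid corresponds to
position ``p + DDF[p]`` in the moving image.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)


def validate_ddf(ddf: np.ndarray) -> np.ndarray:
    ddf = np.asarray(ddf, dtype=float)
    if ddf.ndim != 4 or ddf.shape[3] != 3:
        raise ValueError("DDF must have shape (X, Y, Z, 3)")
    if not np.isfinite(ddf).all():
        raise ValueError("DDF contains non-finite values")
    return ddf


def identity_grid(shape) -> np.ndarray:
    """Voxel coordinates of a grid, shape ``(X, Y, Z, 3)``."""
    return np.stack(
        np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij"),
        axis=-1,
    )


def make_rigid_ddf(shape, rotation: np.ndarray, translation) -> np.ndarray:
    """DDF realizing a rigid-body map about the grid center.

    ``DDF[p] = R (p - c) + c + t - p`` with ``c`` the geometric grid center;
    the identity rotation with zero translation yields the all-zero DDF.

    Raises
    ------
    ValueError
        If ``rotation`` is not orthonormal within 1e-6.
    """
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3) or not np.allclose(
        rotation.T @ rotation, np.eye(3), atol=1e-6
    ):
        raise ValueError("rotation must be a 3x3 orthonormal matrix")
    translation = np.asarray(translation, dtype=float).reshape(3)
    center = (np.asarray(shape, dtype=float) - 1) / 2
    grid = identity_grid(shape)
    return (grid - center) @ rotation.T + center + translation - grid


def warp_image(moving: np.ndarray, ddf: np.ndarray, order: int = 1) -> np.ndarray:
    """Resample ``moving`` at ``p + DDF[p]`` for every fixed-grid voxel.

    Trilinear interpolation (``order=1``) for intensity volumes; pass
    ``order=0`` for label data such as ROI volumes.  Out-of-bounds samples
    are filled with 0.
    """
    ddf = validate_ddf(ddf)
    moving = np.asarray(moving)
    if moving.shape != ddf.shape[:3]:
        raise ValueError("moving volume and DDF grids differ")
    coords = identity_grid(moving.shape) + ddf
    out = ndimage.map_coordinates(
        moving.astype(float),
        [coords[..., m] for m in range(3)],
        order=order,
        cval=0.0,
    )
    if np.issubdtype(moving.dtype, np.integer) and order == 0:
        return out.astype(moving.dtype)
    return out


def warp_roi(rois: np.ndarray, ddf: np.ndarray) -> np.ndarray:
    """Nearest-neighbor warp of an integer ROI volume."""
    return warp_image(np.asarray(rois), ddf, order=0)


def interpolate_ddf(ddf: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Trilinearly interpolate a DDF at (N, 3) positions.

    Points outside the grid are clamped to the border (with a warning), so
    the sampled displacement is that of the nearest edge voxel.
    """
    ddf = validate_ddf(ddf)
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    upper = np.asarray(ddf.shape[:3], dtype=float) - 1
    if len(points) and ((points < 0) | (points > upper)).any():
        logger.warning("centroid outside grid; clamping DDF sample to border")
    clamped = np.clip(points, 0, upper)
    return np.stack(
        [
            ndimage.map_coordinates(ddf[..., m], clamped.T, order=1, mode="nearest")
            for m in range(3)
        ],
        axis=1,
    )


def warp_centroids(fixed_centroids, ddf: np.ndarray):
    """Map fixed-image centroids to predicted moving positions ``p + DDF(p)``.

    Pad rows ``(-1, -1, -1)`` pass through untouched.
    """
    pts = fixed_centroids.points
    if len(pts) == 0:
        return fixed_centroids.replace_points(pts)
    return fixed_centroids.replace_points(pts + interpolate_ddf(ddf, pts))


def mask_ddf_z(ddf: np.ndarray) -> np.ndarray:
    """Zero the z-displacement component (keeps voxels within their slice)."""
    ddf = validate_ddf(ddf).copy()
    ddf[..., 2] = 0.0
    return ddf
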