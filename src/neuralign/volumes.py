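"""Core volumetric data types, coordinate conventions and preprocessing.

Arrays follow one internal convention everywhere in the package:

* ``ImageVolume`` -- real-valued :class:`numpy.ndarray` indexed ``(x, y, z)``.
* ``MultiChannelVolume`` -- real-valued array indexed ``(x, y, z, c)``.
* ``ROIVolume`` -- non-negative integer array indexed ``(x, y, z)``; ``0`` is
  background and every positive value is one segmented cell (ROI).  Indices
  need not be consecutive.

File formats that store other axis orders (e.g. channel-first label stacks)
are converted at the I/O boundary (:mod:`neuralign.io`), never inside the
numerical code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import (
    CapacityError,
    DegenerateInputError,
    NoCorrespondenceError,
)

#: Default volume shape (X, Y, Z) used by the full-scale networks.
DEFAULT_SHAPE = (284, 120, 64)

#: Fixed row capacity of a padded centroid list.
CENTROID_CAPACITY = 200

#: Pad value marking unused centroid rows.
CENTROID_PAD = -1.0


@dataclass(frozen=True)
class EulerTransform:
    """In-plane rigid transform plus an axial shift.

    The transform maps *moving*-image content onto the fixed image: a point
    ``p`` is sent to ``c + R(theta) (p_xy - c_xy) + (dx, dy)`` in-plane
    (rotation about the geometric grid center, counter-clockwise viewed from
    +z) and shifted by ``dz`` along the optical axis.

    Parameters are expressed in degrees (``theta``) and voxels (``dx, dy,
    dz``).
    """

    theta: float = 0.0
    dx: float = 0.0
    dy: float = 0.0
    dz: float = 0.0

    def inverse(self) -> "EulerTransform":
        """Exact inverse for point mapping (rotation about the same center)."""
        th = np.deg2rad(self.theta)
        c, s = np.cos(th), np.sin(th)
        # inverse rotation applied to the negated translation
        dxi = -(c * self.dx + s * self.dy)
        dyi = -(-s * self.dx + c * self.dy)
        return EulerTransform(-self.theta, dxi, dyi, -self.dz)


class CentroidList:
    """Fixed-capacity padded list of neuron-center coordinates.

    ``rows`` is a ``(capacity, 3)`` float array whose first ``valid_count``
    rows are real ``(x, y, z)`` coordinates (componentwise >= 0) and whose
    remaining rows equal ``(-1, -1, -1)``.  Matched fixed/moving lists share
    row ordering: row *i* of both lists is the same neuron.
    """

    def __init__(self, points: np.ndarray, capacity: int = CENTROID_CAPACITY):
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        if len(points) > capacity:
            raise CapacityError(
                f"{len(points)} centroids exceed capacity {capacity}"
            )
        if len(points) and points.min() < 0:
            raise ValueError("valid centroid coordinates must be >= 0")
        self.rows = np.full((capacity, 3), CENTROID_PAD, dtype=float)
        self.rows[: len(points)] = points
        self.valid_count = int(len(points))

    @classmethod
    def from_padded(cls, rows: np.ndarray) -> "CentroidList":
        """Rebuild from an already-padded array (e.g. read from disk)."""
        rows = np.asarray(rows, dtype=float)
        valid = ~np.all(rows == CENTROID_PAD, axis=1)
        if valid.any() and not valid[: valid.sum()].all():
            raise ValueError("pad rows must trail the valid rows")
        out = cls(rows[valid], capacity=len(rows))
        return out

    @property
    def capacity(self) -> int:
        return len(self.rows)

    @property
    def points(self) -> np.ndarray:
        """View of the valid rows, shape ``(valid_count, 3)``."""
        return self.rows[: self.valid_count]

    def replace_points(self, points: np.ndarray) -> "CentroidList":
        """New list with the same capacity and the given valid rows.

        Unlike the constructor this permits negative coordinates, which arise
        when a transform moves a centroid out of the grid.
        """
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        out = CentroidList.__new__(CentroidList)
        out.rows = np.full((self.capacity, 3), CENTROID_PAD, dtype=float)
        out.rows[: len(points)] = points
        out.valid_count = int(len(points))
        return out

    def __len__(self) -> int:
        return self.valid_count

    def __eq__(self, other) -> bool:
        return isinstance(other, CentroidList) and np.array_equal(
            self.rows, other.rows
        )

    def __repr__(self) -> str:
        return f"CentroidList({self.valid_count}/{self.capacity})"


def preprocess_to_shape(vol: np.ndarray, target_shape=DEFAULT_SHAPE) -> np.ndarray:
    """Median-subtract, clip, and crop/pad a volume to a standard shape.

    The image median is subtracted and negative values set to zero; the
    volume is then cropped or zero-padded so that its intensity center of
    mass (computed after subtraction, rounded half-up) lands on the geometric
    center of the target grid.

    Raises
    ------
    DegenerateInputError
        If the volume is all-zero after median subtraction.
    """
    vol = np.asarray(vol, dtype=float)
    if vol.ndim != 3:
        raise ValueError("expected a 3-D (x, y, z) volume")
    work = vol - np.median(vol)
    np.clip(work, 0, None, out=work)
    total = work.sum()
    if total == 0:
        raise DegenerateInputError("volume is all-zero after median subtraction")

    com = np.array(ndimage.center_of_mass(work))
    src_center = np.floor(com + 0.5).astype(int)  # round half-up
    tgt = np.asarray(target_shape, dtype=int)
    if (tgt <= 0).any():
        raise ValueError("target shape must be positive")
    tgt_center = np.floor((tgt - 1) / 2 + 0.5).astype(int)

    out = np.zeros(tuple(tgt), dtype=work.dtype)
    # voxel q of the output reads work[q - tgt_center + src_center]
    offset = src_center - tgt_center
    src_lo = np.maximum(offset, 0)
    src_hi = np.minimum(offset + tgt, work.shape)
    dst_lo = src_lo - offset
    dst_hi = src_hi - offset
    if (src_hi > src_lo).all():
        out[tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))] = work[
            tuple(slice(a, b) for a, b in zip(src_lo, src_hi))
        ]
    return out


def roi_centroids(rois: np.ndarray) -> dict[int, np.ndarray]:
    """Centroid of every ROI: the unweighted mean voxel coordinate.

    Returns a mapping ``{roi_index: (x, y, z)}``; an ROI volume without any
    positive index yields an empty mapping.
    """
    rois = np.asarray(rois)
    labels = np.unique(rois)
    labels = labels[labels > 0]
    if labels.size == 0:
        return {}
    coms = ndimage.center_of_mass(np.ones_like(rois, dtype=float), rois, labels)
    return {int(k): np.asarray(c, dtype=float) for k, c in zip(labels, coms)}


def match_and_pad_centroids(
    fixed: np.ndarray, moving: np.ndarray, capacity: int = CENTROID_CAPACITY
) -> tuple[CentroidList, CentroidList]:
    """Matched centroid lists for the ROI indices present in both volumes.

    Only shared indices are retained (ascending index order in both lists,
    so row *i* of each list is the same neuron), and both lists are padded
    with ``(-1, -1, -1)`` rows up to ``capacity``.

    Raises
    ------
    NoCorrespondenceError
        If the volumes share no positive index.
    CapacityError
        If more than ``capacity`` indices are shared.
    """
    cf = roi_centroids(fixed)
    cm = roi_centroids(moving)
    shared = sorted(set(cf) & set(cm))
    if not shared:
        raise NoCorrespondenceError("no ROI index present in both volumes")
    if len(shared) > capacity:
        raise CapacityError(f"{len(shared)} shared ROIs exceed capacity {capacity}")
    fixed_list = CentroidList(np.array([cf[i] for i in shared]), capacity)
    moving_list = CentroidList(np.array([cm[i] for i in shared]), capacity)
    return fixed_list, moving_list
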