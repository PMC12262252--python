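"""File I/O: TIFF / HDF5 volumes, CSV centroid and label tables, DDF storage.

Internal arrays are ``(x, y, z[, c])``; files use the conventional imaging
layouts (TIFF: one ``(y, x)`` page per z-slice; HDF5: one dataset per
channel).  All writers round-trip bit-exactly through the matching readers.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd
import tifffile

from .volumes import CentroidList

# ---------------------------------------------------------------------------
# TIFF


def write_tiff(path, vol: np.ndarray) -> None:
    """Write an (x, y, z) volume as a multi-page TIFF (one page per z)."""
    vol = np.asarray(vol)
    tifffile.imwrite(path, vol.transpose(2, 1, 0), photometric="minisblack")


def read_tiff(path) -> np.ndarray:
    pages = tifffile.imread(path)
    if pages.ndim == 2:  # single z-slice
        pages = pages[None]
    return pages.transpose(2, 1, 0)


def write_roi_tiff(path, rois: np.ndarray) -> None:
    """ROI volumes are stored as 16-bit unsigned integer TIFF."""
    rois = np.asarray(rois)
    if rois.min() < 0 or rois.max() > np.iinfo(np.uint16).max:
        raise ValueError("ROI indices out of uint16 range")
    write_tiff(path, rois.astype(np.uint16))


def read_roi_tiff(path) -> np.ndarray:
    return read_tiff(path).astype(np.int64)


# ---------------------------------------------------------------------------
# HDF5


def write_h5_volume(path, vol: np.ndarray, channels=None) -> None:
    """Write a volume to HDF5, one dataset per channel.

    ``vol`` is (x, y, z) for single-channel data or (x, y, z, c) with a
    matching ``channels`` name list.
    """
    vol = np.asarray(vol)
    with h5py.File(path, "w") as f:
        if vol.ndim == 3:
            f.create_dataset("image", data=vol)
        elif vol.ndim == 4:
            names = channels or [f"ch{i}" for i in range(vol.shape[3])]
            if len(names) != vol.shape[3]:
                raise ValueError("channel name count mismatch")
            f.attrs["channels"] = [str(n) for n in names]
            for i, name in enumerate(names):
                f.create_dataset(str(name), data=vol[..., i])
        else:
            raise ValueError("expected 3-D or 4-D volume")


def read_h5_volume(path):
    """Read a volume written by :func:`write_h5_volume`.

    Returns ``(array, channels)`` where ``channels`` is ``None`` for
    single-channel volumes.
    """
    with h5py.File(path, "r") as f:
        if "image" in f:
            return f["image"][()], None
        names = [str(n) for n in f.attrs["channels"]]
        vol = np.stack([f[n][()] for n in names], axis=-1)
        return vol, names


def write_ddf(path, ddf: np.ndarray) -> None:
    ddf = np.asarray(ddf)
    if ddf.ndim != 4 or ddf.shape[3] != 3:
        raise ValueError("DDF must have shape (X, Y, Z, 3)")
    with h5py.File(path, "w") as f:
        d = f.create_dataset("ddf", data=ddf)
        d.attrs["shape"] = ddf.shape


def read_ddf(path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["ddf"][()]


# ---------------------------------------------------------------------------
# CSV tables


def write_centroids_csv(path, centroids: dict | CentroidList) -> None:
    """Write centroids as CSV with header ``roi_index,x,y,z``.

    Accepts either a ``{roi_index: (x, y, z)}`` mapping or a
    :class:`CentroidList` (rows numbered 1..valid_count).
    """
    if isinstance(centroids, CentroidList):
        centroids = {i + 1: p for i, p in enumerate(centroids.points)}
    df = pd.DataFrame(
        [(int(k), *map(float, v)) for k, v in sorted(centroids.items())],
        columns=["roi_index", "x", "y", "z"],
    )
    df.to_csv(path, index=False)


def read_centroids_csv(path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path)
    return {
        int(r.roi_index): np.array([r.x, r.y, r.z], dtype=float)
        for r in df.itertuples()
    }


def write_label_table(path, table: pd.DataFrame) -> None:
    """Label tables are CSV with header ``roi_index,label,confidence``."""
    cols = ["roi_index", "label", "confidence"]
    if list(table.columns) != cols:
        table = table[cols]
    table.to_csv(path, index=False)


def read_label_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["roi_index"] = df["roi_index"].astype(int)
    df["label"] = df["label"].astype(str)
    return df


def write_similarity_matrix(path, sim) -> None:
    """Store a sparse similarity matrix as HDF5 triplets (i, j, value)."""
    items = sorted(sim.entries.items())
    i = np.array([k[0] for k, _ in items], dtype=np.int64)
    j = np.array([k[1] for k, _ in items], dtype=np.int64)
    v = np.array([val for _, val in items], dtype=float)
    with h5py.File(path, "w") as f:
        f.create_dataset("i", data=i)
        f.create_dataset("j", data=j)
        f.create_dataset("value", data=v)
        f.attrs["n"] = len(sim)


def read_similarity_matrix(path):
    """Triplets back as ``(n, {(i, j): value})``."""
    with h5py.File(path, "r") as f:
        i = f["i"][()]
        j = f["j"][()]
        v = f["value"][()]
        n = int(f.attrs["n"])
    return n, {(int(a), int(b)): float(x) for a, b, x in zip(i, j, v)}
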