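"""Synthetic fixtures with known ground truth for the full stack.

The generator emulates the imaging substrate the pipeline consumes:
nuclei-dense head volumes (isotropic Gaussian blobs on a dark background),
smooth invertible non-rigid deformations (affine composed with a
low-frequency bend), per-cell-type multi-channel color signatures
conserved across animals, and sparsely green-labeled trace populations
with planted identity swaps.  Every generator is a pure function of its
configuration, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import CentroidList, roi_centroids

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SynthConfig:
    """Settings of the synthetic-volume generator.

    ``shape`` is (X, Y, Z); ``n_cells`` Gaussian nuclei of width
    ``nucleus_sigma`` (voxels, isotropic by default; ``nucleus_anisotropy``
    scales the z width) are placed at least ``min_separation`` voxels
    apart.  Peak intensities are log-normal around ``intensity_mean``.
    Deformations compose a random affine (strength = relative corner
    displacement) with a sinusoidal y-bend of amplitude ``bend_amplitude``
    voxels.  ``noise_sd`` is additive Gaussian observation noise.
    """

    shape: tuple = (64, 32, 16)
    n_cells: int = 15
    nucleus_sigma: float = 1.5
    nucleus_anisotropy: float = 1.0
    intensity_mean: float = 1.0
    intensity_jitter: float = 0.2
    n_channels: int = 1
    n_cell_types: int | None = None
    signatures: tuple | None = None  # explicit (type, channel) table
    affine_strength: float = 0.02
    bend_amplitude: float = 1.5
    bend_period: float | None = None  # default: x extent
    noise_sd: float = 0.0
    margin: float = 6.0
    min_separation: float = 4.0
    seed: int = 0


# ---------------------------------------------------------------------------
# nuclei volumes


def _place_centers(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    dims = np.asarray(cfg.shape, dtype=float)
    lo = np.minimum(cfg.margin, dims / 4)
    hi = dims - 1 - lo
    centers = []
    for _ in range(cfg.n_cells * 200):
        cand = rng.uniform(lo, hi)
        if all(np.linalg.norm(cand - c) >= cfg.min_separation for c in centers):
            centers.append(cand)
            if len(centers) == cfg.n_cells:
                return np.array(centers)
    raise RuntimeError(
        f"could not place {cfg.n_cells} nuclei at separation "
        f"{cfg.min_separation} in shape {cfg.shape}"
    )


def _render_nuclei(centers, amplitudes, cfg: SynthConfig) -> np.ndarray:
    grid = np.stack(
        np.meshgrid(*(np.arange(s, dtype=float) for s in cfg.shape), indexing="ij"),
        axis=-1,
    )
    sigma = np.array([cfg.nucleus_sigma, cfg.nucleus_sigma,
                      cfg.nucleus_sigma * cfg.nucleus_anisotropy])
    vol = np.zeros(cfg.shape)
    for center, amp in zip(centers, amplitudes):
        d2 = (((grid - center) / sigma) ** 2).sum(axis=-1)
        vol += amp * np.exp(-0.5 * d2)
    return vol


def _segment_rois(vol, centers, amplitudes, cfg: SynthConfig) -> np.ndarray:
    """Voxels above half the weakest peak, assigned to the nearest center."""
    threshold = 0.5 * float(np.min(amplitudes))
    mask = vol > threshold
    grid = np.stack(
        np.meshgrid(*(np.arange(s, dtype=float) for s in cfg.shape), indexing="ij"),
        axis=-1,
    )
    d2 = ((grid[None] - centers[:, None, None, None, :]) ** 2).sum(axis=-1)
    nearest = d2.argmin(axis=0)
    return np.where(mask, nearest + 1, 0).astype(np.int32)


def make_nuclei_volume(cfg: SynthConfig):
    """Nuclei volume with matching ROIs, centroids, and a label table.

    Returns ``(volume, rois, centroids, table)``.  The volume is (X, Y, Z)
    for ``n_channels == 1`` and (X, Y, Z, C) otherwise, in which case each
    cell draws its per-channel intensity from its cell type's conserved
    channel signature with multiplicative jitter.  ``centroids`` are the
    planted centers; the table maps ROI index to cell-type name with a
    confidence of 5.
    """
    rng = np.random.default_rng(cfg.seed)
    centers = _place_centers(cfg, rng)
    amplitudes = cfg.intensity_mean * np.exp(
        rng.normal(0.0, cfg.intensity_jitter, cfg.n_cells))
    base = _render_nuclei(centers, amplitudes, cfg)
    rois = _segment_rois(base, centers, amplitudes, cfg)

    n_types = cfg.n_cell_types or cfg.n_cells
    types = (np.arange(cfg.n_cells) % n_types if cfg.n_cell_types
             else np.arange(cfg.n_cells))
    table = pd.DataFrame(
        {
            "roi_index": np.arange(1, cfg.n_cells + 1),
            "label": [f"T{t:03d}" for t in types],
            "confidence": 5,
        }
    )
    if cfg.n_channels == 1:
        vol = base
    else:
        if cfg.signatures is not None:
            signatures = np.asarray(cfg.signatures, dtype=float)
            if signatures.shape != (n_types, cfg.n_channels):
                raise ValueError("signature table shape mismatch")
        else:
            signatures = channel_signatures(n_types, cfg.n_channels, cfg.seed)
        vol = np.zeros(cfg.shape + (cfg.n_channels,))
        for i, (center, amp) in enumerate(zip(centers, amplitudes)):
            sig = signatures[types[i]] * np.exp(
                rng.normal(0.0, cfg.intensity_jitter, cfg.n_channels))
            blob = _render_nuclei(center[None], [amp], cfg)
            vol += blob[..., None] * sig
    if cfg.noise_sd:
        vol = vol + rng.normal(0.0, cfg.noise_sd, vol.shape)
    centroids = CentroidList(centers)
    return vol, rois, centroids, table


def channel_signatures(n_types: int, n_channels: int, seed: int) -> np.ndarray:
    """Conserved per-cell-type channel signatures (Dirichlet over channels)."""
    rng = np.random.default_rng(seed + 7919)
    return rng.dirichlet(np.ones(n_channels), size=n_types)


# ---------------------------------------------------------------------------
# deformations


class SmoothDeformation:
    """Invertible smooth point map: affine composed with a sinusoidal bend.

    The forward map sends fixed-image coordinates to moving-image
    coordinates; ``to_ddf`` converts it to the dense displacement field
    that registers the generated moving image back onto the fixed one.
    """

    def __init__(self, shape, affine: np.ndarray, translation: np.ndarray,
                 bend_amplitude: float, bend_period: float):
        self.shape = tuple(shape)
        self.affine = np.asarray(affine, dtype=float)
        self.translation = np.asarray(translation, dtype=float)
        self.bend_amplitude = float(bend_amplitude)
        self.bend_period = float(bend_period)
        self.center = (np.asarray(shape, dtype=float) - 1) / 2

    def _bend(self, pts: np.ndarray, sign: float) -> np.ndarray:
        out = pts.copy()
        out[:, 1] += sign * self.bend_amplitude * np.sin(
            2 * np.pi * pts[:, 0] / self.bend_period)
        return out

    def forward(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        affined = (pts - self.center) @ self.affine.T + self.center \
            + self.translation
        return self._bend(affined, +1.0)

    def inverse(self, pts: np.ndarray) -> np.ndarray:
        pts = self._bend(np.asarray(pts, dtype=float).reshape(-1, 3), -1.0)
        return (pts - self.center - self.translation) @ \
            np.linalg.inv(self.affine).T + self.center

    def to_ddf(self) -> np.ndarray:
        grid = np.stack(
            np.meshgrid(*(np.arange(s, dtype=float) for s in self.shape),
                        indexing="ij"), axis=-1)
        pts = grid.reshape(-1, 3)
        return (self.forward(pts) - pts).reshape(grid.shape)

    def resample(self, vol: np.ndarray, order: int = 1) -> np.ndarray:
        """Moving image: ``moving(q) = fixed(inverse(q))``."""
        grid = np.stack(
            np.meshgrid(*(np.arange(s, dtype=float) for s in self.shape),
                        indexing="ij"), axis=-1)
        src = self.inverse(grid.reshape(-1, 3)).T
        if vol.ndim == 4:
            return np.stack(
                [ndimage.map_coordinates(vol[..., c], src, order=order,
                                         cval=0.0).reshape(self.shape)
                 for c in range(vol.shape[3])], axis=-1)
        out = ndimage.map_coordinates(np.asarray(vol, dtype=float), src,
                                      order=order, cval=0.0)
        return out.reshape(self.shape)


def random_deformation(cfg: SynthConfig, rng: np.random.Generator
                       ) -> SmoothDeformation:
    dims = np.asarray(cfg.shape, dtype=float)
    affine = np.eye(3) + rng.uniform(
        -cfg.affine_strength, cfg.affine_strength, (3, 3))
    translation = rng.uniform(-cfg.affine_strength, cfg.affine_strength, 3) * dims
    return SmoothDeformation(
        cfg.shape, affine, translation, cfg.bend_amplitude,
        cfg.bend_period or float(dims[0]))


def make_deformed_pair(cfg: SynthConfig):
    """Fixed/moving pair under a known smooth deformation.

    Returns ``(fixed, moving, fixed_centroids, moving_centroids, rois,
    deformation)``; applying ``deformation.forward`` to the fixed
    centroids reproduces the moving centroids exactly.  Deformations that
    would push a centroid out of bounds are redrawn.
    """
    rng = np.random.default_rng(cfg.seed)
    fixed, rois, centroids, _ = make_nuclei_volume(replace(cfg, noise_sd=0.0))
    upper = np.asarray(cfg.shape, dtype=float) - 1
    for attempt in range(50):
        deform = random_deformation(cfg, rng)
        moved = deform.forward(centroids.points)
        if (moved >= 0).all() and (moved <= upper).all():
            break
    else:
        raise RuntimeError("could not draw an in-bounds deformation")
    moving = deform.resample(fixed)
    if cfg.noise_sd:
        noise_rng = np.random.default_rng(cfg.seed + 1)
        fixed = fixed + noise_rng.normal(0.0, cfg.noise_sd, fixed.shape)
        moving = moving + noise_rng.normal(0.0, cfg.noise_sd, moving.shape)
    moving_centroids = centroids.replace_points(moved)
    return fixed, moving, centroids, moving_centroids, rois, deform


# ---------------------------------------------------------------------------
# trace time series with planted identity swaps


def make_gfp_timeseries(n_traces: int = 20, n_timepoints: int = 100,
                        frac_positive: float = 0.5, swap_rate: float = 0.0,
                        noise_sd: float = 0.05, positive_level: float = 3.0,
                        negative_level: float = 0.2, seed: int = 0):
    """Constant-baseline traces with planted identity swaps.

    A fraction ``frac_positive`` of traces sits at ``positive_level``
    (green-positive), the rest at ``negative_level``; observation noise is
    Gaussian.  Each (trace, timepoint) cell independently swaps its value
    with the opposite population at ``swap_rate``.  Returns ``(traces,
    swap_mask)`` as a DataFrame and boolean array.
    """
    if not 0 < frac_positive < 1:
        raise ValueError("frac_positive must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_pos = max(1, round(n_traces * frac_positive))
    levels = np.full(n_traces, negative_level)
    levels[:n_pos] = positive_level
    values = levels[:, None] + rng.normal(0.0, noise_sd,
                                          (n_traces, n_timepoints))
    swaps = rng.random((n_traces, n_timepoints)) < swap_rate
    other = np.where(levels[:, None] == positive_level,
                     negative_level, positive_level)
    values = np.where(
        swaps, other + rng.normal(0.0, noise_sd, values.shape), values)
    return pd.DataFrame(values), swaps


# ---------------------------------------------------------------------------
# multi-animal cohorts


def make_neuropal_cohort(cfg: SynthConfig, n_animals: int):
    """Cohort of multi-spectral animals sharing one canonical cell layout.

    Each animal is the canonical multi-channel nuclei volume under a
    per-animal smooth deformation plus positional jitter; per-cell-type
    channel signatures are conserved across animals (with multiplicative
    jitter).  Returns a list of ``(volume, rois, table)`` triples, and the
    per-animal deformations as ground-truth correspondence (cells with
    equal ROI index correspond across animals).
    """
    if n_animals < 2:
        raise ValueError("a cohort needs at least 2 animals")
    if cfg.n_channels < 2:
        raise ValueError("cohorts are multi-spectral; set n_channels >= 2")
    animals = []
    deforms = []
    for a in range(n_animals):
        acfg = replace(cfg, seed=cfg.seed)  # same layout for all animals
        vol, rois, centroids, table = make_nuclei_volume(
            replace(acfg, noise_sd=0.0))
        rng = np.random.default_rng(cfg.seed + 1000 * (a + 1))
        if a == 0 or (cfg.affine_strength == 0 and cfg.bend_amplitude == 0):
            deform = SmoothDeformation(cfg.shape, np.eye(3), np.zeros(3),
                                       0.0, 1.0)
            moved_vol, moved_rois = vol, rois
        else:
            deform = random_deformation(cfg, rng)
            moved_vol = deform.resample(vol)
            moved_rois = deform.resample(rois.astype(float), order=0
                                         ).astype(rois.dtype)
        if cfg.noise_sd:
            moved_vol = moved_vol + rng.normal(0.0, cfg.noise_sd,
                                               moved_vol.shape)
        animals.append((moved_vol, moved_rois, table.copy()))
        deforms.append(deform)
    return animals, deforms


def composed_pair_ddf(deform_moving: SmoothDeformation,
                      deform_fixed: SmoothDeformation, shape) -> np.ndarray:
    """Ground-truth DDF registering one deformed copy onto another.

    Both deformations act on the same canonical volume; the DDF maps
    fixed-image coordinates through the canonical frame into the moving
    image: ``p -> forward_moving(inverse_fixed(p)) - p``.
    """
    grid = np.stack(
        np.meshgrid(*(np.arange(s, dtype=float) for s in shape),
                    indexing="ij"), axis=-1)
    pts = grid.reshape(-1, 3)
    mapped = deform_moving.forward(deform_fixed.inverse(pts))
    return (mapped - pts).reshape(grid.shape)
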