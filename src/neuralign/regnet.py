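"""Registration networks: LocalNet variants, training, and inference.

The registration model is a LocalNet -- a 3-D U-Net whose output layer
averages upsampled 3-channel projections of the bottom block and of every
decoder level -- mapping a concatenated (fixed, moving) image pair to a
dense displacement field (DDF).  Three variants are provided:

* ``worm`` -- single-channel pairs, trained with LNCC image loss, centroid
  alignment loss, and the four-term regularizer;
* ``jellyfish`` -- as ``worm`` but the z-displacement is zeroed after the
  output layer, the gradient norm ignores z, and no centroid loss is used;
* ``discovery`` -- 4-channel multi-spectral pairs concatenated along the
  existing channel axis (8-channel stem), squared channel-averaged NCC
  image loss, no centroid loss.

Training runs on the package's own autodiff engine at configurable (desk
scale) volume sizes; centroids enter only through the loss, never as model
input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import nn
from .exceptions import ConfigurationError
from .losses import PRESETS, LossWeights
from .volumes import CentroidList
from .warp import warp_image

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class RegNetConfig:
    """Architecture settings.

    ``base_channels * 2**i`` feature channels at level *i*; the spatial
    shape must be divisible by ``2**levels``.  ``input_channels`` is per
    image (1 for worm/jellyfish, 4 for discovery).
    """

    input_shape: tuple = (284, 120, 64)
    input_channels: int = 1
    levels: int = 3
    base_channels: int = 16
    variant: str = "worm"

    def __post_init__(self):
        if self.variant not in ("worm", "jellyfish", "discovery"):
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if any(s % 2**self.levels for s in self.input_shape):
            raise ConfigurationError(
                f"shape {self.input_shape} not divisible by 2^{self.levels}"
            )
        if self.base_channels % 4:
            raise ConfigurationError("base_channels must be divisible by 4")
        if self.variant == "discovery" and self.input_channels == 1:
            object.__setattr__(self, "input_channels", 4)


@dataclass
class TrainConfig:
    """Training-loop settings (Adam, learning rate 1e-4 by default)."""

    learning_rate: float = 1e-4
    epochs: int = 10
    seed: int = 0
    preset: str = "worm"
    weights: LossWeights | None = None
    lncc_n: int = 16
    lncc_eps: float = 1e-7
    augment_strength: float = 0.0
    augment_rot90: bool = False

    def loss_weights(self) -> LossWeights:
        return self.weights if self.weights is not None else PRESETS[self.preset]


@dataclass
class RegistrationProblem:
    """One training/inference pair.

    ``fixed``/``moving`` are (X, Y, Z) arrays, or (X, Y, Z, C) for the
    discovery variant; centroid lists may be ``None`` for presets that do
    not use the centroid loss.
    """

    fixed: np.ndarray
    moving: np.ndarray
    fixed_centroids: CentroidList | None = None
    moving_centroids: CentroidList | None = None


# ---------------------------------------------------------------------------
# architecture


def _halve_even(c: int) -> int:
    """Half the channel count, rounded up to keep it even."""
    h = c // 2
    return h + (h % 2)


class _ConvBlock(nn.Module):
    """conv(k=3) -> batch-norm -> ReLU."""

    def __init__(self, cin, cout, rng):
        self.conv = nn.Conv3d(cin, cout, rng)
        self.norm = nn.BatchNorm3d(cout)

    def __call__(self, x):
        return self.norm(self.conv(x)).relu()


class _ResidualBlock(nn.Module):
    """Two conv blocks; the input is added before the second ReLU."""

    def __init__(self, c, rng):
        self.block1 = _ConvBlock(c, c, rng)
        self.conv2 = nn.Conv3d(c, c, rng)
        self.norm2 = nn.BatchNorm3d(c)

    def __call__(self, x):
        h = self.norm2(self.conv2(self.block1(x)))
        return (h + x).relu()


class _EncoderBlock(nn.Module):
    def __init__(self, cin, cout, rng):
        self.block = _ConvBlock(cin, cout, rng)
        self.res = _ResidualBlock(cout, rng)

    def __call__(self, x):
        skip = self.res(self.block(x))
        return skip, nn.maxpool2(skip)


class _DecoderBlock(nn.Module):
    """Transposed-conv + resize-split-sum upsampling, skip concat, convs."""

    def __init__(self, cin, skip_ch, rng):
        if cin % 2:
            raise ConfigurationError("decoder input channels must be even")
        self.up = nn.ConvTranspose3d(cin, cin // 2, rng)
        self.out_channels = _halve_even(cin // 2 + skip_ch)
        self.block = _ConvBlock(cin // 2 + skip_ch, self.out_channels, rng)
        self.res = _ResidualBlock(self.out_channels, rng)

    def __call__(self, x, skip):
        half = x.data.shape[0] // 2
        up = self.up(x)
        resized = nn.resize_linear(x, tuple(2 * s for s in x.data.shape[1:]))
        summed = resized[:half] + resized[half:]
        merged = nn.concat([up + summed, skip], axis=0)
        return self.res(self.block(merged))


class LocalNet(nn.Module):
    """Image-pair -> DDF network.  See the module docstring."""

    def __init__(self, cfg: RegNetConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        b = cfg.base_channels
        stem = 2 * cfg.input_channels
        enc_ch = [b * 2**i for i in range(cfg.levels)]
        self.encoders = []
        cin = stem
        for c in enc_ch:
            self.encoders.append(_EncoderBlock(cin, c, rng))
            cin = c
        self.bottom = _ConvBlock(enc_ch[-1], enc_ch[-1], rng)
        self.decoders = []
        cin = enc_ch[-1]
        for skip_ch in reversed(enc_ch):
            dec = _DecoderBlock(cin, skip_ch, rng)
            self.decoders.append(dec)
            cin = dec.out_channels
        head_in = [enc_ch[-1]] + [d.out_channels for d in self.decoders]
        # zero-initialized heads: the initial DDF is the identity map
        self.heads = [nn.Conv3d(c, 3, rng, zero_init=True) for c in head_in]

    def __call__(self, fixed: np.ndarray, moving: np.ndarray) -> nn.Tensor:
        """Forward pass; returns the DDF as an (X, Y, Z, 3) tensor."""
        x = nn.Tensor(_stack_pair(fixed, moving, self.cfg))
        skips = []
        for enc in self.encoders:
            skip, x = enc(x)
            skips.append(skip)
        x = self.bottom(x)
        outputs = [x]
        for dec, skip in zip(self.decoders, reversed(skips)):
            x = dec(x, skip)
            outputs.append(x)
        full = tuple(self.cfg.input_shape)
        total = None
        for head, h in zip(self.heads, outputs):
            proj = nn.resize_linear(head(h), full)
            total = proj if total is None else total + proj
        ddf = (total * (1.0 / len(outputs))).transpose((1, 2, 3, 0))
        if self.cfg.variant == "jellyfish":
            mask = np.array([1.0, 1.0, 0.0])
            ddf = ddf * nn.Tensor(mask)
        return ddf


def _stack_pair(fixed, moving, cfg: RegNetConfig) -> np.ndarray:
    """Concatenate a pair along the channel axis, channel-first."""
    def chan_first(v):
        v = np.asarray(v, dtype=float)
        if v.ndim == 3:
            v = v[..., None]
        return np.moveaxis(v, -1, 0)

    f, m = chan_first(fixed), chan_first(moving)
    if f.shape != m.shape or f.shape[1:] != tuple(cfg.input_shape):
        raise ValueError("image pair does not match the configured shape")
    if f.shape[0] != cfg.input_channels:
        raise ValueError(
            f"expected {cfg.input_channels} channels per image, got {f.shape[0]}"
        )
    return np.concatenate([m, f], axis=0)


def build_localnet(cfg: RegNetConfig, seed: int = 0) -> LocalNet:
    return LocalNet(cfg, seed=seed)


# ---------------------------------------------------------------------------
# differentiable loss


def _lncc_loss_tensor(fixed: np.ndarray, warped: nn.Tensor, n: int, eps: float):
    from .losses import sliding_mean

    ef = sliding_mean(fixed, n)
    vf = np.maximum(sliding_mean(fixed * fixed, n) - ef * ef, 0.0)
    ep = nn.box_mean(warped, n)
    efp = nn.box_mean(warped * nn.Tensor(fixed), n)
    vp = (nn.box_mean(warped * warped, n) - ep * ep).clip_min(0.0)
    lncc = (efp - ep * nn.Tensor(ef)) ** 2 / (vp * nn.Tensor(vf) + eps)
    return -lncc.mean()


def _ncc_sq_channel_tensor(fixed_c: np.ndarray, warped_c: nn.Tensor):
    df = fixed_c - fixed_c.mean()
    vf = np.mean(df * df)
    mu = warped_c.mean()
    dp = warped_c - mu
    vp = (dp * dp).mean()
    cov = (dp * nn.Tensor(df)).mean()
    return (cov * cov) / (vp * vf + 1e-12)


def _regularizers_tensor(ddf: nn.Tensor, weights: LossWeights):
    """Differentiable versions of the four DDF regularizers."""
    X, Y, Z = ddf.data.shape[:3]

    def cdiff(t):
        dx = (t[2:, 1:-1, 1:-1] - t[:-2, 1:-1, 1:-1]) * 0.5
        dy = (t[1:-1, 2:, 1:-1] - t[1:-1, :-2, 1:-1]) * 0.5
        dz = (t[1:-1, 1:-1, 2:] - t[1:-1, 1:-1, :-2]) * 0.5
        return dx, dy, dz

    comps = {}
    if weights.grad_2d:
        gx = (ddf[2:, 1:-1] - ddf[:-2, 1:-1]) * 0.5
        gy = (ddf[1:-1, 2:] - ddf[1:-1, :-2]) * 0.5
        comps["grad"] = ((gx * gx).sum() + (gy * gy).sum()) * (
            1.0 / (3 * (X - 2) * (Y - 2) * Z)
        )
    else:
        dx, dy, dz = cdiff(ddf)
        comps["grad"] = ((dx * dx).sum() + (dy * dy).sum() + (dz * dz).sum()) * (
            1.0 / (3 * (X - 2) * (Y - 2) * (Z - 2))
        )
    comps["diff"] = (ddf * ddf).sum() * (1.0 / (3 * X * Y * Z))
    zc = ddf[..., 2]
    comps["axis"] = (zc * zc).mean()
    grid = np.stack(
        np.meshgrid(*(np.arange(s, dtype=float) for s in (X, Y, Z)), indexing="ij"),
        axis=-1,
    )
    dxr, dyr, dzr = cdiff(ddf + nn.Tensor(grid))
    m = (dxr * dxr + dyr * dyr + dzr * dzr).clip_min(1e-8)
    comps["nonrigid"] = (m + 1.0 / m - 2.0).mean()
    return comps


def registration_loss_tensor(
    ddf: nn.Tensor,
    problem: RegistrationProblem,
    weights: LossWeights,
    lncc_n: int = 16,
    eps: float = 1e-7,
) -> nn.Tensor:
    """Composite weighted loss as a differentiable scalar tensor."""
    fixed = np.asarray(problem.fixed, dtype=float)
    moving = np.asarray(problem.moving, dtype=float)
    if fixed.ndim == 4:  # multi-channel: squared channel-averaged NCC
        total_img = None
        for c in range(fixed.shape[3]):
            warped_c = nn.warp_volume(moving[..., c], ddf)
            term = _ncc_sq_channel_tensor(fixed[..., c], warped_c)
            total_img = term if total_img is None else total_img + term
        image_loss = -(total_img * (1.0 / fixed.shape[3]))
    else:
        warped = nn.warp_volume(moving, ddf)
        image_loss = _lncc_loss_tensor(fixed, warped, lncc_n, eps)

    total = weights.wI * image_loss
    if weights.wC > 0:
        if problem.fixed_centroids is None or problem.moving_centroids is None:
            raise ValueError("centroid loss requires matched centroid lists")
        pred = nn.warp_points(problem.fixed_centroids.points, ddf)
        delta = pred - nn.Tensor(problem.moving_centroids.points)
        dist = ((delta * delta).sum(axis=1) + 1e-12).sqrt()
        total = total + weights.wC * dist.mean()

    comps = _regularizers_tensor(ddf, weights)
    reg = (
        weights.w_grad * comps["grad"]
        + weights.w_diff * comps["diff"]
        + weights.w_axis * comps["axis"]
        + weights.w_nonrigid * comps["nonrigid"]
    )
    return total + weights.wR * reg


# ---------------------------------------------------------------------------
# augmentation


def _affine_from_corners(shape, strength: float, rng: np.random.Generator):
    """Random affine map from perturbed cube-corner correspondences.

    The eight corners of the volume are displaced by uniform offsets of up
    to ``strength`` times each dimension; the least-squares affine fitting
    those correspondences is returned as ``(A, b)`` (point map
    ``p -> A p + b``).  Degenerate draws are resampled.
    """
    dims = np.asarray(shape, dtype=float)
    corners = np.array(
        [[x, y, z] for x in (0, dims[0] - 1) for y in (0, dims[1] - 1)
         for z in (0, dims[2] - 1)]
    )
    for _ in range(100):
        target = corners + rng.uniform(-strength, strength, corners.shape) * dims
        hom = np.concatenate([corners, np.ones((8, 1))], axis=1)
        sol, *_ = np.linalg.lstsq(hom, target, rcond=None)
        a = sol[:3].T
        bvec = sol[3]
        if abs(np.linalg.det(a)) > 1e-3:
            return a, bvec
        logger.info("degenerate affine perturbation; resampling")
    raise RuntimeError("could not draw a non-degenerate affine augmentation")


def _apply_affine_volume(vol, a, b, order=1):
    vol = np.asarray(vol, dtype=float)
    inv = np.linalg.inv(a)
    fill = float(np.median(vol))
    if vol.ndim == 3:
        return ndimage.affine_transform(
            vol, inv, offset=-inv @ b, order=order, cval=fill
        )
    return np.stack(
        [
            ndimage.affine_transform(
                vol[..., c], inv, offset=-inv @ b, order=order,
                cval=float(np.median(vol[..., c])),
            )
            for c in range(vol.shape[3])
        ],
        axis=-1,
    )


def augment_affine_pair(
    fixed,
    moving,
    fixed_centroids: CentroidList | None,
    moving_centroids: CentroidList | None,
    strength: float,
    seed_or_rng,
):
    """One random affine applied identically to both images and centroids.

    Images (all channels) are resampled with linear interpolation and
    median fill; centroids are mapped analytically.  The same seed gives
    bit-identical output.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    if strength == 0:
        return fixed, moving, fixed_centroids, moving_centroids
    shape = np.asarray(fixed).shape[:3]
    a, b = _affine_from_corners(shape, strength, rng)
    out_f = _apply_affine_volume(fixed, a, b)
    out_m = _apply_affine_volume(moving, a, b)

    def map_centroids(cl):
        if cl is None:
            return None
        return cl.replace_points(cl.points @ a.T + b)

    return out_f, out_m, map_centroids(fixed_centroids), map_centroids(moving_centroids)


def augment_rot90(fixed, moving, seed_or_rng):
    """Rotate both images of a pair by the same random multiple of 90 deg.

    The rotation is in the x-y plane; x and y extents must be equal.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    fixed = np.asarray(fixed)
    if fixed.shape[0] != fixed.shape[1]:
        raise ValueError("x-y plane must be square for 90-degree rotation")
    k = int(rng.integers(0, 4))
    return np.rot90(fixed, k, axes=(0, 1)).copy(), np.rot90(
        np.asarray(moving), k, axes=(0, 1)
    ).copy(), k


# ---------------------------------------------------------------------------
# training / inference


def train_registration(
    model: LocalNet,
    dataset: list[RegistrationProblem],
    cfg: TrainConfig,
    val_dataset: list[RegistrationProblem] | None = None,
):
    """Train a registration model; returns ``(model, history)``.

    ``history`` is a dict with per-epoch mean training loss (and validation
    loss when a validation set is given).  Centroids are consumed only by
    the loss.  A non-finite loss aborts with a diagnostic.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    weights = cfg.loss_weights()
    if weights.wC > 0:
        for p in dataset:
            if p.fixed_centroids is None or p.moving_centroids is None:
                raise ValueError("this preset requires matched centroids per pair")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    history = {"train": [], "val": []}
    for epoch in range(cfg.epochs):
        losses = []
        for prob in dataset:
            prob_aug = prob
            if cfg.augment_strength > 0:
                f, m, fc, mc = augment_affine_pair(
                    prob.fixed, prob.moving, prob.fixed_centroids,
                    prob.moving_centroids, cfg.augment_strength, rng,
                )
                prob_aug = RegistrationProblem(f, m, fc, mc)
            if cfg.augment_rot90:
                f, m, _ = augment_rot90(prob_aug.fixed, prob_aug.moving, rng)
                prob_aug = RegistrationProblem(
                    f, m, prob_aug.fixed_centroids, prob_aug.moving_centroids
                )
            ddf = model(prob_aug.fixed, prob_aug.moving)
            loss = registration_loss_tensor(
                ddf, prob_aug, weights, cfg.lncc_n, cfg.lncc_eps
            )
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {loss.data!r}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["train"].append(float(np.mean(losses)))
        if val_dataset:
            history["val"].append(
                float(
                    np.mean(
                        [
                            evaluate_loss(model, p, weights, cfg)
                            for p in val_dataset
                        ]
                    )
                )
            )
    return model, history


def evaluate_loss(
    model: LocalNet, problem: RegistrationProblem, weights, cfg: TrainConfig
) -> float:
    ddf = model(problem.fixed, problem.moving)
    return float(
        registration_loss_tensor(
            ddf, problem, weights, cfg.lncc_n, cfg.lncc_eps
        ).data
    )


def infer_ddf(model: LocalNet, fixed: np.ndarray, moving: np.ndarray) -> np.ndarray:
    """Deterministic DDF for an image pair (no centroid information used)."""
    return model(fixed, moving).data


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model: LocalNet, path) -> None:
    params = model.parameters()
    arrays = {f"p{i}": p.data for i, p in enumerate(params)}
    cfg = model.cfg
    meta = json.dumps(
        {
            "input_shape": list(cfg.input_shape),
            "input_channels": cfg.input_channels,
            "levels": cfg.levels,
            "base_channels": cfg.base_channels,
            "variant": cfg.variant,
        }
    )
    np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> LocalNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        cfg = RegNetConfig(
            input_shape=tuple(meta["input_shape"]),
            input_channels=meta["input_channels"],
            levels=meta["levels"],
            base_channels=meta["base_channels"],
            variant=meta["variant"],
        )
        model = LocalNet(cfg)
        for i, p in enumerate(model.parameters()):
            p.data[...] = data[f"p{i}"]
    return model


def jellyfish_pairs(frames: list[np.ndarray]) -> list[RegistrationProblem]:
    """Pair builder for quasi-2-D recordings: every frame registers to the
    first frame of the dataset (the jellyfish preset's fixed-image
    convention); no centroids are attached since that preset trains
    without the centroid loss."""
    if not frames:
        raise ValueError("empty frame list")
    fixed = np.asarray(frames[0], dtype=float)
    return [RegistrationProblem(fixed, np.asarray(f, dtype=float))
            for f in frames[1:]]
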