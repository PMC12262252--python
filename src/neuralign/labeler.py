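"""Multi-spectral cell annotation: weighted training targets, the
pixel-weighted loss and metric, ROI-level label extraction, and the
postprocessing heuristics, plus a reduced trainable 3-D U-Net.

Label arrays in this module follow the label-stack convention
``(K, Z, Y, X)`` (channel-first, z-major), matching how annotated label
volumes are stored on disk; image volumes entering the network are
``(C, Z, Y, X)``.  Conversion from the package's (x, y, z) volumes happens
via :func:`to_zyx` / :func:`from_zyx`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import nn
from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)

#: Human-confidence weighting of labels; confidence-1 labels are excluded.
CONFIDENCE_WEIGHTS = {2: 50.0, 3: 600.0, 4: 900.0, 5: 1000.0}

#: Rarity normalizer: the maximum count of any neuronal label in the
#: reference annotation corpus.
RARITY_NORMALIZER = 130.0

#: Neuron classes rarely present in annotated data; their predicted labels
#: are deleted during postprocessing.
RARE_CLASSES = (
    "ADF", "AFD", "AVF", "AVG", "DB02", "DD01", "RIF", "RIG",
    "RMF", "RMH", "SAB", "SABV", "SIAD", "SIBD", "VA01", "VD01",
)

#: Non-neuronal classes whose labels are always deleted.
NON_NEURONAL = ("glia", "granule")


def to_zyx(vol_xyz: np.ndarray) -> np.ndarray:
    """(x, y, z[, c]) -> (c,) z, y, x."""
    v = np.asarray(vol_xyz)
    if v.ndim == 3:
        return v.transpose(2, 1, 0)
    return v.transpose(3, 2, 1, 0)


def from_zyx(vol_zyx: np.ndarray) -> np.ndarray:
    v = np.asarray(vol_zyx)
    if v.ndim == 3:
        return v.transpose(2, 1, 0)
    return v.transpose(3, 2, 1, 0)


# ---------------------------------------------------------------------------
# catalog


class LabelCatalog:
    """Ordered label names; index 0 is the background.

    Bilateral classes are recorded in an explicit subclass table mapping a
    class name to its L/R member names, so subclass handling never relies
    on parsing names like ``"RMH?"``.
    """

    def __init__(self, names: list[str], lr_pairs: dict[str, tuple[str, str]] | None = None):
        names = list(names)
        if len(set(names)) != len(names):
            raise ValueError("label names must be unique")
        if names[0] != "background":
            raise ValueError("index 0 must be the background label")
        self.names = names
        self.index = {n: i for i, n in enumerate(names)}
        if lr_pairs is None:
            lr_pairs = _infer_lr_pairs(names)
        self.lr_pairs = dict(lr_pairs)
        self.subclass_to_class = {}
        for cls, (left, right) in self.lr_pairs.items():
            self.subclass_to_class[left] = cls
            self.subclass_to_class[right] = cls

    def __len__(self) -> int:
        return len(self.names)

    def class_of(self, name: str) -> str:
        """Class-level name with the L/R subclass stripped (D/V kept)."""
        return self.subclass_to_class.get(name, name)


def _infer_lr_pairs(names) -> dict[str, tuple[str, str]]:
    pairs = {}
    name_set = set(names)
    for n in names:
        if n.endswith("L") and len(n) > 1:
            stem, partner = n[:-1], n[:-1] + "R"
            if partner in name_set and stem not in name_set:
                pairs[stem] = (n, partner)
    return pairs


def make_default_catalog(n_classes: int = 185) -> LabelCatalog:
    """Synthetic stand-in catalog with the reference structure.

    Real annotation corpora define ~185 labels (background, bilateral L/R
    neuron pairs, D/V classes, the ambiguous "RMH?", and the non-neuronal
    "glia"/"granule" classes).  The true name list is data-dependent, so
    this constructor fabricates a catalog of the same size and structure:
    the rare classes referenced by postprocessing, glia/granule, RMH?, and
    generated bilateral pairs (``N01L/N01R`` ...) to fill the remainder.
    """
    names = ["background", "glia", "granule", "RMH?"]
    names += [c for c in RARE_CLASSES]
    i = 1
    while len(names) < n_classes:
        names += [f"N{i:02d}L", f"N{i:02d}R"]
        i += 1
    return LabelCatalog(names[:n_classes])


# ---------------------------------------------------------------------------
# training targets


def one_hot_labels(rois_zyx: np.ndarray, table: pd.DataFrame, catalog: LabelCatalog,
                   min_confidence: int = 2) -> np.ndarray:
    """One-hot (K, Z, Y, X) label matrix from an ROI volume and label table.

    ROIs without a usable label (unlabeled, or confidence below
    ``min_confidence``) are background; the background channel is 1
    wherever every other channel is 0.
    """
    rois_zyx = np.asarray(rois_zyx)
    k = len(catalog)
    out = np.zeros((k,) + rois_zyx.shape, dtype=np.uint8)
    assigned = np.zeros(rois_zyx.shape, dtype=bool)
    for row in table.itertuples():
        if int(row.confidence) < min_confidence:
            continue
        if row.label not in catalog.index:
            raise KeyError(f"unknown label {row.label!r}")
        mask = rois_zyx == int(row.roi_index)
        out[catalog.index[row.label]][mask] = 1
        assigned |= mask
    out[0] = ~assigned
    return out


def build_weight_volume(
    rois_zyx: np.ndarray,
    table: pd.DataFrame,
    global_label_counts: dict[str, int],
    catalog: LabelCatalog,
    confidence_weights: dict[int, float] = CONFIDENCE_WEIGHTS,
    rarity_normalizer: float = RARITY_NORMALIZER,
) -> np.ndarray:
    """Per-voxel training weights (Z, Y, X).

    Background voxels weigh 1; a voxel of an ROI labeled ``l`` at
    confidence ``c`` weighs ``(rarity_normalizer / N_l) * f(c)`` where
    ``N_l`` is the corpus-wide count of label ``l`` and ``f`` maps
    confidence 2..5 to (50, 600, 900, 1000).  Confidence-1 labels are
    excluded (weight 1, like background).
    """
    rois_zyx = np.asarray(rois_zyx)
    w = np.ones(rois_zyx.shape, dtype=float)
    for row in table.itertuples():
        conf = int(row.confidence)
        if conf not in (1, 2, 3, 4, 5):
            raise ValueError(f"confidence must be 1..5, got {conf}")
        if conf == 1:
            continue
        if row.label not in catalog.index:
            raise KeyError(f"unknown label {row.label!r}")
        n_l = global_label_counts.get(row.label, 0)
        if n_l < 1:
            raise ValueError(f"global count for {row.label!r} must be >= 1")
        w[rois_zyx == int(row.roi_index)] = (
            rarity_normalizer / n_l
        ) * confidence_weights[conf]
    return w


# ---------------------------------------------------------------------------
# loss and metric


def weighted_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                           weights: np.ndarray) -> float:
    """Pixel-wise weighted cross-entropy.

    ``-(1 / XYZK) sum W * L * log softmax(logits)`` with the softmax over
    the label channel; approaches 0 as predictions become confidently
    correct everywhere.
    """
    logits = np.asarray(logits, dtype=float)
    k = logits.shape[0]
    shift = logits - logits.max(axis=0, keepdims=True)
    logp = shift - np.log(np.exp(shift).sum(axis=0, keepdims=True))
    per_voxel = -(np.asarray(labels) * logp).sum(axis=0) * np.asarray(weights)
    return float(per_voxel.sum() / (per_voxel.size * k))


def weighted_cross_entropy_tensor(logits: nn.Tensor, labels: np.ndarray,
                                  weights: np.ndarray) -> nn.Tensor:
    """Differentiable version of :func:`weighted_cross_entropy`."""
    k = logits.data.shape[0]
    logp = nn.log_softmax(logits, axis=0)
    wl = np.asarray(labels, dtype=float) * np.asarray(weights, dtype=float)[None]
    total = (logp * nn.Tensor(wl)).sum()
    return -total * (1.0 / (k * np.prod(logits.data.shape[1:])))


def argmax_one_hot(p: np.ndarray) -> np.ndarray:
    """Per-voxel argmax of a (K, ...) stack as one-hot; ties -> lower index."""
    idx = np.asarray(p).argmax(axis=0)
    out = np.zeros_like(p, dtype=np.uint8)
    np.put_along_axis(out, idx[None], 1, axis=0)
    return out


def weighted_mean_iou(p: np.ndarray, labels: np.ndarray,
                      weights: np.ndarray) -> float:
    """Weighted mean intersection-over-union across label channels.

    Per channel n: ``sum(W * L_n * A_n) / sum(W * max(L_n, A_n))`` with A
    the argmax one-hot of ``p``; channels whose denominator is zero (label
    absent and never predicted) are excluded from the average.  1 when the
    argmax equals the labels; 0 when they disagree on every weighted voxel.
    """
    a = argmax_one_hot(p).astype(float)
    l = np.asarray(labels, dtype=float)
    w = np.asarray(weights, dtype=float)[None]
    inter = (w * l * a).sum(axis=tuple(range(1, l.ndim)))
    union = (w * np.maximum(l, a)).sum(axis=tuple(range(1, l.ndim)))
    used = union > 0
    if not used.any():
        return 0.0
    return float(np.mean(inter[used] / union[used]))


# ---------------------------------------------------------------------------
# ROI label assignment


@dataclass
class ROILabelResult:
    roi_index: int
    label: str | None
    confidence: float
    deletion_reason: str | None = None
    merged_from: tuple[str, str] | None = None  # L/R subclass merge

    @property
    def active(self) -> bool:
        return self.label is not None and self.deletion_reason is None


def softmax_probabilities(logits: np.ndarray) -> np.ndarray:
    """Softmax over the label channel of (K, Z, Y, X) logits."""
    shift = np.asarray(logits, dtype=float)
    shift = shift - shift.max(axis=0, keepdims=True)
    e = np.exp(shift)
    return e / e.sum(axis=0, keepdims=True)


def roi_edge_mask(rois_zyx: np.ndarray) -> np.ndarray:
    """Weight mask: 1 on ROI interiors, 0.01 on face-adjacent edges, 0 outside."""
    rois_zyx = np.asarray(rois_zyx)
    interior = np.ones(rois_zyx.shape, dtype=bool)
    for axis in range(rois_zyx.ndim):
        shifted_fwd = np.roll(rois_zyx, 1, axis=axis)
        shifted_bwd = np.roll(rois_zyx, -1, axis=axis)
        same_fwd = shifted_fwd == rois_zyx
        same_bwd = shifted_bwd == rois_zyx
        # array borders count as exterior
        same_fwd[(slice(None),) * axis + (0,)] = False
        same_bwd[(slice(None),) * axis + (-1,)] = False
        interior &= same_fwd & same_bwd
    mask = np.where(interior, 1.0, 0.01)
    mask[rois_zyx == 0] = 0.0
    return mask


def roi_prediction_matrix(p: np.ndarray, rois_zyx: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Edge-discounted per-ROI probability rows D (V x K); rows sum to 1."""
    rois_zyx = np.asarray(rois_zyx)
    mask = roi_edge_mask(rois_zyx)
    indices = [int(i) for i in np.unique(rois_zyx) if i > 0]
    if not indices:
        return np.zeros((0, p.shape[0])), []
    flat_roi = rois_zyx.ravel()
    flat_mask = mask.ravel()
    nmax = max(indices) + 1
    denom = np.bincount(flat_roi, weights=flat_mask, minlength=nmax)
    rows = np.zeros((len(indices), p.shape[0]))
    for n in range(p.shape[0]):
        num = np.bincount(flat_roi, weights=flat_mask * p[n].ravel(), minlength=nmax)
        rows[:, n] = num[indices]
    rows /= denom[indices][:, None]
    return rows, indices


def roi_label_assignment(p: np.ndarray, rois_zyx: np.ndarray,
                         catalog: LabelCatalog) -> list[ROILabelResult]:
    """Assign each ROI the label with the largest edge-discounted mean
    probability; the confidence is that probability mass.

    Ties break toward the lower label index.  Empty ROI sets yield an
    empty result list.
    """
    rows, indices = roi_prediction_matrix(p, rois_zyx)
    results = []
    for row, idx in zip(rows, indices):
        n_i = int(row.argmax())
        results.append(
            ROILabelResult(idx, catalog.names[n_i], float(row[n_i]))
        )
    return results


# ---------------------------------------------------------------------------
# postprocessing


@dataclass(frozen=True)
class PostprocessThresholds:
    merge_distance: float = 4.0        # over-segmentation collision radius
    underseg_probability: float = 0.75
    underseg_min_voxels: int = 10
    underseg_fraction: float = 0.2
    lr_subclass_mass: float = 0.10
    min_confidence: float = 0.75


def postprocess_labels(
    results: list[ROILabelResult],
    p: np.ndarray,
    rois_zyx: np.ndarray,
    centroids: dict[int, np.ndarray],
    catalog: LabelCatalog,
    thresholds: PostprocessThresholds = PostprocessThresholds(),
    rare_classes=RARE_CLASSES,
) -> list[ROILabelResult]:
    """Apply the label-cleanup heuristics, in order:

    1. duplicate resolution by descending confidence (nearby duplicates are
       treated as over-segmentation and share the label; distant ones lose
       the lower-confidence copy);
    2. under-segmentation: an ROI containing >= 10 voxels, or >= 20% of its
       voxels, confidently (P > 0.75) assigned to a different label is
       deleted;
    3. L/R subclass merging: if both subclasses of a bilateral class carry
       > 10% mass, the class-level label is emitted with the summed mass
       (never done for D/V subclasses);
    4. rare-class and glia/granule deletion;
    5. deletion of labels below 75% confidence.

    Deletions are recorded, never silently dropped; confidences are never
    increased except by the L/R subclass merge, which replaces two
    subclass masses by their sum.
    """
    rows, indices = roi_prediction_matrix(p, rois_zyx)
    row_of = {idx: row for idx, row in zip(indices, rows)}
    out = [
        ROILabelResult(r.roi_index, r.label, r.confidence, r.deletion_reason)
        for r in results
    ]
    order = sorted(range(len(out)), key=lambda i: -out[i].confidence)

    # (1) collisions
    assigned: dict[str, int] = {}
    for i in order:
        r = out[i]
        if r.label is None or r.label == "background":
            continue
        if r.label in assigned:
            other = out[assigned[r.label]]
            dist = np.linalg.norm(
                np.asarray(centroids[r.roi_index])
                - np.asarray(centroids[other.roi_index])
            )
            if dist > thresholds.merge_distance:
                r.deletion_reason = "duplicate-label"
            # else: over-segmentation, both keep the label
        else:
            assigned[r.label] = i

    # (2) under-segmentation
    rois_arr = np.asarray(rois_zyx)
    for r in out:
        if not r.active:
            continue
        n_i = catalog.index[r.label] if r.label in catalog.index else None
        if n_i is None:
            continue
        mask = rois_arr == r.roi_index
        size = int(mask.sum())
        if size == 0:
            continue
        other = p[:, mask]
        confident_other = (
            (np.delete(other, n_i, axis=0) > thresholds.underseg_probability)
            .any(axis=0)
            .sum()
        )
        if confident_other >= thresholds.underseg_min_voxels or (
            confident_other >= thresholds.underseg_fraction * size
        ):
            r.deletion_reason = "under-segmentation"

    # (3) L/R subclass merge
    for r in out:
        if not r.active:
            continue
        cls = catalog.class_of(r.label)
        if cls == r.label:
            continue
        left, right = catalog.lr_pairs[cls]
        row = row_of[r.roi_index]
        ml = float(row[catalog.index[left]])
        mr = float(row[catalog.index[right]])
        if ml > thresholds.lr_subclass_mass and mr > thresholds.lr_subclass_mass:
            r.merged_from = (left, right)
            r.label = cls
            r.confidence = ml + mr

    # (4) rare classes and non-neuronal labels
    rare = set(rare_classes)
    for r in out:
        if not r.active:
            continue
        if r.label in rare:
            r.deletion_reason = "rare-class"
        elif r.label in NON_NEURONAL:
            r.deletion_reason = "non-neuronal"

    # (5) confidence threshold
    for r in out:
        if r.active and r.confidence < thresholds.min_confidence:
            r.deletion_reason = "low-confidence"
    return out


# ---------------------------------------------------------------------------
# reduced 3-D U-Net


@dataclass(frozen=True)
class LabelerConfig:
    """Reduced annotation U-Net settings.

    The full-scale reference uses 4 levels with 64 * 2**i channels and 185
    output classes; tests run far smaller instances.  ``group_size`` caps
    the GroupNorm group (the first convolution always uses group size 1).
    """

    input_shape_zyx: tuple = (64, 120, 284)
    input_channels: int = 4
    n_classes: int = 185
    levels: int = 4
    base_channels: int = 64
    group_size: int = 16

    def __post_init__(self):
        if any(s % 2 ** (self.levels - 1) for s in self.input_shape_zyx):
            raise ConfigurationError(
                f"shape {self.input_shape_zyx} not divisible by "
                f"2^{self.levels - 1}"
            )


class _GNConvBlock(nn.Module):
    """GroupNorm -> conv(k=3) -> ReLU."""

    def __init__(self, cin, cout, rng, group_size):
        g = min(group_size, cin)
        while cin % g:
            g -= 1
        self.norm = nn.GroupNorm(cin, g)
        self.conv = nn.Conv3d(cin, cout, rng)

    def __call__(self, x):
        return self.conv(self.norm(x)).relu()


class LabelerUNet(nn.Module):
    """4-level 3-D U-Net emitting per-voxel label logits (K, Z, Y, X)."""

    def __init__(self, cfg: LabelerConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        ch = [cfg.base_channels * 2**i for i in range(cfg.levels)]
        self.enc_blocks = []
        cin = cfg.input_channels
        for i, c in enumerate(ch):
            g1 = 1 if i == 0 else cfg.group_size
            self.enc_blocks.append(
                [
                    _GNConvBlock(cin, c, rng, g1),
                    _GNConvBlock(c, c, rng, cfg.group_size),
                ]
            )
            cin = c
        self.dec_blocks = []
        for i in reversed(range(cfg.levels - 1)):
            cat = ch[i + 1] + ch[i]
            self.dec_blocks.append(
                [
                    _GNConvBlock(cat, ch[i], rng, cfg.group_size),
                    _GNConvBlock(ch[i], ch[i], rng, cfg.group_size),
                ]
            )
        self.final = nn.Conv3d(ch[0], cfg.n_classes, rng, kernel=1)

    def __call__(self, image_czyx: np.ndarray) -> nn.Tensor:
        image_czyx = np.asarray(image_czyx, dtype=float)
        if image_czyx.ndim == 3:
            image_czyx = image_czyx[None]
        if image_czyx.shape[0] != self.cfg.input_channels:
            raise ValueError(
                f"expected {self.cfg.input_channels} channels, got "
                f"{image_czyx.shape[0]}"
            )
        x = nn.Tensor(image_czyx)
        skips = []
        for i, (b1, b2) in enumerate(self.enc_blocks):
            if i > 0:
                x = nn.maxpool2(x)
            x = b2(b1(x))
            skips.append(x)
        for (b1, b2), skip in zip(self.dec_blocks, reversed(skips[:-1])):
            x = nn.resize_linear(x, skip.data.shape[1:])
            x = nn.concat([x, skip], axis=0)
            x = b2(b1(x))
        return self.final(x)


def build_labeler_unet(cfg: LabelerConfig, seed: int = 0) -> LabelerUNet:
    return LabelerUNet(cfg, seed=seed)


def train_labeler(
    model: LabelerUNet,
    image_czyx: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray,
    epochs: int = 50,
    learning_rate: float = 1e-4,
    augment=None,
    seed: int = 0,
):
    """Train the annotation U-Net on one or more labeled volumes.

    ``image_czyx``/``labels``/``weights`` may be single volumes or lists.
    ``augment`` is an optional callable ``(image, L, W, rng) -> (image, L,
    W)`` applied per iteration.  Returns ``(model, loss_history)``.
    """
    if not isinstance(image_czyx, (list, tuple)):
        image_czyx, labels, weights = [image_czyx], [labels], [weights]
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.parameters(), lr=learning_rate)
    history = []
    for _ in range(epochs):
        losses = []
        for img, lab, w in zip(image_czyx, labels, weights):
            if augment is not None:
                img, lab, w = augment(img, lab, w, rng)
            logits = model(img)
            loss = weighted_cross_entropy_tensor(logits, lab, w)
            if not np.isfinite(loss.data):
                raise RuntimeError("non-finite labeler loss")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    return model, history


# ---------------------------------------------------------------------------
# augmentation of labeled volumes


@dataclass(frozen=True)
class LabelerAugmentSettings:
    """Strengths of the labeled-volume augmentation pipeline.

    Geometric settings are maximal magnitudes of uniformly drawn
    perturbations; all zeros give the exact identity.  In-plane (xy) and
    yz rotations default to much larger ranges than xz, reflecting that
    the specimen lies along x under a coverslip and cannot roll about y.
    """

    rot_xy_deg: float = 10.0
    rot_yz_deg: float = 10.0
    rot_xz_deg: float = 2.0
    translate_vox: float = 4.0
    scale_frac: float = 0.05
    shear_frac: float = 0.05
    bspline_points: int = 5
    bspline_sigma_vox: float = 2.0
    bend_amplitude_vox: float = 4.0
    rot180_prob: float = 0.5
    contrast_frac: float = 0.2
    blur_sigma_max: float = 1.0
    gaussian_noise_sd: float = 0.02
    poisson_scale: float = 0.0  # photons per intensity unit; 0 disables

    @classmethod
    def identity(cls) -> "LabelerAugmentSettings":
        return cls(rot_xy_deg=0, rot_yz_deg=0, rot_xz_deg=0, translate_vox=0,
                   scale_frac=0, shear_frac=0, bspline_sigma_vox=0,
                   bend_amplitude_vox=0, rot180_prob=0, contrast_frac=0,
                   blur_sigma_max=0, gaussian_noise_sd=0, poisson_scale=0)


def _rotation_zyx(axis_pair, deg):
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    m = np.eye(3)
    a, b = axis_pair
    m[a, a] = c
    m[a, b] = -s
    m[b, a] = s
    m[b, b] = c
    return m


def _bend_displacement(shape_zyx, settings, rng):
    """Smooth low-frequency displacement along the x axis (worm bend).

    Control points placed evenly along x receive Gaussian offsets in all
    coordinates plus a bounded random y-displacement forming an arc; cubic
    interpolation yields a per-x-column displacement applied to the whole
    volume.  Returns (3, Z, Y, X) displacement in (z, y, x) order.
    """
    from scipy.interpolate import CubicSpline

    z, y, x = shape_zyx
    n = max(int(settings.bspline_points), 2)
    xs = np.linspace(0, x - 1, n)
    offsets = rng.normal(0.0, settings.bspline_sigma_vox, size=(n, 3))
    if settings.bend_amplitude_vox > 0:
        dy = rng.uniform(-settings.bend_amplitude_vox, settings.bend_amplitude_vox, n)
        # preserve inter-point spacing along the arc: shrink x accordingly
        seg = np.diff(xs)
        dxy = np.diff(dy)
        dx = np.concatenate([[0.0], np.cumsum(seg - np.sqrt(
            np.maximum(seg**2 - dxy**2, 0.0)))])
        offsets[:, 1] += dy
        offsets[:, 2] += dx
    disp_cols = CubicSpline(xs, offsets, axis=0)(np.arange(x))  # (X, 3)
    out = np.zeros((3, z, y, x))
    for m in range(3):
        out[m] = disp_cols[:, m][None, None, :]
    return out


def augment_labeled_volume(image_czyx, labels, weights,
                           settings: LabelerAugmentSettings,
                           seed_or_rng=0):
    """Ordered augmentation of an (image, one-hot label, weight) triple.

    Order: B-spline + bend, rotations, translation, scaling, shearing
    (composed into one resampling), 180-degree rotation about a random
    axis, per-channel contrast, z-gradient Gaussian blur, Gaussian noise,
    Poisson noise.  Geometric operations are applied identically to all
    three arrays (linear interpolation and median fill for the image;
    nearest-neighbor via an index volume for labels, which preserves the
    one-hot sum; nearest with zero fill for weights).  Intensity
    operations touch only the image.  Seeded and deterministic.
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    img = np.asarray(image_czyx, dtype=float)
    single = img.ndim == 3
    if single:
        img = img[None]
    lab = np.asarray(labels)
    w = np.asarray(weights, dtype=float)
    shape = img.shape[1:]

    geometric = (settings.rot_xy_deg or settings.rot_yz_deg
                 or settings.rot_xz_deg or settings.translate_vox
                 or settings.scale_frac or settings.shear_frac
                 or settings.bspline_sigma_vox or settings.bend_amplitude_vox
                 or settings.rot180_prob)
    if geometric:
        disp = np.zeros((3,) + shape)
        if settings.bspline_sigma_vox or settings.bend_amplitude_vox:
            disp += _bend_displacement(shape, settings, rng)
        m = np.eye(3)
        m = m @ _rotation_zyx((1, 2), rng.uniform(-settings.rot_xy_deg,
                                                  settings.rot_xy_deg))
        m = m @ _rotation_zyx((0, 1), rng.uniform(-settings.rot_yz_deg,
                                                  settings.rot_yz_deg))
        m = m @ _rotation_zyx((0, 2), rng.uniform(-settings.rot_xz_deg,
                                                  settings.rot_xz_deg))
        scale = 1.0 + rng.uniform(-settings.scale_frac, settings.scale_frac, 3)
        m = m @ np.diag(scale)
        shear = np.eye(3)
        if settings.shear_frac:
            shear[0, 2] = rng.uniform(-settings.shear_frac, settings.shear_frac)
            shear[1, 2] = rng.uniform(-settings.shear_frac, settings.shear_frac)
        m = m @ shear
        if settings.rot180_prob and rng.random() < settings.rot180_prob:
            axis = int(rng.integers(0, 3))
            flip = -np.ones(3)
            flip[axis] = 1.0
            m = m @ np.diag(flip)
        t = rng.uniform(-settings.translate_vox, settings.translate_vox, 3)
        center = (np.asarray(shape, dtype=float) - 1) / 2
        grid = np.stack(np.meshgrid(*(np.arange(s, dtype=float) for s in shape),
                                    indexing="ij"))
        coords = np.einsum("ij,j...->i...", m, grid - center[:, None, None, None])
        coords += center[:, None, None, None] + t[:, None, None, None] + disp

        img = np.stack([
            ndimage.map_coordinates(ch, coords, order=1, cval=float(np.median(ch)))
            for ch in img
        ])
        lab_idx = lab.argmax(axis=0)
        lab_idx = ndimage.map_coordinates(lab_idx, coords, order=0, cval=0)
        new_lab = np.zeros_like(lab)
        np.put_along_axis(new_lab, lab_idx[None], 1, axis=0)
        lab = new_lab
        w = ndimage.map_coordinates(w, coords, order=0, cval=0.0)

    if settings.contrast_frac:
        for c in range(img.shape[0]):
            factor = 1.0 + rng.uniform(-settings.contrast_frac,
                                       settings.contrast_frac)
            mu = img[c].mean()
            img[c] = mu + (img[c] - mu) * factor
    if settings.blur_sigma_max:
        nz = img.shape[1]
        sigmas = (settings.blur_sigma_max * np.arange(nz) / max(nz - 1, 1))
        for c in range(img.shape[0]):
            for iz, sigma in enumerate(sigmas):
                if sigma > 0:
                    img[c, iz] = ndimage.gaussian_filter(img[c, iz], sigma)
    if settings.gaussian_noise_sd:
        img = img + rng.normal(0.0, settings.gaussian_noise_sd, img.shape)
    if settings.poisson_scale:
        img = rng.poisson(np.clip(img, 0, None) * settings.poisson_scale
                          ) / settings.poisson_scale

    return (img[0] if single else img), lab, w


# ---------------------------------------------------------------------------
# checkpointing


def save_labeler_checkpoint(model: LabelerUNet, path) -> None:
    import json

    cfg = model.cfg
    meta = json.dumps({
        "input_shape_zyx": list(cfg.input_shape_zyx),
        "input_channels": cfg.input_channels,
        "n_classes": cfg.n_classes,
        "levels": cfg.levels,
        "base_channels": cfg.base_channels,
        "group_size": cfg.group_size,
    })
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_labeler_checkpoint(path) -> LabelerUNet:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        cfg = LabelerConfig(
            input_shape_zyx=tuple(meta["input_shape_zyx"]),
            input_channels=meta["input_channels"],
            n_classes=meta["n_classes"],
            levels=meta["levels"],
            base_channels=meta["base_channels"],
            group_size=meta["group_size"],
        )
        model = LabelerUNet(cfg)
        for i, p in enumerate(model.parameters()):
            p.data[...] = data[f"p{i}"]
    return model
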