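"""Loss and similarity terms of the registration networks.

Three families of terms are implemented:

* image losses -- the local squared zero-normalized cross-correlation
  (LNCC) used for single-channel worm/jellyfish volumes, and the squared
  channel-averaged global NCC used by the cross-animal variant;
* the centroid alignment loss -- mean Euclidean distance between true and
  predicted moving centroids;
* four DDF regularizers -- gradient norm (plus its in-plane 2-D variant),
  difference norm, axis difference norm, and the nonrigid penalty that is
  zero exactly on rigid-body coordinate maps.

These are the reference (numpy) evaluations; the differentiable versions
used in training are built from the same formulas in
:mod:`neuralign.regnet`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError
from .warp import validate_ddf

_M_FLOOR = 1e-8  # lower guard on M before computing 1/M


@dataclass(frozen=True)
class LossWeights:
    """Weights of the composite registration loss.

    ``total = wI * LI + wC * LC + wR * (w_grad*LGrad + w_diff*LDiff +
    w_axis*LAxisDiff + w_nonrigid*LNonrigid)``.
    """

    wI: float = 1.0
    wC: float = 0.1
    wR: float = 1.0
    w_grad: float = 0.02
    w_diff: float = 0.005
    w_axis: float = 0.001
    w_nonrigid: float = 0.02
    grad_2d: bool = False  # use the in-plane gradient norm

    def __post_init__(self):
        for name in ("wI", "wC", "wR", "w_grad", "w_diff", "w_axis", "w_nonrigid"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative loss weight {name}")


#: Single-channel worm preset: image + centroid + all four regularizers.
WORM_WEIGHTS = LossWeights()

#: Jellyfish preset: no centroid term; the gradient norm ignores z.
JELLYFISH_WEIGHTS = LossWeights(wC=0.0, grad_2d=True)

#: Cross-animal multi-spectral preset (squared channel-averaged NCC image
#: loss; no centroid term; no axis term).
DISCOVERY_WEIGHTS = LossWeights(
    wC=0.0, w_grad=0.05, w_diff=0.0025, w_axis=0.0, w_nonrigid=0.05
)

PRESETS = {
    "worm": WORM_WEIGHTS,
    "jellyfish": JELLYFISH_WEIGHTS,
    "discovery": DISCOVERY_WEIGHTS,
}


# ---------------------------------------------------------------------------
# sliding-cube moments (anchored windows, clipped at the far border)


def sliding_sum(x: np.ndarray, n: int) -> np.ndarray:
    """Sum of x over the cube anchored at each voxel, clipped to the grid.

    ``out[p] = sum over q in [p, p+n-1]^3 intersect grid of x[q]``.
    """
    out = np.asarray(x, dtype=float)
    for axis in range(3):
        cs = np.cumsum(out, axis=axis)
        cs = np.concatenate(
            [np.zeros_like(np.take(cs, [0], axis=axis)), cs], axis=axis
        )
        size = out.shape[axis]
        hi = np.minimum(np.arange(size) + n, size)
        lo = np.arange(size)
        out = np.take(cs, hi, axis=axis) - np.take(cs, lo, axis=axis)
    return out


def _window_counts(shape, n: int) -> np.ndarray:
    return sliding_sum(np.ones(shape), n)


def sliding_mean(x: np.ndarray, n: int) -> np.ndarray:
    return sliding_sum(x, n) / _window_counts(x.shape, n)


def lncc_image_loss(
    fixed: np.ndarray, warped: np.ndarray, n: int = 16, eps: float = 1e-7
) -> float:
    """Negative mean local squared zero-normalized cross-correlation.

    Local first and second moments are taken over a sliding cube of side
    ``n`` anchored at each voxel (windows clipped at the far border); the
    loss is ``-mean((E[FP] - E[F]E[P])^2 / (V(F) V(P) + eps))``, in
    ``[-1, 0]`` up to the eps guard.
    """
    fixed = np.asarray(fixed, dtype=float)
    warped = np.asarray(warped, dtype=float)
    if fixed.shape != warped.shape:
        raise ValueError("shape mismatch")
    if n < 2:
        raise ValueError("cube side must be >= 2")
    ef = sliding_mean(fixed, n)
    ep = sliding_mean(warped, n)
    efp = sliding_mean(fixed * warped, n)
    vf = sliding_mean(fixed * fixed, n) - ef * ef
    vp = sliding_mean(warped * warped, n) - ep * ep
    lncc = (efp - ef * ep) ** 2 / (np.maximum(vf, 0) * np.maximum(vp, 0) + eps)
    return float(-np.mean(lncc))


# ---------------------------------------------------------------------------
# centroid loss


def centroid_alignment_loss(true_moving, predicted_moving) -> float:
    """Mean Euclidean distance over valid centroid rows (pads excluded)."""
    if true_moving.valid_count != predicted_moving.valid_count:
        raise ValueError("centroid lists have different valid counts")
    if true_moving.valid_count == 0:
        raise DegenerateInputError("no valid centroids")
    d = true_moving.points - predicted_moving.points
    return float(np.mean(np.sqrt(np.sum(d * d, axis=1))))


# ---------------------------------------------------------------------------
# DDF regularizers


def _central_differences(ddf: np.ndarray) -> np.ndarray:
    """Stacked central differences over the interior, shape (3, X-2, Y-2, Z-2, 3).

    Axis 0 enumerates the derivative direction (x, y, z); the trailing axis
    is the displacement component m.
    """
    d = ddf
    dx = 0.5 * (d[2:, 1:-1, 1:-1] - d[:-2, 1:-1, 1:-1])
    dy = 0.5 * (d[1:-1, 2:, 1:-1] - d[1:-1, :-2, 1:-1])
    dz = 0.5 * (d[1:-1, 1:-1, 2:] - d[1:-1, 1:-1, :-2])
    return np.stack([dx, dy, dz])


def gradient_norm(ddf: np.ndarray) -> float:
    """Mean squared central-difference gradient of the DDF.

    Sums the squared x/y/z-derivatives of every displacement component over
    interior voxels and divides by ``3 (X-2)(Y-2)(Z-2)``; zero iff the DDF
    is constant on the interior stencil.
    """
    ddf = validate_ddf(ddf)
    if min(ddf.shape[:3]) < 3:
        raise ValueError("each dimension must be >= 3")
    g = _central_differences(ddf)
    return float(np.sum(g * g) / (3 * np.prod([s - 2 for s in ddf.shape[:3]])))


def gradient_norm_2d(ddf: np.ndarray) -> float:
    """Gradient norm restricted to in-plane (x, y) derivatives.

    Used for quasi-2-D recordings where out-of-plane deformation is masked;
    interior voxels are pooled across all z-slices and the sum divided by
    ``3 (X-2)(Y-2) Z``.
    """
    ddf = validate_ddf(ddf)
    x, y, z = ddf.shape[:3]
    if x < 3 or y < 3:
        raise ValueError("x and y dimensions must be >= 3")
    dx = 0.5 * (ddf[2:, 1:-1] - ddf[:-2, 1:-1])
    dy = 0.5 * (ddf[1:-1, 2:] - ddf[1:-1, :-2])
    return float((np.sum(dx * dx) + np.sum(dy * dy)) / (3 * (x - 2) * (y - 2) * z))


def difference_norm(ddf: np.ndarray) -> float:
    """Average squared displacement, ``(1/3XYZ) sum D^2``."""
    ddf = validate_ddf(ddf)
    return float(np.sum(ddf * ddf) / (3 * np.prod(ddf.shape[:3])))


def axis_difference_norm(ddf: np.ndarray) -> float:
    """Average squared z-displacement."""
    ddf = validate_ddf(ddf)
    dz = ddf[..., 2]
    return float(np.mean(dz * dz))


def rigid_gradient_magnitude(ddf: np.ndarray) -> np.ndarray:
    """Per-voxel, per-component gradient magnitude M of ``D - D_ref``.

    ``D_ref[p] = -p`` maps the whole grid to the origin, so ``D_diff = D -
    D_ref = D + p`` is the absolute coordinate map; ``M[. , m]`` sums the
    squared central differences of component m over the three axes and
    equals 1 everywhere for any rigid-body transform.
    """
    ddf = validate_ddf(ddf)
    if min(ddf.shape[:3]) < 3:
        raise ValueError("each dimension must be >= 3")
    grid = np.stack(
        np.meshgrid(*(np.arange(s, dtype=float) for s in ddf.shape[:3]), indexing="ij"),
        axis=-1,
    )
    g = _central_differences(ddf + grid)
    return np.sum(g * g, axis=0)


def nonrigid_penalty(ddf: np.ndarray) -> float:
    """Regularizer vanishing exactly on rigid-body coordinate maps.

    With M the rigid gradient magnitude, the penalty is the mean over
    interior voxels and components of ``M + 1/M - 2`` (convex, minimized at
    ``M = 1``); M is floored at 1e-8 before inversion.
    """
    m = rigid_gradient_magnitude(ddf)
    m = np.maximum(m, _M_FLOOR)
    return float(np.mean(m + 1.0 / m - 2.0))


# ---------------------------------------------------------------------------
# multi-channel (cross-animal) image loss


def discovery_image_loss(fixed: np.ndarray, predicted: np.ndarray) -> float:
    """Negative squared channel-averaged global NCC, in [-1, 0].

    ``-(1/C) sum_c NCC_c(fixed, predicted)^2`` over channels; invariant to
    independent affine intensity rescaling of each channel.

    Raises
    ------
    DegenerateInputError
        If any channel of either image has zero variance.
    """
    fixed = np.asarray(fixed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if fixed.shape != predicted.shape or fixed.ndim != 4:
        raise ValueError("expected matching (X, Y, Z, C) volumes")
    total = 0.0
    for c in range(fixed.shape[3]):
        f = fixed[..., c]
        p = predicted[..., c]
        df = f - f.mean()
        dp = p - p.mean()
        vf = np.mean(df * df)
        vp = np.mean(dp * dp)
        if vf == 0 or vp == 0:
            raise DegenerateInputError(f"zero-variance channel {c}")
        total += (np.mean(df * dp) / np.sqrt(vf * vp)) ** 2
    return float(-total / fixed.shape[3])


# ---------------------------------------------------------------------------
# composite


def regularization_loss(ddf: np.ndarray, weights: LossWeights = WORM_WEIGHTS) -> float:
    grad = gradient_norm_2d(ddf) if weights.grad_2d else gradient_norm(ddf)
    return (
        weights.w_grad * grad
        + weights.w_diff * difference_norm(ddf)
        + weights.w_axis * axis_difference_norm(ddf)
        + weights.w_nonrigid * nonrigid_penalty(ddf)
    )


def total_registration_loss(
    image_loss: float,
    centroid_loss: float,
    reg_components: dict,
    weights: LossWeights = WORM_WEIGHTS,
) -> float:
    """Weighted combination ``wI*LI + wC*LC + wR*LR``.

    ``reg_components`` maps the regularizer names ``grad``, ``diff``,
    ``axis``, ``nonrigid`` to their (unweighted) values.
    """
    for v in (image_loss, centroid_loss, *reg_components.values()):
        if not np.isfinite(v):
            raise ValueError("non-finite loss component")
    lr = (
        weights.w_grad * reg_components.get("grad", 0.0)
        + weights.w_diff * reg_components.get("diff", 0.0)
        + weights.w_axis * reg_components.get("axis", 0.0)
        + weights.w_nonrigid * reg_components.get("nonrigid", 0.0)
    )
    return float(weights.wI * image_loss + weights.wC * centroid_loss + weights.wR * lr)
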