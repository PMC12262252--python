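"""Identity linking across timepoints (temporal) or animals (cross-animal).

Registered ROI pairs are scored by a multiplicative similarity heuristic

``M_ij = R * 1/(1 + w1 d_i) * q^w2 * r_ij^w3 * exp(-(w4 a_ij + w5 c_ij +
w6 n))``

where ``R`` indicates that the two contexts were registered, ``d_i`` is
the centroid displacement of the moving ROI under the DDF, ``q`` the
registration quality (NCC of warped moving vs fixed image), ``r_ij`` the
fractional overlap of warped moving and fixed ROI (intersection / max
size), ``a_ij`` a brightness (temporal) or color (cross-animal) mismatch,
``c_ij`` the warped-to-fixed centroid distance and ``n`` the unweighted
nonrigid penalty of the DDF.  The sparse symmetric matrix is clustered by
collision-constrained agglomerative merging; clusters are neuron
identities.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .euler import ncc
from .exceptions import DegenerateInputError
from .losses import nonrigid_penalty
from .volumes import roi_centroids
from .warp import interpolate_ddf, warp_image, warp_roi

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HeuristicWeights:
    """Similarity-heuristic and clustering weights.

    Temporal defaults: ``w1..w6 = (2, 25, 1, 3, 1, 1)``, merge floor
    ``w7 = 1e-4``, collision tolerance ``w8 = 0.05``.  The cross-animal
    preset replaces the brightness term by a 4-channel color distance with
    ``w4 = 7``, sets ``w8 = 0`` and uses a far lower floor ``w7 = 1e-9``.
    """

    w1: float = 2.0
    w2: float = 25.0
    w3: float = 1.0
    w4: float = 3.0
    w5: float = 1.0
    w6: float = 1.0
    w7: float = 1e-4
    w8: float = 0.05

    def __post_init__(self):
        if min(self.w1, self.w2, self.w3, self.w4, self.w5, self.w6) < 0:
            raise ValueError("w1..w6 must be non-negative")
        if self.w7 <= 0:
            raise ValueError("w7 must be positive")
        if not 0 <= self.w8 <= 1:
            raise ValueError("w8 must be in [0, 1]")


TEMPORAL_WEIGHTS = HeuristicWeights()
CROSS_ANIMAL_WEIGHTS = HeuristicWeights(w4=7.0, w7=1e-9, w8=0.0)


@dataclass(frozen=True)
class ROIRecord:
    """One ROI in one context (timepoint or animal)."""

    context: int
    roi_index: int
    centroid: tuple
    voxel_count: int
    brightness: tuple  # one entry per channel


@dataclass
class RegistrationRecord:
    """A solved registration problem between two contexts."""

    moving_context: int
    fixed_context: int
    ddf: np.ndarray
    quality: float | None = None  # NCC(warped moving, fixed)
    nonrigid: float | None = None


def roi_records_from_volumes(context: int, rois: np.ndarray,
                             image: np.ndarray) -> list[ROIRecord]:
    """Extract per-ROI records from an ROI volume and its intensity image.

    ``image`` is (X, Y, Z) or (X, Y, Z, C); brightness is the per-channel
    mean intensity over the ROI's voxels.
    """
    rois = np.asarray(rois)
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        image = image[..., None]
    out = []
    for idx, cent in sorted(roi_centroids(rois).items()):
        mask = rois == idx
        out.append(
            ROIRecord(
                context=context,
                roi_index=idx,
                centroid=tuple(float(c) for c in cent),
                voxel_count=int(mask.sum()),
                brightness=tuple(float(image[..., c][mask].mean())
                                 for c in range(image.shape[3])),
            )
        )
    return out


class SimilarityMatrix:
    """Sparse symmetric similarity scores over globally indexed ROI records."""

    def __init__(self, records: list[ROIRecord]):
        self.records = list(records)
        self.key = {(r.context, r.roi_index): i for i, r in enumerate(self.records)}
        self.entries: dict[tuple[int, int], float] = {}

    def set(self, i: int, j: int, value: float) -> None:
        if value > 0:
            self.entries[(i, j)] = value

    def symmetrize(self) -> None:
        for (i, j), v in list(self.entries.items()):
            if (j, i) not in self.entries:
                self.entries[(j, i)] = v

    def get(self, i: int, j: int) -> float:
        return self.entries.get((i, j), 0.0)

    def __len__(self) -> int:
        return len(self.records)


def similarity_matrix(
    records: list[ROIRecord],
    registrations: list[RegistrationRecord],
    rois_by_context: dict[int, np.ndarray],
    weights: HeuristicWeights = TEMPORAL_WEIGHTS,
    mode: str = "temporal",
    images_by_context: dict[int, np.ndarray] | None = None,
) -> SimilarityMatrix:
    """Build the ROI similarity matrix over all registered context pairs.

    Missing ``quality``/``nonrigid`` entries of a registration are computed
    from its DDF and the supplied images.  Unregistered context pairs and
    non-overlapping ROI pairs score 0 (absent from the sparse matrix);
    the result is symmetrized.
    """
    if mode not in ("temporal", "cross_animal"):
        raise ValueError(f"unknown mode {mode!r}")
    sim = SimilarityMatrix(records)
    rec_by_context: dict[int, list[ROIRecord]] = {}
    for r in records:
        rec_by_context.setdefault(r.context, []).append(r)

    # per-context mean brightness for the temporal activity term
    mean_brightness = {
        ctx: float(np.mean([r.brightness[0] for r in rs])) or 1.0
        for ctx, rs in rec_by_context.items()
    }

    def color_vector(rec: ROIRecord) -> np.ndarray:
        b = np.asarray(rec.brightness, dtype=float)
        mean = b.mean()
        return b / mean if mean else b

    for reg in registrations:
        tm, tf = reg.moving_context, reg.fixed_context
        if reg.ddf is None:
            raise ValueError(f"registration {tm}->{tf} has no DDF")
        rois_m = np.asarray(rois_by_context[tm])
        rois_f = np.asarray(rois_by_context[tf])
        warped_m = warp_roi(rois_m, reg.ddf)
        if reg.nonrigid is None:
            reg.nonrigid = nonrigid_penalty(reg.ddf)
        if reg.quality is None:
            if images_by_context is None:
                raise ValueError("images are required to compute quality q")
            img_m = np.asarray(images_by_context[tm], dtype=float)
            img_f = np.asarray(images_by_context[tf], dtype=float)
            if img_m.ndim == 4:  # multi-channel: NCC over the whole 4-D stack
                warped = np.stack(
                    [warp_image(img_m[..., c], reg.ddf)
                     for c in range(img_m.shape[3])], axis=-1)
            else:
                warped = warp_image(img_m, reg.ddf)
            reg.quality = ncc(warped, img_f)
        q = max(float(reg.quality), 0.0)
        warped_centroids = roi_centroids(warped_m)
        fixed_centroids = {
            (rec.context, rec.roi_index): np.asarray(rec.centroid)
            for rec in rec_by_context.get(tf, [])
        }
        fixed_sizes = {rec.roi_index: rec.voxel_count
                       for rec in rec_by_context.get(tf, [])}
        for rec_m in rec_by_context.get(tm, []):
            i = sim.key[(tm, rec_m.roi_index)]
            if rec_m.roi_index not in warped_centroids:
                continue  # ROI warped entirely out of the grid
            disp = interpolate_ddf(reg.ddf, np.asarray(rec_m.centroid)[None])[0]
            d_i = float(np.linalg.norm(disp))
            warped_mask = warped_m == rec_m.roi_index
            warped_size = int(warped_mask.sum())
            overlap_labels, overlap_counts = np.unique(
                rois_f[warped_mask], return_counts=True)
            for lab, count in zip(overlap_labels, overlap_counts):
                if lab == 0:
                    continue
                rec_f_key = (tf, int(lab))
                if rec_f_key not in sim.key:
                    continue
                j = sim.key[rec_f_key]
                rec_f = sim.records[j]
                r_ij = count / max(warped_size, fixed_sizes.get(int(lab), 0))
                c_ij = float(np.linalg.norm(
                    warped_centroids[rec_m.roi_index]
                    - fixed_centroids[rec_f_key]))
                if mode == "temporal":
                    a_ij = abs(
                        rec_m.brightness[0] / mean_brightness[tm]
                        - rec_f.brightness[0] / mean_brightness[tf]
                    )
                else:
                    a_ij = float(np.abs(
                        color_vector(rec_m) - color_vector(rec_f)).sum())
                m_ij = (
                    1.0 / (1.0 + weights.w1 * d_i)
                    * q ** weights.w2
                    * r_ij ** weights.w3
                    * np.exp(-(weights.w4 * a_ij + weights.w5 * c_ij
                               + weights.w6 * reg.nonrigid))
                )
                sim.set(i, j, float(m_ij))
    sim.symmetrize()
    return sim


# ---------------------------------------------------------------------------
# clustering


def cluster_identities(sim: SimilarityMatrix, w7: float | None = None,
                       w8: float | None = None,
                       weights: HeuristicWeights = TEMPORAL_WEIGHTS
                       ) -> list[list[int]]:
    """Collision-constrained agglomerative clustering of the similarity matrix.

    Clusters are merged in descending average-linkage similarity (the mean
    of nonzero pairwise entries between the two clusters).  No merge below
    the floor ``w7`` is executed; a merge whose result would contain a
    fraction of colliding ROIs (two members from one context) above ``w8``
    is rejected and that cluster pair is permanently excluded.  With
    ``w8 = 0`` no cluster ever holds two ROIs from the same context.
    Deterministic: ties break on the smaller cluster ids.

    Returns clusters as lists of record indices into ``sim.records``.
    """
    w7 = weights.w7 if w7 is None else w7
    w8 = weights.w8 if w8 is None else w8
    n = len(sim)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    next_id = n
    excluded: set[tuple[int, int]] = set()

    def linkage(a: int, b: int) -> float:
        vals = [
            v
            for i in members[a]
            for j in members[b]
            if (v := sim.get(i, j)) > 0
        ]
        return float(np.mean(vals)) if vals else 0.0

    # candidate heap of (-similarity, a, b); lazily invalidated
    heap = []
    for (i, j), v in sim.entries.items():
        if i < j and v >= w7:
            heapq.heappush(heap, (-v, i, j))

    while heap:
        neg, a, b = heapq.heappop(heap)
        if a not in members or b not in members or (a, b) in excluded:
            continue
        link = linkage(a, b)
        if link < w7:
            continue
        if -neg - link > 1e-12:  # stale entry; reinsert with current value
            heapq.heappush(heap, (-link, a, b))
            continue
        merged = members[a] + members[b]
        contexts = [sim.records[i].context for i in merged]
        counts = pd.Series(contexts).value_counts()
        colliding = int(counts[counts > 1].sum())
        if colliding / len(merged) > w8:
            excluded.add((a, b))
            continue
        del members[a], members[b]
        cid = next_id
        next_id += 1
        members[cid] = sorted(merged)
        for other in list(members):
            if other == cid:
                continue
            link2 = linkage(cid, other)
            if link2 >= w7:
                lo, hi = min(cid, other), max(cid, other)
                heapq.heappush(heap, (-link2, lo, hi))
    return sorted(members.values())


# ---------------------------------------------------------------------------
# traces and validation statistics


def extract_traces(
    clusters: list[list[int]],
    records: list[ROIRecord],
    gcamp_by_context: dict[int, np.ndarray],
    marker_by_context: dict[int, np.ndarray],
    rois_by_context: dict[int, np.ndarray],
) -> pd.DataFrame:
    """Activity traces: per cluster and timepoint, mean green / mean marker.

    Missing timepoints are NaN; a zero marker intensity is recorded as
    missing (logged).  Index = cluster id, columns = sorted contexts.
    """
    contexts = sorted(rois_by_context)
    table = np.full((len(clusters), len(contexts)), np.nan)
    col = {c: k for k, c in enumerate(contexts)}
    for ci, cluster in enumerate(clusters):
        for i in cluster:
            rec = records[i]
            mask = np.asarray(rois_by_context[rec.context]) == rec.roi_index
            marker = float(np.asarray(marker_by_context[rec.context])[mask].mean())
            if marker == 0:
                logger.warning(
                    "zero marker intensity for ROI %s at context %s",
                    rec.roi_index, rec.context)
                continue
            green = float(np.asarray(gcamp_by_context[rec.context])[mask].mean())
            table[ci, col[rec.context]] = green / marker
    return pd.DataFrame(table, columns=contexts)


def gfp_error_rate(traces, threshold: float = 1.5) -> float:
    """Linking error rate from a sparsely green-labeled population.

    A trace is called positive when its median exceeds ``threshold``.  A
    timepoint mismatches when its value differs from the trace median by
    more than ``threshold`` while exactly one of the two exceeds
    ``threshold`` -- a positive cell linked into a negative trace or vice
    versa.  The rate is ``mismatches / (total timepoints * 2 * FracGFP *
    (1 - FracGFP))``; the denominator factor corrects for undetectable
    same-class mis-links.

    Raises
    ------
    DegenerateInputError
        If every trace (or none) is called positive.
    """
    values = np.asarray(traces, dtype=float)
    if values.ndim != 2 or values.size == 0:
        raise ValueError("expected a (traces, timepoints) table")
    medians = np.nanmedian(values, axis=1)
    frac = float(np.mean(medians > threshold))
    if frac in (0.0, 1.0):
        raise DegenerateInputError(
            "all traces on one side of the threshold; error rate undefined")
    with np.errstate(invalid="ignore"):
        diff = np.abs(values - medians[:, None]) > threshold
        one_side = (values > threshold) ^ (medians[:, None] > threshold)
        mismatch = np.nansum(diff & one_side & ~np.isnan(values))
    total = np.sum(~np.isnan(values))
    return float(mismatch / (total * 2 * frac * (1 - frac)))


def _strip_lr(name: str) -> str:
    if len(name) > 2 and name[-1] in "LR":
        return name[:-1]
    return name


def cluster_accuracy(
    clusters: list[list[int]],
    records: list[ROIRecord],
    labels: dict[tuple[int, int], str],
    min_members: int = 2,
    strip_lr: bool = True,
) -> float:
    """Fraction of labeled cluster members matching their cluster's mode.

    Only clusters with more than ``min_members`` labeled members count;
    labels are compared ignoring the L/R subclass; members labeled
    ``"UNKNOWN"`` (or absent from ``labels``) are excluded.

    Raises
    ------
    DegenerateInputError
        If no cluster qualifies.
    """
    matches = 0
    total = 0
    qualified = False
    for cluster in clusters:
        names = []
        for i in cluster:
            rec = records[i]
            name = labels.get((rec.context, rec.roi_index))
            if name is None or name == "UNKNOWN":
                continue
            names.append(_strip_lr(name) if strip_lr else name)
        if len(names) <= min_members:
            continue
        qualified = True
        mode = pd.Series(names).mode().iloc[0]
        matches += sum(1 for n in names if n == mode)
        total += len(names)
    if not qualified:
        raise DegenerateInputError("no cluster with enough labeled members")
    return matches / total


# ---------------------------------------------------------------------------
# registration-pair enumeration


def enumerate_pairs(ids: list) -> list[tuple]:
    """All unordered pairs of a context list (each pair registered once)."""
    return list(combinations(ids, 2))


def discovery_split_pairs(train_ids, val_ids, test_ids) -> dict[str, list[tuple]]:
    """Pair bookkeeping of a train/validation/test image split.

    Training pairs are all pairs within the training images; validation
    pairs all pairs within the validation images; test pairs every pair of
    the full cohort seen in neither (pairs straddling two splits are test
    pairs).
    """
    train = set(train_ids)
    val = set(val_ids)
    test = set(test_ids)
    if train & val or train & test or val & test:
        raise ValueError("splits must be disjoint")
    train_pairs = enumerate_pairs(sorted(train))
    val_pairs = enumerate_pairs(sorted(val))
    seen = set(train_pairs) | set(val_pairs)
    all_pairs = enumerate_pairs(sorted(train | val | test))
    test_pairs = [p for p in all_pairs if p not in seen]
    return {"train": train_pairs, "val": val_pairs, "test": test_pairs}


def temporal_registration_graph(
    images_by_context: dict[int, np.ndarray], k_neighbors: int = 3
) -> list[tuple[int, int]]:
    """Default temporal registration graph: k nearest neighbors by z-MIP NCC.

    Each timepoint is paired (as moving) with the ``k`` timepoints whose
    z-maximum-intensity projections correlate best with its own; duplicate
    unordered pairs are emitted once.
    """
    contexts = sorted(images_by_context)
    mips = {c: np.asarray(images_by_context[c], dtype=float).max(axis=2)
            for c in contexts}
    pairs = set()
    for cm in contexts:
        scores = []
        for cf in contexts:
            if cf == cm:
                continue
            try:
                scores.append((ncc(mips[cm], mips[cf]), cf))
            except DegenerateInputError:
                continue
        scores.sort(key=lambda t: (-t[0], t[1]))
        for _, cf in scores[:k_neighbors]:
            pairs.add((min(cm, cf), max(cm, cf)))
    return sorted(pairs)


def link_contexts(
    images_by_context: dict[int, np.ndarray],
    rois_by_context: dict[int, np.ndarray],
    registrations: list[RegistrationRecord],
    weights: HeuristicWeights = TEMPORAL_WEIGHTS,
    mode: str = "temporal",
):
    """End-to-end linking: records, similarity matrix, clustering.

    Returns ``(records, sim, clusters)`` where clusters index into
    ``records``.
    """
    records = []
    for ctx in sorted(images_by_context):
        records.extend(
            roi_records_from_volumes(ctx, rois_by_context[ctx],
                                     images_by_context[ctx]))
    sim = similarity_matrix(records, registrations, rois_by_context, weights,
                            mode=mode, images_by_context=images_by_context)
    clusters = cluster_identities(sim, weights.w7, weights.w8)
    return records, sim, clusters
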