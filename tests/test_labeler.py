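"""Annotation machinery: weights, losses, ROI labeling, postprocessing."""

import numpy as np
import pandas as pd
import pytest

from neuralign import labeler, nn


@pytest.fixture()
def catalog():
    return labeler.LabelCatalog(
        ["background", "AVAL", "AVAR", "RMED", "RMEV", "glia", "RMH", "RMH?"]
    )


def _table(rows):
    return pd.DataFrame(rows, columns=["roi_index", "label", "confidence"])


class TestCatalog:
    def test_lr_pairs_inferred(self, catalog):
        assert catalog.class_of("AVAL") == "AVA"
        assert catalog.class_of("AVAR") == "AVA"

    def test_dv_names_not_merged(self, catalog):
        assert catalog.class_of("RMED") == "RMED"
        assert catalog.class_of("RMEV") == "RMEV"

    def test_odd_names_are_safe(self, catalog):
        assert catalog.class_of("RMH?") == "RMH?"
        assert catalog.class_of("RMH") == "RMH"

    def test_default_catalog_structure(self):
        cat = labeler.make_default_catalog(185)
        assert len(cat) == 185
        assert cat.names[0] == "background"
        assert "glia" in cat.index and "granule" in cat.index
        assert "RMH?" in cat.index


class TestWeightVolume:
    def test_reference_spot_values(self, catalog):
        rois = np.zeros((4, 4, 4), dtype=int)
        rois[0, 0, 0] = 1
        rois[1, 1, 1] = 2
        table = _table([(1, "AVAL", 5), (2, "AVAR", 2)])
        w = labeler.build_weight_volume(
            rois, table, {"AVAL": 130, "AVAR": 65}, catalog)
        assert w[0, 0, 0] == pytest.approx(1000.0)  # (130/130) * f(5)
        assert w[1, 1, 1] == pytest.approx(100.0)   # (130/65) * f(2)
        assert w[2, 2, 2] == 1.0                     # background

    def test_confidence_one_treated_as_background(self, catalog):
        rois = np.zeros((3, 3, 3), dtype=int)
        rois[0, 0, 0] = 1
        w = labeler.build_weight_volume(
            rois, _table([(1, "AVAL", 1)]), {"AVAL": 10}, catalog)
        assert w[0, 0, 0] == 1.0

    def test_unknown_label_raises(self, catalog):
        rois = np.ones((2, 2, 2), dtype=int)
        with pytest.raises(KeyError):
            labeler.build_weight_volume(
                rois, _table([(1, "NOPE", 5)]), {"NOPE": 1}, catalog)


class TestOneHot:
    def test_channels_partition_volume(self, catalog):
        rois = np.zeros((3, 3, 3), dtype=int)
        rois[0] = 1
        rois[1] = 2
        table = _table([(1, "AVAL", 5), (2, "AVAR", 1)])  # conf 1 excluded
        lab = labeler.one_hot_labels(rois, table, catalog)
        np.testing.assert_array_equal(lab.sum(axis=0), 1)
        assert lab[catalog.index["AVAL"], 0].all()
        assert lab[0, 1].all()  # excluded ROI is background


class TestWeightedCrossEntropy:
    def test_uniform_logits_toy_value(self):
        # 2x2x2 volume, K = 3, a single labeled voxel with W = 1 there and
        # 0 elsewhere: the printed formula gives log(3) / (XYZ * K)
        logits = np.zeros((3, 2, 2, 2))
        labels = np.zeros((3, 2, 2, 2))
        labels[0] = 1
        labels[0, 0, 0, 0] = 0
        labels[1, 0, 0, 0] = 1
        w = np.zeros((2, 2, 2))
        w[0, 0, 0] = 1.0
        got = labeler.weighted_cross_entropy(logits, labels, w)
        assert got == pytest.approx(np.log(3) / 24)

    def test_confidently_correct_is_tiny(self, rng):
        labels = np.zeros((4, 3, 3, 3))
        idx = rng.integers(0, 4, (3, 3, 3))
        np.put_along_axis(labels, idx[None], 1, axis=0)
        logits = 50.0 * labels
        w = np.ones((3, 3, 3))
        assert labeler.weighted_cross_entropy(logits, labels, w) < 1e-3

    def test_linear_in_weights(self, rng):
        logits = rng.normal(size=(3, 2, 2, 2))
        labels = np.zeros((3, 2, 2, 2))
        labels[1] = 1
        w = rng.uniform(0.5, 2.0, (2, 2, 2))
        one = labeler.weighted_cross_entropy(logits, labels, w)
        two = labeler.weighted_cross_entropy(logits, labels, 2 * w)
        assert two == pytest.approx(2 * one)

    def test_tensor_version_matches_reference(self, rng):
        logits = rng.normal(size=(4, 3, 2, 2))
        labels = np.zeros((4, 3, 2, 2))
        idx = rng.integers(0, 4, (3, 2, 2))
        np.put_along_axis(labels, idx[None], 1, axis=0)
        w = rng.uniform(0.1, 3.0, (3, 2, 2))
        ref = labeler.weighted_cross_entropy(logits, labels, w)
        got = labeler.weighted_cross_entropy_tensor(
            nn.Tensor(logits), labels, w)
        assert float(got.data) == pytest.approx(ref, abs=1e-10)


class TestWeightedMeanIoU:
    @staticmethod
    def _fixture(rng, k=5, shape=(6, 6, 6)):
        labels = np.zeros((k,) + shape)
        idx = rng.integers(0, k, shape)
        np.put_along_axis(labels, idx[None], 1, axis=0)
        w = rng.uniform(0.5, 2.0, shape)
        return labels, w, idx

    def test_perfect_prediction_is_one(self, rng):
        labels, w, _ = self._fixture(rng)
        assert labeler.weighted_mean_iou(labels, labels, w) == 1.0

    def test_cyclic_permutation_is_zero(self, rng):
        labels, w, _ = self._fixture(rng)
        pred = np.roll(labels, 1, axis=0)
        assert labeler.weighted_mean_iou(pred, labels, w) == 0.0

    def test_half_overlap_hand_value(self):
        labels = np.zeros((2, 4, 1, 1))
        labels[1, :2] = 1
        labels[0] = 1 - labels[1]
        pred = np.zeros((2, 4, 1, 1))
        pred[1, 1:3] = 1  # covers half of the labeled voxels
        pred[0] = 1 - pred[1]
        w = np.ones((4, 1, 1))
        # channel 1: inter 1, union 3 -> 1/3; channel 0 symmetric -> 1/3
        got = labeler.weighted_mean_iou(pred, labels, w)
        assert got == pytest.approx(1 / 3)


class TestROIAssignment:
    def test_rows_sum_to_one(self, rng):
        p = labeler.softmax_probabilities(rng.normal(size=(6, 8, 8, 8)))
        rois = rng.integers(0, 4, (8, 8, 8))
        rows, idx = labeler.roi_prediction_matrix(p, rois)
        np.testing.assert_allclose(rows.sum(axis=1), 1.0, atol=1e-5)

    def test_interior_votes_dominate_edges(self, catalog):
        shape = (7, 7, 7)
        rois = np.zeros(shape, dtype=int)
        rois[1:6, 1:6, 1:6] = 1
        edge = labeler.roi_edge_mask(rois)
        interior = edge == 1.0
        p = np.zeros((len(catalog),) + shape)
        p[catalog.index["AVAL"]][(rois == 1) & ~interior] = 1.0  # edge votes
        p[catalog.index["AVAR"]][interior] = 1.0                  # interior
        p[0][rois == 0] = 1.0
        results = labeler.roi_label_assignment(p, rois, catalog)
        assert results[0].label == "AVAR"

    def test_single_voxel_roi_is_labeled(self, catalog):
        shape = (5, 5, 5)
        rois = np.zeros(shape, dtype=int)
        rois[2, 2, 2] = 3
        p = np.zeros((len(catalog),) + shape)
        p[catalog.index["RMED"]] = 1.0
        results = labeler.roi_label_assignment(p, rois, catalog)
        assert results[0].roi_index == 3
        assert results[0].label == "RMED"
        assert results[0].confidence == pytest.approx(1.0)

    def test_invariant_to_roi_renumbering(self, rng, catalog):
        p = labeler.softmax_probabilities(
            rng.normal(size=(len(catalog), 6, 6, 6)))
        rois = rng.integers(0, 3, (6, 6, 6))
        renumbered = np.where(rois > 0, rois * 7 + 1, 0)
        a = labeler.roi_label_assignment(p, rois, catalog)
        b = labeler.roi_label_assignment(p, renumbered, catalog)
        assert [(r.label, round(r.confidence, 12)) for r in a] == \
            [(r.label, round(r.confidence, 12)) for r in b]


class TestPostprocessing:
    @staticmethod
    def _roi_pair(shape=(12, 6, 6), far=True):
        rois = np.zeros(shape, dtype=int)
        rois[1:3, 1:3, 1:3] = 1
        if far:
            rois[8:10, 3:5, 3:5] = 2
        else:
            rois[3:5, 1:3, 1:3] = 2
        return rois

    @staticmethod
    def _probs(catalog, rois, spec):
        """spec: {roi_index: {label: prob}} (rest of the mass -> background)."""
        k = len(catalog)
        p = np.zeros((k,) + rois.shape)
        p[0] = 1.0
        for idx, dist in spec.items():
            mask = rois == idx
            p[:, mask] = 0.0
            rest = 1.0 - sum(dist.values())
            p[0, mask] = rest
            for name, prob in dist.items():
                p[catalog.index[name], mask] = prob
        return p

    def _run(self, catalog, rois, spec, **kw):
        from neuralign.volumes import roi_centroids

        p = self._probs(catalog, rois, spec)
        results = labeler.roi_label_assignment(p, rois, catalog)
        cents = roi_centroids(rois)
        return labeler.postprocess_labels(results, p, rois, cents, catalog,
                                          **kw)

    def test_distant_duplicate_loses_lower_confidence(self, catalog):
        rois = self._roi_pair(far=True)
        out = self._run(catalog, rois,
                        {1: {"AVAL": 0.9}, 2: {"AVAL": 0.8}})
        by_idx = {r.roi_index: r for r in out}
        assert by_idx[1].active
        assert by_idx[2].deletion_reason == "duplicate-label"

    def test_nearby_duplicate_shares_label(self, catalog):
        rois = self._roi_pair(far=False)
        out = self._run(catalog, rois,
                        {1: {"AVAL": 0.9}, 2: {"AVAL": 0.8}})
        assert all(r.active and r.label == "AVAL" for r in out)

    def test_undersegmentation_deletes(self, catalog):
        rois = np.zeros((8, 8, 8), dtype=int)
        rois[1:4, 1:4, 1:4] = 1  # 27 voxels
        p = np.zeros((len(catalog),) + rois.shape)
        p[0] = 1.0
        mask = rois == 1
        p[:, mask] = 0.0
        p[catalog.index["AVAL"], mask] = 0.9
        # 12 voxels confidently claim a different label
        sub = np.argwhere(mask)[:12]
        for x, y, z in sub:
            p[catalog.index["AVAL"], x, y, z] = 0.1
            p[catalog.index["RMED"], x, y, z] = 0.8
        results = labeler.roi_label_assignment(p, rois, catalog)
        from neuralign.volumes import roi_centroids

        out = labeler.postprocess_labels(
            results, p, rois, roi_centroids(rois), catalog)
        assert out[0].deletion_reason == "under-segmentation"

    def test_lr_ambiguity_merges_to_class(self, catalog):
        rois = np.zeros((6, 6, 6), dtype=int)
        rois[1:4, 1:4, 1:4] = 1
        out = self._run(catalog, rois, {1: {"AVAL": 0.55, "AVAR": 0.40}})
        r = out[0]
        assert r.label == "AVA"
        assert r.confidence == pytest.approx(0.95)
        assert r.merged_from == ("AVAL", "AVAR")
        assert r.active

    def test_rare_class_and_glia_deleted(self, catalog):
        rois = self._roi_pair(far=True)
        out = self._run(catalog, rois,
                        {1: {"RMH": 0.95}, 2: {"glia": 0.9}})
        by_idx = {r.roi_index: r for r in out}
        assert by_idx[1].deletion_reason == "rare-class"
        assert by_idx[2].deletion_reason == "non-neuronal"

    def test_low_confidence_deleted(self, catalog):
        rois = np.zeros((6, 6, 6), dtype=int)
        rois[1:4, 1:4, 1:4] = 1
        out = self._run(catalog, rois, {1: {"RMED": 0.6}})
        assert out[0].deletion_reason == "low-confidence"

    def test_never_increases_confidence_except_lr_merge(self, rng, catalog):
        p = labeler.softmax_probabilities(
            rng.normal(size=(len(catalog), 8, 8, 8)))
        rois = rng.integers(0, 4, (8, 8, 8))
        results = labeler.roi_label_assignment(p, rois, catalog)
        from neuralign.volumes import roi_centroids

        out = labeler.postprocess_labels(
            results, p, rois, roi_centroids(rois), catalog)
        before = {r.roi_index: r.confidence for r in results}
        for r in out:
            if r.merged_from is None:
                assert r.confidence <= before[r.roi_index] + 1e-12


class TestLabelerUNet:
    CFG = labeler.LabelerConfig(input_shape_zyx=(8, 8, 16), input_channels=4,
                                n_classes=6, levels=3, base_channels=4,
                                group_size=4)

    def test_output_shape(self, rng):
        model = labeler.build_labeler_unet(self.CFG, seed=0)
        logits = model(rng.normal(size=(4, 8, 8, 16)))
        assert logits.data.shape == (6, 8, 8, 16)

    def test_single_channel_variant(self, rng):
        cfg = labeler.LabelerConfig(input_shape_zyx=(8, 8, 16),
                                    input_channels=1, n_classes=6, levels=3,
                                    base_channels=4, group_size=4)
        model = labeler.build_labeler_unet(cfg, seed=0)
        logits = model(rng.normal(size=(1, 8, 8, 16)))
        assert logits.data.shape == (6, 8, 8, 16)

    def test_parameter_count_matches_block_arithmetic(self):
        b, levels, cin, k = 4, 3, 4, 6
        ch = [b * 2**i for i in range(levels)]

        def conv(ci, co, kk=3):
            return co * ci * kk**3 + co

        def gn(c):
            return 2 * c

        total = 0
        prev = cin
        for c in ch:  # encoder: two GroupNorm->conv blocks each
            total += gn(prev) + conv(prev, c) + gn(c) + conv(c, c)
            prev = c
        for i in reversed(range(levels - 1)):  # decoders
            cat = ch[i + 1] + ch[i]
            total += gn(cat) + conv(cat, ch[i]) + gn(ch[i]) + conv(ch[i], ch[i])
        total += conv(ch[0], k, 1)  # final 1x1
        model = labeler.build_labeler_unet(self.CFG, seed=0)
        assert model.num_parameters() == total

    def test_overfit_single_volume(self):
        """The reduced U-Net memorizes one synthetic labeled volume to
        weighted IoU > 0.9."""
        from neuralign import synthetic

        cfg = synthetic.SynthConfig(shape=(16, 8, 8), n_cells=4,
                                    nucleus_sigma=1.2, margin=2.5,
                                    min_separation=3.0, n_channels=4,
                                    seed=3)
        vol, rois, _, table = synthetic.make_nuclei_volume(cfg)
        catalog = labeler.LabelCatalog(
            ["background"] + sorted(table["label"].unique()))
        rois_zyx = labeler.to_zyx(rois)
        labels = labeler.one_hot_labels(rois_zyx, table, catalog)
        # corpus-scale label counts (the rarity normalizer over itself),
        # keeping the neuron/background weight ratio realistic
        counts = {l: 130 for l in table["label"]}
        weights = labeler.build_weight_volume(rois_zyx, table, counts, catalog)
        model = labeler.build_labeler_unet(
            labeler.LabelerConfig(input_shape_zyx=(8, 8, 16),
                                  input_channels=4,
                                  n_classes=len(catalog), levels=3,
                                  base_channels=4, group_size=4), seed=0)
        image = labeler.to_zyx(vol)
        model, history = labeler.train_labeler(
            model, image, labels, weights, epochs=150, learning_rate=3e-3,
            seed=0)
        probs = labeler.softmax_probabilities(model(image).data)
        iou = labeler.weighted_mean_iou(probs, labels, weights)
        assert iou > 0.9
        assert history[-1] < history[0]


class TestAugmentLabeledVolume:
    @staticmethod
    def _triple(rng, shape=(8, 10, 12), k=3, c=2):
        img = rng.uniform(0, 1, (c,) + shape)
        labels = np.zeros((k,) + shape)
        idx = rng.integers(0, k, shape)
        np.put_along_axis(labels, idx[None], 1, axis=0)
        w = rng.uniform(0.5, 2.0, shape)
        return img, labels, w

    def test_zero_settings_identity(self, rng):
        img, labels, w = self._triple(rng)
        out = labeler.augment_labeled_volume(
            img, labels, w, labeler.LabelerAugmentSettings.identity(), 0)
        np.testing.assert_array_equal(out[0], img)
        np.testing.assert_array_equal(out[1], labels)
        np.testing.assert_array_equal(out[2], w)

    def test_one_hot_preserved_by_geometry(self, rng):
        img, labels, w = self._triple(rng)
        settings = labeler.LabelerAugmentSettings(
            contrast_frac=0, blur_sigma_max=0, gaussian_noise_sd=0)
        _, out_l, _ = labeler.augment_labeled_volume(img, labels, w,
                                                     settings, 5)
        np.testing.assert_array_equal(out_l.sum(axis=0), 1)

    def test_blur_gradient_along_z(self, rng):
        shape = (12, 16, 16)
        img = rng.normal(size=(1,) + shape)
        labels = np.zeros((2,) + shape)
        labels[0] = 1
        w = np.ones(shape)
        settings = labeler.LabelerAugmentSettings.identity()
        settings = labeler.LabelerAugmentSettings(
            rot_xy_deg=0, rot_yz_deg=0, rot_xz_deg=0, translate_vox=0,
            scale_frac=0, shear_frac=0, bspline_sigma_vox=0,
            bend_amplitude_vox=0, rot180_prob=0, contrast_frac=0,
            blur_sigma_max=2.0, gaussian_noise_sd=0, poisson_scale=0)
        out, _, _ = labeler.augment_labeled_volume(img, labels, w, settings, 0)
        # blur strength grows with z: the far slice is smoother
        near = np.var(np.diff(out[0, 1], axis=0))
        far = np.var(np.diff(out[0, -1], axis=0))
        assert far < near

    def test_seeded_determinism(self, rng):
        img, labels, w = self._triple(rng)
        settings = labeler.LabelerAugmentSettings()
        a = labeler.augment_labeled_volume(img, labels, w, settings, 42)
        b = labeler.augment_labeled_volume(img, labels, w, settings, 42)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)
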