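"""LocalNet architecture, training loop, and augmentation."""

import numpy as np
import pytest
from scipy import stats

from neuralign import losses, nn, regnet
from neuralign.euler import ncc
from neuralign.exceptions import ConfigurationError
from neuralign.volumes import CentroidList
from neuralign.warp import warp_centroids, warp_image

TINY = regnet.RegNetConfig(input_shape=(16, 8, 8), input_channels=1,
                           levels=3, base_channels=4, variant="worm")


def _tiny_pair(seed=0, shape=(16, 8, 8)):
    rng = np.random.default_rng(seed)
    g = np.indices(shape).transpose(1, 2, 3, 0).astype(float)
    fixed = np.zeros(shape)
    for _ in range(3):
        c = rng.uniform(1.5, np.maximum(np.array(shape) - 3, 1.6))
        fixed += np.exp(-0.5 * np.sum((g - c) ** 2, axis=-1) / 1.5)
    moving = np.roll(fixed, 1, axis=0)
    return fixed, moving


class TestArchitecture:
    def test_ddf_shape_matches_input(self):
        model = regnet.build_localnet(TINY, seed=0)
        fixed, moving = _tiny_pair()
        ddf = model(fixed, moving)
        assert ddf.data.shape == (16, 8, 8, 3)

    def test_zero_initialized_heads_give_zero_ddf(self):
        model = regnet.build_localnet(TINY, seed=1)
        fixed, moving = _tiny_pair(1)
        np.testing.assert_allclose(regnet.infer_ddf(model, fixed, moving), 0.0)

    def test_inference_deterministic(self):
        model = regnet.build_localnet(TINY, seed=2)
        # give the heads nonzero weights so the DDF is nontrivial
        for head in model.heads:
            head.weight.data[...] = 0.01
        fixed, moving = _tiny_pair(2)
        a = regnet.infer_ddf(model, fixed, moving)
        b = regnet.infer_ddf(model, fixed, moving)
        np.testing.assert_array_equal(a, b)
        assert np.abs(a).max() > 0

    def test_jellyfish_zeroes_z_component(self):
        cfg = regnet.RegNetConfig(input_shape=(16, 16, 8), input_channels=1,
                                  levels=3, base_channels=4,
                                  variant="jellyfish")
        model = regnet.build_localnet(cfg, seed=3)
        for head in model.heads:
            head.weight.data[...] = 0.01
        rng = np.random.default_rng(0)
        ddf = regnet.infer_ddf(model, rng.uniform(size=(16, 16, 8)),
                               rng.uniform(size=(16, 16, 8)))
        assert np.abs(ddf[..., 2]).sum() == 0
        assert np.abs(ddf[..., :2]).sum() > 0

    def test_discovery_variant_accepts_four_channels(self):
        cfg = regnet.RegNetConfig(input_shape=(16, 8, 8), input_channels=4,
                                  levels=3, base_channels=4,
                                  variant="discovery")
        model = regnet.build_localnet(cfg, seed=0)
        rng = np.random.default_rng(0)
        ddf = model(rng.uniform(size=(16, 8, 8, 4)),
                    rng.uniform(size=(16, 8, 8, 4)))
        assert ddf.data.shape == (16, 8, 8, 3)

    def test_invalid_shape_rejected(self):
        with pytest.raises(ConfigurationError):
            regnet.RegNetConfig(input_shape=(17, 8, 8), base_channels=4)

    def test_parameter_count_matches_block_arithmetic(self):
        """Derive the parameter count from the block definitions alone."""
        b, stem, levels = 4, 2, 3
        enc_ch = [b * 2**i for i in range(levels)]

        def conv(cin, cout, k=3):
            return cout * cin * k**3 + cout

        def conv_block(cin, cout):
            return conv(cin, cout) + 2 * cout  # + batch-norm affine

        def residual(c):
            return conv_block(c, c) + conv(c, c) + 2 * c

        total = 0
        cin = stem
        for c in enc_ch:  # encoders: conv block + residual block
            total += conv_block(cin, c) + residual(c)
            cin = c
        total += conv_block(enc_ch[-1], enc_ch[-1])  # bottom
        head_channels = [enc_ch[-1]]
        cin = enc_ch[-1]
        for skip in reversed(enc_ch):  # decoders
            up_out = cin // 2
            total += conv(cin, up_out)  # transposed conv
            cat = up_out + skip
            out = cat // 2 + (cat // 2) % 2  # halved, kept even
            total += conv_block(cat, out) + residual(out)
            head_channels.append(out)
            cin = out
        for c in head_channels:  # output heads project to 3 channels
            total += conv(c, 3)

        model = regnet.build_localnet(TINY, seed=0)
        assert model.num_parameters() == total


class TestAugmentation:
    def test_zero_strength_is_identity(self, rng):
        fixed, moving = _tiny_pair()
        cl = CentroidList(np.array([[4.0, 4.0, 4.0]]), capacity=8)
        out = regnet.augment_affine_pair(fixed, moving, cl, cl, 0.0, rng)
        assert out[0] is fixed and out[1] is moving

    def test_same_seed_bit_identical(self):
        fixed, moving = _tiny_pair()
        cl = CentroidList(np.array([[4.0, 4.0, 4.0]]), capacity=8)
        a = regnet.augment_affine_pair(fixed, moving, cl, cl, 0.05, 11)
        b = regnet.augment_affine_pair(fixed, moving, cl, cl, 0.05, 11)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])
        np.testing.assert_array_equal(a[2].rows, b[2].rows)

    def test_warped_centroid_tracks_blob_peak(self):
        shape = (24, 24, 12)
        g = np.indices(shape).transpose(1, 2, 3, 0).astype(float)
        center = np.array([12.0, 11.0, 6.0])
        blob = np.exp(-0.5 * np.sum((g - center) ** 2, axis=-1) / 2.0)
        cl = CentroidList(center[None], capacity=4)
        out_img, _, out_cl, _ = regnet.augment_affine_pair(
            blob, blob, cl, cl, 0.05, 99)
        # intensity peak of the warped blob vs the analytically mapped center
        mask = out_img > 0.3 * out_img.max()
        com = (g * (out_img * mask)[..., None]).sum(axis=(0, 1, 2)) / \
            (out_img * mask).sum()
        assert np.linalg.norm(com - out_cl.points[0]) < 0.5

    def test_rot90_involution_and_identity(self):
        fixed, _ = _tiny_pair(shape=(8, 8, 4))
        f1, m1, k = regnet.augment_rot90(fixed, fixed, 123)
        back = np.rot90(f1, 4 - k, axes=(0, 1))
        np.testing.assert_array_equal(back, fixed)
        if k == 0:
            np.testing.assert_array_equal(f1, fixed)

    def test_rot90_draws_are_uniform(self):
        rng = np.random.default_rng(0)
        fixed, _ = _tiny_pair(shape=(8, 8, 4))
        counts = np.zeros(4)
        for _ in range(4000):
            _, _, k = regnet.augment_rot90(fixed, fixed, rng)
            counts[k] += 1
        assert stats.chisquare(counts).pvalue > 0.01

    def test_rot90_requires_square_plane(self):
        fixed, moving = _tiny_pair()
        with pytest.raises(ValueError):
            regnet.augment_rot90(fixed, moving, 0)


class TestTraining:
    def test_identical_seeds_identical_losses(self, small_pair):
        prob = regnet.RegistrationProblem(
            small_pair["fixed"], small_pair["moving"],
            small_pair["fixed_centroids"], small_pair["moving_centroids"])
        cfg = regnet.RegNetConfig(input_shape=(32, 16, 8), input_channels=1,
                                  levels=3, base_channels=4, variant="worm")
        runs = []
        for _ in range(2):
            model = regnet.build_localnet(cfg, seed=5)
            _, hist = regnet.train_registration(
                model, [prob],
                regnet.TrainConfig(learning_rate=1e-3, epochs=3, seed=5,
                                   preset="worm", lncc_n=8,
                                   augment_strength=0.03))
            runs.append(hist["train"])
        assert runs[0] == runs[1]

    def test_loss_decreases_with_smoothing(self):
        rng = np.random.default_rng(4)
        problems = []
        for seed in range(3):
            fixed, moving = _tiny_pair(seed)
            pts = rng.uniform(2, 6, (4, 3))
            problems.append(regnet.RegistrationProblem(
                fixed, moving, CentroidList(pts, capacity=8),
                CentroidList(pts + [1.0, 0, 0], capacity=8)))
        model = regnet.build_localnet(TINY, seed=0)
        _, hist = regnet.train_registration(
            model, problems,
            regnet.TrainConfig(learning_rate=1e-3, epochs=12, seed=0,
                               preset="worm", lncc_n=4))
        smooth = np.convolve(hist["train"], np.ones(3) / 3, mode="valid")
        assert smooth[-1] <= smooth[0]

    def test_missing_centroids_rejected_for_worm_preset(self):
        fixed, moving = _tiny_pair()
        with pytest.raises(ValueError):
            regnet.train_registration(
                [regnet.build_localnet(TINY)][0],
                [regnet.RegistrationProblem(fixed, moving)],
                regnet.TrainConfig(epochs=1, preset="worm"))

    def test_overfit_single_pair(self, overfit_regnet, small_pair):
        """Capacity check: one pair is driven to NCC > 0.9 and sub-voxel
        centroid alignment, well below the pre-registration baseline."""
        model = overfit_regnet["model"]
        ddf = regnet.infer_ddf(model, small_pair["fixed"],
                               small_pair["moving"])
        warped = warp_image(small_pair["moving"], ddf)
        assert ncc(small_pair["fixed"], warped) > 0.9
        pred = warp_centroids(small_pair["fixed_centroids"], ddf)
        dist = np.mean(np.linalg.norm(
            pred.points - small_pair["moving_centroids"].points, axis=1))
        baseline = np.mean(np.linalg.norm(
            small_pair["fixed_centroids"].points
            - small_pair["moving_centroids"].points, axis=1))
        assert dist < 2.0
        assert dist < baseline

    def test_loss_paths_agree(self, small_pair):
        """The differentiable loss equals the reference (numpy) evaluation
        applied to the inferred DDF."""
        model = regnet.build_localnet(
            regnet.RegNetConfig(input_shape=(32, 16, 8), input_channels=1,
                                levels=3, base_channels=4, variant="worm"),
            seed=9)
        for head in model.heads:
            head.weight.data[...] = 0.005
        fixed = small_pair["fixed"]
        moving = small_pair["moving"]
        prob = regnet.RegistrationProblem(
            fixed, moving, small_pair["fixed_centroids"],
            small_pair["moving_centroids"])
        ddf_t = model(fixed, moving)
        tensor_total = regnet.registration_loss_tensor(
            ddf_t, prob, losses.WORM_WEIGHTS, lncc_n=8).data

        ddf = regnet.infer_ddf(model, fixed, moving)
        image = losses.lncc_image_loss(fixed, warp_image(moving, ddf), n=8)
        centroid = losses.centroid_alignment_loss(
            small_pair["moving_centroids"],
            warp_centroids(small_pair["fixed_centroids"], ddf))
        comps = {
            "grad": losses.gradient_norm(ddf),
            "diff": losses.difference_norm(ddf),
            "axis": losses.axis_difference_norm(ddf),
            "nonrigid": losses.nonrigid_penalty(ddf),
        }
        ref_total = losses.total_registration_loss(
            image, centroid, comps, losses.WORM_WEIGHTS)
        assert tensor_total == pytest.approx(ref_total, abs=1e-8)


class TestCheckpoint:
    def test_roundtrip(self, tmp_path):
        model = regnet.build_localnet(TINY, seed=7)
        for head in model.heads:
            head.weight.data[...] = 0.01
        path = tmp_path / "model.npz"
        regnet.save_checkpoint(model, path)
        loaded = regnet.load_checkpoint(path)
        fixed, moving = _tiny_pair(3)
        np.testing.assert_array_equal(
            regnet.infer_ddf(model, fixed, moving),
            regnet.infer_ddf(loaded, fixed, moving))


def test_jellyfish_pairs_use_first_frame_as_fixed():
    frames = [np.full((4, 4, 2), float(i)) for i in range(4)]
    problems = regnet.jellyfish_pairs(frames)
    assert len(problems) == 3
    for k, p in enumerate(problems, start=1):
        np.testing.assert_array_equal(p.fixed, frames[0])
        np.testing.assert_array_equal(p.moving, frames[k])
        assert p.fixed_centroids is None
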