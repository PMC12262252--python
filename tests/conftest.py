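"""Shared fixtures.

The expensive fixtures (overfit-trained networks) are session-scoped so
unit tests and the end-to-end checks share one training run.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from neuralign import regnet, synthetic

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_pair():
    """One synthetic deformed pair at desk scale with ground truth."""
    cfg = synthetic.SynthConfig(
        shape=(32, 16, 8), n_cells=6, nucleus_sigma=1.2, margin=4.0,
        min_separation=3.5, affine_strength=0.06, bend_amplitude=2.5,
        seed=7,
    )
    fixed, moving, fc, mc, rois, deform = synthetic.make_deformed_pair(cfg)
    return {
        "cfg": cfg, "fixed": fixed, "moving": moving,
        "fixed_centroids": fc, "moving_centroids": mc,
        "rois": rois, "deform": deform,
    }


@pytest.fixture(scope="session")
def overfit_regnet(small_pair):
    """Worm-variant LocalNet overfit to the single synthetic pair.

    Trained once per session at reduced scale (32x16x8, base 4 channels);
    shared by the capacity test and the end-to-end acceptance check.
    """
    cfg = regnet.RegNetConfig(
        input_shape=(32, 16, 8), input_channels=1, levels=3, base_channels=4,
        variant="worm",
    )
    model = regnet.build_localnet(cfg, seed=0)
    problem = regnet.RegistrationProblem(
        small_pair["fixed"], small_pair["moving"],
        small_pair["fixed_centroids"], small_pair["moving_centroids"],
    )
    train_cfg = regnet.TrainConfig(
        learning_rate=2e-3, epochs=150, seed=0, preset="worm", lncc_n=8,
    )
    model, history = regnet.train_registration(model, [problem], train_cfg)
    return {"model": model, "history": history, "problem": problem,
            "train_cfg": train_cfg}
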