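"""Shared fixtures: tiny analytic models and cached scaled-down training runs."""

from __future__ import annotations

import numpy as np
import pytest

import stec

# Fixed seeds for the multi-seed condition comparisons.
CONDITION_SEEDS = (11, 12, 13)


@pytest.fixture(scope="session")
def tiny_cfg() -> stec.HierarchyConfig:
    """A 6x8-pixel model small enough for finite differences and brute force."""
    return stec.HierarchyConfig(units=(8, 4), image_shape=(6, 8), patch_shape=(4, 5))


@pytest.fixture(scope="session")
def small_cfg() -> stec.HierarchyConfig:
    """The scaled-down study profile: 32x48 images, 16+16 units."""
    return stec.HierarchyConfig(units=(16, 16), image_shape=(32, 48), patch_shape=(19, 29))


@pytest.fixture(scope="session")
def small_stim(small_cfg) -> stec.StimulusSet:
    return stec.generate_naturalistic(60, shape=small_cfg.image_shape, seed=101)


@pytest.fixture(scope="session")
def small_glyphs(small_cfg) -> stec.StimulusSet:
    return stec.generate_glyphs(60, shape=small_cfg.image_shape, seed=102)


class TrainedModelCache:
    """Train-on-demand cache of scaled-down runs, shared across the session.

    All runs use the same stimulus set and profile (minibatch 20, window 5,
    one repetition); lambda and the seed select the condition.
    """

    def __init__(self, cfg: stec.HierarchyConfig, stim: stec.StimulusSet):
        self.cfg = cfg
        self.stim = stim
        self._cache: dict = {}

    def get(self, lambda_reg: float, seed: int, iterations: int = 4000, **obj_kwargs):
        key = (lambda_reg, seed, iterations, tuple(sorted(obj_kwargs.items())))
        if key not in self._cache:
            obj = stec.ObjectiveConfig(lambda_reg=lambda_reg, **obj_kwargs)
            tr = stec.TrainingConfig(
                iterations_per_repetition=iterations,
                repetitions=1,
                minibatch_size=20,
                seed=seed,
            )
            self._cache[key] = stec.train(self.stim, self.cfg, obj, tr)
        return self._cache[key]

    def init_params_for_seed(self, seed: int) -> stec.ModelParams:
        """The untrained parameters a run with this training seed starts from."""
        from stec.training import derived_seeds

        return stec.init_params(self.cfg, derived_seeds(seed)["init"])


@pytest.fixture(scope="session")
def trained(small_cfg, small_stim) -> TrainedModelCache:
    return TrainedModelCache(small_cfg, small_stim)
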