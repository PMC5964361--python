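"""Shared fixtures: scaled-down session configs and small synthetic inputs.

Full-scale sessions (50 trials per class at 30 kHz) are too heavy for unit
tests; the scaled config keeps the same structure (two cuffs, shared
sources, marker segmentation, stratified CV) at roughly 1 s of compute per
session: 6 kHz sampling, 0.6 s ON / 0.3 s OFF epochs, 0.3 s windows and
ten repetitions per class.
"""

import numpy as np
import pytest

from cuffsep import ExperimentConfig, TrialWindow


@pytest.fixture(scope="session")
def scaled_config():
    """Factory for desk-scale ExperimentConfig instances."""

    def make(design: str, seed: int = 0, **overrides) -> ExperimentConfig:
        kwargs = dict(
            design=design,
            fs=6000.0,
            source_band=(300.0, 2500.0),
            on_s=0.6,
            off_s=0.3,
            noci_on_s=0.6,
            noci_off_s=0.3,
            window_len_s=0.3,
            window_offset_s=0.15,
            reps_per_class_per_block=10,
            n_blocks=1,
            sim_seed=seed,
            fold_seed=seed,
            run_pair_search=False,
        )
        kwargs.update(overrides)
        return ExperimentConfig(**kwargs)

    return make


@pytest.fixture
def gaussian_windows():
    """Factory for homogeneous white-noise trial windows."""

    def make(n_windows=20, n_channels=4, n_samples=600, seed=0, sd=1.0):
        rng = np.random.default_rng(seed)
        return [
            TrialWindow(
                class_id=k % 2,
                t_start=float(k),
                t_len=n_samples / 600.0,
                samples=sd * rng.standard_normal((n_channels, n_samples)),
                trial_id=k,
            )
            for k in range(n_windows)
        ]

    return make
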