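"""Shared fixtures: small synthetic sessions built once per test run."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from gonogo_erp.montage import compact_montage
from gonogo_erp.pipeline import exp1_config
from gonogo_erp.simulate import exp1_params, simulate_subject
from gonogo_erp.task import TaskConfig, make_schedule

FS = 256.0


@pytest.fixture(scope="session")
def small_task() -> TaskConfig:
    return TaskConfig(trials_per_block=20, n_blocks_directional=3,
                      n_blocks_nondirectional=2)


@pytest.fixture(scope="session")
def noiseless_params():
    return exp1_params(noise_rms=0.0, line_amp=0.0, miss_rate=0.0,
                       false_alarm_rate=0.0)


@pytest.fixture(scope="session")
def noiseless_recording(small_task, noiseless_params):
    """One clean session: every deposited template is exactly recoverable."""
    schedule = make_schedule(small_task, seed=42)
    return simulate_subject(schedule, noiseless_params,
                            montage=compact_montage(), fs=FS, seed=7)


@pytest.fixture(scope="session")
def noisy_recording(small_task):
    params = exp1_params()  # default noise_rms 10, line 2
    schedule = make_schedule(small_task, seed=13)
    return simulate_subject(schedule, params, montage=compact_montage(),
                            fs=FS, seed=14)


@pytest.fixture()
def unfiltered_config():
    """Measurement config bypassing the band-pass (signal-chain fidelity)."""
    return replace(exp1_config(seed=0), band=None, montage=compact_montage())


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def balanced_table(rng, n_subjects=10, factors=("stimulation", "cue", "hand"),
                   levels=(("active", "sham"), ("directional", "nondirectional"),
                           ("L", "R")), effects=None, noise=1.0):
    """Long-format balanced within-subject table with optional cell effects."""
    rows = []
    from itertools import product
    for s in range(n_subjects):
        base = rng.normal(0, 1)
        for combo in product(*levels):
            val = base + rng.normal(0, noise)
            if effects:
                for (fac, lev), delta in effects.items():
                    if combo[list(factors).index(fac)] == lev:
                        val += delta
            rows.append(dict(subject=f"s{s}", value=val,
                             **dict(zip(factors, combo))))
    return pd.DataFrame(rows)
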