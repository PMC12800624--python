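"""Shared fixtures: one synthetic call dataset and one playback experiment,
built once per session and reused by read-only tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from callcontext import features, simulate


def make_pool_manifest(per_condition: int, seed: int) -> pd.DataFrame:
    """Metadata-only call pool (no audio) for stimulus assembly tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for cond in simulate.CONDITIONS:
        for i in range(per_condition):
            rows.append(
                {
                    "call_id": f"{cond}_{i:03d}",
                    "caller_id": f"M{i % 5 + 1}",
                    "context": cond,
                    "duration_s": float(rng.uniform(0.4, 1.6)),
                    "peak_amp": float(rng.uniform(0.5, 0.9)),
                }
            )
    return pd.DataFrame(rows)


SUBJECTS = [(f"S{i + 1}", "male" if i % 2 == 0 else "female") for i in range(9)]

#: desk-scale call config reused across tests
FAST_CONFIG = simulate.SynthCallConfig(sample_rate_hz=22050, duration_s=0.35)


@pytest.fixture(scope="session")
def call_dataset():
    """45 synthetic calls (5 callers x 3 contexts x 3) with default shifts."""
    return simulate.generate_call_dataset(
        base_config=FAST_CONFIG, n_callers=5, calls_per_caller_per_context=3, seed=101
    )


@pytest.fixture(scope="session")
def feature_table(call_dataset):
    waveforms, _ = call_dataset
    return features.extract_table(waveforms)


@pytest.fixture(scope="session")
def playback_experiment():
    """(stimuli, design, trials) for 9 subjects x 8 sessions."""
    manifest = make_pool_manifest(30, seed=7)
    stimuli = simulate.assemble_stimuli(manifest, {c: 10 for c in simulate.CONDITIONS}, seed=7)
    design = simulate.schedule_playbacks(SUBJECTS, stimuli, seed=7)
    trials = simulate.generate_behavioral_dataset(design, seed=7)
    return stimuli, design, trials
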