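import dataclasses

import numpy as np
import pytest

from awear.synth import (
    CohortSpec,
    MotionModelParams,
    default_class_models,
    simulate_recording,
)


@pytest.fixture(scope="session")
def tremor_params() -> MotionModelParams:
    return MotionModelParams(
        class_label="tremor",
        task="rest",
        tremor_freq_hz=5.0,
        tremor_amp_g=0.15,
        tremor_amp_dps=25.0,
        noise_sd=0.005,
    )


@pytest.fixture(scope="session")
def tremor_recording(tremor_params):
    return simulate_recording(tremor_params, fs=100.0, duration=60.0, seed=7)


def small_cohort_spec(seed: int = 0, **kwargs) -> CohortSpec:
    """4/3/3 subjects, 20 s trials, three tasks — cheap but structured."""
    defaults = dict(
        n_healthy=4,
        n_tremor=3,
        n_bradykinesia=3,
        tasks=("rest", "kinetic", "finger_tap"),
        duration_s=20.0,
        seed=seed,
    )
    defaults.update(kwargs)
    return CohortSpec(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    from awear.synth import generate_cohort

    return generate_cohort(small_cohort_spec(seed=11))


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    from awear.features import build_feature_table
    from awear.preprocess import preprocess_recording

    recs, labels = small_cohort
    filt = [preprocess_recording(r) for r in recs]
    return build_feature_table(filt, labels)
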