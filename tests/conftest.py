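import warnings

import numpy as np
import pandas as pd
import pytest

from decispeed.containers import SubjectBehavior
from decispeed.synthetic_cohort import CohortConfig, SubjectParams, synthesize_epochs

warnings.filterwarnings("ignore", message="TSE baseline window")


def make_subject(**overrides) -> SubjectParams:
    params = dict(
        subject_id="t000",
        group="older",
        age=70.0,
        v=7.0,
        a=2.7,
        t0=0.11,
        cpp_slope_true=0.08,
        cpp_onset_true=300.0,
        n2c_latency_true=280.0,
        n2c_amp_true=-3.0,
        lhb_depth_true=2.0,
        cri_leisure=130.0,
        cri_education=110.0,
        cri_occupation=120.0,
        noise_sd=0.0,
    )
    params.update(overrides)
    return SubjectParams(**params)


def make_behavior(n=120, rt_ms=600.0, subject_id="t000") -> SubjectBehavior:
    """Balanced, constant-RT behavior for deterministic round-trips."""
    trials = pd.DataFrame(
        {
            "rt_ms": np.full(n, float(rt_ms)),
            "responded": True,
            "hemifield": np.tile(["left", "right"], (n + 1) // 2)[:n],
            "direction": np.tile(["up", "up", "down", "down"], (n + 3) // 4)[:n],
            "iti_s": np.tile([1.8, 2.8, 3.8], (n + 2) // 3)[:n],
        }
    )
    return SubjectBehavior(trials=trials, subject_id=subject_id)


@pytest.fixture(scope="session")
def quiet_config() -> CohortConfig:
    return CohortConfig(n_older=1, n_younger=1, trials_per_subject=120, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def planted_subject() -> SubjectParams:
    return make_subject()


@pytest.fixture(scope="session")
def constant_behavior() -> SubjectBehavior:
    return make_behavior()


@pytest.fixture(scope="session")
def noiseless_epochs(planted_subject, constant_behavior, quiet_config):
    return synthesize_epochs(planted_subject, constant_behavior, quiet_config)
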