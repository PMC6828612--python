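import numpy as np
import pandas as pd
import pytest

from peritheta import CohortParams, sample_behavior
from peritheta.cohort import GroupParams


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Six-subject behaviour-only cohort used across behaviour tests."""
    return sample_behavior(CohortParams(n_td=3, n_adhd=3, seed=20240901))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_trials(correct, rt=None, subject="s1", group="TD", block=None):
    """Build a minimal one-subject trial table from a correctness string
    like 'CCCECCC' (C correct, E commission error, M miss)."""
    correct = list(correct)
    n = len(correct)
    if block is None:
        block = [1] * n
    if rt is None:
        rt = [400.0] * n
    rt = [np.nan if c == "M" else r for c, r in zip(correct, rt)]
    return pd.DataFrame({
        "subject": subject, "group": group, "subtype": "",
        "block": block, "trial": _within_block_index(block),
        "correct": [1 if c == "C" else 0 for c in correct],
        "compatibility": (["compatible", "incompatible"] * (n // 2 + 1))[:n],
        "rt_ms": rt,
    })


def _within_block_index(block):
    out, counts = [], {}
    for b in block:
        counts[b] = counts.get(b, 0) + 1
        out.append(counts[b])
    return out


@pytest.fixture()
def quiet_group_params() -> GroupParams:
    """EEG generation without nuisance components (for null tests)."""
    return GroupParams(theta_burst_db=0.0, theta_correct_db=0.0,
                      blink_rate_hz=0.0, line_amp_uv=0.0,
                      artifacts_per_recording=0.0, error_rate=0.15)
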