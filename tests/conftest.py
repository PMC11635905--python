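import numpy as np
import pytest

from habitdecay.families import evaluate
from habitdecay.series import DiarySeries
from habitdecay.synthetic import CohortConfig


def noiseless_config(**overrides) -> CohortConfig:
    """Cohort config with every stochastic component switched off."""
    base = dict(
        noise_sd_range=(0.0, 0.0),
        p_isolated_missing=0.0,
        gap_spec=None,
        p_duplicate=0.0,
        p_after_midnight=0.0,
        group_shifts={},
    )
    base.update(overrides)
    return CohortConfig(**base)


def series_from_curve(family, theta, n_days=84, pid="p1", group="SB") -> DiarySeries:
    """Noise-free series evaluated on the full occasion grid."""
    t = np.arange(n_days, dtype=float)
    return DiarySeries(pid, group, evaluate(family, theta, t))


@pytest.fixture
def outlier_after_gap_series() -> DiarySeries:
    """Linear decay observed on days 0-61, a 21-day missing gap, then a
    single extreme observation: deleting the outlier flips the BIC
    selection from cubic back to linear."""
    vals = np.full(84, np.nan)
    t = np.arange(84.0)
    line = 3.0 - 0.02 * t
    vals[:62] = line[:62]
    vals[83] = 4.0  # the outlier, placed after the gap
    return DiarySeries("outlier", "SB", vals)


@pytest.fixture
def outlier_after_long_gap_series() -> DiarySeries:
    """Same construction with the gap lengthened to 22 days."""
    vals = np.full(84, np.nan)
    t = np.arange(84.0)
    line = 3.0 - 0.02 * t
    vals[:61] = line[:61]
    vals[83] = 4.0
    return DiarySeries("outlier22", "SB", vals)
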