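"""Synthetic daily-diary cohort generator with known ground truth.

Emulates the structure of an intensive-longitudinal habit-decay study:
four behavioral groups (sedentary behavior, unhealthy snacking, alcohol
consumption, tobacco smoking), up to 84 daily SRBAI measurements per
participant on a 0-4 scale in steps of 0.25 (the mean of four integer
Likert items), roughly 29% missing values with long gaps concentrated in
the second half of the series, occasional same-day duplicate responses,
and responses submitted after midnight that belong to the previous day.

Each participant's latent trajectory is drawn from one of the six model
families with parameters drawn from per-family priors, so downstream
fitting, selection and stabilization stages can be tested against exact
ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

from .families import FAMILY_ORDER, evaluate, get_family

__all__ = [
    "ConfigError",
    "GapSpec",
    "CohortConfig",
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_PARAM_PRIORS",
    "sample_family_params",
    "simulate_cohort",
]


class ConfigError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


#: Group sizes of the emulated study cohort (N = 194).
DEFAULT_GROUP_SIZES = {"SB": 46, "US": 57, "AC": 52, "TS": 39}

#: Mix of generating families. Decay-curve families dominate, matching
#: the observed prevalence of best-fitting asymptotic/logistic models.
DEFAULT_FAMILY_MIX = {
    "constant": 0.06,
    "linear": 0.07,
    "quadratic": 0.14,
    "cubic": 0.17,
    "asymptotic": 0.29,
    "logistic": 0.27,
}

#: Per-family uniform parameter ranges. Chosen so latent curves stay on
#: the 0-4 scale over 84 days and decay at plausible rates (asymptotic
#: rate constants 0.03-0.4/day give 95%-drop times of roughly 7-100 days).
DEFAULT_PARAM_PRIORS: dict[str, dict[str, tuple[float, float]]] = {
    "constant": {"b0": (1.0, 4.0)},
    "linear": {"b0": (2.0, 4.0), "b1": (-0.03, -0.005)},
    "quadratic": {"b0": (2.0, 4.0), "b1": (-0.06, -0.01), "b2": (0.0, 5e-4)},
    "cubic": {
        "b0": (2.0, 4.0),
        "b1": (-0.09, -0.02),
        "b2": (3e-4, 1.5e-3),
        "b3": (-9e-6, -2e-6),
    },
    "asymptotic": {
        "A": (0.0, 2.0),
        "R0": (2.5, 4.0),
        "lam": (math.log(0.03), math.log(0.4)),
    },
    "logistic": {
        "L": (0.0, 2.0),
        "U": (2.5, 4.0),
        "m": (5.0, 40.0),
        "s": (1.0, 8.0),
    },
}

#: Additive intercept shifts per behavioral group (habit level only; the
#: emulated study found group differences in intercept, not in shape).
DEFAULT_GROUP_SHIFTS = {"SB": 0.5, "US": -0.3, "AC": -0.6, "TS": 0.3}


@dataclass(frozen=True)
class GapSpec:
    """Long-gap process: per participant, ``n_gaps`` blocks of missing
    days with geometric lengths, biased toward the second half."""

    n_gap_weights: tuple[float, ...] = (0.18, 0.30, 0.27, 0.25)  # P(0..3 gaps)
    min_length: int = 2
    mean_extra_length: float = 12.0  # geometric mean beyond min_length
    late_bias: float = 0.7  # P(gap starts in second half)

    def validate(self) -> None:
        if abs(sum(self.n_gap_weights) - 1.0) > 1e-9 or any(
            w < 0 for w in self.n_gap_weights
        ):
            raise ConfigError("gap_spec.n_gap_weights must be a probability vector")
        if self.min_length < 2:
            raise ConfigError("gap_spec.min_length must be >= 2 (singletons are not gaps)")
        if not 0.0 <= self.late_bias <= 1.0:
            raise ConfigError("gap_spec.late_bias must be in [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of one synthetic cohort draw."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_days: int = 84
    family_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_MIX)
    )
    param_priors: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PARAM_PRIORS.items()}
    )
    noise_sd_range: tuple[float, float] = (0.2, 0.5)
    p_isolated_missing: float = 0.12
    gap_spec: GapSpec | None = field(default_factory=GapSpec)
    p_duplicate: float = 0.02
    p_after_midnight: float = 0.08
    p_increasing: float = 0.0  # chance of a relapse-type (non-decaying) truth
    group_shifts: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SHIFTS)
    )
    include_baseline: bool = True
    start_date: date = date(2023, 1, 1)  # study Day 0; decay phase = Days 8..91
    day_offset: int = 8  # study day of occasion t=0
    seed: int = 0

    @property
    def groups(self) -> list[str]:
        return list(self.n_per_group)

    def validate(self) -> None:
        for name, p in [
            ("p_isolated_missing", self.p_isolated_missing),
            ("p_duplicate", self.p_duplicate),
            ("p_after_midnight", self.p_after_midnight),
            ("p_increasing", self.p_increasing),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.n_days < 8:
            raise ConfigError(f"n_days must be >= 8, got {self.n_days}")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ConfigError("n_per_group counts must be non-negative")
        mix_sum = sum(self.family_mix.values())
        if abs(mix_sum - 1.0) > 1e-9 or any(p < 0 for p in self.family_mix.values()):
            raise ConfigError(
                f"family_mix must be a probability vector summing to 1, sums to {mix_sum}"
            )
        for fam in self.family_mix:
            get_family(fam)  # raises on unknown name
            if fam not in self.param_priors:
                raise ConfigError(f"param_priors missing family {fam!r}")
        lo, hi = self.noise_sd_range
        if lo < 0 or hi < lo:
            raise ConfigError(f"noise_sd_range must satisfy 0 <= lo <= hi, got {self.noise_sd_range}")
        if self.gap_spec is not None:
            self.gap_spec.validate()


def _curve_on_scale(family: str, theta: np.ndarray, n_days: int) -> bool:
    t = np.arange(n_days, dtype=float)
    f = evaluate(family, theta, t)
    return bool(np.all(f >= 0.0) and np.all(f <= 4.0))


def sample_family_params(
    family: str,
    priors: dict[str, dict[str, tuple[float, float]]],
    rng: np.random.Generator,
    *,
    n_days: int = 84,
    increasing: bool = False,
    max_tries: int = 1000,
) -> np.ndarray:
    """Draw one parameter vector for ``family`` from uniform priors.

    Rejection-samples until the latent curve stays on the 0-4 scale over
    ``n_days`` occasions and, for asymptotic/logistic, the curve decays
    (initial value above the lower asymptote) unless ``increasing`` is
    set, in which case the orientation is flipped to model habits that
    retain or regain strength.
    """
    fam = get_family(family)
    ranges = priors[family]
    for _ in range(max_tries):
        theta = np.array([rng.uniform(*ranges[p]) for p in fam.param_names])
        if family == "asymptotic":
            a, r0 = theta[0], theta[1]
            if increasing:
                theta[0], theta[1] = max(a, r0), min(a, r0)  # A >= R0: rises
            else:
                theta[0], theta[1] = min(a, r0), max(a, r0)
            if theta[0] == theta[1]:
                continue
        elif family == "logistic":
            low, up = theta[0], theta[1]
            if increasing:
                theta[0], theta[1] = max(low, up), min(low, up)  # L >= U: rises
            else:
                theta[0], theta[1] = min(low, up), max(low, up)
            if theta[0] == theta[1]:
                continue
        elif increasing and family != "constant":
            theta[1] = abs(theta[1])  # flip slope sign for polynomials
        if _curve_on_scale(family, theta, n_days):
            return theta
    raise ConfigError(
        f"param_priors for {family!r} do not admit curves on the 0-4 scale"
    )


def _apply_group_shift(
    family: str, theta: np.ndarray, shift: float, n_days: int
) -> np.ndarray:
    """Shift a trajectory's level parameters, halving the shift until the
    curve stays on the 0-4 scale (deterministic)."""
    if shift == 0.0:
        return theta
    fam = get_family(family)
    level_idx = {"asymptotic": [0, 1], "logistic": [0, 1]}.get(family, [0])
    if fam.is_polynomial:
        level_idx = [0]
    for _ in range(12):
        shifted = theta.copy()
        shifted[level_idx] += shift
        if _curve_on_scale(family, shifted, n_days):
            return shifted
        shift *= 0.5
    return theta


def _truth_stabilization_day(
    family: str, theta: np.ndarray, n_days: int
) -> float | None:
    """Noiseless 95%-of-lower-asymptote day for decaying curve families."""
    # local import: stabilization also imports families, not this module
    from .stabilization import asymptote95_time

    if family not in ("asymptotic", "logistic"):
        return None
    f0 = float(evaluate(family, theta, 0.0))
    lower = float(theta[0])
    if f0 <= lower:  # non-decaying (relapse-type) truth
        return None
    t_star = asymptote95_time(family, theta)
    day = math.ceil(t_star)
    return float(day) if 0 <= day <= n_days - 1 else None


def _value_to_items(value: float) -> tuple[int, int, int, int]:
    """Decompose an SRBAI score into four integer 0-4 items whose mean,
    after rounding the score to the nearest 0.25, reproduces it."""
    total = int(round(float(np.clip(value, 0.0, 4.0)) * 4.0))
    base, rem = divmod(total, 4)
    items = [base + 1] * rem + [base] * (4 - rem)
    return tuple(items)  # type: ignore[return-value]


def _missing_mask(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """True where a day's response is missing."""
    n = config.n_days
    missing = rng.random(n) < config.p_isolated_missing
    spec = config.gap_spec
    if spec is not None:
        n_gaps = rng.choice(len(spec.n_gap_weights), p=spec.n_gap_weights)
        half = n // 2
        for _ in range(n_gaps):
            length = spec.min_length + rng.geometric(1.0 / (1.0 + spec.mean_extra_length)) - 1
            if rng.random() < spec.late_bias:
                start = int(rng.integers(half, n))
            else:
                start = int(rng.integers(0, half))
            missing[start : min(start + length, n)] = True
    return missing


def _response_rows(
    config: CohortConfig,
    pid: str,
    group: str,
    day: int,
    latent: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> list[dict]:
    """Rows for one participant-day: 1 response, possibly duplicated."""
    n_resp = 2 if rng.random() < config.p_duplicate else 1
    rows = []
    for _ in range(n_resp):
        value = latent + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        items = _value_to_items(value)
        if rng.random() < config.p_after_midnight:
            # submitted after midnight: next calendar day, morning clock time
            stamp_day = day + 1
            seconds = int(rng.integers(0, 12 * 3600))
        else:
            stamp_day = day
            seconds = int(18 * 3600 + rng.integers(0, 6 * 3600 - 60))
        stamp = datetime.combine(
            config.start_date + timedelta(days=stamp_day), datetime.min.time()
        ) + timedelta(seconds=seconds)
        rows.append(
            {
                "participant_id": pid,
                "group": group,
                "timestamp": stamp.isoformat(),
                "item_1": items[0],
                "item_2": items[1],
                "item_3": items[2],
                "item_4": items[3],
            }
        )
    return rows


def simulate_cohort(
    config: CohortConfig | None = None, *, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort of daily diary responses.

    Returns
    -------
    raw : DataFrame
        Long-format response table with columns ``participant_id``,
        ``group``, ``timestamp`` (ISO-8601), ``item_1`` .. ``item_4``
        (integers 0-4). One row per response; missing days are absent;
        duplicate and after-midnight responses are injected per config.
    truth : DataFrame
        One row per participant: generating ``family``, parameters
        ``theta_1`` .. ``theta_4`` (NaN-padded), ``noise_sd``,
        ``decreasing`` flag and noiseless ``stabilization_day``
        (95%-of-lower-asymptote day; NaN for non-decay families).

    Identical configs (including seed) produce byte-identical tables.
    """
    config = config if config is not None else CohortConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    rng = np.random.default_rng(config.seed)

    families = list(config.family_mix)
    mix = np.array([config.family_mix[f] for f in families], dtype=float)
    mix = mix / mix.sum()

    raw_rows: list[dict] = []
    truth_rows: list[dict] = []
    counter = 0
    for group, n in config.n_per_group.items():
        shift = config.group_shifts.get(group, 0.0)
        for _ in range(n):
            counter += 1
            pid = f"P{counter:04d}"
            family = str(rng.choice(families, p=mix))
            increasing = (
                family in ("asymptotic", "logistic", "linear", "quadratic", "cubic")
                and rng.random() < config.p_increasing
            )
            theta = sample_family_params(
                family,
                config.param_priors,
                rng,
                n_days=config.n_days,
                increasing=increasing,
            )
            theta = _apply_group_shift(family, theta, shift, config.n_days)
            lo, hi = config.noise_sd_range
            noise_sd = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
            latent = evaluate(family, theta, np.arange(config.n_days, dtype=float))
            missing = _missing_mask(config, rng)

            if config.include_baseline:
                # Day-7 baseline measurement, taken just before decay begins
                base_day = config.day_offset - 1
                raw_rows.extend(
                    _response_rows(
                        config, pid, group, base_day, float(latent[0]), noise_sd, rng
                    )
                )
            for t in range(config.n_days):
                if missing[t]:
                    continue
                raw_rows.extend(
                    _response_rows(
                        config,
                        pid,
                        group,
                        config.day_offset + t,
                        float(latent[t]),
                        noise_sd,
                        rng,
                    )
                )

            padded = np.full(4, np.nan)
            padded[: len(theta)] = theta
            f0, f_end = float(latent[0]), float(latent[-1])
            truth_rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "family": family,
                    "theta_1": padded[0],
                    "theta_2": padded[1],
                    "theta_3": padded[2],
                    "theta_4": padded[3],
                    "noise_sd": noise_sd,
                    "decreasing": f0 > f_end,
                    "stabilization_day": _truth_stabilization_day(
                        family, theta, config.n_days
                    ),
                }
            )

    raw = pd.DataFrame(
        raw_rows,
        columns=[
            "participant_id",
            "group",
            "timestamp",
            "item_1",
            "item_2",
            "item_3",
            "item_4",
        ],
    )
    truth = pd.DataFrame(truth_rows)
    return raw, truth
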