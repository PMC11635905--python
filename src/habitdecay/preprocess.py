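"""Diary preprocessing: from raw responses to clean per-participant series.

The cleaning pipeline mirrors standard end-of-day e-diary handling:

1. responses stamped between 00:00 and 12:00 refer to the previous day;
2. the four 0-4 Likert items are averaged into the SRBAI score (rows with
   a partial item set are rejected);
3. same-day duplicate responses are collapsed by averaging;
4. isolated missing days (both neighbors observed) are imputed with the
   neighbor mean, longer gaps are retained as missing;
5. participants are retained only with at least ``min_measurements``
   observed values and engagement through the decay-phase midpoint.
"""

from __future__ import annotations

import warnings
from datetime import date

import numpy as np
import pandas as pd

from .series import DiarySeries

__all__ = [
    "recode_after_midnight",
    "score_srbai",
    "collapse_duplicates",
    "build_series",
    "impute_isolated",
    "retention_filter",
    "missingness_profile",
    "preprocess",
]

ITEM_COLS = ["item_1", "item_2", "item_3", "item_4"]

#: Default retention thresholds: at least six observed SRBAI values and a
#: last observed occasion at or past the decay-phase midpoint.
MIN_MEASUREMENTS = 6
MIDPOINT_OCCASION = 41


def recode_after_midnight(raw: pd.DataFrame) -> pd.DataFrame:
    """Assign each response to its diary day.

    Responses with clock time in the half-open interval [00:00, 12:00)
    were given after midnight and refer to the previous day; all others
    keep their calendar day. Adds a ``date`` column (datetime.date).

    Raises ``ValueError`` naming the row index if a timestamp cannot be
    parsed.
    """
    out = raw.copy()
    stamps = pd.to_datetime(out["timestamp"], errors="coerce", format="ISO8601")
    bad = stamps.isna() & out["timestamp"].notna()
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"unparseable timestamp at row {idx}: {out['timestamp'].iloc[idx]!r}")
    if stamps.isna().any():
        idx = int(np.flatnonzero(stamps.isna().to_numpy())[0])
        raise ValueError(f"missing timestamp at row {idx}")
    after_midnight = stamps.dt.hour < 12
    out["date"] = (stamps - pd.to_timedelta(after_midnight.astype(int), unit="D")).dt.date
    return out


def score_srbai(raw: pd.DataFrame) -> pd.DataFrame:
    """Average the four items into an ``srbai`` column.

    Rows with any item missing or outside 0..4 are dropped with a
    warning (complete scales are the norm in this instrument; partial
    rows indicate a data error rather than a score).
    """
    out = raw.copy()
    items = out[ITEM_COLS].apply(pd.to_numeric, errors="coerce")
    valid = items.notna().all(axis=1) & items.ge(0).all(axis=1) & items.le(4).all(axis=1)
    n_bad = int((~valid).sum())
    if n_bad:
        warnings.warn(
            f"rejected {n_bad} row(s) with partial or out-of-range SRBAI items",
            stacklevel=2,
        )
        out = out.loc[valid].copy()
        items = items.loc[valid]
    out["srbai"] = items.mean(axis=1)
    return out


def collapse_duplicates(scored: pd.DataFrame) -> pd.DataFrame:
    """One row per participant-day; duplicates averaged.

    Requires day recoding and scoring already applied (``date`` and
    ``srbai`` columns present).
    """
    grouped = (
        scored.groupby(["participant_id", "date"], sort=True)
        .agg(group=("group", "first"), srbai=("srbai", "mean"))
        .reset_index()
    )
    return grouped


def build_series(
    daily: pd.DataFrame,
    *,
    start_date: date,
    n_days: int = 84,
    day_offset: int = 8,
    include_day7_baseline: bool = True,
) -> list[DiarySeries]:
    """Assemble per-participant series on the occasion grid t = 0..n_days-1.

    Occasion t corresponds to study day ``day_offset + t`` relative to
    ``start_date``. The day just before the decay phase (study Day
    ``day_offset - 1``, i.e. Day 7 under defaults) is stored as the
    baseline value, not as part of the modelled series. Responses outside
    the baseline day and the occasion grid are ignored.
    """
    series = []
    for pid, sub in daily.groupby("participant_id", sort=True):
        values = np.full(n_days, np.nan)
        baseline = None
        for _, row in sub.iterrows():
            study_day = (row["date"] - start_date).days
            t = study_day - day_offset
            if include_day7_baseline and study_day == day_offset - 1:
                baseline = float(row["srbai"])
            elif 0 <= t < n_days:
                values[t] = float(row["srbai"])
        series.append(
            DiarySeries(str(pid), str(sub["group"].iloc[0]), values, baseline=baseline)
        )
    return series


def impute_isolated(series: DiarySeries) -> DiarySeries:
    """Fill isolated missing occasions with the mean of their neighbors.

    Only interior singletons — missing occasions whose immediate left and
    right neighbors are both present — are filled; runs of two or more,
    and missing occasions at the series edges, are retained as missing.
    For a singleton gap this equals linear interpolation. Idempotent.
    """
    values = series.values.copy()
    imputed = series.imputed.copy()
    present = np.isfinite(values)
    for t in range(1, len(values) - 1):
        if not present[t] and present[t - 1] and present[t + 1]:
            values[t] = 0.5 * (values[t - 1] + values[t + 1])
            imputed[t] = True
    return DiarySeries(
        series.participant_id, series.group, values, imputed, series.baseline
    )


def retention_filter(
    series_list: list[DiarySeries],
    *,
    min_measurements: int = MIN_MEASUREMENTS,
    midpoint_occasion: int = MIDPOINT_OCCASION,
) -> tuple[list[DiarySeries], pd.DataFrame]:
    """Apply the retention rules; returns (retained, exclusion log).

    A participant is retained iff the observed (non-imputed) measurement
    count is >= ``min_measurements`` AND the last observed occasion is at
    or beyond ``midpoint_occasion`` (engagement through the decay-phase
    midpoint). The exclusion log has one row per excluded participant
    with the first failed rule: ``min_measurements`` or
    ``midpoint_engagement``.
    """
    retained: list[DiarySeries] = []
    log_rows: list[dict] = []
    for s in series_list:
        n_obs = s.n_observed
        last = s.last_observed
        if n_obs < min_measurements:
            log_rows.append(
                {"participant_id": s.participant_id, "group": s.group,
                 "reason": "min_measurements", "n_observed": n_obs,
                 "last_observed": last}
            )
        elif last is None or last < midpoint_occasion:
            log_rows.append(
                {"participant_id": s.participant_id, "group": s.group,
                 "reason": "midpoint_engagement", "n_observed": n_obs,
                 "last_observed": last}
            )
        else:
            retained.append(s)
    log = pd.DataFrame(
        log_rows,
        columns=["participant_id", "group", "reason", "n_observed", "last_observed"],
    )
    return retained, log


def missingness_profile(series_list: list[DiarySeries]) -> pd.DataFrame:
    """Per-participant and overall missingness summary.

    Counts missing occasions before imputation, imputed occasions, and
    the longest missing run (post-imputation). The overall row uses
    denominator n_participants x n_days.
    """
    rows = []
    for s in series_list:
        n_missing_pre = int(s.n_days - s.n_observed)
        rows.append(
            {
                "participant_id": s.participant_id,
                "group": s.group,
                "n_days": s.n_days,
                "missing_pre_imputation": n_missing_pre,
                "imputed": int(s.imputed.sum()),
                "longest_gap": s.longest_gap,
            }
        )
    profile = pd.DataFrame(
        rows,
        columns=[
            "participant_id", "group", "n_days",
            "missing_pre_imputation", "imputed", "longest_gap",
        ],
    )
    if len(profile):
        total = {
            "participant_id": "__overall__",
            "group": "",
            "n_days": int(profile["n_days"].sum()),
            "missing_pre_imputation": int(profile["missing_pre_imputation"].sum()),
            "imputed": int(profile["imputed"].sum()),
            "longest_gap": int(profile["longest_gap"].max()),
        }
        profile = pd.concat([profile, pd.DataFrame([total])], ignore_index=True)
    return profile


def preprocess(
    raw: pd.DataFrame,
    *,
    start_date: date,
    n_days: int = 84,
    day_offset: int = 8,
    min_measurements: int = MIN_MEASUREMENTS,
    midpoint_occasion: int = MIDPOINT_OCCASION,
    include_day7_baseline: bool = True,
) -> tuple[list[DiarySeries], pd.DataFrame, pd.DataFrame]:
    """Full cleaning pipeline: raw responses -> retained, imputed series.

    Returns (retained series, exclusion log, missingness profile). The
    retention rules are applied to pre-imputation observed counts; the
    missingness profile is computed over the retained participants.
    """
    daily = collapse_duplicates(score_srbai(recode_after_midnight(raw)))
    series = build_series(
        daily,
        start_date=start_date,
        n_days=n_days,
        day_offset=day_offset,
        include_day7_baseline=include_day7_baseline,
    )
    series = [impute_isolated(s) for s in series]
    retained, log = retention_filter(
        series,
        min_measurements=min_measurements,
        midpoint_occasion=midpoint_occasion,
    )
    profile = missingness_profile(retained)
    return retained, log, profile
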