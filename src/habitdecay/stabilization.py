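"""Time for habit decay to stabilize, three operationalizations.

All estimates are confined to the observed window — no extrapolation
beyond the last usable occasion. Reported days are ceilings of the
continuous solutions ("reached by day d" semantics).

* ``asymptote95`` — day the fitted curve completes 95% of its total
  drop from f(0) to the lower asymptote; closed forms exist for both
  curve families:

  - asymptotic: exp(-r t*) = 0.05  =>  t* = ln(20) / r,  r = e^lam
  - logistic:   t* = m + s * ln(20 * (1 + e^(-m/s)) - 1)

* ``window7`` — first occasion t such that the change in fitted values
  across a 7-day window, |f(t+6) - f(t)|, is below a threshold (0.1 by
  default; 0.01 is the stricter documented alternative).

* ``midpoint_cross`` — first occasion with f(t) below the scale
  midpoint 2.0, an indicator that substantial change occurred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .families import evaluate
from .fitting import TrajectoryFit
from .series import DiarySeries

__all__ = [
    "StabilizationEstimate",
    "asymptote95_time",
    "time_to_95_asymptote",
    "time_to_window_stability",
    "midpoint_crossing",
    "summarize_stabilization",
    "SCALE_MIDPOINT",
]

SCALE_MIDPOINT = 2.0
_DROP_FRACTION = 0.95


@dataclass
class StabilizationEstimate:
    participant_id: str
    method: str  # asymptote95 | window7 | midpoint_cross
    family: str
    day: int | None
    within_window: bool
    midpoint_crossed_before_stabilization: bool | None = None


def asymptote95_time(family: str, theta, *, drop_from_f0: bool = True) -> float:
    """Continuous time at which 95% of the drop to the lower asymptote
    is completed, in days.

    For the asymptotic family the drop starts at f(0) = R0, so the two
    conventions coincide; for the logistic, ``drop_from_f0=True``
    (default) measures the drop from f(0), the alternative measures it
    from the upper asymptote U.
    """
    theta = np.asarray(theta, dtype=float)
    if family == "asymptotic":
        _, _, lam = theta
        return math.log(20.0) * math.exp(-lam)
    if family == "logistic":
        low, up, m, s = theta
        if drop_from_f0:
            # f(t*) = f(0) - 0.95*(f(0) - L), f(0) = L + (U-L)/(1+e^(-m/s))
            return m + s * math.log(20.0 * (1.0 + math.exp(-m / s)) - 1.0)
        # drop measured from U: f(t*) - L = 0.05 * (U - L)
        return m + s * math.log(19.0)
    raise ValueError(f"no 95%-asymptote closed form for family {family!r}")


def time_to_95_asymptote(
    fit: TrajectoryFit,
    series: DiarySeries,
    *,
    drop_from_f0: bool = True,
) -> StabilizationEstimate:
    """95%-of-lower-asymptote stabilization day for curve-family fits.

    Requires a decreasing asymptotic or logistic fit. The day is the
    ceiling of the continuous solution, clipped below at 0; if the
    solution lies beyond the last usable occasion the estimate is null
    with ``within_window=False``.
    """
    if fit.family not in ("asymptotic", "logistic"):
        raise ValueError(f"asymptote95 undefined for family {fit.family!r}")
    f0 = float(fit.predict(float(series.t_first)))
    lower = float(fit.theta[0])
    if f0 <= lower:
        raise ValueError("asymptote95 requires a decreasing fit (f(0) > lower asymptote)")
    t_star = asymptote95_time(fit.family, fit.theta, drop_from_f0=drop_from_f0)
    day = max(0, math.ceil(t_star))
    if day > series.t_last:
        return StabilizationEstimate(
            fit.participant_id, "asymptote95", fit.family, None, False
        )
    return StabilizationEstimate(
        fit.participant_id, "asymptote95", fit.family, day, True
    )


def time_to_window_stability(
    fit: TrajectoryFit,
    series: DiarySeries,
    *,
    threshold: float = 0.1,
    window: int = 7,
) -> StabilizationEstimate:
    """First occasion whose ``window``-day fitted change is below
    ``threshold``.

    Scans integer occasions t from the first usable occasion while the
    window endpoint t + window - 1 stays inside the observed span;
    change is measured between the window's endpoints,
    |f(t + window - 1) - f(t)|. Null when no in-window occasion
    qualifies (including when the window exceeds the observed span).
    """
    t0, t1 = series.t_first, series.t_last
    last_start = t1 - (window - 1)
    if last_start < t0:
        return StabilizationEstimate(
            fit.participant_id, "window7", fit.family, None, False
        )
    starts = np.arange(t0, last_start + 1, dtype=float)
    change = np.abs(fit.predict(starts + window - 1) - fit.predict(starts))
    hits = np.flatnonzero(change < threshold)
    if hits.size == 0:
        return StabilizationEstimate(
            fit.participant_id, "window7", fit.family, None, False
        )
    return StabilizationEstimate(
        fit.participant_id, "window7", fit.family, int(starts[hits[0]]), True
    )


def midpoint_crossing(
    fit: TrajectoryFit,
    series: DiarySeries,
    *,
    midpoint: float = SCALE_MIDPOINT,
    stabilization_day: int | None = None,
) -> StabilizationEstimate:
    """First occasion with fitted value below the scale midpoint.

    If a method-specific ``stabilization_day`` is supplied, flags
    whether the crossing precedes it.
    """
    t = np.arange(series.t_first, series.t_last + 1, dtype=float)
    below = np.flatnonzero(fit.predict(t) < midpoint)
    if below.size == 0:
        return StabilizationEstimate(
            fit.participant_id, "midpoint_cross", fit.family, None, False, None
        )
    day = int(t[below[0]])
    crossed_before = None if stabilization_day is None else day < stabilization_day
    return StabilizationEstimate(
        fit.participant_id, "midpoint_cross", fit.family, day, True, crossed_before
    )


def summarize_stabilization(
    estimates: list[StabilizationEstimate],
    *,
    eligible_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Median (min, max) of in-window days per method x family.

    ``eligible_ids`` restricts the summary (e.g. to participants with
    overall-valid fits whose predictions cross the scale midpoint).
    Strata with no in-window estimates are emitted with n = 0.
    """
    rows = []
    frame = pd.DataFrame(
        [
            {
                "participant_id": e.participant_id,
                "method": e.method,
                "family": e.family,
                "day": e.day,
                "within_window": e.within_window,
            }
            for e in estimates
        ]
    )
    if frame.empty:
        return pd.DataFrame(
            columns=["method", "family", "n", "median", "min", "max"]
        )
    if eligible_ids is not None:
        frame = frame[frame["participant_id"].isin(eligible_ids)]
    for (method, family), sub in frame.groupby(["method", "family"], sort=True):
        days = sub.loc[sub["within_window"], "day"].dropna().astype(float)
        rows.append(
            {
                "method": method,
                "family": family,
                "n": int(len(days)),
                "median": float(days.median()) if len(days) else math.nan,
                "min": float(days.min()) if len(days) else math.nan,
                "max": float(days.max()) if len(days) else math.nan,
            }
        )
    return pd.DataFrame(rows, columns=["method", "family", "n", "median", "min", "max"])
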