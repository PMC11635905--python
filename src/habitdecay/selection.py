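"""Best-family selection by BIC and the four-step validity gate.

A participant's best-fitting family is the converged fit with the lowest
BIC (ties within 1e-9 go to the smaller mean-structure parameter count,
then to the canonical family order — parsimony first). Whether the
fitted values validly describe the trajectory is decided by four checks:

1. the fitted trajectory decreases over the observed window;
2. the selected family is unchanged when any single observed occasion
   is deleted and all families are refitted (leave-one-out stability);
3. the fit's root-mean-square error is at most 0.33 (inclusive);
4. the series contains no missing gap longer than 21 days (inclusive).

A best-fitting constant model cannot "decrease"; for it, checks 2-4
decide a separate verdict — that a stably strong (or weak) habit is a
valid description — recorded as ``stable_habit_valid``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .families import FAMILY_ORDER, get_family
from .fitting import TrajectoryFit, fit_all_families
from .series import DiarySeries

__all__ = [
    "RMSE_CUTOFF",
    "GAP_CUTOFF",
    "ValidityVerdict",
    "select_best",
    "check_decreasing",
    "check_loo_stability",
    "check_rmse",
    "check_gaps",
    "classify",
    "verdicts_frame",
]

RMSE_CUTOFF = 0.33
GAP_CUTOFF = 21
_BIC_TIE_TOL = 1e-9


@dataclass
class ValidityVerdict:
    participant_id: str
    best_family: str
    bic_margin: float
    step1_decreasing: bool
    step2_loo_stable: bool
    step3_rmse_ok: bool
    step4_gap_ok: bool
    overall_valid: bool
    stable_habit_valid: bool | None  # only defined for constant best fits
    rmse: float
    longest_gap: int
    rmse_cutoff: float = RMSE_CUTOFF
    gap_cutoff: int = GAP_CUTOFF


def select_best(fits: dict[str, TrajectoryFit]) -> tuple[str, float]:
    """Pick the argmin-BIC family among converged fits.

    Returns (family, margin to the runner-up BIC; +inf with a single
    candidate). Ties within 1e-9 are broken by smaller ``k_mean``, then
    by the canonical family order. Raises ``ValueError`` when no fit
    converged (the participant is unmodellable).
    """
    candidates = []
    for name in FAMILY_ORDER:
        fit = fits.get(name)
        if fit is not None and fit.converged:
            candidates.append((fit.bic, get_family(name).k_mean, name))
    if not candidates:
        raise ValueError("no converged fits: participant unmodellable")
    best_bic = min(c[0] for c in candidates)
    tied = [c for c in candidates if c[0] <= best_bic + _BIC_TIE_TOL]
    tied.sort(key=lambda c: (c[1], FAMILY_ORDER.index(c[2])))
    best = tied[0]
    others = [c[0] for c in candidates if c[2] != best[2]]
    margin = (min(others) - best[0]) if others else math.inf
    return best[2], margin


def check_decreasing(fit: TrajectoryFit, series: DiarySeries, *, delta: float = 0.0) -> bool:
    """Step 1: fitted values strictly decrease end-to-end.

    Compares the fitted value at the first and last usable occasions of
    the observed window; a constant fit never passes.
    """
    f_first = float(fit.predict(float(series.t_first)))
    f_last = float(fit.predict(float(series.t_last)))
    return (f_first - f_last) > delta


def check_loo_stability(
    series: DiarySeries,
    best_family: str,
    *,
    min_agreement: float = 1.0,
) -> bool:
    """Step 2: selection unchanged under single-observation deletion.

    Every usable occasion is deleted in turn, all families are refitted
    and the best-by-BIC family recomputed. With the default
    ``min_agreement=1.0`` the check demands unanimity; a lower value
    (e.g. 0.95) accepts that fraction of agreeing replicates. A
    replicate in which no fit converges counts as disagreement.
    """
    occasions = np.flatnonzero(series.present)
    agree = 0
    for t in occasions:
        reduced = series.drop_occasion(int(t))
        try:
            fam, _ = select_best(fit_all_families(reduced))
        except ValueError:
            continue  # no converged fits: counts as instability
        if fam == best_family:
            agree += 1
    return agree >= min_agreement * len(occasions) - 1e-12


def check_rmse(fit: TrajectoryFit, *, cutoff: float = RMSE_CUTOFF) -> bool:
    """Step 3: RMSE at or below the cutoff (inclusive)."""
    return fit.rmse <= cutoff


def check_gaps(series: DiarySeries, *, cutoff: int = GAP_CUTOFF) -> bool:
    """Step 4: longest missing run at most ``cutoff`` days (inclusive)."""
    return series.longest_gap <= cutoff


def classify(
    series: DiarySeries,
    fits: dict[str, TrajectoryFit],
    *,
    rmse_cutoff: float = RMSE_CUTOFF,
    gap_cutoff: int = GAP_CUTOFF,
    loo_min_agreement: float = 1.0,
    run_loo: bool = True,
) -> ValidityVerdict:
    """Combine the four checks into a verdict for one participant.

    For non-constant best fits, ``overall_valid`` requires all four
    steps. For a constant best fit, step 1 is not applicable: steps 2-4
    decide ``stable_habit_valid`` and ``overall_valid`` is False (a
    stable habit is not a decay trajectory). ``run_loo=False`` skips the
    expensive step-2 refits and records the step as failed-unknown
    (False); use it only for exploratory passes.
    """
    best_family, margin = select_best(fits)
    fit = fits[best_family]
    step1 = check_decreasing(fit, series)
    step3 = check_rmse(fit, cutoff=rmse_cutoff)
    step4 = check_gaps(series, cutoff=gap_cutoff)
    if run_loo:
        step2 = check_loo_stability(series, best_family, min_agreement=loo_min_agreement)
    else:
        step2 = False
    steps234 = step2 and step3 and step4
    if best_family == "constant":
        overall = False
        stable_valid: bool | None = steps234
    else:
        overall = step1 and steps234
        stable_valid = None
    return ValidityVerdict(
        participant_id=series.participant_id,
        best_family=best_family,
        bic_margin=margin,
        step1_decreasing=step1,
        step2_loo_stable=step2,
        step3_rmse_ok=step3,
        step4_gap_ok=step4,
        overall_valid=overall,
        stable_habit_valid=stable_valid,
        rmse=fit.rmse,
        longest_gap=series.longest_gap,
        rmse_cutoff=rmse_cutoff,
        gap_cutoff=gap_cutoff,
    )


def verdicts_frame(verdicts: list[ValidityVerdict]) -> pd.DataFrame:
    """Tidy verdict table, one row per participant."""
    return pd.DataFrame([vars(v) for v in verdicts])
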