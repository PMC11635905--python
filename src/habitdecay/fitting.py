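"""Person-specific trajectory fitting and BIC computation.

Each of the six families is fitted to one participant's usable occasions
(observed plus singleton-imputed values; missing days are simply absent
from the least-squares problem). Polynomials are solved exactly by
ordinary least squares. The asymptotic and logistic curves are fitted by
bounded nonlinear least squares from a deterministic multi-start grid,
so repeated runs give identical results without stochastic restarts.

Fits are compared with a Gaussian-likelihood BIC,

    BIC = n * ln(max(SSE, eps) / n) + k * ln(n),    k = k_mean + 1,

where the error variance counts as one estimated parameter and the
``eps`` floor keeps the criterion finite on perfect (noise-free) fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .families import FAMILY_ORDER, ModelFamily, evaluate, get_family
from .series import DiarySeries

__all__ = [
    "TrajectoryFit",
    "BOUNDS",
    "bic",
    "fit_family",
    "fit_all_families",
]

SSE_FLOOR = 1e-10

#: Box bounds for the nonlinear families. Level parameters may overshoot
#: the 0-4 scale slightly to tolerate boundary-flat fits; the log rate
#: spans half-lives from hours to years.
BOUNDS = {
    "level": (-1.0, 5.0),  # A, R0, L, U
    "lam": (math.log(1e-4), math.log(2.0)),
    "m": (-30.0, 120.0),
    "s": (0.25, 60.0),
}

#: Rate-constant start grid for the asymptotic family (9 starts).
_ASYMPTOTIC_RATE_STARTS = (0.003, 0.008, 0.02, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6)


@dataclass
class TrajectoryFit:
    """One family fitted to one participant's series."""

    participant_id: str
    family: str
    theta: np.ndarray
    sse: float
    n_obs: int
    converged: bool

    @property
    def k_mean(self) -> int:
        return get_family(self.family).k_mean

    @property
    def rmse(self) -> float:
        return math.sqrt(self.sse / self.n_obs) if self.n_obs else math.nan

    @property
    def bic(self) -> float:
        return bic(self)

    def predict(self, t) -> np.ndarray:
        return evaluate(self.family, self.theta, t)


def bic(fit: TrajectoryFit) -> float:
    """Gaussian BIC of a converged fit; lower is better.

    Comparable across families fitted to the identical data. Raises if
    the fit did not converge (a non-converged fit has no defined BIC and
    is excluded from selection).
    """
    if not fit.converged:
        raise ValueError(f"BIC undefined for non-converged {fit.family} fit")
    if fit.n_obs <= 0:
        raise ValueError("BIC requires n_obs > 0")
    n = fit.n_obs
    k = fit.k_mean + 1
    return n * math.log(max(fit.sse, SSE_FLOOR) / n) + k * math.log(n)


def _fit_polynomial(t: np.ndarray, y: np.ndarray, degree: int) -> tuple[np.ndarray, float]:
    X = np.vander(t, degree + 1, increasing=True)
    theta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ theta
    return theta, float(resid @ resid)


def _nls(residual, jac, x0, lo, hi) -> tuple[np.ndarray, float, bool]:
    x0 = np.clip(x0, lo, hi)
    try:
        res = least_squares(
            residual, x0, jac=jac, bounds=(lo, hi), method="trf",
            ftol=1e-13, xtol=1e-13, gtol=1e-13, max_nfev=400,
        )
    except Exception:
        return x0, math.inf, False
    return res.x, float(2.0 * res.cost), bool(res.success)


def _fit_asymptotic(t: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
    # data-driven level starts: R0 from the first, A from the last 5 values
    r0_start = float(np.mean(y[:5]))
    a_start = float(np.mean(y[-5:]))
    lo = np.array([BOUNDS["level"][0], BOUNDS["level"][0], BOUNDS["lam"][0]])
    hi = np.array([BOUNDS["level"][1], BOUNDS["level"][1], BOUNDS["lam"][1]])

    def residual(p):
        a, r0, lam = p
        return a + (r0 - a) * np.exp(-np.exp(lam) * t) - y

    def jac(p):
        a, r0, lam = p
        rate = np.exp(lam)
        decay = np.exp(-rate * t)
        return np.column_stack(
            [1.0 - decay, decay, -(r0 - a) * t * decay * rate]
        )

    best = None
    for rate in _ASYMPTOTIC_RATE_STARTS:
        x0 = np.array([a_start, r0_start, math.log(rate)])
        theta, sse, ok = _nls(residual, jac, x0, lo, hi)
        if ok and (best is None or sse < best[1] - 1e-12):
            best = (theta, sse)
    if best is None:
        return np.array([a_start, r0_start, math.log(0.05)]), math.inf, False
    return best[0], best[1], True


def _fit_logistic(t: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
    u_start = float(np.mean(y[:5]))
    l_start = float(np.mean(y[-5:]))
    lo = np.array(
        [BOUNDS["level"][0], BOUNDS["level"][0], BOUNDS["m"][0], BOUNDS["s"][0]]
    )
    hi = np.array(
        [BOUNDS["level"][1], BOUNDS["level"][1], BOUNDS["m"][1], BOUNDS["s"][1]]
    )

    def residual(p):
        low, up, m, s = p
        return low + (up - low) / (1.0 + np.exp((t - m) / s)) - y

    def jac(p):
        low, up, m, s = p
        z = (t - m) / s
        sig = 1.0 / (1.0 + np.exp(z))
        dsig = sig * (1.0 - sig)  # -d sigma / dz
        return np.column_stack(
            [1.0 - sig, sig, (up - low) * dsig / s, (up - low) * dsig * z / s]
        )

    # 3x3 deterministic grid over midpoint and scale
    span = t[-1] - t[0] if len(t) > 1 else 1.0
    m_starts = (t[0] + 0.25 * span, t[0] + 0.5 * span, t[0] + 0.75 * span)
    s_starts = (2.0, 8.0, 25.0)
    best = None
    for m0 in m_starts:
        for s0 in s_starts:
            x0 = np.array([l_start, u_start, m0, s0])
            theta, sse, ok = _nls(residual, jac, x0, lo, hi)
            if ok and (best is None or sse < best[1] - 1e-12):
                best = (theta, sse)
    if best is None:
        return np.array([l_start, u_start, float(np.median(t)), 5.0]), math.inf, False
    return best[0], best[1], True


def fit_family(series: DiarySeries, family: str | ModelFamily) -> TrajectoryFit:
    """Fit one trajectory family to one participant's series.

    Both observed and imputed occasions enter the fit; missing occasions
    are skipped. A family is unfittable (``converged=False``) when fewer
    than ``k_mean + 2`` usable occasions are available or every
    optimizer start fails.
    """
    fam = get_family(family) if isinstance(family, str) else family
    t, y = series.fit_arrays()
    n = len(y)
    if n < fam.k_mean + 2:
        return TrajectoryFit(
            series.participant_id, fam.name,
            np.full(fam.k_mean, np.nan), math.inf, n, False,
        )
    if fam.is_polynomial:
        theta, sse = _fit_polynomial(t, y, fam.degree)
        return TrajectoryFit(series.participant_id, fam.name, theta, sse, n, True)
    if fam.name == "asymptotic":
        theta, sse, ok = _fit_asymptotic(t, y)
    else:
        theta, sse, ok = _fit_logistic(t, y)
    return TrajectoryFit(series.participant_id, fam.name, theta, sse, n, ok)


def fit_all_families(series: DiarySeries) -> dict[str, TrajectoryFit]:
    """Fit all six families; keys follow the canonical family order."""
    return {name: fit_family(series, name) for name in FAMILY_ORDER}
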