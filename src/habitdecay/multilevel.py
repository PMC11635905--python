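"""Group-level (multilevel) models of habit decay.

Three model surfaces over the long-format cohort table (one row per
participant x occasion):

* a random-intercept-only ("constant") model whose intraclass
  correlation quantifies how much outcome variance is between-person;
* linear mixed models with a fixed cubic polynomial in rescaled time,
  random effects added iteratively (intercept up to full cubic), and
  optional behavioral-group intercept/interaction contrasts — fitted by
  maximum likelihood so BIC comparisons across fixed-effect structures
  are coherent;
* a two-stage estimator of the nonlinear asymptotic mixed model:
  per-person bounded nonlinear least squares, then precision-weighted
  pooling of the person-level estimates with a moment estimator of the
  between-person covariance (full-likelihood nonlinear mixed models for
  this curve are notoriously fragile; the two-stage route is
  deterministic and its components are individually testable).

Time is rescaled to [0, 1.72] before linear mixed modelling, which
improves optimizer conditioning; the rescaling is affine, so fitted
values are invariant and coefficients map back exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM

from .fitting import _fit_asymptotic

__all__ = [
    "TIME_SCALE_MAX",
    "MultilevelResult",
    "rescale_time",
    "fit_constant_icc",
    "fit_cubic_mlm",
    "fit_asymptotic_mlm",
    "compare_models",
]

TIME_SCALE_MAX = 1.72
_RANDOM_LADDER = ("intercept", "linear", "quadratic", "cubic")


@dataclass
class MultilevelResult:
    """Fitted group-level model summary."""

    name: str
    fixed_effects: pd.DataFrame  # index: term; columns: estimate, se, ci_low, ci_high
    random_cov: np.ndarray
    residual_var: float
    bic: float
    n_obs: int
    n_participants: int
    converged: bool
    icc: float | None = None
    group_effects: pd.DataFrame | None = None
    diagnostics: dict = field(default_factory=dict)


def rescale_time(t: np.ndarray, *, t_max: float, scale_max: float = TIME_SCALE_MAX) -> np.ndarray:
    """Affine map of occasions [0, t_max] onto [0, scale_max]."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    return np.asarray(t, dtype=float) * (scale_max / t_max)


def _check_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    required = {"participant_id", "t", "y"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    out = cohort.dropna(subset=["y"]).copy()
    out["t"] = out["t"].astype(float)
    return out


def _mlm_bic(result, n_vc: int) -> float:
    """ML BIC with fixed + variance-component + residual parameters."""
    k = result.k_fe + n_vc + 1
    return float(-2.0 * result.llf + k * math.log(result.nobs))


def fit_constant_icc(cohort: pd.DataFrame) -> MultilevelResult:
    """Random-intercept-only model and its intraclass correlation.

    ICC = sigma2_between / (sigma2_between + sigma2_within), estimated
    by maximum likelihood. Degenerate inputs are handled analytically:
    zero within-person variance with between-person spread gives
    ICC = 1 (with a warning); no between-person spread gives ICC = 0
    (flagged).
    """
    data = _check_cohort(cohort)
    sizes = data.groupby("participant_id")["y"].size()
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValueError("ICC requires >= 2 participants with >= 2 occasions each")

    within_var = float(data.groupby("participant_id")["y"].var(ddof=1).mean())
    between_var = float(data.groupby("participant_id")["y"].mean().var(ddof=1))
    diagnostics: dict = {}
    if within_var < 1e-12:
        icc = 1.0 if between_var > 1e-12 else 0.0
        warnings.warn(
            f"degenerate cohort (within-person variance ~ 0); ICC set to {icc}",
            stacklevel=2,
        )
        diagnostics["degenerate"] = True
        fixed = pd.DataFrame(
            {"estimate": [float(data["y"].mean())], "se": [math.nan],
             "ci_low": [math.nan], "ci_high": [math.nan]},
            index=["Intercept"],
        )
        return MultilevelResult(
            name="constant",
            fixed_effects=fixed,
            random_cov=np.array([[between_var]]),
            residual_var=within_var,
            bic=math.nan,
            n_obs=len(data),
            n_participants=len(sizes),
            converged=True,
            icc=icc,
            diagnostics=diagnostics,
        )

    exog = np.ones((len(data), 1))
    model = MixedLM(data["y"].to_numpy(), exog, groups=data["participant_id"].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=False)
    sigma_b = float(np.asarray(result.cov_re)[0, 0])
    sigma_w = float(result.scale)
    icc = sigma_b / (sigma_b + sigma_w)
    if sigma_b < 1e-10:
        diagnostics["zero_between_variance"] = True
    est = float(result.fe_params[0])
    se = float(result.bse_fe[0])
    fixed = pd.DataFrame(
        {"estimate": [est], "se": [se],
         "ci_low": [est - 1.96 * se], "ci_high": [est + 1.96 * se]},
        index=["Intercept"],
    )
    return MultilevelResult(
        name="constant",
        fixed_effects=fixed,
        random_cov=np.array([[sigma_b]]),
        residual_var=sigma_w,
        bic=_mlm_bic(result, n_vc=1),
        n_obs=int(result.nobs),
        n_participants=len(sizes),
        converged=bool(result.converged),
        icc=icc,
        diagnostics=diagnostics,
    )


def _design(tp: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(tp, degree + 1, increasing=True)


def fit_cubic_mlm(
    cohort: pd.DataFrame,
    *,
    random_spec: str = "cubic",
    focal_group: str | None = None,
    group_interactions: bool = False,
    scale_max: float = TIME_SCALE_MAX,
) -> MultilevelResult:
    """Linear mixed model with fixed cubic polynomial in rescaled time.

    ``random_spec`` selects the random-effect structure from the
    iterative ladder: ``intercept``, ``linear``, ``quadratic`` or
    ``cubic`` (random polynomial terms up to that order). With
    ``focal_group`` set, a 0/1 dummy for that group is added as a main
    effect (and, with ``group_interactions``, its products with the
    three time terms), contrasting the focal group against the combined
    average of the others. Estimated by ML. A singular random-effects
    covariance is flagged in diagnostics but the model is retained.
    """
    if random_spec not in _RANDOM_LADDER:
        raise ValueError(f"random_spec must be one of {_RANDOM_LADDER}")
    data = _check_cohort(cohort)
    t_max = float(data["t"].max())
    tp = rescale_time(data["t"].to_numpy(), t_max=t_max, scale_max=scale_max)

    fixed_terms = ["Intercept", "t", "t2", "t3"]
    X = _design(tp, 3)
    if focal_group is not None:
        if "group" not in data.columns:
            raise ValueError("cohort table needs a 'group' column for group contrasts")
        dummy = (data["group"].to_numpy() == focal_group).astype(float)
        X = np.column_stack([X, dummy])
        fixed_terms.append(f"group[{focal_group}]")
        if group_interactions:
            for j, nm in enumerate(("t", "t2", "t3"), start=1):
                X = np.column_stack([X, dummy * tp**j])
                fixed_terms.append(f"group[{focal_group}]:{nm}")

    re_degree = _RANDOM_LADDER.index(random_spec)
    exog_re = _design(tp, re_degree)

    model = MixedLM(
        data["y"].to_numpy(), X, groups=data["participant_id"].to_numpy(),
        exog_re=exog_re,
    )
    diagnostics: dict = {}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        result = model.fit(reml=False)
    messages = [str(w.message) for w in caught]
    if any("singular" in m.lower() for m in messages):
        diagnostics["singular_random_cov"] = True
    if not result.converged:
        diagnostics["not_converged"] = True

    est = np.asarray(result.fe_params, dtype=float)
    se = np.asarray(result.bse_fe, dtype=float)
    fixed = pd.DataFrame(
        {"estimate": est, "se": se,
         "ci_low": est - 1.96 * se, "ci_high": est + 1.96 * se},
        index=fixed_terms,
    )
    group_effects = None
    if focal_group is not None:
        group_effects = fixed.loc[[t for t in fixed_terms if t.startswith("group[")]]
    q = re_degree + 1
    n_vc = q * (q + 1) // 2
    return MultilevelResult(
        name=f"cubic(random={random_spec}"
        + (f", group={focal_group}{'+ix' if group_interactions else ''}" if focal_group else "")
        + ")",
        fixed_effects=fixed,
        random_cov=np.asarray(result.cov_re, dtype=float),
        residual_var=float(result.scale),
        bic=_mlm_bic(result, n_vc=n_vc),
        n_obs=int(result.nobs),
        n_participants=int(data["participant_id"].nunique()),
        converged=bool(result.converged),
        group_effects=group_effects,
        diagnostics=diagnostics,
    )


def _asymptotic_jacobian(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    a, r0, lam = theta
    rate = math.exp(lam)
    decay = np.exp(-rate * t)
    return np.column_stack([1.0 - decay, decay, -(r0 - a) * t * decay * rate])


def fit_asymptotic_mlm(cohort: pd.DataFrame, *, max_failure_rate: float = 0.5) -> MultilevelResult:
    """Two-stage asymptotic mixed model.

    Stage 1 fits the asymptotic curve (A_i, R0_i, lam_i) per participant
    by bounded nonlinear least squares; each estimate carries a sampling
    covariance from the fit's Jacobian. Stage 2 pools: the between-person
    covariance is a moment estimator (sample covariance of the stage-1
    estimates minus their mean sampling covariance, floored at zero by
    eigenvalue clipping), and fixed effects are precision-weighted means
    with weights 1 / (sampling variance + between-person variance).

    The reported BIC is a conditional pseudo-BIC computed from stage-1
    residuals (penalty: 3 fixed effects + 6 covariance terms + 1
    residual variance); it is *not* comparable with the marginal BICs of
    the linear mixed models. Declared non-estimable when more than
    ``max_failure_rate`` of stage-1 fits fail.
    """
    data = _check_cohort(cohort)
    thetas, covs, sses, ns = [], [], [], []
    n_fail = 0
    n_total = 0
    for _, sub in data.groupby("participant_id", sort=True):
        n_total += 1
        t = sub["t"].to_numpy(dtype=float)
        y = sub["y"].to_numpy(dtype=float)
        if len(y) < 5:
            n_fail += 1
            continue
        theta, sse, ok = _fit_asymptotic(t, y)
        if not ok:
            n_fail += 1
            continue
        dof = max(len(y) - 3, 1)
        sigma2 = max(sse / dof, 1e-10)
        J = _asymptotic_jacobian(theta, t)
        cov = sigma2 * np.linalg.pinv(J.T @ J)
        thetas.append(theta)
        covs.append(cov)
        sses.append(sse)
        ns.append(len(y))
    failure_rate = n_fail / max(n_total, 1)
    if failure_rate > max_failure_rate:
        raise RuntimeError(
            f"asymptotic mixed model non-estimable: {n_fail}/{n_total} "
            "person-level fits failed"
        )

    theta_mat = np.vstack(thetas)
    mean_cov = np.mean(np.stack(covs), axis=0)
    sample_cov = np.cov(theta_mat, rowvar=False, ddof=1)
    D = sample_cov - mean_cov
    # floor at PSD: clip negative eigenvalues to zero
    evals, evecs = np.linalg.eigh(D)
    D = (evecs * np.clip(evals, 0.0, None)) @ evecs.T

    tau2 = np.diag(D)
    est = np.empty(3)
    se = np.empty(3)
    for j in range(3):
        var_j = np.array([c[j, j] for c in covs]) + tau2[j]
        w = 1.0 / np.maximum(var_j, 1e-12)
        est[j] = float(np.sum(w * theta_mat[:, j]) / np.sum(w))
        se[j] = float(math.sqrt(1.0 / np.sum(w)))
    fixed = pd.DataFrame(
        {"estimate": est, "se": se,
         "ci_low": est - 1.96 * se, "ci_high": est + 1.96 * se},
        index=["A", "R0", "lam"],
    )
    sigma2_resid = float(np.sum(sses) / max(np.sum(ns) - 3 * len(ns), 1))
    n_obs = int(np.sum(ns))
    loglik = -0.5 * n_obs * (math.log(2.0 * math.pi * sigma2_resid) + 1.0)
    pseudo_bic = float(-2.0 * loglik + (3 + 6 + 1) * math.log(n_obs))
    return MultilevelResult(
        name="asymptotic(two-stage)",
        fixed_effects=fixed,
        random_cov=D,
        residual_var=sigma2_resid,
        bic=pseudo_bic,
        n_obs=n_obs,
        n_participants=n_total,
        converged=True,
        diagnostics={
            "stage1_failure_rate": failure_rate,
            "bic_kind": "two_stage_pseudo",
        },
    )


def compare_models(results: list[MultilevelResult]) -> pd.DataFrame:
    """BIC-ranked ladder table (stable sort; input order breaks ties)."""
    frame = pd.DataFrame(
        {
            "name": [r.name for r in results],
            "bic": [r.bic for r in results],
            "converged": [r.converged for r in results],
            "n_obs": [r.n_obs for r in results],
        }
    )
    return frame.sort_values("bic", kind="stable").reset_index(drop=True)
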