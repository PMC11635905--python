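import math

import numpy as np
import pandas as pd
import pytest

from habitdecay.multilevel import (
    TIME_SCALE_MAX,
    compare_models,
    fit_asymptotic_mlm,
    fit_constant_icc,
    fit_cubic_mlm,
    rescale_time,
)


def intercept_cohort(seed, n=60, t_obs=40, sigma_b=3.0, sigma_w=1.0):
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, math.sqrt(sigma_b), n)
    y = (2.0 + b[:, None] + rng.normal(0, math.sqrt(sigma_w), (n, t_obs))).ravel()
    return pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(n), t_obs),
            "t": np.tile(np.arange(t_obs, dtype=float), n),
            "y": y,
        }
    )


def cubic_cohort(seed, n=80, t_obs=84, shift=0.0, sigma_b=0.36, sigma_w=0.16):
    rng = np.random.default_rng(seed)
    tp = np.arange(t_obs) / (t_obs - 1) * TIME_SCALE_MAX
    fe = 2.8 - 1.2 * tp + 0.5 * tp**2 - 0.12 * tp**3
    b = rng.normal(0, math.sqrt(sigma_b), n)
    grp = np.array(["SB"] * (n // 4) + ["US"] * (n - n // 4))
    y = (
        fe[None, :]
        + b[:, None]
        + (grp == "SB")[:, None] * shift
        + rng.normal(0, math.sqrt(sigma_w), (n, t_obs))
    ).ravel()
    return pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(n), t_obs),
            "group": np.repeat(grp, t_obs),
            "t": np.tile(np.arange(t_obs, dtype=float), n),
            "y": y,
        }
    )


def test_icc_recovers_variance_ratio():
    res = fit_constant_icc(intercept_cohort(0, n=150, t_obs=60))
    assert res.icc == pytest.approx(0.75, abs=0.05)
    assert res.converged and math.isfinite(res.bic)


def test_icc_degenerate_identical_series_flagged_zero():
    frame = pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(5), 10),
            "t": np.tile(np.arange(10.0), 5),
            "y": 2.0,
        }
    )
    with pytest.warns(UserWarning, match="degenerate"):
        res = fit_constant_icc(frame)
    assert res.icc == 0.0


def test_icc_degenerate_no_within_noise_is_one():
    frame = pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(5), 10),
            "t": np.tile(np.arange(10.0), 5),
            "y": np.repeat([1.0, 1.5, 2.0, 2.5, 3.0], 10),
        }
    )
    with pytest.warns(UserWarning, match="degenerate"):
        res = fit_constant_icc(frame)
    assert res.icc == 1.0


def test_icc_requires_replication():
    frame = pd.DataFrame({"participant_id": [1, 1, 1], "t": [0.0, 1, 2], "y": [1.0, 2, 3]})
    with pytest.raises(ValueError, match=">= 2 participants"):
        fit_constant_icc(frame)


def test_cubic_mlm_recovers_fixed_effects_within_2se():
    res = fit_cubic_mlm(cubic_cohort(1), random_spec="intercept")
    truth = {"Intercept": 2.8, "t": -1.2, "t2": 0.5, "t3": -0.12}
    for term, value in truth.items():
        row = res.fixed_effects.loc[term]
        assert abs(row["estimate"] - value) < 2 * row["se"] + 1e-9


def test_cubic_mlm_group_intercept_shift_recovered():
    res = fit_cubic_mlm(
        cubic_cohort(2, shift=0.8), random_spec="intercept", focal_group="SB"
    )
    eff = res.group_effects.loc["group[SB]"]
    assert abs(eff["estimate"] - 0.8) < 2 * eff["se"]
    with_ix = fit_cubic_mlm(
        cubic_cohort(2, shift=0.8),
        random_spec="intercept",
        focal_group="SB",
        group_interactions=True,
    )
    assert "group[SB]:t3" in with_ix.fixed_effects.index


def test_zero_noise_no_random_effects_equals_pooled_ols():
    frame = cubic_cohort(3, n=20, sigma_b=0.0, sigma_w=1e-12)
    res = fit_cubic_mlm(frame, random_spec="intercept")
    tp = rescale_time(frame["t"].to_numpy(), t_max=float(frame["t"].max()))
    X = np.vander(tp, 4, increasing=True)
    beta = np.linalg.lstsq(X, frame["y"].to_numpy(), rcond=None)[0]
    np.testing.assert_allclose(res.fixed_effects["estimate"].to_numpy()[:4], beta, atol=1e-5)


def test_time_rescaling_leaves_fitted_values_invariant():
    frame = cubic_cohort(4, n=30)
    res_a = fit_cubic_mlm(frame, random_spec="intercept", scale_max=TIME_SCALE_MAX)
    res_b = fit_cubic_mlm(frame, random_spec="intercept", scale_max=1.0)
    t_max = float(frame["t"].max())
    grid_a = rescale_time(np.arange(0, 84.0, 7), t_max=t_max, scale_max=TIME_SCALE_MAX)
    grid_b = rescale_time(np.arange(0, 84.0, 7), t_max=t_max, scale_max=1.0)
    fitted_a = np.vander(grid_a, 4, increasing=True) @ res_a.fixed_effects["estimate"].to_numpy()[:4]
    fitted_b = np.vander(grid_b, 4, increasing=True) @ res_b.fixed_effects["estimate"].to_numpy()[:4]
    np.testing.assert_allclose(fitted_a, fitted_b, atol=1e-6)
    # coefficients themselves differ (they absorb the affine map)
    assert not np.allclose(
        res_a.fixed_effects["estimate"].to_numpy(), res_b.fixed_effects["estimate"].to_numpy()
    )


def asymptotic_cohort(seed, n=60, t_obs=84, sd=(0.2, 0.3, 0.25), noise=0.3):
    rng = np.random.default_rng(seed)
    t = np.arange(t_obs, dtype=float)
    A = rng.normal(1.0, sd[0], n)
    R0 = rng.normal(3.2, sd[1], n)
    lam = rng.normal(math.log(0.08), sd[2], n)
    rows = []
    for i in range(n):
        y = A[i] + (R0[i] - A[i]) * np.exp(-np.exp(lam[i]) * t)
        y = y + rng.normal(0, noise, t_obs)
        rows.append(pd.DataFrame({"participant_id": i, "t": t, "y": y}))
    return pd.concat(rows, ignore_index=True)


def test_two_stage_asymptotic_recovers_fixed_effects():
    res = fit_asymptotic_mlm(asymptotic_cohort(5, n=80))
    truth = {"A": 1.0, "R0": 3.2, "lam": math.log(0.08)}
    for term, value in truth.items():
        row = res.fixed_effects.loc[term]
        assert abs(row["estimate"] - value) < max(2 * row["se"], 0.05)
    assert res.diagnostics["stage1_failure_rate"] == 0.0
    # random-effect covariance is PSD by construction
    assert np.linalg.eigvalsh(res.random_cov).min() >= -1e-12


def test_two_stage_no_between_variance_floors_at_zero():
    res = fit_asymptotic_mlm(asymptotic_cohort(6, n=40, sd=(0.0, 0.0, 0.0), noise=0.05))
    assert np.all(np.diag(res.random_cov) < 0.01)


def test_two_stage_population_curve_decreasing():
    res = fit_asymptotic_mlm(asymptotic_cohort(7, n=30))
    a, r0 = res.fixed_effects.loc["A", "estimate"], res.fixed_effects.loc["R0", "estimate"]
    assert r0 > a


def test_two_stage_declares_non_estimable_on_mass_failure():
    # two observations per participant: far too few for a 3-parameter curve
    frame = pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(10), 2),
            "t": np.tile([0.0, 1.0], 10),
            "y": np.tile([3.0, 2.9], 10),
        }
    )
    with pytest.raises(RuntimeError, match="non-estimable"):
        fit_asymptotic_mlm(frame)


def test_compare_models_ranks_by_bic_stably():
    r1 = fit_constant_icc(intercept_cohort(8, n=20, t_obs=10))
    r2 = fit_cubic_mlm(intercept_cohort(8, n=20, t_obs=10), random_spec="intercept")
    ladder = compare_models([r1, r2])
    assert list(ladder["bic"]) == sorted(ladder["bic"])
    same = compare_models([r1, r1])
    assert list(same["name"]) == [r1.name, r1.name]


def test_random_slope_ladder_does_not_beat_truth_on_intercept_data():
    frame = cubic_cohort(9, n=60)
    res_int = fit_cubic_mlm(frame, random_spec="intercept")
    res_lin = fit_cubic_mlm(frame, random_spec="linear")
    assert res_int.bic <= res_lin.bic


def test_rescale_time_affine_and_order_preserving():
    t = np.array([0.0, 41.5, 83.0])
    tp = rescale_time(t, t_max=83.0)
    assert tp[0] == 0.0 and tp[-1] == pytest.approx(1.72)
    assert np.all(np.diff(tp) > 0)
    with pytest.raises(ValueError):
        rescale_time(t, t_max=0.0)
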