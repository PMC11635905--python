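"""End-to-end pipeline: simulate/load -> preprocess -> fit -> validate
-> stabilize -> multilevel -> report.

Every stage writes a tidy CSV into the output directory; the final
report is a machine-readable ``summary.json`` plus per-participant
plot-data (observed points, fitted curves, stabilization markers) as
CSV, so figures can be redrawn anywhere. A run is fully reproducible
from its config and seed, both echoed into ``run_metadata.json``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .families import FAMILY_ORDER
from .fitting import fit_all_families
from .multilevel import (
    compare_models,
    fit_asymptotic_mlm,
    fit_constant_icc,
    fit_cubic_mlm,
)
from .preprocess import MIDPOINT_OCCASION, MIN_MEASUREMENTS, preprocess
from .selection import GAP_CUTOFF, RMSE_CUTOFF, classify, verdicts_frame
from .series import DiarySeries
from .stabilization import (
    midpoint_crossing,
    summarize_stabilization,
    time_to_95_asymptote,
    time_to_window_stability,
)
from .synthetic import CohortConfig, simulate_cohort

__all__ = ["RunConfig", "run_pipeline", "make_summary_tables", "load_config"]

logger = logging.getLogger("habitdecay")

STAGES = ("simulate", "preprocess", "fit", "select", "stabilize", "multilevel", "report")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_path: str | None = None  # raw diary CSV; None -> simulate
    output_dir: str = "habitdecay_out"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    n_per_group: dict[str, int] | None = None  # simulate-stage override
    n_days: int = 84
    day_offset: int = 8
    start_date: str = "2023-01-01"
    min_measurements: int = MIN_MEASUREMENTS
    midpoint_occasion: int = MIDPOINT_OCCASION
    rmse_cutoff: float = RMSE_CUTOFF
    gap_cutoff: int = GAP_CUTOFF
    window_threshold: float = 0.1
    window_threshold_alt: float = 0.01
    midpoint: float = 2.0
    run_loo: bool = True
    loo_min_agreement: float = 1.0

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s) {unknown}; valid: {STAGES}")
        for name in ("rmse_cutoff", "window_threshold", "window_threshold_alt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.gap_cutoff < 1:
            raise ValueError("gap_cutoff must be >= 1")


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML or JSON; unknown keys are rejected."""
    text = Path(path).read_text()
    payload = yaml.safe_load(text)
    if not isinstance(payload, dict):
        raise ValueError("config file must contain a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "stages" in payload:
        payload["stages"] = tuple(payload["stages"])
    cfg = RunConfig(**payload)
    cfg.validate()
    return cfg


def _cohort_frame(series_list: list[DiarySeries]) -> pd.DataFrame:
    """Long-format (participant_id, group, t, y) table of usable values."""
    rows = []
    for s in series_list:
        t = np.flatnonzero(s.present)
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": s.participant_id,
                    "group": s.group,
                    "t": t.astype(float),
                    "y": s.values[t],
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["participant_id", "group", "t", "y"])
    return pd.concat(rows, ignore_index=True)


def _fit_stage(series_list: list[DiarySeries]) -> tuple[dict, pd.DataFrame]:
    all_fits = {}
    rows = []
    for s in series_list:
        fits = fit_all_families(s)
        all_fits[s.participant_id] = fits
        for name in FAMILY_ORDER:
            f = fits[name]
            row = {
                "participant_id": s.participant_id,
                "group": s.group,
                "family": name,
                "n_obs": f.n_obs,
                "sse": f.sse,
                "rmse": f.rmse if f.converged else np.nan,
                "bic": f.bic if f.converged else np.nan,
                "converged": f.converged,
            }
            for j in range(4):
                row[f"theta_{j + 1}"] = f.theta[j] if j < len(f.theta) else np.nan
            rows.append(row)
    return all_fits, pd.DataFrame(rows)


def _stabilize_stage(
    series_list: list[DiarySeries],
    all_fits: dict,
    verdicts: pd.DataFrame,
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    by_id = {s.participant_id: s for s in series_list}
    est_rows = []
    estimates = []
    for _, v in verdicts.iterrows():
        pid = v["participant_id"]
        series = by_id[pid]
        fit = all_fits[pid][v["best_family"]]
        stab_day = None
        curve_method = False
        records = []
        if v["best_family"] in ("asymptotic", "logistic") and v["overall_valid"]:
            est = time_to_95_asymptote(fit, series)
            records.append(est)
            stab_day = est.day
            curve_method = True
        # 7-day window criterion: primary for the polynomial families,
        # emitted for all families for comparison (both thresholds)
        est = time_to_window_stability(fit, series, threshold=config.window_threshold)
        records.append(est)
        if not curve_method:
            stab_day = est.day
        alt = time_to_window_stability(
            fit, series, threshold=config.window_threshold_alt
        )
        alt = dataclasses.replace(alt, method="window7_alt")
        records.append(alt)
        mid = midpoint_crossing(
            fit, series, midpoint=config.midpoint, stabilization_day=stab_day
        )
        records.append(mid)
        estimates.extend(records)
        for e in records:
            est_rows.append(
                {
                    "participant_id": e.participant_id,
                    "group": series.group,
                    "method": e.method,
                    "family": e.family,
                    "day": e.day,
                    "within_window": e.within_window,
                    "midpoint_crossed_before_stabilization":
                        e.midpoint_crossed_before_stabilization,
                }
            )
    est_frame = pd.DataFrame(
        est_rows,
        columns=[
            "participant_id", "group", "method", "family", "day",
            "within_window", "midpoint_crossed_before_stabilization",
        ],
    )
    # Table-2 eligibility: overall-valid fits whose predictions cross the midpoint
    crossed = set(
        est_frame.loc[
            (est_frame["method"] == "midpoint_cross") & est_frame["within_window"],
            "participant_id",
        ]
    )
    valid_ids = set(verdicts.loc[verdicts["overall_valid"], "participant_id"])
    summary = summarize_stabilization(
        [e for e in estimates if e.method != "window7_alt"],
        eligible_ids=valid_ids & crossed,
    )
    return est_frame, summary


def _multilevel_stage(series_list: list[DiarySeries], config: RunConfig) -> dict:
    cohort = _cohort_frame(series_list)
    out: dict = {}
    results = []
    icc_res = fit_constant_icc(cohort)
    out["icc"] = icc_res.icc
    results.append(icc_res)
    for spec in ("intercept", "linear", "quadratic", "cubic"):
        try:
            results.append(fit_cubic_mlm(cohort, random_spec=spec))
        except Exception as exc:  # singular fits on tiny cohorts
            logger.warning("cubic MLM (random=%s) failed: %s", spec, exc)
    try:
        results.append(fit_asymptotic_mlm(cohort))
    except RuntimeError as exc:
        logger.warning("asymptotic two-stage model non-estimable: %s", exc)
    group_effects = {}
    for grp in sorted(cohort["group"].unique()):
        try:
            res = fit_cubic_mlm(cohort, random_spec="intercept", focal_group=grp)
            eff = res.group_effects.iloc[0]
            group_effects[grp] = {
                "estimate": float(eff["estimate"]),
                "ci_low": float(eff["ci_low"]),
                "ci_high": float(eff["ci_high"]),
            }
        except Exception as exc:
            logger.warning("group contrast for %s failed: %s", grp, exc)
    out["group_intercept_effects"] = group_effects
    ladder = compare_models(results)
    out["ladder"] = ladder
    out["results"] = results
    return out


def _plot_data(series_list: list[DiarySeries], all_fits: dict, verdicts: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-participant curves and points behind trajectory panels."""
    best = dict(zip(verdicts["participant_id"], verdicts["best_family"]))
    rows = []
    for s in series_list:
        fam = best.get(s.participant_id)
        if fam is None:
            continue
        fit = all_fits[s.participant_id][fam]
        t_obs = np.flatnonzero(s.present)
        t_grid = np.arange(s.t_first, s.t_last + 1)
        fitted = fit.predict(t_grid.astype(float))
        for t, y in zip(t_obs, s.values[t_obs]):
            rows.append(
                {"participant_id": s.participant_id, "kind": "observed",
                 "t": int(t), "value": float(y), "family": fam}
            )
        for t, y in zip(t_grid, fitted):
            rows.append(
                {"participant_id": s.participant_id, "kind": "fitted",
                 "t": int(t), "value": float(y), "family": fam}
            )
    return pd.DataFrame(rows, columns=["participant_id", "kind", "t", "value", "family"])


def make_summary_tables(
    verdicts: pd.DataFrame,
    series_list: list[DiarySeries],
    stab_summary: pd.DataFrame,
    profile: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Report tables: best-family frequencies (overall and by group),
    valid counts per family, the stabilization summary and the
    missingness profile."""
    groups = {s.participant_id: s.group for s in series_list}
    v = verdicts.copy()
    v["group"] = v["participant_id"].map(groups)
    freq = (
        v.groupby("best_family").size().reindex(FAMILY_ORDER, fill_value=0)
        .rename("n").reset_index().rename(columns={"best_family": "family"})
    )
    freq["pct"] = 100.0 * freq["n"] / max(len(v), 1)
    by_group = (
        v.groupby(["group", "best_family"]).size().rename("n").reset_index()
        .rename(columns={"best_family": "family"})
    )
    stable_ok = v["stable_habit_valid"].map(lambda x: bool(x) if pd.notna(x) else False)
    valid = (
        v.assign(valid=v["overall_valid"] | stable_ok)
        .groupby("best_family")["valid"].sum().reindex(FAMILY_ORDER, fill_value=0)
        .rename("n_valid").reset_index().rename(columns={"best_family": "family"})
    )
    return {
        "best_family_freq": freq,
        "best_family_by_group": by_group,
        "valid_counts": valid,
        "stabilization_summary": stab_summary,
        "missingness_profile": profile,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the summary dict.

    Writes per-stage CSVs, ``summary.json`` and ``run_metadata.json``
    into ``config.output_dir``. On a stage failure the exception is
    re-raised after logging the stage name; partial outputs written by
    earlier stages are preserved.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    summary: dict = {"seed": config.seed, "stages": sorted(stages)}
    metadata = {
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }
    (out_dir / "run_metadata.json").write_text(json.dumps(metadata, indent=2, sort_keys=True))

    stage = "simulate"
    try:
        if config.input_path is not None:
            raw = pd.read_csv(config.input_path)
        elif "simulate" in stages:
            logger.info("stage: simulate")
            sim_cfg = CohortConfig(seed=config.seed, n_days=config.n_days,
                                   day_offset=config.day_offset,
                                   start_date=date.fromisoformat(config.start_date))
            if config.n_per_group is not None:
                sim_cfg = dataclasses.replace(sim_cfg, n_per_group=dict(config.n_per_group))
            raw, truth = simulate_cohort(sim_cfg)
            raw.to_csv(out_dir / "simulated_raw.csv", index=False)
            truth.to_csv(out_dir / "simulated_truth.csv", index=False)
        else:
            raise ValueError("no input_path and simulate stage disabled")

        stage = "preprocess"
        logger.info("stage: preprocess")
        retained, exclusions, profile = preprocess(
            raw,
            start_date=date.fromisoformat(config.start_date),
            n_days=config.n_days,
            day_offset=config.day_offset,
            min_measurements=config.min_measurements,
            midpoint_occasion=config.midpoint_occasion,
        )
        exclusions.to_csv(out_dir / "exclusions.csv", index=False)
        profile.to_csv(out_dir / "missingness_profile.csv", index=False)
        summary["n_retained"] = len(retained)
        summary["n_excluded"] = len(exclusions)
        if len(profile):
            overall = profile.iloc[-1]
            summary["missing_pct"] = round(
                100.0 * overall["missing_pre_imputation"] / overall["n_days"], 2
            )
            summary["n_imputed"] = int(overall["imputed"])

        if "fit" not in stages:
            _write_summary(out_dir, summary)
            return summary
        stage = "fit"
        logger.info("stage: fit (%d participants x 6 families)", len(retained))
        all_fits, fits_frame = _fit_stage(retained)
        fits_frame.to_csv(out_dir / "fits.csv", index=False)

        if "select" not in stages:
            _write_summary(out_dir, summary)
            return summary
        stage = "select"
        logger.info("stage: select/validate (LOO=%s)", config.run_loo)
        verdicts = verdicts_frame(
            [
                classify(
                    s, all_fits[s.participant_id],
                    rmse_cutoff=config.rmse_cutoff,
                    gap_cutoff=config.gap_cutoff,
                    loo_min_agreement=config.loo_min_agreement,
                    run_loo=config.run_loo,
                )
                for s in retained
            ]
        )
        verdicts.to_csv(out_dir / "verdicts.csv", index=False)
        counts = verdicts.groupby("best_family").size()
        summary["best_family_counts"] = {
            f: int(counts.get(f, 0)) for f in FAMILY_ORDER
        }
        summary["n_overall_valid"] = int(verdicts["overall_valid"].sum())
        summary["n_stable_habit_valid"] = int(
            verdicts["stable_habit_valid"]
            .map(lambda x: bool(x) if pd.notna(x) else False)
            .sum()
        )

        stab_summary = pd.DataFrame()
        if "stabilize" in stages:
            stage = "stabilize"
            logger.info("stage: stabilize")
            estimates, stab_summary = _stabilize_stage(
                retained, all_fits, verdicts, config
            )
            estimates.to_csv(out_dir / "stabilization_estimates.csv", index=False)
            stab_summary.to_csv(out_dir / "stabilization_summary.csv", index=False)
            summary["stabilization"] = {
                f"{r.method}/{r.family}": {
                    "n": int(r.n),
                    "median": None if pd.isna(r.median) else float(r.median),
                    "min": None if pd.isna(r.min) else float(r.min),
                    "max": None if pd.isna(r.max) else float(r.max),
                }
                for r in stab_summary.itertuples()
            }

        if "multilevel" in stages:
            stage = "multilevel"
            logger.info("stage: multilevel")
            ml = _multilevel_stage(retained, config)
            ml["ladder"].to_csv(out_dir / "mlm_ladder.csv", index=False)
            for res in ml["results"]:
                slug = res.name.replace("(", "_").replace(")", "").replace(
                    "=", "-").replace(", ", "_").replace("+", "")
                res.fixed_effects.to_csv(out_dir / f"mlm_{slug}.csv")
            summary["multilevel"] = {
                "icc": None if ml["icc"] is None else round(float(ml["icc"]), 4),
                "group_intercept_effects": ml["group_intercept_effects"],
                "ladder": [
                    {"name": r.name, "bic": None if pd.isna(r.bic) else round(float(r.bic), 2)}
                    for r in ml["ladder"].itertuples()
                ],
            }

        if "report" in stages:
            stage = "report"
            logger.info("stage: report")
            tables = make_summary_tables(verdicts, retained, stab_summary, profile)
            for name, frame in tables.items():
                frame.to_csv(out_dir / f"table_{name}.csv", index=False)
            plot = _plot_data(retained, all_fits, verdicts)
            plot.to_csv(out_dir / "plot_data.csv", index=False)
    except Exception:
        logger.exception("pipeline failed in stage %r", stage)
        summary["failed_stage"] = stage
        _write_summary(out_dir, summary)
        raise

    _write_summary(out_dir, summary)
    return summary


def _write_summary(out_dir: Path, summary: dict) -> None:
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
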