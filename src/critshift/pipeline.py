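"""End-to-end analysis: psychometric tables, per-cell estimation, exclusions.

The pipeline consumes a trial-level table in the shared CSV schema and
produces tidy per-participant and group-level tables:

* shifted-mean experiment — d′ and criterion c per base-rate block ×
  contrast, the biased-block criterion shift D_criterion, the ideal-observer
  benchmark (β_opt, c_opt) and the sign-normalized deviation c_error per
  contrast, and mean gamble stakes per block;
* embedded experiment — fitted σ_sens and boundary k per contrast, the
  ideal boundary k_opt at the fitted noise, and the signed deviation
  k_error.

Outlier guards are applied in two stages.  Stage "all" removes participants
whose accuracy over the three highest contrasts (pooled across blocks) falls
below 0.6, and — in the embedded experiment — those with an extreme fitted
boundary (k > 100) or noise (σ_sens > 100) at any contrast.  Stage
"optimality" additionally removes extreme deviations from the ideal
observer (c_error > 50, or |k_error| > 35).  Every exclusion is reported
with the single rule (first in precedence order) and value that triggered
it, and retained + excluded always reconciles with the input.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .embedded import boundary_error, fit_embedded_counts, optimal_boundary
from .sdt import (
    count_responses,
    criterion_error,
    criterion_shift,
    estimate_dprime_criterion,
    optimal_beta,
    optimal_criterion,
)
from .tasks import EmbeddedCategoryTask2, validate_trials

__all__ = [
    "AnalysisConfig",
    "DEFAULT_BIN_CENTERS",
    "assign_bins",
    "bin_orientations",
    "apply_exclusions",
    "run_experiment1_analysis",
    "run_experiment2_analysis",
    "summarize_gamble",
    "write_tables",
]

#: Orientation bin centers (degrees from reference) for psychometric tables.
DEFAULT_BIN_CENTERS: tuple[float, ...] = tuple(float(x) for x in range(-14, 15, 2))

STAGES = ("all", "optimality")


@dataclass(frozen=True)
class AnalysisConfig:
    """Estimation and exclusion settings; defaults follow the study protocol."""

    correction: str = "loglinear"
    accuracy_threshold: float = 0.6
    n_top_contrasts: int = 3
    c_error_max: float = 50.0
    k_max: float = 100.0
    sigma_max: float = 100.0
    k_error_max: float = 35.0
    bin_centers: tuple[float, ...] = DEFAULT_BIN_CENTERS
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("accuracy_threshold", "c_error_max", "k_max", "sigma_max", "k_error_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        centers = tuple(float(x) for x in self.bin_centers)
        object.__setattr__(self, "bin_centers", centers)
        if list(centers) != sorted(centers):
            raise ValueError("bin_centers must be sorted ascending")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "bin_centers" in data:
            data["bin_centers"] = tuple(data["bin_centers"])
        return cls(**data)


# ---------------------------------------------------------------------------
# Psychometric tables


def assign_bins(orientations: np.ndarray, centers: tuple[float, ...]) -> np.ndarray:
    """Nearest-center bin assignment; ties go clockwise, out-of-range clamps."""
    centers_arr = np.asarray(centers, dtype=float)
    mids = 0.5 * (centers_arr[:-1] + centers_arr[1:])
    idx = np.searchsorted(mids, np.asarray(orientations, dtype=float), side="right")
    return centers_arr[idx]


def _participant_psychometric(
    trials: pd.DataFrame, centers: tuple[float, ...], condition: str
) -> pd.DataFrame:
    df = trials.copy()
    df["orientation_bin_center"] = assign_bins(df["orientation_deg"].to_numpy(), centers)
    df["_is_b"] = (df["response"] == "B").astype(float)
    out = (
        df.groupby(["participant_id", "group", condition, "orientation_bin_center"])
        .agg(p_report_B=("_is_b", "mean"), n=("_is_b", "size"))
        .reset_index()
    )
    return out


def bin_orientations(
    trials: pd.DataFrame,
    bin_centers: tuple[float, ...] = DEFAULT_BIN_CENTERS,
    condition: str = "block_alpha_B",
) -> pd.DataFrame:
    """Group-level psychometric table: P(report B) per condition × orientation bin.

    Proportions are computed per participant first and then averaged across
    participants (with across-participant SE), matching how group curves are
    usually displayed.  Empty input yields an empty table.
    """
    if len(trials) == 0:
        return pd.DataFrame(
            columns=["group", condition, "orientation_bin_center", "p_report_B", "se", "n"]
        )
    exps = trials["experiment"].unique()
    if len(exps) != 1:
        raise ValueError(f"trials mix experiments: {sorted(exps)}")
    per_pp = _participant_psychometric(trials, bin_centers, condition)
    grp = (
        per_pp.groupby(["group", condition, "orientation_bin_center"])
        .agg(
            p_report_B=("p_report_B", "mean"),
            se=("p_report_B", lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0),
            n=("n", "sum"),
            n_participants=("participant_id", "nunique"),
        )
        .reset_index()
    )
    return grp


# ---------------------------------------------------------------------------
# Exclusions


def _first_violation(row: pd.Series, rules: list[tuple[str, str, float, str]]):
    """rules: (rule_name, column, threshold, direction 'lt'|'gt')."""
    for name, col, thresh, direction in rules:
        if col not in row or pd.isna(row[col]):
            continue
        value = row[col]
        if (direction == "lt" and value < thresh) or (direction == "gt" and value > thresh):
            return name, float(value)
    return None


def apply_exclusions(
    summary: pd.DataFrame,
    config: AnalysisConfig,
    stage: str,
    experiment: int,
) -> tuple[list, pd.DataFrame]:
    """Apply the stage's outlier rules to a per-participant summary table.

    ``summary`` needs one row per participant with whichever of the columns
    ``accuracy_top3``, ``k_max``, ``sigma_max``, ``c_error_max``,
    ``k_error_abs_max`` the stage consults.  Returns the retained
    participant ids and a report with one row per participant (retained
    flag, triggering rule and value).
    """
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}; got {stage!r}")
    rules: list[tuple[str, str, float, str]] = [
        ("accuracy", "accuracy_top3", config.accuracy_threshold, "lt")
    ]
    if experiment == 2:
        rules += [
            ("extreme_k", "k_max", config.k_max, "gt"),
            ("extreme_sigma", "sigma_max", config.sigma_max, "gt"),
        ]
    if stage == "optimality":
        if experiment == 1:
            rules.append(("c_error", "c_error_max", config.c_error_max, "gt"))
        else:
            rules.append(("k_error", "k_error_abs_max", config.k_error_max, "gt"))

    rows = []
    for _, row in summary.iterrows():
        hit = _first_violation(row, rules)
        rows.append(
            {
                "participant_id": row["participant_id"],
                "stage": stage,
                "retained": hit is None,
                "rule": "" if hit is None else hit[0],
                "value": np.nan if hit is None else hit[1],
            }
        )
    report = pd.DataFrame(rows)
    retained = report.loc[report["retained"], "participant_id"].tolist()
    return retained, report


def _accuracy_summary(trials: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Mean accuracy over the n highest contrasts, pooled across blocks."""
    top = sorted(trials["contrast"].unique())[-config.n_top_contrasts :]
    sub = trials[trials["contrast"].isin(top)]
    acc = (
        (sub["response"] == sub["true_category"])
        .groupby(sub["participant_id"])
        .mean()
        .rename("accuracy_top3")
        .reset_index()
    )
    return acc


# ---------------------------------------------------------------------------
# Experiment 1


def run_experiment1_analysis(trials: pd.DataFrame, config: AnalysisConfig = AnalysisConfig()):
    """Full shifted-mean (base-rate) analysis chain.

    Returns a dict of tables: per-cell SDT estimates (``cells``),
    per-contrast optimality metrics (``by_contrast``), group summaries,
    psychometric and gamble tables, and the exclusion reports.
    """
    validate_trials(trials)
    trials = trials[trials["experiment"] == 1]
    if len(trials) == 0:
        raise ValueError("no experiment-1 trials in input")

    # Per-cell SDT estimates for every participant.
    cell_rows = []
    groups = trials.groupby("participant_id", sort=True)
    group_of = trials.drop_duplicates("participant_id").set_index("participant_id")["group"]
    for pid, sub in groups:
        for counts in count_responses(sub):
            est = estimate_dprime_criterion(counts, config.correction)
            _, alpha, contrast = counts.cell
            row = {
                "participant_id": pid,
                "group": group_of[pid],
                "block_alpha_B": alpha,
                "contrast": contrast,
                "n_trials": counts.n_trials,
                "hit_rate": est.hit_rate,
                "fa_rate": est.fa_rate,
                "d_prime": est.d_prime,
                "criterion_c": est.criterion_c,
            }
            if alpha != 0.5:
                row["beta_opt"] = optimal_beta(alpha)
                if est.d_prime != 0:
                    row["c_opt"] = optimal_criterion(row["beta_opt"], est.d_prime)
                    row["c_error"] = criterion_error(est.criterion_c, est.d_prime, alpha)
                else:  # unbounded ideal criterion; flagged by the c_error rule
                    row["c_opt"] = np.inf
                    row["c_error"] = np.inf
            else:
                row["beta_opt"] = 1.0
                row["c_opt"] = 0.0
                row["c_error"] = np.nan
            cell_rows.append(row)
    cells = pd.DataFrame(cell_rows)

    # Per-contrast derived metrics: D_criterion and mean biased-block c_error.
    by_rows = []
    for (pid, contrast), sub in cells.groupby(["participant_id", "contrast"]):
        sub = sub.set_index("block_alpha_B")
        row = {
            "participant_id": pid,
            "group": group_of[pid],
            "contrast": contrast,
            "d_prime": sub["d_prime"].mean(),
        }
        if 0.75 in sub.index and 0.25 in sub.index:
            row["d_criterion"] = criterion_shift(
                sub.loc[0.75, "criterion_c"], sub.loc[0.25, "criterion_c"]
            )
            row["c_error"] = sub.loc[[0.25, 0.75], "c_error"].mean()
        by_rows.append(row)
    by_contrast = pd.DataFrame(by_rows)

    # Exclusions.
    acc = _accuracy_summary(trials, config)
    retained_all, report_all = apply_exclusions(acc, config, "all", experiment=1)
    cerr_max = (
        by_contrast.groupby("participant_id")["c_error"].max().rename("c_error_max").reset_index()
    )
    opt_summary = acc.merge(cerr_max, on="participant_id", how="left")
    retained_opt, report_opt = apply_exclusions(opt_summary, config, "optimality", experiment=1)

    cells_r = cells[cells["participant_id"].isin(retained_all)]
    by_r = by_contrast[by_contrast["participant_id"].isin(retained_all)]
    by_opt = by_contrast[by_contrast["participant_id"].isin(retained_opt)]

    def _group_mean(df, value, by):
        return (
            df.groupby(by)[value]
            .agg(
                mean="mean",
                se=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0,
                n="size",
            )
            .reset_index()
        )

    tables = {
        "cells": cells.sort_values(["participant_id", "block_alpha_B", "contrast"]).reset_index(drop=True),
        "by_contrast": by_contrast.sort_values(["participant_id", "contrast"]).reset_index(drop=True),
        "psychometric": bin_orientations(
            trials[trials["participant_id"].isin(retained_all)], config.bin_centers
        ),
        "gamble": summarize_gamble(trials[trials["participant_id"].isin(retained_all)]),
        "exclusions": pd.concat([report_all, report_opt], ignore_index=True),
        "group_d_prime": _group_mean(by_r, "d_prime", ["group", "contrast"]),
        "group_criterion": _group_mean(cells_r, "criterion_c", ["group", "block_alpha_B", "contrast"]),
        "group_d_criterion": _group_mean(by_r.dropna(subset=["d_criterion"]), "d_criterion", ["group", "contrast"]),
        "group_c_error": _group_mean(
            by_opt.replace([np.inf, -np.inf], np.nan).dropna(subset=["c_error"]),
            "c_error",
            ["group", "contrast"],
        ),
    }
    tables["retained_all"] = retained_all
    tables["retained_optimality"] = retained_opt
    return tables


# ---------------------------------------------------------------------------
# Experiment 2


def run_experiment2_analysis(trials: pd.DataFrame, config: AnalysisConfig = AnalysisConfig()):
    """Full embedded-task analysis chain (σ_sens, k, k_opt, k_error)."""
    validate_trials(trials)
    trials = trials[trials["experiment"] == 2]
    if len(trials) == 0:
        raise ValueError("no experiment-2 trials in input")
    task = EmbeddedCategoryTask2()

    fit_rows = []
    group_of = trials.drop_duplicates("participant_id").set_index("participant_id")["group"]
    for (pid, contrast), sub in trials.groupby(["participant_id", "contrast"], sort=True):
        is_a = sub["true_category"].to_numpy() == "A"
        resp_a = sub["response"].to_numpy() == "A"
        n_a, n_b = int(is_a.sum()), int((~is_a).sum())
        if n_a == 0 or n_b == 0:
            continue
        fit = fit_embedded_counts(
            int((resp_a & is_a).sum()), n_a,
            int((resp_a & ~is_a).sum()), n_b,
            task=task, cell=(pid, float(contrast)),
        )
        opt = optimal_boundary(fit.sigma_sens, task)
        row = {
            "participant_id": pid,
            "group": group_of[pid],
            "contrast": float(contrast),
            "n_trials": n_a + n_b,
            "sigma_sens": fit.sigma_sens,
            "k": fit.k,
            "k_opt": opt.k_opt,
            "k_error": boundary_error(fit.k, opt.k_opt) if fit.k > 0 else np.nan,
            "converged": fit.converged,
            "objective": fit.objective_at_optimum,
        }
        fit_rows.append(row)
    fits = pd.DataFrame(fit_rows)

    acc = _accuracy_summary(trials, config)
    extremes = (
        fits.groupby("participant_id")
        .agg(k_max=("k", "max"), sigma_max=("sigma_sens", "max"))
        .reset_index()
    )
    summary = acc.merge(extremes, on="participant_id", how="left")
    retained_all, report_all = apply_exclusions(summary, config, "all", experiment=2)
    kerr = (
        fits.assign(k_error_abs=fits["k_error"].abs())
        .groupby("participant_id")["k_error_abs"]
        .max()
        .rename("k_error_abs_max")
        .reset_index()
    )
    retained_opt, report_opt = apply_exclusions(
        summary.merge(kerr, on="participant_id", how="left"), config, "optimality", experiment=2
    )

    fits_r = fits[fits["participant_id"].isin(retained_all)]
    fits_opt = fits[fits["participant_id"].isin(retained_opt)]
    conv_r = fits_r[fits_r["converged"]]
    conv_opt = fits_opt[fits_opt["converged"]]

    def _group_mean(df, value):
        return (
            df.groupby(["group", "contrast"])[value]
            .agg(
                mean="mean",
                se=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0,
                n="size",
            )
            .reset_index()
        )

    tables = {
        "fits": fits.sort_values(["participant_id", "contrast"]).reset_index(drop=True),
        "psychometric": bin_orientations(
            trials[trials["participant_id"].isin(retained_all)],
            config.bin_centers,
            condition="contrast",
        ),
        "exclusions": pd.concat([report_all, report_opt], ignore_index=True),
        "group_sigma_sens": _group_mean(conv_r, "sigma_sens"),
        "group_k": _group_mean(conv_r, "k"),
        "group_k_opt": _group_mean(conv_opt, "k_opt"),
        "group_k_error": _group_mean(conv_opt, "k_error"),
        "n_nonconverged": int((~fits_r["converged"]).sum()),
    }
    tables["retained_all"] = retained_all
    tables["retained_optimality"] = retained_opt
    return tables


# ---------------------------------------------------------------------------
# Gamble checks


def summarize_gamble(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean stake on category B per participant × base-rate block, with group stats."""
    checks = trials.dropna(subset=["gamble_stake_B"])
    if len(checks) == 0:
        import warnings

        warnings.warn("no check trials present; gamble table is empty", stacklevel=2)
        return pd.DataFrame(
            columns=["group", "block_alpha_B", "mean_stake", "se", "n_participants"]
        )
    per_pp = (
        checks.groupby(["participant_id", "group", "block_alpha_B"])["gamble_stake_B"]
        .mean()
        .rename("mean_stake")
        .reset_index()
    )
    grp = (
        per_pp.groupby(["group", "block_alpha_B"])["mean_stake"]
        .agg(
            mean_stake="mean",
            se=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0,
            n_participants="size",
        )
        .reset_index()
    )
    return grp


# ---------------------------------------------------------------------------
# Output


def write_tables(tables: dict, outdir, config: AnalysisConfig | None = None, seed=None) -> None:
    """Write every DataFrame in ``tables`` as CSV plus a JSON run-metadata sidecar."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        if isinstance(table, pd.DataFrame):
            path = out / f"{name}.csv"
            table.to_csv(path, index=False, float_format="%.8g")
            written.append(path.name)
    meta = {
        "package": "critshift",
        "version": _pkg_version,
        "seed": seed,
        "tables": sorted(written),
    }
    if config is not None:
        cfg = asdict(config)
        cfg["bin_centers"] = list(cfg["bin_centers"])
        meta["config"] = cfg
        meta["config_sha256"] = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
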