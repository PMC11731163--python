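"""Parameter-recovery harness for the embedded-task estimator.

Simulates binomial report counts from known (σ_sens, k) pairs through the
forward model, refits them with the two-step estimator, and summarizes bias,
RMSE, and median absolute (relative) error — the standard validation that an
estimator returns the parameters that generated the data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .embedded import fit_embedded_counts, prob_report_narrow, combined_sd
from .tasks import EmbeddedCategoryTask2

__all__ = ["simulate_report_counts", "recovery_study", "summarize_recovery"]


def simulate_report_counts(
    sigma_sens: float,
    k: float,
    n_per_category: int,
    rng: np.random.Generator,
    task: EmbeddedCategoryTask2 = EmbeddedCategoryTask2(),
) -> tuple[int, int]:
    """Binomial narrow-report counts for both categories under the forward model."""
    p_a = prob_report_narrow(k, combined_sd(task.sd_narrow, sigma_sens))
    p_b = prob_report_narrow(k, combined_sd(task.sd_broad, sigma_sens))
    return int(rng.binomial(n_per_category, p_a)), int(rng.binomial(n_per_category, p_b))


def recovery_study(
    sigma_values=(1.0, 3.0, 6.0, 12.0),
    k_values=(3.0, 6.0, 9.0),
    n_trials_per_contrast: int = 10_000,
    n_reps: int = 17,
    seed: int = 0,
    task: EmbeddedCategoryTask2 = EmbeddedCategoryTask2(),
) -> pd.DataFrame:
    """Refit simulated observers over a (σ_sens × k) factorial.

    ``n_trials_per_contrast`` is the total trial count of one contrast cell;
    under equal priors half the trials fall in each category.  Returns one
    row per (σ_sens, k, rep) with the fitted values and errors.
    """
    rng = np.random.default_rng(seed)
    n_cat = n_trials_per_contrast // 2
    rows = []
    for sigma in sigma_values:
        for k in k_values:
            for rep in range(n_reps):
                c_a, c_b = simulate_report_counts(sigma, k, n_cat, rng, task)
                fit = fit_embedded_counts(c_a, n_cat, c_b, n_cat, task=task)
                rows.append(
                    {
                        "sigma_true": sigma,
                        "k_true": k,
                        "rep": rep,
                        "sigma_hat": fit.sigma_sens,
                        "k_hat": fit.k,
                        "converged": fit.converged,
                        "sigma_err": fit.sigma_sens - sigma,
                        "k_err": fit.k - k,
                    }
                )
    return pd.DataFrame(rows)


def summarize_recovery(results: pd.DataFrame) -> pd.DataFrame:
    """Per-cell bias, RMSE, and median absolute relative error of both parameters."""
    df = results.assign(
        sigma_rel_err=results["sigma_err"].abs() / results["sigma_true"],
        k_rel_err=results["k_err"].abs() / results["k_true"],
    )
    return (
        df.groupby(["sigma_true", "k_true"])
        .agg(
            sigma_bias=("sigma_err", "mean"),
            sigma_rmse=("sigma_err", lambda x: float(np.sqrt((x**2).mean()))),
            sigma_med_rel_err=("sigma_rel_err", "median"),
            k_bias=("k_err", "mean"),
            k_rmse=("k_err", lambda x: float(np.sqrt((x**2).mean()))),
            k_med_rel_err=("k_rel_err", "median"),
            n_reps=("rep", "size"),
            n_converged=("converged", "sum"),
        )
        .reset_index()
    )
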