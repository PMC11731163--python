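"""Observer model and estimator for the embedded categorization task.

Both categories are centred on 0° and differ only in spread, so the internal
measurement distribution for category *cat* across trials is a zero-mean
Gaussian whose sd combines external (stimulus) and internal (sensory) noise:

    σ_cat = sqrt(s_cat² + σ_sens²)

An observer with symmetric, trial-stable boundaries ±k reports the narrow
category A whenever the measurement falls inside (−k, k), so

    p(report A | cat) = 2 Φ(k / σ_cat) − 1.

Given the observed narrow-report proportions for the two categories at one
contrast, the two-step estimator first finds the σ_sens most consistent with
a *single* boundary across both categories (each proportion implies a
boundary k_cat(σ) = σ_cat · z((1+p)/2); σ_sens is chosen to minimise their
squared discrepancy), then takes k as the mean of the two implied boundaries
at that σ_sens.

The accuracy-maximizing boundary sits at the density crossing of the two
internal measurement distributions:

    k_opt = sqrt( 2 σ_A² σ_B² log(σ_B / σ_A) / (σ_B² − σ_A²) )

and widens monotonically with sensory noise.  The signed suboptimality is
k_error = k − k_opt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .sdt import loglinear_rate
from .tasks import EmbeddedCategoryTask2

__all__ = [
    "EmbeddedFit",
    "BoundaryOptimality",
    "combined_sd",
    "prob_report_narrow",
    "invert_boundary",
    "fit_embedded_observer",
    "fit_embedded_counts",
    "optimal_boundary",
    "boundary_error",
    "expected_accuracy",
]

#: Upper bound of the σ_sens search interval, in degrees.  Estimates at the
#: bound correspond to participants the exclusion rules remove (σ > 100).
SIGMA_MAX = 100.0

_MULTISTARTS = (0.5, 2.0, 8.0, 32.0)
_OBJECTIVE_TOL = 1e-8


@dataclass(frozen=True)
class EmbeddedFit:
    """Fitted sensory noise and boundary for one participant × contrast cell."""

    sigma_sens: float
    k: float
    objective_at_optimum: float
    converged: bool
    cell: tuple = ()


@dataclass(frozen=True)
class BoundaryOptimality:
    """Ideal-observer boundary benchmark at a given sensory noise."""

    sigma_a: float
    sigma_b: float
    k_opt: float
    k_error: float = math.nan


def combined_sd(s_cat: float, sigma_sens: float) -> float:
    """Total measurement sd: external and internal noise in quadrature."""
    if s_cat <= 0:
        raise ValueError(f"s_cat must be positive; got {s_cat}")
    if sigma_sens < 0:
        raise ValueError(f"sigma_sens must be non-negative; got {sigma_sens}")
    return math.hypot(s_cat, sigma_sens)


def prob_report_narrow(k: float, sigma_cat: float) -> float:
    """Mass of N(0, σ_cat) inside (−k, k): the narrow-report probability."""
    if k < 0:
        raise ValueError(f"k must be non-negative; got {k}")
    if sigma_cat <= 0:
        raise ValueError(f"sigma_cat must be positive; got {sigma_cat}")
    return float(2.0 * norm.cdf(k / sigma_cat) - 1.0)


def invert_boundary(p_narrow: float, sigma_cat: float) -> float:
    """Boundary implied by a narrow-report probability (exact inverse).

    k = σ_cat · z((1 + p) / 2).  Undefined at p ∈ {0, 1}; apply a count
    correction upstream.
    """
    if not 0 < p_narrow < 1:
        raise ValueError(f"p_narrow must lie strictly in (0, 1); got {p_narrow}")
    if sigma_cat <= 0:
        raise ValueError(f"sigma_cat must be positive; got {sigma_cat}")
    return float(sigma_cat * norm.ppf((1.0 + p_narrow) / 2.0))


def fit_embedded_observer(
    p_narrow_given_a: float,
    p_narrow_given_b: float,
    task: EmbeddedCategoryTask2 = EmbeddedCategoryTask2(),
    cell: tuple = (),
) -> EmbeddedFit:
    """Two-step fit of (σ_sens, k) from per-category narrow-report proportions.

    σ_sens minimises the squared gap between the category-wise implied
    boundaries over [0, 100]°; k is the mean implied boundary at the optimum.
    When no σ_sens ≥ 0 can reconcile the two proportions (e.g. the narrow
    category was reported *less* often under A than under B) the best
    boundary-case fit is returned with ``converged=False`` rather than NaN.
    """
    for name, p in (("p_narrow_given_A", p_narrow_given_a), ("p_narrow_given_B", p_narrow_given_b)):
        if not 0 < p < 1:
            raise ValueError(f"{name} must lie strictly in (0, 1); got {p}")

    za = norm.ppf((1.0 + p_narrow_given_a) / 2.0)
    zb = norm.ppf((1.0 + p_narrow_given_b) / 2.0)
    sa, sb = task.sd_narrow, task.sd_broad

    def gap(sigma: float) -> float:
        return math.hypot(sa, sigma) * za - math.hypot(sb, sigma) * zb

    def objective(sigma: float) -> float:
        return gap(sigma) ** 2

    # Candidate optima: interval endpoints, an exact root where the gap
    # changes sign, and bounded local minimisation from several starts
    # (the objective can be flat near zero).
    candidates = [0.0, SIGMA_MAX]
    g0, gmax = gap(0.0), gap(SIGMA_MAX)
    if g0 == 0.0:
        candidates.append(0.0)
    elif g0 * gmax < 0:
        candidates.append(float(optimize.brentq(gap, 0.0, SIGMA_MAX, xtol=1e-12)))
    for start in _MULTISTARTS:
        res = optimize.minimize(
            lambda s: objective(float(s[0])),
            x0=[start],
            bounds=[(0.0, SIGMA_MAX)],
            method="L-BFGS-B",
        )
        candidates.append(float(res.x[0]))

    sigma_hat = min(candidates, key=objective)
    obj = objective(sigma_hat)
    k_a = math.hypot(sa, sigma_hat) * za
    k_b = math.hypot(sb, sigma_hat) * zb
    return EmbeddedFit(
        sigma_sens=float(sigma_hat),
        k=float(0.5 * (k_a + k_b)),
        objective_at_optimum=float(obj),
        converged=bool(obj <= _OBJECTIVE_TOL),
        cell=cell,
    )


def fit_embedded_counts(
    n_narrow_given_a: int,
    n_trials_a: int,
    n_narrow_given_b: int,
    n_trials_b: int,
    task: EmbeddedCategoryTask2 = EmbeddedCategoryTask2(),
    cell: tuple = (),
) -> EmbeddedFit:
    """Fit from raw report counts, applying the log-linear correction first."""
    if n_trials_a <= 0 or n_trials_b <= 0:
        raise ValueError(f"cell {cell} has no trials in one category")
    return fit_embedded_observer(
        loglinear_rate(n_narrow_given_a, n_trials_a),
        loglinear_rate(n_narrow_given_b, n_trials_b),
        task=task,
        cell=cell,
    )


def optimal_boundary(
    sigma_sens: float, task: EmbeddedCategoryTask2 = EmbeddedCategoryTask2()
) -> BoundaryOptimality:
    """Accuracy-maximizing boundary at a given sensory noise.

    k_opt is the positive crossing point of the two internal measurement
    densities; the returned record carries the combined per-category sds.
    """
    sigma_a = combined_sd(task.sd_narrow, sigma_sens)
    sigma_b = combined_sd(task.sd_broad, sigma_sens)
    if math.isclose(sigma_a, sigma_b):
        raise ValueError("optimal boundary undefined when the category sds coincide")
    va, vb = sigma_a**2, sigma_b**2
    k_opt = math.sqrt(2.0 * va * vb * math.log(sigma_b / sigma_a) / (vb - va))
    return BoundaryOptimality(sigma_a=sigma_a, sigma_b=sigma_b, k_opt=k_opt)


def boundary_error(k: float, k_opt: float) -> float:
    """Signed boundary suboptimality k_error = k − k_opt (0 = optimal)."""
    if k <= 0 or k_opt <= 0:
        raise ValueError(f"boundaries must be positive; got k={k}, k_opt={k_opt}")
    return k - k_opt


def expected_accuracy(
    k: float, sigma_sens: float, task: EmbeddedCategoryTask2 = EmbeddedCategoryTask2()
) -> float:
    """Expected accuracy of boundaries ±k under equal priors at a given noise."""
    sigma_a = combined_sd(task.sd_narrow, sigma_sens)
    sigma_b = combined_sd(task.sd_broad, sigma_sens)
    p_a = 2.0 * norm.cdf(k / sigma_a) - 1.0
    p_b = 2.0 * (1.0 - norm.cdf(k / sigma_b))
    return float(0.5 * (p_a + p_b))
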