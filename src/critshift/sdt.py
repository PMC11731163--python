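"""Equal-variance signal detection theory for the shifted-mean task.

Category B is treated as the "signal": the hit rate is P(respond B | true B)
and the false-alarm rate is P(respond B | true A).  Sensitivity and criterion
follow the standard definitions

    d' = z(H) - z(F)          c = -(z(H) + z(F)) / 2

with z the standard-normal quantile; positive c is a bias *against*
reporting B.  The ideal-observer benchmark places the likelihood-ratio
criterion at the prior odds, β_opt = (1 - α) / α for base rate α of
category B, which on the criterion axis is c_opt = log(β_opt) / d'.
Suboptimality metrics (the biased-block criterion shift D_criterion and the
sign-normalized deviation c_error) are defined so their magnitudes do not
depend on the sign convention.

Extreme response rates (0 or 1) are handled either by the log-linear rule
(add 0.5 to each count and 1 to each total) or by clamping rates to
[1/2n, 1 - 1/2n]; the log-linear rule is the default and is always applied,
so corrected rates are continuous in the counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Iterable

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "ResponseCounts",
    "SDTEstimate",
    "OptimalityRecord",
    "count_responses",
    "estimate_dprime_criterion",
    "optimal_beta",
    "optimal_criterion",
    "criterion_shift",
    "criterion_error",
    "loglinear_rate",
    "clamp_rate",
]

CORRECTIONS = ("loglinear", "clamp")


@dataclass(frozen=True)
class ResponseCounts:
    """Response tallies for one participant × base-rate block × contrast cell."""

    n_b_given_b: int
    n_trials_b: int
    n_b_given_a: int
    n_trials_a: int
    cell: tuple = ()

    def __post_init__(self) -> None:
        if not 0 <= self.n_b_given_b <= self.n_trials_b:
            raise ValueError(f"invalid B-trial counts in cell {self.cell}")
        if not 0 <= self.n_b_given_a <= self.n_trials_a:
            raise ValueError(f"invalid A-trial counts in cell {self.cell}")
        if self.n_trials_a + self.n_trials_b <= 0:
            raise ValueError(f"empty cell {self.cell}")

    @property
    def n_trials(self) -> int:
        return self.n_trials_a + self.n_trials_b


@dataclass(frozen=True)
class SDTEstimate:
    """d' and criterion c for one cell, with the corrected rates that produced them."""

    d_prime: float
    criterion_c: float
    hit_rate: float
    fa_rate: float
    correction: str
    cell: tuple = ()


@dataclass(frozen=True)
class OptimalityRecord:
    """Ideal-observer benchmark for one biased-block cell."""

    alpha_b: float
    beta_opt: float
    c_opt: float
    c_error: float
    cell: tuple = ()


def loglinear_rate(count: float, total: float) -> float:
    """Log-linear corrected proportion: (count + 0.5) / (total + 1)."""
    return (count + 0.5) / (total + 1.0)


def clamp_rate(count: float, total: float) -> float:
    """Raw proportion clamped to [1/2n, 1 - 1/2n]."""
    lo = 0.5 / total
    return float(np.clip(count / total, lo, 1.0 - lo))


def count_responses(trials: pd.DataFrame) -> list[ResponseCounts]:
    """Tally B-responses per (base-rate block × contrast) cell.

    ``trials`` must come from a single participant in the shifted-mean
    experiment; one :class:`ResponseCounts` is returned per non-empty cell,
    keyed ``(participant_id, block_alpha_B, contrast)``.
    """
    if len(trials) == 0:
        return []
    pids = trials["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError(f"trials mix participants: {sorted(pids)}")
    exps = trials["experiment"].unique()
    if len(exps) != 1 or int(exps[0]) != 1:
        raise ValueError(f"count_responses expects experiment-1 trials; got {sorted(exps)}")
    pid = pids[0]

    out: list[ResponseCounts] = []
    grouped = trials.groupby(["block_alpha_B", "contrast"], sort=True)
    for (alpha, contrast), cell in grouped:
        is_b = cell["true_category"].to_numpy() == "B"
        resp_b = cell["response"].to_numpy() == "B"
        out.append(
            ResponseCounts(
                n_b_given_b=int((resp_b & is_b).sum()),
                n_trials_b=int(is_b.sum()),
                n_b_given_a=int((resp_b & ~is_b).sum()),
                n_trials_a=int((~is_b).sum()),
                cell=(pid, float(alpha), float(contrast)),
            )
        )
    return out


def estimate_dprime_criterion(
    counts: ResponseCounts, correction: str = "loglinear"
) -> SDTEstimate:
    """Estimate d' and c from response counts with an extreme-rate correction."""
    if correction not in CORRECTIONS:
        raise ValueError(f"correction must be one of {CORRECTIONS}; got {correction!r}")
    if counts.n_trials_a == 0 or counts.n_trials_b == 0:
        raise ValueError(
            f"cell {counts.cell} has no trials in one category "
            f"(n_A={counts.n_trials_a}, n_B={counts.n_trials_b})"
        )
    rate = loglinear_rate if correction == "loglinear" else clamp_rate
    hit = rate(counts.n_b_given_b, counts.n_trials_b)
    fa = rate(counts.n_b_given_a, counts.n_trials_a)
    zh, zf = norm.ppf(hit), norm.ppf(fa)
    return SDTEstimate(
        d_prime=float(zh - zf),
        criterion_c=float(-(zh + zf) / 2.0),
        hit_rate=float(hit),
        fa_rate=float(fa),
        correction=correction,
        cell=counts.cell,
    )


def optimal_beta(alpha_b: float) -> float:
    """Ideal likelihood-ratio criterion β_opt = (1 - α_B) / α_B."""
    if not 0 < alpha_b < 1:
        raise ValueError(f"alpha_B must lie strictly in (0, 1); got {alpha_b}")
    return (1.0 - alpha_b) / alpha_b


def optimal_criterion(beta_opt: float, d_prime: float) -> float:
    """Ideal criterion c_opt = log(β_opt) / d' on the criterion axis.

    Undefined at d' = 0 (the ideal criterion runs off to infinity as the
    categories become indistinguishable, which is what the extreme-deviation
    exclusion rule downstream guards against).
    """
    if beta_opt <= 0:
        raise ValueError(f"beta_opt must be positive; got {beta_opt}")
    if d_prime == 0:
        raise ValueError("optimal criterion is unbounded at d_prime = 0")
    return math.log(beta_opt) / d_prime


def criterion_shift(c_at_alpha75: float, c_at_alpha25: float) -> float:
    """Criterion shift between biased blocks: D_criterion = c(75%) - c(25%).

    An observer who uses the base rate yields D < 0 under this module's sign
    convention, with |D| growing as sensitivity shrinks.
    """
    return c_at_alpha75 - c_at_alpha25


def criterion_error(c: float, d_prime: float, alpha_b: float) -> float:
    """Sign-normalized deviation from the ideal criterion in one biased block.

    c_error = sign(c_opt) · (c_opt - c): positive values mean the observer
    under-shifted toward the prior, zero is optimal, and the magnitude is
    invariant to the A/B labelling convention.  Only defined for biased
    blocks (α_B ≠ 0.5).
    """
    if not 0 < alpha_b < 1:
        raise ValueError(f"alpha_B must lie strictly in (0, 1); got {alpha_b}")
    if alpha_b == 0.5:
        raise ValueError("criterion_error is undefined for the neutral block (alpha_B = 0.5)")
    c_opt = optimal_criterion(optimal_beta(alpha_b), d_prime)
    return math.copysign(1.0, c_opt) * (c_opt - c)
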