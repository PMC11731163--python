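"""Synthetic observers and cohorts for both categorization experiments.

Every pipeline stage is testable without any external data: this module
generates trial-level responses (and gamble check-question stakes) from
explicit observer models with tunable optimality, and emits the generative
ground truth next to the data so recovery can be verified.

The observer's sensory noise falls with stimulus contrast through a
parametric map σ(c) = σ_floor + a·c^(−b).  In the shifted-mean experiment
the observer responds B when the noisy measurement exceeds a criterion that
weights the log prior odds by ``prior_weight`` (1 = ideal, 0 =
prior-ignoring):

    x* = w · log((1−α_B)/α_B) · (s² + σ(c)²) / (m_B − m_A)

relative to the reference.  In the embedded experiment the observer reports
the narrow category when |x| < k_obs(c), where k_obs = γ · k_opt(ρ·σ(c)):
``boundary_scale`` γ distorts the boundary itself and ``noise_misestimate``
ρ distorts the noise the observer *believes* it has.  γ and ρ are jointly
unidentifiable from k alone (only k_obs is observable per contrast); they
are separate knobs so suboptimality of either kind can be injected.  A
lapse rate λ replaces responses with a fair coin.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .embedded import optimal_boundary
from .tasks import (
    DEFAULT_CONTRASTS,
    TRIAL_COLUMNS,
    BaseRateBlock,
    EmbeddedCategoryTask2,
    GaussianCategoryTask1,
    SessionDesign,
    sample_stimuli,
)

__all__ = [
    "ObserverParams",
    "CohortConfig",
    "decision_threshold_exp1",
    "true_d_prime",
    "expected_d_criterion",
    "observed_boundary",
    "simulate_participant_exp1",
    "simulate_participant_exp2",
    "simulate_gamble_responses",
    "simulate_cohort",
    "null_cohort",
    "altered_integration_cohort",
    "ideal_cohort",
    "save_cohort_config",
    "load_cohort_config",
]

# Hard parameter ranges used when drawing participants from a cohort config.
_PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "sigma_floor": (0.2, 50.0),
    "noise_scale": (0.0, 10.0),
    "noise_exponent": (0.0, 3.0),
    "prior_weight": (0.0, 1.5),
    "boundary_scale": (0.05, 5.0),
    "noise_misestimate": (0.05, 5.0),
    "lapse_rate": (0.0, 0.1),
    "gamble_weight": (0.0, 1.0),
    "gamble_sd": (0.0, 20.0),
}


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one simulated participant.

    Defaults describe an ideal observer (apart from a small lapse rate) whose
    sensory noise spans roughly 2°–14° across the contrast ladder.
    """

    sigma_floor: float = 2.0       # asymptotic noise at high contrast, degrees
    noise_scale: float = 0.08      # contrast-dependent noise amplitude
    noise_exponent: float = 0.9    # decay of noise with contrast
    prior_weight: float = 1.0      # w: use of log prior odds (1 = ideal)
    boundary_scale: float = 1.0    # γ: k_obs = γ·k_opt(σ_assumed)
    noise_misestimate: float = 1.0  # ρ: σ_assumed = ρ·σ_sens
    lapse_rate: float = 0.02       # λ: probability of a coin-flip response
    gamble_weight: float = 1.0     # w_g: stake calibration toward the base rate
    gamble_sd: float = 5.0         # stake noise, cents

    def __post_init__(self) -> None:
        for name, (lo, hi) in _PARAM_BOUNDS.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside allowed range [{lo}, {hi}]")

    def sigma_sens(self, contrast):
        """Sensory noise (degrees) at the given contrast(s); decreasing in c."""
        c = np.asarray(contrast, dtype=float)
        out = self.sigma_floor + self.noise_scale * np.power(c, -self.noise_exponent)
        return float(out) if np.isscalar(contrast) else out


def decision_threshold_exp1(
    params: ObserverParams,
    alpha_b: float,
    contrast: float,
    task: GaussianCategoryTask1 = GaussianCategoryTask1(),
) -> float:
    """Measurement criterion (degrees, relative to reference) for responding B.

    The ideal observer (w = 1) places it where the posterior odds flip:
    x* = log((1−α)/α)·(s² + σ²)/(m_B − m_A); w scales the prior term.
    """
    if not 0 < alpha_b < 1:
        raise ValueError(f"alpha_B must lie in (0, 1); got {alpha_b}")
    sigma = params.sigma_sens(contrast)
    log_odds = math.log((1.0 - alpha_b) / alpha_b)
    return params.prior_weight * log_odds * (task.sd**2 + sigma**2) / task.separation


def true_d_prime(
    params: ObserverParams,
    contrast: float,
    task: GaussianCategoryTask1 = GaussianCategoryTask1(),
) -> float:
    """Generative sensitivity Δ/σ_tot at a contrast (ignoring lapses)."""
    sigma_tot = math.hypot(task.sd, params.sigma_sens(contrast))
    return task.separation / sigma_tot


def expected_d_criterion(
    params: ObserverParams,
    contrast: float,
    task: GaussianCategoryTask1 = GaussianCategoryTask1(),
    alpha_high: float = 0.75,
) -> float:
    """Closed-form criterion shift c(α_high) − c(1−α_high) of the generative rule.

    The observer's criterion on the z-scaled axis is c = x*/σ_tot =
    w·log(β)·σ_tot/Δ, so the shift is w·(log β_high − log β_low)·σ_tot/Δ —
    negative for a prior-using observer, shrinking as contrast rises.
    """
    sigma_tot = math.hypot(task.sd, params.sigma_sens(contrast))
    lb_high = math.log((1.0 - alpha_high) / alpha_high)
    lb_low = math.log(alpha_high / (1.0 - alpha_high))
    return params.prior_weight * (lb_high - lb_low) * sigma_tot / task.separation


def observed_boundary(
    params: ObserverParams,
    contrast: float,
    task: EmbeddedCategoryTask2 = EmbeddedCategoryTask2(),
) -> float:
    """Boundary the simulated observer actually uses: γ·k_opt(ρ·σ(c))."""
    sigma_assumed = params.noise_misestimate * params.sigma_sens(contrast)
    return params.boundary_scale * optimal_boundary(sigma_assumed, task).k_opt


def _balanced_contrasts(
    contrasts: tuple[float, ...], n: int, rng: np.random.Generator
) -> np.ndarray:
    """Shuffled assignment of contrasts to trials with near-equal cell sizes."""
    levels = np.asarray(contrasts, dtype=float)
    reps = np.tile(levels, n // len(levels))
    extra = rng.choice(levels, size=n - len(reps), replace=False) if n % len(levels) else []
    out = np.concatenate([reps, extra])
    rng.shuffle(out)
    return out


def simulate_gamble_responses(
    params: ObserverParams,
    alphas: list[float],
    n_checks: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stakes (cents on category B) for check questions, one row per block.

    stake = clip(round(99·(w_g·α_B + (1−w_g)·0.5) + ε), 0, 99), ε ~ N(0, gamble_sd).
    """
    if n_checks < 1:
        raise ValueError(f"n_checks must be at least 1; got {n_checks}")
    alphas_arr = np.asarray(alphas, dtype=float)[:, None]
    target = 99.0 * (params.gamble_weight * alphas_arr + (1.0 - params.gamble_weight) * 0.5)
    eps = rng.normal(0.0, params.gamble_sd, size=(len(alphas), n_checks)) if params.gamble_sd > 0 else 0.0
    stakes = np.broadcast_to(target + eps, (len(alphas), n_checks))
    return np.clip(np.rint(stakes), 0, 99).astype(int)


def _blank_optionals(n: int) -> dict:
    return {
        "confidence": np.full(n, np.nan),
        "rt_s": np.full(n, np.nan),
        "gamble_stake_B": np.full(n, np.nan),
    }


def _as_categories(values) -> pd.Categorical:
    # Compact dtype: large simulated cohorts would be memory-hungry as objects.
    return pd.Categorical(values, categories=["A", "B"])


def _assemble(frames: list[pd.DataFrame]) -> pd.DataFrame:
    df = pd.concat(frames, ignore_index=True)
    return df[TRIAL_COLUMNS]


def simulate_participant_exp1(
    params: ObserverParams,
    design: SessionDesign,
    seed,
    *,
    task: GaussianCategoryTask1 = GaussianCategoryTask1(),
    contrasts: tuple[float, ...] = DEFAULT_CONTRASTS,
    participant_id: str = "sim001",
    group: str = "non-autistic",
    check_rate: float = 1.0 / 80.0,
) -> pd.DataFrame:
    """Simulate one participant's shifted-mean (base-rate) session.

    Per trial the observer draws a measurement x ~ N(orientation, σ(c)) and
    responds B when x exceeds the prior-weighted criterion; with probability
    λ the response is replaced by a fair coin.  A fraction ``check_rate`` of
    trials carry a gamble stake.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for _session in range(design.n_sessions):
        for block in design.blocks:
            n = design.trials_per_block
            contrast = _balanced_contrasts(contrasts, n, rng)
            cats, oris = sample_stimuli(task, block.alpha_b, n, rng)
            sigma = params.sigma_sens(contrast)
            x = oris + rng.normal(0.0, 1.0, n) * sigma
            log_odds = math.log((1.0 - block.alpha_b) / block.alpha_b)
            thresh = params.prior_weight * log_odds * (task.sd**2 + sigma**2) / task.separation
            resp = np.where(x > thresh, "B", "A")
            if params.lapse_rate > 0:
                lapse = rng.random(n) < params.lapse_rate
                coin = np.where(rng.random(n) < 0.5, "B", "A")
                resp = np.where(lapse, coin, resp)
            frame = pd.DataFrame(
                {
                    "participant_id": participant_id,
                    "group": group,
                    "experiment": 1,
                    "block_alpha_B": block.alpha_b,
                    "contrast": contrast,
                    "orientation_deg": oris,
                    "true_category": _as_categories(cats),
                    "response": _as_categories(resp),
                    **_blank_optionals(n),
                }
            )
            if check_rate > 0:
                n_checks = max(1, int(round(check_rate * n)))
                stakes = simulate_gamble_responses(params, [block.alpha_b], n_checks, rng)
                pos = rng.choice(n, size=n_checks, replace=False)
                frame.loc[pos, "gamble_stake_B"] = stakes[0].astype(float)
            frames.append(frame)
    return _assemble(frames)


def simulate_participant_exp2(
    params: ObserverParams,
    design: SessionDesign,
    seed,
    *,
    task: EmbeddedCategoryTask2 = EmbeddedCategoryTask2(),
    contrasts: tuple[float, ...] = DEFAULT_CONTRASTS,
    participant_id: str = "sim001",
    group: str = "non-autistic",
    check_rate: float = 1.0 / 80.0,
) -> pd.DataFrame:
    """Simulate one participant's embedded-task sessions (equal base rates).

    The observer reports the narrow category A when |x| < k_obs(c) with
    k_obs = γ·k_opt(ρ·σ(c)); lapses as in the shifted-mean task.
    """
    rng = np.random.default_rng(seed)
    k_map = {c: observed_boundary(params, c, task) for c in contrasts}
    frames = []
    for _session in range(design.n_sessions):
        for block in design.blocks:
            n = design.trials_per_block
            contrast = _balanced_contrasts(contrasts, n, rng)
            cats, oris = sample_stimuli(task, block.alpha_b, n, rng)
            sigma = params.sigma_sens(contrast)
            x = oris + rng.normal(0.0, 1.0, n) * sigma
            k_obs = np.vectorize(k_map.get)(contrast)
            resp = np.where(np.abs(x) < k_obs, "A", "B")
            if params.lapse_rate > 0:
                lapse = rng.random(n) < params.lapse_rate
                coin = np.where(rng.random(n) < 0.5, "B", "A")
                resp = np.where(lapse, coin, resp)
            frame = pd.DataFrame(
                {
                    "participant_id": participant_id,
                    "group": group,
                    "experiment": 2,
                    "block_alpha_B": block.alpha_b,
                    "contrast": contrast,
                    "orientation_deg": oris,
                    "true_category": _as_categories(cats),
                    "response": _as_categories(resp),
                    **_blank_optionals(n),
                }
            )
            if check_rate > 0:
                n_checks = max(1, int(round(check_rate * n)))
                stakes = simulate_gamble_responses(params, [block.alpha_b], n_checks, rng)
                pos = rng.choice(n, size=n_checks, replace=False)
                frame.loc[pos, "gamble_stake_B"] = stakes[0].astype(float)
            frames.append(frame)
    return _assemble(frames)


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class CohortConfig:
    """Full recipe for a synthetic cohort; the seed fixes the dataset bit-for-bit."""

    experiment: int = 1
    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"autistic": 34, "non-autistic": 49}
    )
    group_means: Mapping[str, ObserverParams] = field(
        default_factory=lambda: {
            "autistic": ObserverParams(),
            "non-autistic": ObserverParams(),
        }
    )
    param_sds: Mapping[str, float] = field(
        default_factory=lambda: {
            "sigma_floor": 0.3,
            "noise_scale": 0.02,
            "prior_weight": 0.15,
            "boundary_scale": 0.1,
            "noise_misestimate": 0.1,
            "lapse_rate": 0.01,
            "gamble_weight": 0.1,
            "gamble_sd": 1.0,
        }
    )
    trials_per_block: int = 320
    counterbalance: bool = True
    check_rate: float = 1.0 / 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2):
            raise ValueError(f"experiment must be 1 or 2; got {self.experiment}")
        bad = [g for g, n in self.n_per_group.items() if n < 1]
        if bad:
            raise ValueError(f"n_per_group must be >= 1; offending groups: {bad}")
        unknown = [f for f in self.param_sds if f not in _PARAM_BOUNDS]
        if unknown:
            raise ValueError(f"param_sds names unknown fields: {unknown}")
        missing = [g for g in self.n_per_group if g not in self.group_means]
        if missing:
            raise ValueError(f"group_means missing groups: {missing}")

    def design_for(self, participant_index: int) -> SessionDesign:
        if self.experiment == 1:
            low_first = (participant_index % 2 == 0) if self.counterbalance else True
            return SessionDesign.experiment1(self.trials_per_block, low_block_first=low_first)
        return SessionDesign.experiment2(self.trials_per_block)


def _draw_params(
    means: ObserverParams, sds: Mapping[str, float], rng: np.random.Generator
) -> ObserverParams:
    values = asdict(means)
    for name, sd in sds.items():
        if sd > 0:
            lo, hi = _PARAM_BOUNDS[name]
            values[name] = float(np.clip(rng.normal(values[name], sd), lo, hi))
    return ObserverParams(**values)


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; returns (trial table, ground-truth table).

    The ground truth carries every generative parameter plus the derived
    per-contrast sensory noise and true d′ (experiment 1) or true boundary
    k_obs (experiment 2), joinable 1:1 on participant_id.
    """
    master = np.random.SeedSequence(config.seed)
    trial_frames: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    idx = 0
    for group in sorted(config.n_per_group):
        n_group = config.n_per_group[group]
        prefix = "".join(ch for ch in group if ch.isalnum())[:3] or "grp"
        for j in range(n_group):
            child = master.spawn(1)[0]
            draw_rng = np.random.default_rng(child)
            params = _draw_params(config.group_means[group], config.param_sds, draw_rng)
            pid = f"{prefix}{j + 1:03d}"
            design = config.design_for(idx)
            sim = simulate_participant_exp1 if config.experiment == 1 else simulate_participant_exp2
            trial_frames.append(
                sim(
                    params,
                    design,
                    child.spawn(1)[0],
                    participant_id=pid,
                    group=group,
                    check_rate=config.check_rate,
                )
            )
            row = {"participant_id": pid, "group": group, **asdict(params)}
            for c in DEFAULT_CONTRASTS:
                row[f"sigma_sens_{c:g}"] = params.sigma_sens(c)
                if config.experiment == 1:
                    row[f"d_prime_true_{c:g}"] = true_d_prime(params, c)
                else:
                    row[f"k_obs_true_{c:g}"] = observed_boundary(params, c)
            truth_rows.append(row)
            idx += 1
    trials = pd.concat(trial_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return trials, truth


def null_cohort(experiment: int = 1, seed: int = 0, **overrides) -> CohortConfig:
    """Cohort preset with identical parameter distributions in both groups."""
    n = {"autistic": 34, "non-autistic": 49 if experiment == 1 else 44}
    return CohortConfig(experiment=experiment, n_per_group=n, seed=seed, **overrides)


def altered_integration_cohort(experiment: int = 1, seed: int = 0, **overrides) -> CohortConfig:
    """Cohort preset in which the autistic group under-weights the prior (w ≈ 0.6)."""
    cfg = null_cohort(experiment=experiment, seed=seed, **overrides)
    means = dict(cfg.group_means)
    means["autistic"] = replace(means["autistic"], prior_weight=0.6)
    return replace(cfg, group_means=means)


def ideal_cohort(
    experiment: int,
    n_participants: int,
    trials_per_block: int,
    seed: int = 0,
    lapse_rate: float = 0.0,
) -> CohortConfig:
    """Single-group cohort of exactly ideal observers (w = γ = ρ = 1, λ = 0).

    Used as the oracle in convergence checks: downstream c_error and k_error
    should be statistically indistinguishable from zero.
    """
    params = ObserverParams(prior_weight=1.0, boundary_scale=1.0,
                            noise_misestimate=1.0, lapse_rate=lapse_rate)
    return CohortConfig(
        experiment=experiment,
        n_per_group={"sim": n_participants},
        group_means={"sim": params},
        param_sds={},
        trials_per_block=trials_per_block,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Config (de)serialization


def cohort_config_to_dict(config: CohortConfig) -> dict:
    return {
        "experiment": config.experiment,
        "n_per_group": dict(config.n_per_group),
        "group_means": {g: asdict(p) for g, p in config.group_means.items()},
        "param_sds": dict(config.param_sds),
        "trials_per_block": config.trials_per_block,
        "counterbalance": config.counterbalance,
        "check_rate": config.check_rate,
        "seed": config.seed,
    }


def cohort_config_from_dict(data: Mapping) -> CohortConfig:
    data = dict(data)
    if "group_means" in data:
        data["group_means"] = {
            g: ObserverParams(**p) for g, p in data["group_means"].items()
        }
    return CohortConfig(**data)


def save_cohort_config(config: CohortConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cohort_config_to_dict(config), fh, sort_keys=True)


def load_cohort_config(path) -> CohortConfig:
    with open(path) as fh:
        return cohort_config_from_dict(yaml.safe_load(fh))
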