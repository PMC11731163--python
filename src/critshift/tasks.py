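"""Task specifications, session designs, and the shared trial data model.

Two orientation-categorization tasks are modelled.  In the *shifted-mean*
task (Task 1) the two categories are Gaussian orientation distributions with
different means (86° and 94° around vertical) and a common spread (5°), so a
single decision criterion separates them.  In the *embedded* task (Task 2)
both categories are centred on horizontal (0°) but differ in spread (3° vs
12°), so the optimal decision rule is a pair of boundaries symmetric around
zero.  All orientations are stored as signed degrees relative to the task
reference (90° vertical for Task 1, 0° horizontal for Task 2), positive =
clockwise.

The module also houses the zero-sensory-noise ideal-observer ceiling for each
task (`max_accuracy`) and the trial-level CSV schema shared by the simulator
and the analysis pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "DEFAULT_CONTRASTS",
    "TRIAL_COLUMNS",
    "GaussianCategoryTask1",
    "EmbeddedCategoryTask2",
    "ContrastLadder",
    "BaseRateBlock",
    "SessionDesign",
    "TrialRecord",
    "sample_stimuli",
    "sample_trial_stimulus",
    "max_accuracy",
    "read_trials",
    "write_trials",
    "validate_trials",
]

#: Michelson contrasts used in both experiments, low (noisy) to high (clear).
DEFAULT_CONTRASTS: tuple[float, ...] = (0.004, 0.016, 0.033, 0.093, 0.18, 0.36, 0.72)

#: Exact column order of the trial-level CSV interchange format.
TRIAL_COLUMNS: list[str] = [
    "participant_id",
    "group",
    "experiment",
    "block_alpha_B",
    "contrast",
    "orientation_deg",
    "true_category",
    "response",
    "confidence",
    "rt_s",
    "gamble_stake_B",
]


@dataclass(frozen=True)
class GaussianCategoryTask1:
    """Shifted-mean categorization task: N(86°, 5°) vs N(94°, 5°).

    Orientations are expressed relative to the reference (the category
    midpoint, 90° vertical), so category means sit at ∓(mean_b − mean_a)/2.
    """

    mean_a: float = 86.0
    mean_b: float = 94.0
    sd: float = 5.0

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"sd must be positive; got {self.sd}")
        if self.mean_a > self.mean_b:
            raise ValueError(
                f"mean_a must not exceed mean_b; got {self.mean_a} > {self.mean_b}"
            )

    @property
    def reference(self) -> float:
        """Reference orientation (midpoint of the two category means)."""
        return 0.5 * (self.mean_a + self.mean_b)

    @property
    def separation(self) -> float:
        """Distance between category means, in degrees."""
        return self.mean_b - self.mean_a

    def category_offset(self, category: str) -> float:
        """Category mean relative to the reference (A negative, B positive)."""
        half = 0.5 * self.separation
        if category == "A":
            return -half
        if category == "B":
            return half
        raise ValueError(f"unknown category {category!r}")


@dataclass(frozen=True)
class EmbeddedCategoryTask2:
    """Embedded categorization task: N(0°, 3°) (narrow A) vs N(0°, 12°) (broad B)."""

    mean: float = 0.0
    sd_narrow: float = 3.0
    sd_broad: float = 12.0

    def __post_init__(self) -> None:
        if not 0 < self.sd_narrow < self.sd_broad:
            raise ValueError(
                "need 0 < sd_narrow < sd_broad; got "
                f"sd_narrow={self.sd_narrow}, sd_broad={self.sd_broad}"
            )

    def category_sd(self, category: str) -> float:
        if category == "A":
            return self.sd_narrow
        if category == "B":
            return self.sd_broad
        raise ValueError(f"unknown category {category!r}")


@dataclass(frozen=True)
class ContrastLadder:
    """Ordered set of Michelson contrasts presented interleaved across trials."""

    levels: tuple[float, ...] = DEFAULT_CONTRASTS

    def __post_init__(self) -> None:
        lv = tuple(float(x) for x in self.levels)
        object.__setattr__(self, "levels", lv)
        if len(lv) == 0:
            raise ValueError("contrast ladder must not be empty")
        if any(not 0 < x <= 1 for x in lv):
            raise ValueError(f"contrasts must lie in (0, 1]; got {lv}")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError(f"contrasts must be strictly increasing; got {lv}")

    def __iter__(self):
        return iter(self.levels)

    def __len__(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class BaseRateBlock:
    """One block of trials with a fixed base rate for category B."""

    alpha_b: float
    position: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.alpha_b < 1:
            raise ValueError(f"alpha_b must lie in (0, 1); got {self.alpha_b}")


@dataclass(frozen=True)
class SessionDesign:
    """Block structure of one experiment for one participant."""

    blocks: tuple[BaseRateBlock, ...]
    trials_per_block: int = 320
    n_sessions: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if self.trials_per_block <= 0:
            raise ValueError("trials_per_block must be positive")
        if self.n_sessions <= 0:
            raise ValueError("n_sessions must be positive")
        if not self.blocks:
            raise ValueError("design needs at least one block")

    @property
    def total_trials(self) -> int:
        return len(self.blocks) * self.trials_per_block * self.n_sessions

    @classmethod
    def experiment1(
        cls, trials_per_block: int = 320, low_block_first: bool = True
    ) -> "SessionDesign":
        """Three base-rate blocks (25/50/75% category B), neutral block second.

        The order of the two biased blocks is counterbalanced across
        participants; ``low_block_first`` selects which comes first.
        """
        lo, hi = (0.25, 0.75) if low_block_first else (0.75, 0.25)
        blocks = (
            BaseRateBlock(lo, position=1),
            BaseRateBlock(0.50, position=2),
            BaseRateBlock(hi, position=3),
        )
        return cls(blocks=blocks, trials_per_block=trials_per_block, n_sessions=1)

    @classmethod
    def experiment2(
        cls, trials_per_block: int = 320, n_blocks: int = 3, n_sessions: int = 2
    ) -> "SessionDesign":
        """Uniform-base-rate blocks over two sessions (2 × 960 trials by default)."""
        blocks = tuple(BaseRateBlock(0.5, position=i + 1) for i in range(n_blocks))
        return cls(blocks=blocks, trials_per_block=trials_per_block, n_sessions=n_sessions)


@dataclass
class TrialRecord:
    """One behavioral trial; mirrors one row of the trial CSV schema."""

    participant_id: str
    group: str
    experiment: int
    block_alpha_B: float
    contrast: float
    orientation_deg: float
    true_category: str
    response: str
    confidence: int | None = None
    rt_s: float | None = None
    gamble_stake_B: int | None = None


def sample_stimuli(
    task: GaussianCategoryTask1 | EmbeddedCategoryTask2,
    alpha_b: float,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` (category, orientation) pairs from the task's stimulus mixture.

    Category B is drawn with probability ``alpha_b``; the orientation is then
    drawn from that category's Gaussian, expressed relative to the task
    reference.
    """
    if not 0 < alpha_b < 1:
        raise ValueError(f"alpha_B must lie in (0, 1); got {alpha_b}")
    is_b = rng.random(n) < alpha_b
    categories = np.where(is_b, "B", "A")
    if isinstance(task, GaussianCategoryTask1):
        loc = np.where(is_b, task.category_offset("B"), task.category_offset("A"))
        orientations = rng.normal(loc, task.sd)
    elif isinstance(task, EmbeddedCategoryTask2):
        scale = np.where(is_b, task.sd_broad, task.sd_narrow)
        orientations = rng.normal(0.0, 1.0, size=n) * scale
    else:
        raise TypeError(f"unsupported task type {type(task).__name__}")
    return categories, orientations


def sample_trial_stimulus(
    task: GaussianCategoryTask1 | EmbeddedCategoryTask2,
    alpha_b: float,
    rng: np.random.Generator,
) -> tuple[str, float]:
    """Draw one (true_category, orientation) pair; see :func:`sample_stimuli`."""
    cats, oris = sample_stimuli(task, alpha_b, 1, rng)
    return str(cats[0]), float(oris[0])


def _crossing_boundary(sigma_a: float, sigma_b: float) -> float:
    # Positive density-crossing point of two zero-mean Gaussians.
    va, vb = sigma_a**2, sigma_b**2
    return math.sqrt(2.0 * va * vb * math.log(sigma_b / sigma_a) / (vb - va))


def max_accuracy(task: GaussianCategoryTask1 | EmbeddedCategoryTask2) -> float:
    """Expected accuracy of a zero-sensory-noise observer under equal priors.

    Task 1: midpoint criterion between the category means, giving
    Φ(Δ/2s) where Δ is the mean separation and s the common sd.  Task 2:
    symmetric boundaries at the density crossing of the two category
    distributions.  The categories overlap by design, which is what caps
    performance at roughly 80% in both tasks.
    """
    if isinstance(task, GaussianCategoryTask1):
        if task.separation == 0:
            return 0.5
        return float(norm.cdf(task.separation / (2.0 * task.sd)))
    if isinstance(task, EmbeddedCategoryTask2):
        k = _crossing_boundary(task.sd_narrow, task.sd_broad)
        # P(correct) = ½·P(|x|<k | A) + ½·P(|x|>k | B)
        return float(0.5 + norm.cdf(k / task.sd_narrow) - norm.cdf(k / task.sd_broad))
    raise TypeError(f"unsupported task type {type(task).__name__}")


# ---------------------------------------------------------------------------
# Trial-table I/O

_CSV_DTYPES = {
    "participant_id": str,
    "group": str,
    "experiment": "int64",
    "block_alpha_B": float,
    "contrast": float,
    "orientation_deg": float,
    "true_category": str,
    "response": str,
}


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check a trial table against the interchange schema; returns the input."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    if len(trials):
        if not np.isfinite(trials["orientation_deg"].to_numpy(float)).all():
            raise ValueError("orientation_deg contains non-finite values")
        bad = set(trials["true_category"]) | set(trials["response"])
        if not bad <= {"A", "B"}:
            raise ValueError(f"categories must be 'A'/'B'; found {sorted(bad)}")
    return trials


def read_trials(path) -> pd.DataFrame:
    """Read a trial-level CSV in the interchange schema."""
    df = pd.read_csv(path, dtype=_CSV_DTYPES)
    for col in ("confidence", "rt_s", "gamble_stake_B"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return validate_trials(df[TRIAL_COLUMNS])


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial-level CSV in the interchange schema (absent optionals empty)."""
    validate_trials(trials)
    out = trials[TRIAL_COLUMNS].copy()
    out.to_csv(path, index=False, float_format="%.6g")
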