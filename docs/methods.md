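# Methods note

This note documents the models implemented in `critshift`, the estimation
and numerical choices, what the synthetic-data generator does and does not
cover, and known limitations. Every quantitative statement here is computed
by the test suite or by `scripts/acceptance.py`; nothing is an empirical
claim about human data.

## 1. Task models

**Shifted-mean task (experiment 1).** Stimulus orientations are drawn from
one of two Gaussian categories, A ~ N(86°, 5°) and B ~ N(94°, 5°), i.e.
±4° around a 90° reference. The per-block base rate α_B ∈ {0.25, 0.5, 0.75}
sets P(category B); a session holds three 320-trial blocks (960 trials),
with the neutral block always second and the order of the two biased blocks
counterbalanced across participants. A zero-noise observer using the
accuracy-maximizing rule under equal priors (respond B iff the orientation
exceeds the 90° midpoint) is correct with probability Φ(4/5) ≈ 0.7881 —
the task's design ceiling (target t1).

**Embedded task (experiment 2).** Both categories share the 0° mean
(relative to reference) and differ in spread: narrow A ~ N(0°, 3°), broad
B ~ N(0°, 12°), equal base rates throughout. The optimal rule is a pair of
symmetric boundaries ±k: respond "narrow" iff |x| < k. The zero-noise
optimal boundary is the density crossing, and the resulting ceiling is
≈ 0.7909 (target t2).

Both tasks present stimuli over a seven-level contrast ladder
(0.004 … 0.72), balanced within block.

## 2. Signal-detection estimation

For each participant × block × contrast cell of experiment 1 we compute

- hit rate H = P(respond B | B), false-alarm rate F = P(respond B | A),
- d′ = z(H) − z(F), criterion c = −(z(H) + z(F))/2,

with "B" playing the role of the signal, so positive c means a bias
*against* reporting B. Rates are corrected before the probit transform;
the default is the log-linear rule (count + 0.5)/(n + 1) applied to every
cell, with hard clamping to [1/2n, 1 − 1/2n] available as an alternative.
The corrections differ in the extreme cells: a perfect 20/20 vs 0/20 cell
yields d′ = 2·z(20.5/21) ≈ 3.96 under the log-linear rule.

**Ideal observer.** With base rate α for the signal category, the optimal
likelihood-ratio criterion is β_opt = (1 − α)/α and its location on the
criterion axis is c_opt = ln(β_opt)/d′, evaluated at the participant's own
estimated d′. Two derived quantities index prior use:

- **D_criterion** = c(α = 0.75) − c(α = 0.25), negative for an observer who
  shifts with the prior; its ideal magnitude 2·ln(3)/d′ grows as d′ falls.
- **c_error** = sign(c_opt)·(c_opt − c) per biased cell, averaged over the
  two biased blocks at each contrast. The sign normalization makes the two
  biased blocks symmetric, so 0 is "ideal", positive is "under-shifted".
  c_opt is undefined at d′ = 0; the pipeline maps non-positive-d′ cells to
  c_error = +∞ so that the exclusion rule (below) catches them rather than
  silently averaging them.

## 3. Embedded-task estimator

The observer's internal measurement is x ~ N(s, σ_sens) for a stimulus s
from a category with spread s_cat, so the measurement distribution of a
category has spread σ_cat = √(s_cat² + σ_sens²). With symmetric boundaries
±k the forward model is

p(report narrow) = 2Φ(k/σ_cat) − 1,

inverted by k = σ_cat · z((1 + p)/2). Given the two per-category report
proportions (log-linear corrected counts), the two-step fit:

1. finds σ_sens minimizing the squared gap [k_A(σ) − k_B(σ)]² between the
   boundaries implied by each category,
2. returns k as the mean of the two implied boundaries at that σ.

Numerics: the σ search runs over [0, 100]. When the gap changes sign in
that interval the root is found exactly with Brent's method; the root is
also the global minimizer of the squared gap, and bounded L-BFGS-B from
multi-starts {0.5, 2, 8, 32} plus the interval endpoints covers the
no-sign-change case. A fit is flagged `converged=False` when the residual
objective exceeds 1e−8 — this happens when the proportions are
irreconcilable (narrow reported less often under the narrow category);
such fits still return finite values and are excluded from group tables.
A cross-check in the test suite shows the two-step fit agrees with a joint
binomial maximum-likelihood fit to within 0.02 on both parameters at
n = 5000 per category.

**Optimal boundary.** The accuracy-maximizing boundary for two zero-mean
Gaussians with spreads σ_A < σ_B (after convolution with σ_sens) is the
density crossing

k_opt = √( 2·σ_A²σ_B²·ln(σ_B/σ_A) / (σ_B² − σ_A²) ),

verified against a brute-force grid maximizer to ≤ 0.01° over
σ_sens ∈ {0, 1, 2, 5, 10, 20}. k_opt(0) ≈ 5.16° and widens monotonically
with sensory noise. **k_error** = k − k_opt(σ̂_sens) is the signed
deviation from the ideal boundary at the participant's own fitted noise.

## 4. Exclusion rules

Two stages, applied to per-participant summaries; a participant is reported
with the first rule violated in precedence order:

| stage | rule | condition |
|---|---|---|
| all | accuracy | mean accuracy over the 3 highest contrasts < 0.6 |
| all (exp 2) | extreme_k | any fitted k > 100 |
| all (exp 2) | extreme_sigma | any fitted σ_sens > 100 |
| optimality (exp 1) | c_error | any per-contrast c_error > 50 |
| optimality (exp 2) | k_error | any per-contrast \|k_error\| > 35 |

Thresholds are strict inequalities (a value exactly at the threshold is
retained). The k_error rule is applied to the absolute value; the package
exposes the signed k_error, and the sign handling of the threshold is a
documented choice rather than an externally fixed convention.

## 5. Synthetic-data generator

Per-trial generative observer with parameters (defaults in parentheses):

| parameter | default | role |
|---|---|---|
| σ_floor (2.0), a (0.08), b (0.9) | — | sensory noise σ(c) = σ_floor + a·c^(−b), decreasing in contrast c |
| prior_weight w (1.0) | ∈ [0, 1] | weight on the log prior odds in the experiment-1 criterion |
| boundary_scale γ (1.0) | > 0 | multiplies the experiment-2 boundary: k_obs = γ·k_opt(ρ·σ(c)) |
| noise_misestimate ρ (1.0) | > 0 | mis-estimation of own noise when placing the boundary |
| lapse_rate λ (0.02) | ∈ [0, 0.2] | probability of replacing the response with a fair coin |
| gamble_weight, gamble_sd | 1.0, 5.0 | betting on check trials: stake ≈ 99·(w_g·α + (1−w_g)/2) + noise |

Experiment-1 rule: respond B iff x > w·ln((1−α)/α)·(s² + σ²)/Δ, which is
the ideal criterion scaled by w; its closed-form criterion shift is
D = −2·ln(3)·w·σ_tot/Δ. Experiment-2 rule: respond narrow iff
|x| < γ·k_opt(ρ·σ(c)). Cohorts draw per-participant parameters from
truncated normals around group means (numpy `SeedSequence` spawning gives
bit-for-bit reproducibility from one master seed), and every cohort returns
a ground-truth table joinable 1:1 to the trial table.

**Scope.** The generator covers criterion placement, boundary placement,
lapses, and betting. It does not model reaction times, confidence,
learning/drift within a block, serial dependence, or stimulus-level
features (it samples orientations directly, not gratings). Consequently the
test suite validates *estimator correctness and qualitative signatures
under the stated generative model* — it cannot show that human data satisfy
that model, nor reproduce group statistics of any empirical dataset.

## 6. Analysis pipeline choices

- **Psychometric tables** bin signed orientation (degrees from reference)
  to 15 centers −14°…+14° in 2° steps, nearest-center with ties going
  clockwise and out-of-range values clamped to the end bins. Proportions
  are computed per participant, then averaged with across-participant SE.
- **Problem sizes in validation** are this package's own choices: the
  recovery study uses a (σ_sens ∈ {1,3,6,12}) × (k ∈ {3,6,9}) factorial
  with 10⁴ trials per contrast cell (5000 per category under equal priors)
  and reports pooled median absolute relative error (< 5% for both
  parameters, seed 0). The optimal-observer null uses 28 exactly ideal
  observers with ~10⁴ trials per contrast cell and a seed fixed before the
  check was first run. At n = 5000 per category the (σ, k) estimates are
  unbiased but a ±0.2 box around the truth covers only ~74–77% of seeds;
  ±0.2 coverage reaches ~97% at n = 20000 per category.
- **Determinism**: analysis outputs are pure functions of the input table
  and config; `write_tables` emits CSVs (`%.8g`) plus a JSON metadata
  sidecar with a config hash and no timestamps, so re-runs are
  byte-identical.

## 7. Limitations

- γ and ρ are not jointly identifiable from a single contrast: both scale
  the observed boundary. The generator keeps them separate for expressing
  hypotheses (miscalibrated boundary vs misestimated noise); fits recover
  only the product's effect, k_obs.
- The two-step embedded fit uses only the two per-category proportions and
  ignores trial order; it is near-efficient relative to joint ML (see §3)
  but cannot capture within-block nonstationarity.
- c_opt diverges as d′ → 0, so c_error is heavy-tailed at the lowest
  contrast; group summaries therefore report c_error after the optimality-
  stage exclusions, and cells with non-positive d′ are pushed to the
  exclusion rule rather than imputed.
- The 15-bin psychometric grid (±14°, 2° steps) is a display/aggregation
  choice; analyses never depend on the binning.
- Parameter bounds (e.g. σ_sens ∈ [0, 100], k ∈ (0, 100]) are pragmatic
  search ranges, not claims about plausible human values; the exclusion
  thresholds deliberately sit at those scales so runaway fits are flagged,
  not truncated silently.
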