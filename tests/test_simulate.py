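"""Generative observer models and cohort simulation."""

import math

import numpy as np
import pandas as pd
import pytest

from critshift.embedded import optimal_boundary
from critshift.pipeline import run_experiment1_analysis
from critshift.sdt import count_responses, estimate_dprime_criterion
from critshift.simulate import (
    CohortConfig,
    ObserverParams,
    decision_threshold_exp1,
    expected_d_criterion,
    ideal_cohort,
    load_cohort_config,
    null_cohort,
    observed_boundary,
    save_cohort_config,
    simulate_cohort,
    simulate_gamble_responses,
    simulate_participant_exp1,
    simulate_participant_exp2,
)
from critshift.tasks import DEFAULT_CONTRASTS, SessionDesign, max_accuracy


def _flat_noise(sigma: float, **kw) -> ObserverParams:
    return ObserverParams(sigma_floor=sigma, noise_scale=0.0, lapse_rate=0.0, **kw)


class TestObserverParams:
    def test_noise_map_decreases_with_contrast(self):
        p = ObserverParams()
        sig = p.sigma_sens(np.asarray(DEFAULT_CONTRASTS))
        assert np.all(np.diff(sig) < 0)
        assert np.all(sig > 0)

    def test_validation(self):
        with pytest.raises(ValueError, match="lapse_rate"):
            ObserverParams(lapse_rate=0.5)
        with pytest.raises(ValueError, match="prior_weight"):
            ObserverParams(prior_weight=2.0)


class TestExp1Observer:
    def test_neutral_block_threshold_is_midpoint(self):
        assert decision_threshold_exp1(ObserverParams(), 0.5, 0.18) == 0.0

    def test_threshold_closed_form(self):
        # sd=5, sigma=5, means ±4: x* = ln(1/3)·50/8 ≈ −6.87° (liberal toward B)
        p = _flat_noise(5.0)
        assert decision_threshold_exp1(p, 0.75, 0.18) == pytest.approx(-6.8663, abs=1e-3)

    def test_sensitivity_rises_and_shift_shrinks_with_contrast(self):
        p = ObserverParams(lapse_rate=0.0)
        trials = simulate_participant_exp1(
            p, SessionDesign.experiment1(trials_per_block=21_000), seed=5, check_rate=0
        )
        ests = {
            c.cell[1:]: estimate_dprime_criterion(c) for c in count_responses(trials)
        }
        d_low = np.mean([ests[(a, 0.004)].d_prime for a in (0.25, 0.5, 0.75)])
        d_high = np.mean([ests[(a, 0.72)].d_prime for a in (0.25, 0.5, 0.75)])
        assert d_high > d_low + 0.5
        shift_low = ests[(0.75, 0.004)].criterion_c - ests[(0.25, 0.004)].criterion_c
        shift_high = ests[(0.75, 0.72)].criterion_c - ests[(0.25, 0.72)].criterion_c
        assert abs(shift_low) > abs(shift_high)
        # both negative: prior-consistent shift under this sign convention
        assert shift_low < 0 and shift_high < 0

    def test_accuracy_never_beats_the_ideal_ceiling(self, task1):
        trials = simulate_participant_exp1(
            ObserverParams(), SessionDesign.experiment1(trials_per_block=3500), seed=7
        )
        ceiling = max_accuracy(task1)
        for contrast, sub in trials.groupby("contrast"):
            acc = (sub["response"] == sub["true_category"]).mean()
            se = math.sqrt(ceiling * (1 - ceiling) / len(sub))
            assert acc <= ceiling + 3 * se

    def test_expected_criterion_shift_closed_form(self):
        # ideal observer at d'=1 (sigma_tot = 8): |D| = 2·ln3/d' ≈ 2.197
        p = _flat_noise(math.sqrt(64.0 - 25.0))
        assert expected_d_criterion(p, 0.18) == pytest.approx(-2.1972, abs=1e-4)
        half = _flat_noise(math.sqrt(64.0 - 25.0), prior_weight=0.5)
        assert expected_d_criterion(half, 0.18) == pytest.approx(-2.1972 / 2, abs=1e-4)

    def test_prior_ignoring_observer_does_not_shift(self):
        p = ObserverParams(prior_weight=0.0, lapse_rate=0.0)
        trials = simulate_participant_exp1(
            p, SessionDesign.experiment1(trials_per_block=7000), seed=9, check_rate=0
        )
        ests = {c.cell[1:]: estimate_dprime_criterion(c) for c in count_responses(trials)}
        shifts = [
            ests[(0.75, c)].criterion_c - ests[(0.25, c)].criterion_c
            for c in DEFAULT_CONTRASTS
        ]
        assert abs(np.mean(shifts)) < 0.05


class TestExp2Observer:
    def test_flat_noise_keeps_boundary_constant(self):
        p = _flat_noise(4.0)
        ks = [observed_boundary(p, c) for c in DEFAULT_CONTRASTS]
        assert np.ptp(ks) < 1e-12
        assert ks[0] == pytest.approx(optimal_boundary(4.0).k_opt, rel=1e-12)

    def test_conservative_boundary_scale_yields_negative_k_error(self):
        from critshift.pipeline import run_experiment2_analysis

        p = ObserverParams(boundary_scale=0.7, lapse_rate=0.0)
        trials = simulate_participant_exp2(
            p, SessionDesign.experiment2(trials_per_block=5834), seed=13, check_rate=0
        )
        tables = run_experiment2_analysis(trials)
        fits = tables["fits"]
        assert (fits["k_error"] < 0).all()

    def test_boundary_shrinks_by_scale(self):
        p = ObserverParams(boundary_scale=0.7)
        ref = ObserverParams()
        for c in (0.004, 0.72):
            assert observed_boundary(p, c) == pytest.approx(0.7 * observed_boundary(ref, c))


class TestGamble:
    def test_calibrated_stake_closed_form(self, rng):
        p = ObserverParams(gamble_weight=1.0, gamble_sd=0.0)
        stakes = simulate_gamble_responses(p, [0.75], 5, rng)
        assert (stakes == 74).all()  # round(99·0.75) = round(74.25)

    def test_knowledge_free_gambler_stakes_half(self, rng):
        p = ObserverParams(gamble_weight=0.0, gamble_sd=0.0)
        stakes = simulate_gamble_responses(p, [0.25, 0.5, 0.75], 5, rng)
        assert (stakes == 50).all()

    def test_block_ordering(self, rng):
        p = ObserverParams(gamble_weight=1.0, gamble_sd=5.0)
        stakes = simulate_gamble_responses(p, [0.25, 0.5, 0.75], 400, rng)
        means = stakes.mean(axis=1)
        assert means[0] < means[1] < means[2]
        assert means[0] == pytest.approx(24.75, abs=1.0)
        assert means[2] == pytest.approx(74.25, abs=1.0)

    def test_requires_at_least_one_check(self, rng):
        with pytest.raises(ValueError, match="n_checks"):
            simulate_gamble_responses(ObserverParams(), [0.5], 0, rng)


class TestCohorts:
    def test_determinism_bit_for_bit(self, tmp_path):
        cfg = null_cohort(1, seed=42, trials_per_block=70)
        t1, g1 = simulate_cohort(cfg)
        t2, g2 = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(g1, g2)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        t1.to_csv(p1, index=False)
        t2.to_csv(p2, index=False)
        assert p1.read_bytes() == p2.read_bytes()

    def test_cohort_sizes_match_config(self):
        cfg = CohortConfig(
            experiment=1,
            n_per_group={"autistic": 4, "non-autistic": 6},
            trials_per_block=70,
        )
        trials, truth = simulate_cohort(cfg)
        assert len(truth) == 10
        assert truth.groupby("group").size().to_dict() == {
            "autistic": 4,
            "non-autistic": 6,
        }
        assert trials["participant_id"].nunique() == 10
        assert len(trials) == 10 * 3 * 70

    def test_ground_truth_joins_one_to_one(self):
        cfg = ideal_cohort(2, n_participants=3, trials_per_block=70, seed=5)
        trials, truth = simulate_cohort(cfg)
        assert set(trials["participant_id"]) == set(truth["participant_id"])
        assert truth["participant_id"].is_unique
        assert "k_obs_true_0.72" in truth.columns

    def test_group_difference_shows_in_criterion_shift(self):
        from critshift.simulate import altered_integration_cohort

        cfg = altered_integration_cohort(1, seed=3, trials_per_block=2100)
        cfg = CohortConfig(
            **{
                **cfg.__dict__,
                "n_per_group": {"autistic": 8, "non-autistic": 8},
                "param_sds": {},
            }
        )
        trials, _ = simulate_cohort(cfg)
        tables = run_experiment1_analysis(trials)
        d = tables["group_d_criterion"]
        low = d[d["contrast"] == 0.004].set_index("group")["mean"]
        # under-weighted prior: smaller |D| in the autistic group
        assert abs(low["autistic"]) < abs(low["non-autistic"])

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = null_cohort(2, seed=9)
        path = tmp_path / "cohort.yaml"
        save_cohort_config(cfg, path)
        back = load_cohort_config(path)
        assert back == cfg

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="n_per_group"):
            CohortConfig(n_per_group={"autistic": 0, "non-autistic": 5})
        with pytest.raises(ValueError, match="param_sds"):
            CohortConfig(param_sds={"bogus_field": 1.0})
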