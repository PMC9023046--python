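"""Tests for the respondent-level simulator and Monte-Carlo power."""

import numpy as np
import pytest

from crosswise import (
    BehaviorParams,
    CrosswiseError,
    RandomizationDesign,
    cwm_estimate,
    dq_estimate,
    ecwm_pooled_mle,
    expected_ecwm_estimate,
    power_simulation,
    simulate_design,
    simulate_dq,
    simulate_ecwm,
)

DESIGNS = (RandomizationDesign(0.158, "p1"), RandomizationDesign(0.842, "p2"))


class TestSimulateDQ:
    def test_sd_misreporting_shrinks_undesirable_rate(self):
        """Undesirable attribute: agree-rate converges to pi*(1-s)."""
        params = BehaviorParams(pi_true=0.4, desirability="undesirable", sd_rate_dq=0.25)
        _, arm = simulate_dq(200_000, params, seed=11)
        assert arm.frequency == pytest.approx(0.30, abs=0.005)

    def test_sd_misreporting_inflates_desirable_rate(self):
        params = BehaviorParams(pi_true=0.4, desirability="desirable", sd_rate_dq=0.25)
        _, arm = simulate_dq(200_000, params, seed=11)
        assert arm.frequency == pytest.approx(0.4 + 0.6 * 0.25, abs=0.005)

    def test_pure_noise_gives_half(self):
        params = BehaviorParams(pi_true=0.5, gamma_random=1.0)
        _, arm = simulate_dq(100_000, params, seed=3)
        assert arm.frequency == pytest.approx(0.5, abs=0.01)

    def test_honest_regime_recovers_prevalence(self):
        """Emulates a high-prevalence benchmark arm: estimate within 2 SE."""
        params = BehaviorParams(pi_true=0.8395)
        _, arm = simulate_dq(542, params, seed=42)
        est = dq_estimate(arm)
        assert abs(est.pi_hat - 0.8395) < 2 * est.se

    def test_rejects_empty_arm(self):
        with pytest.raises(CrosswiseError):
            simulate_dq(0, BehaviorParams(pi_true=0.5), seed=1)


class TestSimulateECWM:
    def test_honest_answer_matches_latent_statuses(self):
        recs, _ = simulate_ecwm(5000, BehaviorParams(pi_true=0.3), DESIGNS[0], seed=5)
        match = recs["carrier"] == recs["nonsensitive_true"]
        assert (recs["answer"] == match.astype(int)).all()

    def test_random_responding_biases_toward_half(self):
        """E[pi_hat] = (1-gamma)*pi + gamma/2 under pure random responding."""
        params = BehaviorParams(pi_true=0.3, gamma_random=0.2)
        _, arm = simulate_ecwm(400_000, params, DESIGNS[0], seed=9)
        est = cwm_estimate(arm, DESIGNS[0])
        assert est.pi_hat == pytest.approx(0.34, abs=3 * est.se)

    def test_half_is_fixed_point_of_noise_bias(self):
        params = BehaviorParams(pi_true=0.5, gamma_random=0.4)
        _, arm = simulate_ecwm(400_000, params, DESIGNS[1], seed=13)
        est = cwm_estimate(arm, DESIGNS[1])
        assert est.pi_hat == pytest.approx(0.5, abs=3 * est.se)

    def test_bias_law_across_grid(self):
        """The toward-50% law holds across gamma and pi jointly."""
        rng = np.random.default_rng(2024)
        n = 150_000
        for gamma in (0.0, 0.1, 0.3, 0.5):
            for pi in (0.1, 0.3, 0.5, 0.7, 0.9):
                params = BehaviorParams(pi_true=pi, gamma_random=gamma)
                _, arm = simulate_ecwm(n, params, DESIGNS[0], rng=rng)
                est = cwm_estimate(arm, DESIGNS[0])
                assert expected_ecwm_estimate(params) == pytest.approx(
                    (1 - gamma) * pi + gamma / 2, abs=1e-12)
                assert est.pi_hat == pytest.approx(
                    (1 - gamma) * pi + gamma / 2, abs=4 * est.se)

    def test_option_preference_splits_group_estimates(self):
        """beta > 0 raises the low-p estimate and lowers the high-p estimate."""
        from crosswise import ecwm_fit_test

        params = BehaviorParams(pi_true=0.7, beta_exactly_one=0.15)
        _, a1 = simulate_ecwm(50_000, params, DESIGNS[0], seed=21)
        _, a2 = simulate_ecwm(50_000, params, DESIGNS[1], seed=22)
        e1 = cwm_estimate(a1, DESIGNS[0]).pi_hat
        e2 = cwm_estimate(a2, DESIGNS[1]).pi_hat
        assert e1 > 0.7 > e2
        assert ecwm_fit_test(a1, DESIGNS[0], a2, DESIGNS[1]).p_value < 0.001

    def test_gamma_plus_beta_validated(self):
        with pytest.raises(CrosswiseError):
            BehaviorParams(pi_true=0.5, gamma_random=0.6, beta_exactly_one=0.5)


class TestParameterRecovery:
    def test_pooled_estimator_unbiased_and_se_calibrated(self):
        """Under honest behavior the pooled MLE is unbiased and the Fisher SE
        matches the sampling SD."""
        rng = np.random.default_rng(99)
        pi_true, n = 0.35, 1000
        params = BehaviorParams(pi_true=pi_true)
        ests, ses = [], []
        for _ in range(500):
            from crosswise.simulate import _counts_only_ecwm

            _, a1 = _counts_only_ecwm(n, params, DESIGNS[0], rng)
            _, a2 = _counts_only_ecwm(n, params, DESIGNS[1], rng)
            est = ecwm_pooled_mle(a1, DESIGNS[0], a2, DESIGNS[1])
            ests.append(est.pi_hat)
            ses.append(est.se)
        assert abs(np.mean(ests) - pi_true) < 0.01
        assert np.std(ests) == pytest.approx(np.mean(ses), rel=0.10)

    def test_crosswise_less_efficient_than_dq(self):
        """At equal n the crosswise SE exceeds the DQ SE (hence 2:1 allocation)."""
        n, pi = 500, 0.3
        se_dq = dq_estimate(
            simulate_dq(n, BehaviorParams(pi_true=pi), seed=1)[1]).se
        se_cwm = cwm_estimate(
            simulate_ecwm(n, BehaviorParams(pi_true=pi), DESIGNS[0], seed=1)[1],
            DESIGNS[0]).se
        assert se_cwm > 1.3 * se_dq


class TestSimulateDesign:
    CELLS = {
        ("undesirable", "low"): BehaviorParams(pi_true=0.25),
        ("undesirable", "high"): BehaviorParams(pi_true=0.75),
    }
    SIZES = {
        ("undesirable", "low"): {"ECWM_p1": 538, "ECWM_p2": 535, "DQ": 545},
        ("undesirable", "high"): {"ECWM_p1": 541, "ECWM_p2": 538, "DQ": 553},
    }

    def test_recovers_cell_prevalences(self):
        """Cell estimates are calibrated: ~95% of draws land within 2 SE."""
        hits = total = 0
        for seed in range(40):
            _, counts = simulate_design(self.CELLS, self.SIZES, DESIGNS, seed=seed)
            for key, params in self.CELLS.items():
                est = ecwm_pooled_mle(
                    counts[key + ("ECWM_p1",)], DESIGNS[0],
                    counts[key + ("ECWM_p2",)], DESIGNS[1])
                hits += abs(est.pi_hat - params.pi_true) < 2 * est.se
                dq = dq_estimate(counts[key + ("DQ",)])
                hits += abs(dq.pi_hat - params.pi_true) < 2 * dq.se
                total += 2
        assert hits / total >= 0.88

    def test_same_seed_identical_output(self, tmp_path):
        f1, f2 = tmp_path / "a.csv", tmp_path / "b.csv"
        for f in (f1, f2):
            records, _ = simulate_design(self.CELLS, self.SIZES, DESIGNS, seed=7,
                                         keep_latent=True)
            records.to_csv(f, index=False)
        assert f1.read_bytes() == f2.read_bytes()

    def test_zero_arm_size_rejected(self):
        sizes = {("undesirable", "low"): {"ECWM_p1": 0, "ECWM_p2": 10, "DQ": 10}}
        cells = {("undesirable", "low"): BehaviorParams(pi_true=0.2)}
        with pytest.raises(CrosswiseError):
            simulate_design(cells, sizes, DESIGNS, seed=1)

    def test_missing_cell_sizes_rejected(self):
        with pytest.raises(CrosswiseError):
            simulate_design(self.CELLS, {}, DESIGNS, seed=1)


class TestPower:
    def test_null_regimes_give_alpha_level_power(self):
        regime = BehaviorParams(pi_true=0.4)
        res = power_simulation(regime, regime, n_dq=300, n_ecwm_per_group=300,
                               designs=DESIGNS, alpha=0.05, reps=400, seed=17)
        assert res.power == pytest.approx(0.05, abs=0.04)

    def test_power_increases_with_n(self):
        """A 10-point DQ-vs-crosswise gap: power grows with arm size."""
        dq_regime = BehaviorParams(pi_true=0.4, sd_rate_dq=0.25)  # observed ~.30
        ecwm_regime = BehaviorParams(pi_true=0.4)
        powers = []
        for n in (250, 1000):
            res = power_simulation(dq_regime, ecwm_regime, n_dq=n,
                                   n_ecwm_per_group=n, designs=DESIGNS,
                                   alpha=0.05, reps=300, seed=23)
            assert res.mc_se <= 0.03
            powers.append(res.power)
        assert powers[1] > powers[0]
        assert 0 < powers[0] < 1

    def test_study_scale_design_is_well_powered(self):
        """A 10-point effect at the study's arm sizes clears 80% power."""
        dq_regime = BehaviorParams(pi_true=0.40, sd_rate_dq=0.25)
        ecwm_regime = BehaviorParams(pi_true=0.40)
        res = power_simulation(dq_regime, ecwm_regime, n_dq=545,
                               n_ecwm_per_group=537, designs=DESIGNS,
                               alpha=0.05, reps=300, seed=29)
        assert res.power >= 0.80

    def test_too_few_reps_rejected(self):
        regime = BehaviorParams(pi_true=0.4)
        with pytest.raises(CrosswiseError):
            power_simulation(regime, regime, 100, 100, DESIGNS, 0.05, reps=50, seed=1)
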