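"""Activation-to-angle regression and grip-force readout."""

import numpy as np
import pytest

import wristsyn as ws
from wristsyn.exceptions import CalibrationError
from wristsyn.model import estimate_grip_force, predict_sum_diff


class TestFitRegression:
    def test_exact_recovery_without_noise(self):
        rng = np.random.default_rng(0)
        M = rng.uniform(0, 1, (200, 4))
        a0 = np.array([0.3, -0.2])
        A = rng.normal(size=(4, 2))
        targets = a0 + M @ A
        reg = ws.fit_regression(M, targets)
        np.testing.assert_allclose(reg.intercept, a0, atol=1e-9)
        np.testing.assert_allclose(reg.coef, A, atol=1e-9)

    def test_constant_target_gives_pure_bias(self):
        rng = np.random.default_rng(1)
        M = rng.uniform(0, 1, (50, 3))
        targets = np.full((50, 2), 0.7)
        reg = ws.fit_regression(M, targets)
        np.testing.assert_allclose(reg.intercept, 0.7, atol=1e-9)
        np.testing.assert_allclose(reg.coef, 0.0, atol=1e-9)

    def test_hand_solved_three_sample_toy(self):
        # normal equations for M=[[0],[1],[2]], u=[1,3,5]: a0=1, a=2
        M = np.array([[0.0], [1.0], [2.0]])
        targets = np.column_stack([[1.0, 3.0, 5.0], [1.0, 3.0, 5.0]])
        reg = ws.fit_regression(M, targets)
        np.testing.assert_allclose(reg.intercept, [1.0, 1.0], atol=1e-10)
        np.testing.assert_allclose(reg.coef, [[2.0, 2.0]], atol=1e-10)

    def test_rank_deficient_warns(self):
        M = np.zeros((10, 2))
        M[:, 0] = np.arange(10.0)
        # second column duplicates the first -> singular design
        M[:, 1] = M[:, 0]
        with pytest.warns(UserWarning, match="rank-deficient"):
            ws.fit_regression(M, np.ones((10, 2)))

    def test_coefficient_coverage_three_standard_errors(self):
        # noisy refits recover truth within 3 SE for >= 95% of coefficients
        rng = np.random.default_rng(42)
        a0 = np.array([0.1, -0.4])
        A = np.array([[0.8, -0.3], [0.2, 0.9], [-0.5, 0.4]])
        hits = total = 0
        for _ in range(20):
            M = rng.uniform(0, 1, (300, 3))
            targets = a0 + M @ A + rng.normal(0, 0.05, (300, 2))
            reg = ws.fit_regression(M, targets)
            est = np.vstack([reg.intercept, reg.coef])
            true = np.vstack([a0, A])
            hits += np.sum(np.abs(est - true) <= 3 * reg.bse)
            total += est.size
        assert hits / total >= 0.95


class TestPrediction:
    def test_affine_in_activations(self):
        rng = np.random.default_rng(2)
        reg = ws.fit_regression(
            rng.uniform(0, 1, (50, 3)), rng.normal(size=(50, 2))
        )
        M1 = rng.uniform(0, 1, (20, 3))
        M2 = rng.uniform(0, 1, (20, 3))
        alpha = 0.3
        lhs = predict_sum_diff(alpha * M1 + (1 - alpha) * M2, reg)
        rhs = alpha * predict_sum_diff(M1, reg) + (1 - alpha) * predict_sum_diff(
            M2, reg
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_zero_activation_gives_bias_angle(self):
        rng = np.random.default_rng(3)
        reg = ws.fit_regression(
            rng.uniform(0, 1, (50, 2)), rng.normal(size=(50, 2))
        )
        norm = ws.AngleNormalizer(45.0, 30.0)
        out = ws.predict_angles(np.zeros((5, 2)), reg, norm)
        expected = norm.inverse(reg.intercept[None, :])
        np.testing.assert_allclose(out, np.repeat(expected, 5, axis=0), atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        reg = ws.fit_regression(rng.uniform(0, 1, (30, 3)), rng.normal(size=(30, 2)))
        with pytest.raises(ValueError):
            predict_sum_diff(np.zeros((5, 2)), reg)


class TestGripForce:
    def test_linearity_and_zero(self):
        M = np.zeros((10, 3))
        assert np.all(estimate_grip_force(M, 2, 1.5) == 0)
        M[:, 2] = 2.0
        np.testing.assert_allclose(estimate_grip_force(M, 2, 1.5), 3.0)

    def test_training_trial_calibrates_to_unit_peak(self, noiseless_trials):
        wrist = [t for t in noiseless_trials if t.condition == "comfortable_max"]
        grip = [t for t in noiseless_trials if t.condition == "grip_only"]
        res = ws.SynergyLRM(
            wrist[:1], grip[:1], strategy="slrm2",
            hals=ws.HALSConfig(n_restarts=3, seed=0),
        ).fit()
        est = res.estimate_grip_force(grip[0].E)
        assert est.max() == pytest.approx(1.0, abs=1e-9)

    def test_silent_grip_trial_fails_calibration(self, noiseless_trials):
        from wristsyn.exceptions import DegenerateDataError
        from wristsyn.preprocess import AlignedTrial

        wrist = [t for t in noiseless_trials if t.condition == "comfortable_max"]
        silent = AlignedTrial(
            condition="grip_only",
            E=np.zeros_like(wrist[0].E),
            angles=np.zeros_like(wrist[0].angles),
            force=None,
            rate=wrist[0].rate,
        )
        with pytest.raises((CalibrationError, DegenerateDataError)):
            ws.SynergyLRM(
                wrist[:1], [silent], strategy="slrm2",
                hals=ws.HALSConfig(n_restarts=2, seed=0),
            ).fit()

    def test_quarter_force_plateau_recovered(self):
        gt = ws.make_ground_truth(seed=11, noise_snr_db=20.0)
        protocol = [
            ws.TrialSpec("comfortable_max"),
            ws.TrialSpec("grip_only"),
            ws.TrialSpec("force_quarter"),
        ]
        sess = ws.generate_session(gt, protocol, seed=11)
        trials = ws.preprocess_session(sess)
        res = ws.SynergyLRM(
            [trials[0]], [trials[1]], strategy="slrm2",
            hals=ws.HALSConfig(seed=0),
        ).fit()
        quarter = trials[2]
        est = res.estimate_grip_force(quarter.E)
        plateau = quarter.force > 0.99 * quarter.force.max()
        assert np.mean(est[plateau]) == pytest.approx(0.25, abs=0.1)


def test_results_summary_mentions_strategy(noiseless_trials):
    wrist = [t for t in noiseless_trials if t.condition == "comfortable_max"]
    grip = [t for t in noiseless_trials if t.condition == "grip_only"]
    res = ws.SynergyLRM(
        wrist[:1], grip[:1], strategy="slrm2",
        hals=ws.HALSConfig(n_restarts=2, seed=0),
    ).fit()
    text = res.summary()
    assert "slrm2" in text and "grip gain" in text
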