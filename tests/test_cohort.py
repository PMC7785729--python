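"""Synthetic cohort: covariate structure, forward model, SCR generator."""

import numpy as np
import pandas as pd
import pytest

import yokedbml.cohort as co
import yokedbml.glm as fl
import yokedbml.paradigm as par
from yokedbml.cohort import (CalibrationError, CovariateCalibration,
                             GroundTruth, generate_covariates, simulate_roi_bold,
                             simulate_scr, simulate_voxel_volumes)


class TestCovariates:
    def test_large_sample_correlations(self):
        """Empirical correlations converge to the calibration targets."""
        tab = generate_covariates(2000, seed=3)
        pp, pr = tab.participants, tab.pairs
        assert np.corrcoef(pp.state, pp.trait)[0, 1] == pytest.approx(0.5, abs=0.05)
        assert np.corrcoef(pr.StateAnxietyAVG, pr.StateAnxietyDIFF)[0, 1] == \
            pytest.approx(0.05, abs=0.06)
        assert np.corrcoef(pr.TraitAnxietyAVG, pr.TraitAnxietyDIFF)[0, 1] == \
            pytest.approx(-0.22, abs=0.06)

    def test_zero_calibration_independence(self):
        cal = CovariateCalibration(state_trait=0.0, state_avg_diff=0.0,
                                   trait_avg_diff=0.0)
        tab = generate_covariates(3000, calibration=cal, seed=1)
        pp = tab.participants
        assert abs(np.corrcoef(pp.state, pp.trait)[0, 1]) < 0.06

    def test_minimal_two_pairs(self):
        tab = generate_covariates(2, seed=0)
        assert len(tab.participants) == 4
        assert len(tab.pairs) == 2
        u = tab.participants.query("group == 'UNCTL'").sort_values("pair")
        c = tab.participants.query("group == 'CTL'").sort_values("pair")
        assert np.allclose(u.state.to_numpy() - c.state.to_numpy(),
                           tab.pairs.StateAnxietyDIFF)
        assert np.allclose((u.state.to_numpy() + c.state.to_numpy()) / 2,
                           tab.pairs.StateAnxietyAVG)

    def test_non_psd_calibration_raises(self):
        bad = CovariateCalibration(state_trait=0.99, trait_avg_diff=-0.99,
                                   state_avg_diff=0.99)
        with pytest.raises(CalibrationError):
            generate_covariates(10, calibration=bad, seed=0)

    def test_each_pair_one_member_per_group(self):
        tab = generate_covariates(10, seed=5)
        counts = tab.participants.groupby(["pair", "group"]).size()
        assert (counts == 1).all()


class TestGroundTruth:
    def test_invalid_ar1(self):
        with pytest.raises(ValueError, match="AR"):
            GroundTruth(ar1=1.2)

    def test_unknown_effect_roi(self):
        with pytest.raises(ValueError, match="effect_map"):
            GroundTruth(effect_map={"not_a_region": 0.1})

    def test_coupling_range(self):
        with pytest.raises(CalibrationError):
            GroundTruth(scr_coupling={"CTL": 1.5, "UNCTL": 0.0})


class TestROIBold:
    def test_null_effect_noise_off_groups_identical(self, default_session,
                                                    default_behavior):
        amps = dict(GroundTruth().task_amps, presses_parametric=0.0)
        truth = GroundTruth(seed=0, effect_map={}, trial_amp_sd=0.0,
                            task_amps=amps)
        a = simulate_roi_bold(default_session, default_behavior, truth, "CTL", 0,
                              noise=False)
        b = simulate_roi_bold(default_session, default_behavior, truth, "UNCTL", 0,
                              noise=False)
        assert np.allclose(a.data.to_numpy(), b.data.to_numpy())

    def test_forward_inverse_exact(self, default_session, default_behavior):
        """Noise off: the first-level GLM recovers every injected amplitude."""
        truth = GroundTruth(seed=0, trial_amp_sd=0.0)
        ts = simulate_roi_bold(default_session, default_behavior, truth, "UNCTL", 0,
                               noise=False)
        beh = default_behavior
        ev = pd.DataFrame({"onset": beh.onsets(), "duration": beh.durations(),
                           "trial_type": "stressor",
                           "n_presses": beh.press_counts("UNCTL").astype(float)})
        X = fl.build_design(ev, default_session, tr=truth.tr)
        Y = fl.normalize_intensity(ts.data.to_numpy(), ts.run_index)
        res = fl.fit_glm(Y, X)
        b = res.betas[X.columns.index("stressor")]
        expected = np.array([truth.stressor_amp + truth.effect_map.get(r, 0.0)
                             for r in truth.roi_names])
        assert np.allclose(b, expected, atol=1e-6)

    def test_ar1_autocorrelation(self, default_session, default_behavior):
        """Residual noise carries the configured lag-1 autocorrelation."""
        truth = GroundTruth(seed=3, ar1=0.3, drift_sd=0.0)
        ts = simulate_roi_bold(default_session, default_behavior, truth, "CTL", 0)
        beh = default_behavior
        ev = pd.DataFrame({"onset": beh.onsets(), "duration": beh.durations(),
                           "trial_type": "stressor",
                           "n_presses": beh.press_counts("CTL").astype(float)})
        X = fl.build_design(ev, default_session, tr=truth.tr)
        resid = fl.fit_glm(fl.normalize_intensity(ts.data.to_numpy(), ts.run_index),
                           X).residuals
        r1 = np.mean([np.corrcoef(resid[:-1, j], resid[1:, j])[0, 1]
                      for j in range(resid.shape[1])])
        assert r1 == pytest.approx(0.3, abs=0.06)

    def test_seed_determinism(self, default_session, default_behavior):
        truth = GroundTruth(seed=9)
        a = simulate_roi_bold(default_session, default_behavior, truth, "CTL", 1)
        b = simulate_roi_bold(default_session, default_behavior, truth, "CTL", 1)
        assert np.array_equal(a.data.to_numpy(), b.data.to_numpy())


class TestVoxelVolumes:
    def test_uniform_effect_mean_beta(self, default_session, default_behavior):
        """Fitting every voxel and averaging recovers the injected effect."""
        from yokedbml.voxel import VolumeMask

        mask = VolumeMask(np.ones((6, 6, 6), bool), np.diag([2., 2., 2., 1.]))
        truth = GroundTruth(seed=0, trial_amp_sd=0.0)
        eff = np.full(mask.n_voxels, 0.25)
        img, _ = simulate_voxel_volumes(mask, eff, truth, default_session,
                                        default_behavior, "UNCTL", 0, noise=False)
        vol = np.asarray(img.dataobj)
        ijk = mask.coordinates()
        Y = vol[ijk[:, 0], ijk[:, 1], ijk[:, 2], :].T
        beh = default_behavior
        ev = pd.DataFrame({"onset": beh.onsets(), "duration": beh.durations(),
                           "trial_type": "stressor",
                           "n_presses": beh.press_counts("UNCTL").astype(float)})
        X = fl.build_design(ev, default_session, tr=truth.tr)
        res = fl.fit_glm(fl.normalize_intensity(Y, X.run_index), X)
        b = res.betas[X.columns.index("stressor")]
        assert b.mean() == pytest.approx(truth.stressor_amp + 0.25, abs=1e-6)

    def test_empty_mask_raises(self, default_session, default_behavior):
        from yokedbml.voxel import VolumeMask

        mask = VolumeMask(np.zeros((4, 4, 4), bool), np.eye(4))
        with pytest.raises(ValueError, match="empty"):
            simulate_voxel_volumes(mask, np.zeros(0), GroundTruth(seed=0),
                                   default_session, default_behavior, "CTL", 0)

    def test_shape_mismatch_raises(self, default_session, default_behavior):
        from yokedbml.voxel import VolumeMask

        mask = VolumeMask(np.ones((4, 4, 4), bool), np.eye(4))
        with pytest.raises(ValueError, match="shape"):
            simulate_voxel_volumes(mask, np.zeros(3), GroundTruth(seed=0),
                                   default_session, default_behavior, "CTL", 0)


class TestSCRSim:
    def test_perfect_coupling_rank_identity(self, default_behavior):
        truth = GroundTruth(seed=0, scr_coupling={"CTL": 1.0, "UNCTL": 1.0})
        bold = np.random.default_rng(0).normal(size=default_behavior.n_trials)
        tr = simulate_scr(default_behavior, truth, "CTL", 0, trial_bold=bold,
                          noise=False)
        from scipy.stats import spearmanr

        assert spearmanr(bold, tr.true_amplitudes).statistic == pytest.approx(1.0)

    def test_zero_coupling_independence(self, default_behavior):
        truth = GroundTruth(seed=1, scr_coupling={"CTL": 0.0, "UNCTL": 0.0})
        rs = []
        for pair in range(40):
            bold = np.random.default_rng(pair).normal(size=default_behavior.n_trials)
            tr = simulate_scr(default_behavior, truth, "CTL", pair, trial_bold=bold)
            rs.append(np.corrcoef(bold, tr.true_amplitudes)[0, 1])
        assert abs(np.mean(rs)) < 0.1

    def test_sampling_rate_and_finite(self, default_behavior):
        truth = GroundTruth(seed=0, scr_rate=50.0)
        tr = simulate_scr(default_behavior, truth, "UNCTL", 0)
        assert tr.rate == 50.0
        assert np.isfinite(tr.values).all()
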