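"""Generator contracts: cohort draws, coupling model, closed-form ISFC."""
import numpy as np
import pandas as pd
import pytest

from isfcpipe import synthgen as sg
from isfcpipe.isfc import subject_isfc

from conftest import coupled_edges, make_series


class TestCohort:
    def test_sizes_and_age_range(self):
        cfg = sg.CohortConfig(n_subjects=500, age_range=(18, 87), seed=1)
        cohort = sg.generate_cohort(cfg)
        assert len(cohort) == 500
        assert cohort["age"].between(18, 87).all()
        assert cohort["fluid_intelligence"].between(0, 46).all()
        assert set(cohort["sex"].unique()) <= {0, 1}

    def test_noiseless_fluid_intelligence_is_linear_in_age(self):
        cfg = sg.CohortConfig(n_subjects=50, fi_noise_sd=0.0, fi_slope=-0.2,
                              fi_intercept=42.0, seed=2)
        cohort = sg.generate_cohort(cfg)
        sub = cohort[cohort["age"] == 20]
        assert (sub["fluid_intelligence"] == 38.0).all()
        expected = np.clip(42.0 - 0.2 * cohort["age"], 0, 46)
        assert np.allclose(cohort["fluid_intelligence"], expected)

    def test_deterministic_given_seed(self):
        cfg = sg.CohortConfig(n_subjects=30, seed=7)
        pd.testing.assert_frame_equal(sg.generate_cohort(cfg),
                                      sg.generate_cohort(cfg))

    def test_age_fi_correlation_is_strongly_negative(self):
        # defaults emulate the observed lifespan decline (r about -0.65)
        cohort = sg.generate_cohort(sg.CohortConfig(n_subjects=500, seed=3))
        r = np.corrcoef(cohort["age"], cohort["fluid_intelligence"])[0, 1]
        assert -0.75 < r < -0.55

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            sg.generate_cohort(sg.CohortConfig(n_subjects=1))


class TestCouplingModel:
    def test_constant_model(self):
        model = sg.constant_coupling_model(2, 6, 0.2, 0.5)
        assert sg.coupling_strength(30, 0, model) == pytest.approx(0.5)

    def test_clip_at_upper_bound(self):
        model = sg.CouplingModel(network_coupling=[0.5],
                                 voxel_assignment=[0],
                                 theta=[[2.0, 0.0, 0.0]])
        assert sg.coupling_strength(50, 0, model) == pytest.approx(0.95)

    def test_linear_term_evaluated_at_one_scale_unit(self):
        # theta=(0.4, -0.2, 0) at age 52+17 (u=1) -> 0.4 - 0.2 = 0.2
        model = sg.CouplingModel(network_coupling=[0.5],
                                 voxel_assignment=[0],
                                 theta=[[0.4, -0.2, 0.0]])
        assert sg.coupling_strength(69, 0, model) == pytest.approx(0.2)

    def test_profile_always_within_clip_bounds(self):
        model = sg.age_effect_model(3, 30, np.arange(10),
                                    coupling_young=0.9, coupling_old=0.05)
        for age in range(18, 88):
            a = model.coupling_profile(age)
            assert np.all((a >= 0) & (a <= 0.95))

    def test_every_voxel_assigned_to_existing_network(self):
        with pytest.raises(ValueError, match="assigned"):
            sg.CouplingModel(network_coupling=[0.5], voxel_assignment=[1],
                             theta=[[0.2, 0, 0]])


class TestStimulus:
    def test_columns_standardised(self):
        cfg = sg.CohortConfig(n_subjects=4, n_frames=200, seed=5)
        s = sg.generate_stimulus(cfg).signals
        assert np.allclose(s.mean(axis=0), 0, atol=1e-6)
        assert np.allclose(s.var(axis=0, ddof=1), 1, atol=1e-6)

    def test_ar_smoothing_raises_lag1_autocorrelation(self):
        base = sg.CohortConfig(n_subjects=4, n_frames=2000, seed=5)
        smooth = sg.CohortConfig(n_subjects=4, n_frames=2000, seed=5,
                                 stimulus_ar=0.6)
        def lag1(sig):
            return np.mean([np.corrcoef(c[:-1], c[1:])[0, 1] for c in sig.T])
        assert lag1(sg.generate_stimulus(base).signals) < 0.1
        assert lag1(sg.generate_stimulus(smooth).signals) > 0.4


class TestSubjectData:
    def test_near_pure_stimulus_reproduces_signal(self):
        # coupling ~1, no intrinsic signal: series are almost exactly s_k
        cfg = sg.CohortConfig(n_subjects=3, n_networks=2, n_voxels=4,
                              n_frames=100, intrinsic_loading=0.0, seed=6)
        model = sg.constant_coupling_model(2, 4, 0.9999, 0.9499)
        stim = sg.generate_stimulus(cfg)
        sts = sg.generate_subject_data(0, 40.0, stim, model, cfg)
        for k in range(2):
            r = np.corrcoef(sts.network_ts[:, k], stim.signals[:, k])[0, 1]
            assert r > 0.999

    def test_null_coupling_gives_independent_subjects(self):
        cfg = sg.CohortConfig(n_subjects=2, n_networks=2, n_voxels=4,
                              n_frames=5000, intrinsic_loading=0.0, seed=7)
        model = sg.constant_coupling_model(2, 4, 0.0, 0.0)
        stim = sg.generate_stimulus(cfg)
        a = sg.generate_subject_data(0, 30.0, stim, model, cfg)
        b = sg.generate_subject_data(1, 60.0, stim, model, cfg)
        r = np.corrcoef(a.network_ts[:, 0], b.thal_ts[:, 0])[0, 1]
        assert abs(r) < 0.05

    def test_cross_subject_correlation_matches_sqrt_product(self):
        # c = a = 0.25 -> corr(y_k^i, x_v^j) = sqrt(c*a) = 0.25
        cfg = sg.CohortConfig(n_subjects=2, n_networks=1, n_voxels=2,
                              n_frames=5000, intrinsic_loading=0.0, seed=8)
        model = sg.constant_coupling_model(1, 2, 0.25, 0.25)
        stim = sg.generate_stimulus(cfg)
        a = sg.generate_subject_data(0, 30.0, stim, model, cfg)
        b = sg.generate_subject_data(1, 60.0, stim, model, cfg)
        r = np.corrcoef(a.network_ts[:, 0], b.thal_ts[:, 0])[0, 1]
        assert r == pytest.approx(0.25, abs=0.05)

    def test_variance_budget_enforced(self):
        cfg = sg.CohortConfig(n_subjects=2, n_networks=1, n_voxels=1,
                              n_frames=50, intrinsic_loading=0.5, seed=9)
        model = sg.constant_coupling_model(1, 1, 0.6, 0.1)
        with pytest.raises(ValueError, match="variance budget"):
            sg.generate_subject_data(0, 40.0, sg.generate_stimulus(cfg),
                                     model, cfg)

    def test_deterministic_per_subject(self):
        cfg = sg.CohortConfig(n_subjects=2, n_networks=2, n_voxels=3,
                              n_frames=40, seed=10)
        model = sg.constant_coupling_model(2, 3, 0.2, 0.2)
        stim = sg.generate_stimulus(cfg)
        one = sg.generate_subject_data(1, 44.0, stim, model, cfg)
        two = sg.generate_subject_data(1, 44.0, stim, model, cfg)
        assert np.array_equal(one.thal_ts, two.thal_ts)
        other = sg.generate_subject_data(0, 44.0, stim, model, cfg)
        assert not np.array_equal(one.thal_ts, other.thal_ts)


class TestExpectedISFC:
    def test_zero_coupling_gives_zero(self):
        model = sg.constant_coupling_model(2, 4, 0.0, 0.0)
        assert sg.expected_isfc(model, [20, 25, 27], 0, 0, 0) == 0.0

    def test_constant_half_coupling(self):
        model = sg.constant_coupling_model(1, 2, 0.5, 0.5)
        assert sg.expected_isfc(model, [20, 25], 0, 0, 0) == pytest.approx(0.5)

    def test_unshared_network_gives_zero(self):
        model = sg.constant_coupling_model(3, 6, 0.5, 0.5)
        v = 0
        k_other = (model.voxel_assignment[v] + 1) % 3
        assert sg.expected_isfc(model, [20, 25], 0, k_other, v) == 0.0

    def test_leave_one_out_average_over_other_ages(self):
        # declining coupling: expectation averages sqrt(a(age_j)) over j != i
        model = sg.age_effect_model(1, 1, np.array([0]), network_coupling=0.36,
                                    coupling_young=0.64, coupling_old=0.16)
        ages = [18, 87]
        a18 = sg.coupling_strength(18, 0, model)
        expected = np.sqrt(0.36) * np.mean([np.sqrt(a18)])
        got = sg.expected_isfc(model, ages, 1, 0, 0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_monte_carlo_mean_matches_closed_form(self):
        # n=20 subjects, T=2000: sample mean ISFC within 0.03 everywhere
        cfg = sg.CohortConfig(n_subjects=20, n_networks=2, n_voxels=6,
                              n_frames=2000, intrinsic_loading=0.0, seed=11)
        model = sg.age_effect_model(2, 6, np.array([0, 3]),
                                    network_coupling=0.3, null_coupling=0.35,
                                    coupling_young=0.6, coupling_old=0.2)
        cohort, series = make_series(cfg, model)
        ages = cohort["age"].to_numpy()
        slist = list(series.values())
        mats = [np.tanh(subject_isfc(i, slist).values) for i in range(20)]
        mean_mat = np.mean(mats, axis=0)
        expected = np.array([[np.mean([sg.expected_isfc(model, ages, i, k, v)
                                       for i in range(20)])
                              for v in range(6)] for k in range(2)])
        assert np.abs(mean_mat - expected).max() < 0.03


class TestMotion:
    def test_zero_step_scale_gives_zero_trace(self):
        cfg = sg.CohortConfig(n_subjects=2, motion_step_mm=0.0,
                              motion_step_rad=0.0, seed=12)
        assert np.all(sg.generate_motion_trace(0, cfg) == 0.0)

    def test_injected_spike_magnitude(self):
        cfg = sg.CohortConfig(n_subjects=2, motion_step_mm=0.0,
                              motion_step_rad=0.0, seed=12)
        trace = sg.generate_motion_trace(0, cfg, spikes=[(10, 0, 3.0)])
        assert np.abs(trace[:, :3]).max() == pytest.approx(3.0)

    def test_deterministic(self):
        cfg = sg.CohortConfig(n_subjects=2, seed=13)
        assert np.array_equal(sg.generate_motion_trace(1, cfg),
                              sg.generate_motion_trace(1, cfg))


class TestFixtureVolumes:
    def test_mask_voxel_count_and_round_trip(self, tmp_path):
        import nibabel as nib

        cfg = sg.CohortConfig(n_subjects=3, n_networks=2, n_voxels=30,
                              n_frames=25, seed=14)
        model = sg.constant_coupling_model(2, 30, 0.3, 0.3)
        cohort, series = make_series(cfg, model)
        paths = sg.write_fixture_volumes(cohort, series, (8, 6, 6), tmp_path)
        mask = np.asarray(nib.load(paths["mask"]).dataobj)
        assert int((mask > 0).sum()) == 30
        # extracting mask voxels (C-order) recovers thal_ts exactly
        sid = cohort["subject_id"][0]
        vol = np.asarray(nib.load(paths[sid]).dataobj)
        coords = np.argwhere(mask > 0)
        extracted = vol[tuple(coords.T)].T
        assert np.allclose(extracted, series[sid].thal_ts, atol=1e-6)

    def test_grid_too_small(self, tmp_path):
        cfg = sg.CohortConfig(n_subjects=2, n_networks=2, n_voxels=620,
                              n_frames=12, seed=15)
        model = sg.constant_coupling_model(2, 620, 0.3, 0.3)
        cohort, series = make_series(cfg, model)
        with pytest.raises(ValueError, match="too small"):
            sg.write_fixture_volumes(cohort, series, (2, 2, 2), tmp_path)
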