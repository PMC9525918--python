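import numpy as np
import pytest

from perturbkit import synthdata
from perturbkit.datamodel import SERIES_TIME_POINTS_S


class TestTmtSim:
    def test_null_model_gives_zero_log_ratios(self):
        psms, designs, _ = synthdata.simulate_tmt_experiment(
            n_proteins=5, noise_sd=0.0, label_bias_sd=0.0, changer_fraction=0.0,
            seed=1, fractions=("cytosolic",), n_bio_replicates=1,
            missing_series_prob=0.0)
        for psm in psms:
            mix = psm.intensities[-1]
            ratios = np.log2(np.array(psm.intensities[:-1]) / mix)
            np.testing.assert_allclose(ratios, 0.0, atol=1e-12)

    def test_seed_determinism(self):
        a = synthdata.simulate_tmt_experiment(n_proteins=8, seed=3,
                                              fractions=("cytosolic",))
        b = synthdata.simulate_tmt_experiment(n_proteins=8, seed=3,
                                              fractions=("cytosolic",))
        assert a[0] == b[0]
        assert a[1] == b[1]

    def test_changer_count_binomial(self):
        _, _, truth = synthdata.simulate_tmt_experiment(
            n_proteins=200, changer_fraction=0.1, seed=4, fractions=("cytosolic",))
        # binomial(200, 0.1): 3.5 sigma window around 20
        assert 5 <= len(truth.changers) <= 35

    def test_design_matches_series_layout(self):
        _, designs, _ = synthdata.simulate_tmt_experiment(
            n_proteins=2, seed=1, fractions=("cytosolic",), n_bio_replicates=2)
        assert len(designs) == 6  # 3 series x 2 replicates
        for d in designs:
            assert d.time_points_s == SERIES_TIME_POINTS_S[d.series]

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            synthdata.simulate_tmt_experiment(n_proteins=0)
        with pytest.raises(ValueError):
            synthdata.simulate_tmt_experiment(changer_fraction=1.5)


class TestDoseResponseSim:
    def test_midpoint_and_asymptote_exact(self):
        s = synthdata.ScreenSimTruth("A", ec50_um=10.0, k=2.0, onset_s=100.0,
                                     amplitude=0.8, baseline=1.2)
        doses = (0.001, 0.1, 10.0, 1000.0, 1e6)
        table = synthdata.simulate_dose_response_screen(
            [s], doses_um=doses, times_s=(1e6,), n_replicates=1, noise_cv=0.0,
            seed=1)
        at_mid = table.loc[table.dose_um == 10.0, "ratio"].iloc[0]
        assert at_mid == pytest.approx(1.2 + 0.8 / 2, abs=1e-12)
        at_low = table.loc[table.dose_um == 0.001, "ratio"].iloc[0]
        # the logistic foot at 4 decades below EC50 is ~3e-4 of the amplitude
        assert at_low == pytest.approx(1.2, abs=1e-3)

    def test_noise_cv_validation_and_determinism(self):
        s = synthdata.default_sensor_panel(2, 1, seed=1)
        with pytest.raises(ValueError):
            synthdata.simulate_dose_response_screen(s, noise_cv=-0.1)
        a = synthdata.simulate_dose_response_screen(s, seed=9)
        b = synthdata.simulate_dose_response_screen(s, seed=9)
        assert a.equals(b)

    def test_requires_wide_dose_series(self):
        s = synthdata.default_sensor_panel(1, 0)
        with pytest.raises(ValueError):
            synthdata.simulate_dose_response_screen(s, doses_um=(1, 2, 3, 4))


class TestCubeSim:
    def test_noise_free_translocator_perfectly_anticorrelated(self):
        cube, truth = synthdata.simulate_fraction_timecourse(
            n_proteins=10, n_translocators=3, n_changers=2, noise_sd=0.0, seed=5)
        ix = {e: i for i, e in enumerate(cube.entity_ids)}
        f_ix = {f: i for i, f in enumerate(cube.fractions)}
        for protein, f_from, f_to in truth.translocators:
            a = cube.values[ix[protein], f_ix[f_from], :, 0]
            b = cube.values[ix[protein], f_ix[f_to], :, 0]
            assert np.corrcoef(a, b)[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_noise_free_non_changer_flat(self):
        cube, truth = synthdata.simulate_fraction_timecourse(
            n_proteins=10, n_translocators=2, n_changers=2, noise_sd=0.0, seed=6)
        signal = {p for p, *_ in truth.translocators} | set(truth.changers)
        for i, e in enumerate(cube.entity_ids):
            if e not in signal:
                assert np.ptp(cube.values[i]) == 0.0

    def test_truth_lengths_and_capacity_check(self):
        cube, truth = synthdata.simulate_fraction_timecourse(
            n_proteins=30, n_translocators=4, n_changers=5, seed=7)
        assert len(truth.translocators) == 4
        assert len(truth.changers) == 5
        with pytest.raises(ValueError):
            synthdata.simulate_fraction_timecourse(n_proteins=5,
                                                   n_translocators=3, n_changers=3)


class TestNetworkSim:
    def test_null_spearman_near_zero(self):
        veh, _, _ = synthdata.simulate_network_perturbation(
            n_proteins=30, n_timepoints=50, perturbed_pairs=[], seed=8)
        x = veh.values[:, 0, :, 0]
        from scipy.stats import spearmanr
        rho = spearmanr(x.T).statistic
        off = rho[np.triu_indices(30, 1)]
        assert abs(off.mean()) < 3 * off.std() / np.sqrt(len(off)) + 0.02

    def test_perturbed_pair_flips_sign(self):
        veh, tre, pairs = synthdata.simulate_network_perturbation(
            n_proteins=10, n_timepoints=200, perturbed_pairs=[(0, 1)],
            base_correlation=0.9, seed=9)
        from scipy.stats import spearmanr
        rv = spearmanr(veh.values[0, 0, :, 0], veh.values[1, 0, :, 0]).statistic
        rt = spearmanr(tre.values[0, 0, :, 0], tre.values[1, 0, :, 0]).statistic
        assert rv > 0.6 and rt < -0.6

    def test_non_psd_matrix_fails_loudly(self):
        # chained 0.9 correlations on a triangle are not PSD at rho=-0.9
        with pytest.raises(ValueError, match="positive semi-definite"):
            synthdata.simulate_network_perturbation(
                n_proteins=3, perturbed_pairs=[(0, 1), (1, 2), (0, 2)],
                base_correlation=0.9, seed=1)


class TestKineticsFrapImages:
    def test_initial_slope_matches_rate_within_one_percent(self):
        frames = synthdata.simulate_kinetics_plate([(1.0, 80.0)], noise_sd=0.0,
                                                   seed=1)
        one_hour = [f for f in frames if f.time_s <= 3600.0]
        totals = np.array([f.pixels.sum() for f in one_hour])
        times_h = np.array([f.time_s for f in one_hour]) / 3600.0
        slope = np.polyfit(times_h, totals, 1)[0]
        assert abs(slope - 80.0) / 80.0 < 0.01

    def test_zero_rate_flat_and_frame_count(self):
        frames = synthdata.simulate_kinetics_plate(
            [(0.0, 0.0)], frame_interval_s=600.0, horizon_s=18000.0,
            noise_sd=0.0, seed=1)
        assert len(frames) == 31
        assert all(f.pixels.sum() == 0.0 for f in frames)

    def test_frap_asymptote_and_immobile_limit(self):
        t, bleach, remote, truth = synthdata.simulate_frap_series(
            mobile_fraction=0.7, tau_s=2.0, photofade_rate=0.0,
            n_frames=400, seed=1)
        assert bleach[-1] == pytest.approx(truth["bleach_floor"] + truth["amplitude"],
                                           abs=1e-3)
        t, bleach, _, truth = synthdata.simulate_frap_series(
            mobile_fraction=0.0, photofade_rate=0.0, seed=1)
        post = bleach[t >= truth["t_bleach_s"]]
        assert np.ptp(post) == 0.0

    def test_normalized_frap_independent_of_photofade(self):
        t1, b1, r1, _ = synthdata.simulate_frap_series(photofade_rate=0.0, seed=2)
        t2, b2, r2, _ = synthdata.simulate_frap_series(photofade_rate=0.1, seed=2)
        np.testing.assert_allclose(b1 / r1, b2 / r2, rtol=1e-10)

    def test_apoptosis_truth_masks(self):
        _, _, truth = synthdata.simulate_apoptosis_images(
            n_cells=20, apoptotic_fraction=0.0, seed=3)
        assert truth["fitc_pixels"] == 0
        _, _, truth = synthdata.simulate_apoptosis_images(
            n_cells=20, apoptotic_fraction=1.0, seed=3)
        assert truth["fitc_pixels"] == truth["dapi_pixels"]

    def test_disjoint_disc_area_analytic(self):
        r = 3
        yy, xx = np.mgrid[-8:9, -8:9]
        disc_area = int((yy**2 + xx**2 <= r**2).sum())
        _, _, truth = synthdata.simulate_apoptosis_images(
            n_cells=1, apoptotic_fraction=0.0, cell_radius_px=r,
            image_shape=(64, 64), seed=4)
        assert truth["dapi_pixels"] == disc_area
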