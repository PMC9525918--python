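import numpy as np
import pandas as pd
import pytest

from perturbkit import synthdata, tmt
from perturbkit.datamodel import ChannelAssignment, PlexDesign, PsmRecord
from perturbkit.tmt import DeRecord, PowerSpec


def single_label_design(plex_id="px"):
    channels = []
    for t in (0.0, 2400.0, 10800.0, 43200.0, 86400.0):
        channels.append(ChannelAssignment(t, "treated"))
        channels.append(ChannelAssignment(t, "control"))
    channels.append(ChannelAssignment(0.0, "global_mix"))
    return PlexDesign(plex_id, "A", "cytosolic", 1, 1, tuple(channels))


class TestLogRatios:
    def test_equal_intensities_give_zero(self):
        design = single_label_design()
        psm = PsmRecord("p", "PEP", ("P1",), "px", (5.0,) * 11)
        ratios = tmt.psm_log_ratios([psm], [design])
        np.testing.assert_allclose(ratios["ratio"], 0.0)
        assert len(ratios) == 10

    def test_ratio_is_log2(self):
        design = single_label_design()
        intensities = [2.0] * 11
        intensities[0] = 8.0
        psm = PsmRecord("p", "PEP", ("P1",), "px", tuple(intensities))
        ratios = tmt.psm_log_ratios([psm], [design])
        assert ratios.loc[ratios.channel == 1, "ratio"].iloc[0] == pytest.approx(2.0)

    def test_zero_mix_drops_psm_with_count(self):
        design = single_label_design()
        bad = PsmRecord("bad", "PEP", ("P1",), "px", (1.0,) * 10 + (0.0,))
        good = PsmRecord("good", "PEP", ("P1",), "px", (1.0,) * 11)
        ratios = tmt.psm_log_ratios([bad, good], [design])
        assert len(ratios) == 10
        assert ratios.attrs["n_dropped"] == 1

    def test_unknown_plex_raises(self):
        psm = PsmRecord("p", "PEP", ("P1",), "nope", (1.0,) * 11)
        with pytest.raises(ValueError, match="unknown plex"):
            tmt.psm_log_ratios([psm], [single_label_design()])

    def test_razor_assignment_prefers_protein_with_more_peptides(self):
        design = single_label_design()
        psms = [
            PsmRecord("a", "PEP1", ("P1",), "px", (1.0,) * 11),
            PsmRecord("b", "PEP2", ("P1",), "px", (1.0,) * 11),
            PsmRecord("c", "PEP3", ("P1", "P2"), "px", (1.0,) * 11),
        ]
        ratios = tmt.psm_log_ratios(psms, [design])
        assert set(ratios["protein"]) == {"P1"}


class TestSamplerOracles:
    def test_flat_prior_limit_matches_conjugate_posterior(self, rng):
        """With one protein/label, a fixed known sigma and a flat beta prior,
        the sampler must reproduce the Normal(ybar, sigma^2/n) posterior."""
        sigma, n = 0.5, 24
        y = rng.normal(0.7, sigma, n)
        ratios = pd.DataFrame({"protein": "P1", "plex": "px", "channel": 1,
                               "peptide": "PEP", "ratio": y})
        model = tmt.TmtHierarchicalModel(
            n_chains=4, n_steps=1500, nu=50.0, tau=1e-6, sigma_fixed=sigma,
            random_state=0).fit(ratios, [single_label_design()])
        post = model.posteriors_.iloc[0]
        n_draws = post["n_effective_draws"]
        exact_sd = sigma / np.sqrt(n)
        # 3 Monte-Carlo standard errors with a conservative ESS allowance
        mcse = exact_sd / np.sqrt(n_draws / 4.0)
        assert abs(post["mean"] - y.mean()) < 3 * mcse
        assert post["sd"] == pytest.approx(exact_sd, rel=0.08)

    def test_simulated_data_converges(self, small_tmt_fit):
        *_, model = small_tmt_fit
        assert model.max_rhat_ < 1.05
        assert model.convergence_["converged"].all()


class TestTreatedMinusControl:
    def test_gaussian_difference_closed_form(self):
        posteriors = pd.DataFrame({
            "protein": ["P1", "P1"], "plex": ["px", "px"], "channel": [1, 2],
            "mean": [1.0, 0.0], "sd": [0.2, 0.2]})
        records = tmt.treated_minus_control(posteriors, [single_label_design()])
        rec = records[0]
        assert rec.mean == pytest.approx(1.0)
        assert rec.sd == pytest.approx(np.sqrt(0.08), rel=1e-6)  # ~0.283

    def test_antisymmetry_under_condition_swap(self, small_tmt_fit):
        psms, designs, _, ratios, model = small_tmt_fit
        swapped = []
        for d in designs:
            channels = tuple(
                ChannelAssignment(c.time_s,
                                  {"treated": "control", "control": "treated",
                                   "global_mix": "global_mix"}[c.condition])
                for c in d.channel_map)
            swapped.append(PlexDesign(d.plex_id, d.series, d.fraction,
                                      d.bio_replicate, d.tech_replicate, channels))
        model2 = tmt.TmtHierarchicalModel(n_chains=3, n_steps=800,
                                          random_state=101).fit(ratios, swapped)
        c1 = tmt.combine_by_protein_time(model.diff_records_, model._diff_replicates_)
        c2 = tmt.combine_by_protein_time(model2.diff_records_, model2._diff_replicates_)
        m1 = {(r.protein, r.time_s): r for r in c1}
        for r in c2:
            ref = m1[(r.protein, r.time_s)]
            assert r.mean == pytest.approx(-ref.mean, abs=1e-10)
            assert r.cohens_d == pytest.approx(ref.cohens_d, abs=1e-10)

    def test_global_mix_cancellation(self):
        """Multiplying all intensities of one plex by a constant must leave
        every treated-minus-control record unchanged."""
        psms, designs, _ = synthdata.simulate_tmt_experiment(
            n_proteins=15, seed=5, fractions=("cytosolic",))
        target = designs[0].plex_id
        scaled = [PsmRecord(p.psm_id, p.peptide_sequence, p.protein_ids,
                            p.plex_id, tuple(v * 1.37 for v in p.intensities))
                  if p.plex_id == target else p for p in psms]
        r1 = tmt.psm_log_ratios(psms, designs)
        r2 = tmt.psm_log_ratios(scaled, designs)
        m1 = tmt.TmtHierarchicalModel(n_chains=2, n_steps=400,
                                      random_state=3).fit(r1, designs)
        m2 = tmt.TmtHierarchicalModel(n_chains=2, n_steps=400,
                                      random_state=3).fit(r2, designs)
        d1 = np.array([r.mean for r in m1.diff_records_])
        d2 = np.array([r.mean for r in m2.diff_records_])
        np.testing.assert_allclose(d1, d2, atol=1e-10)


class TestCombination:
    def test_bayesian_updating_equal_precision(self):
        a = DeRecord("P", 0.0, "f", mean=0.0, sd=1.0)
        b = DeRecord("P", 0.0, "f", mean=0.0, sd=1.0)
        out = tmt.combine_biological_replicates([a, b])
        assert out.mean == pytest.approx(0.0)
        assert out.sd == pytest.approx(np.sqrt(0.5))
        out = tmt.combine_biological_replicates([
            DeRecord("P", 0.0, "f", 1.0, 1.0), DeRecord("P", 0.0, "f", 3.0, 1.0)])
        assert out.mean == pytest.approx(2.0)
        assert out.sd == pytest.approx(np.sqrt(0.5))

    def test_single_record_identity(self):
        rec = DeRecord("P", 0.0, "f", 1.5, 0.3)
        assert tmt.combine_biological_replicates([rec]).mean == rec.mean
        assert tmt.combine_technical_replicates([rec]) is rec
        with pytest.raises(ValueError):
            tmt.combine_biological_replicates([])

    def test_technical_quadrature(self):
        recs = [DeRecord("P", 0.0, "f", 0.0, 3.0 / 1.96),
                DeRecord("P", 0.0, "f", 0.0, 4.0 / 1.96)]
        out = tmt.combine_technical_replicates(recs)
        assert out.sd * 1.96 == pytest.approx(2.5)
        # identical records: half-width scales as h / sqrt(R)
        recs = [DeRecord("P", 0.0, "f", 1.0, 1.0), DeRecord("P", 0.0, "f", 1.0, 1.0)]
        out = tmt.combine_technical_replicates(recs)
        assert out.sd == pytest.approx(1.0 / np.sqrt(2))
        assert out.mean == pytest.approx(1.0)


class TestEffectSizes:
    @pytest.mark.parametrize("treated,control,expected", [
        ((0.0, 1.0), (0.0, 1.0), 0.0),
        ((1.0, 1.0), (0.0, 1.0), 1.0),
        ((2.0, 1.0), (0.0, 3.0), 2.0 / np.sqrt(5.0)),
    ])
    def test_cohens_d(self, treated, control, expected):
        assert tmt.cohens_d(treated, control) == pytest.approx(expected)

    def test_min_detectable_effect_monotone_and_normal_limit(self):
        values = [tmt.min_detectable_effect(n=n) for n in (3, 5, 10, 50, 200)]
        assert all(a > b for a, b in zip(values, values[1:]))
        from scipy.stats import norm
        n = 400
        approx = (norm.ppf(0.975) + norm.ppf(0.8)) * np.sqrt(2.0 / n)
        assert tmt.min_detectable_effect(n=n) == pytest.approx(approx, rel=0.02)

    def test_min_detectable_effect_matches_grid_inversion(self):
        from scipy.stats import nct, t as t_dist
        n = 10
        df = 2 * n - 2
        t_crit = t_dist.ppf(0.975, df)
        grid = np.linspace(0.5, 3.0, 20001)
        power = 1 - nct.cdf(t_crit, df, grid * np.sqrt(n / 2)) + \
            nct.cdf(-t_crit, df, grid * np.sqrt(n / 2))
        expected = grid[np.searchsorted(power, 0.8)]
        assert tmt.min_detectable_effect(n=n) == pytest.approx(expected, abs=1e-3)
        with pytest.raises(ValueError):
            tmt.min_detectable_effect(n=1)

    def test_selection_thresholds(self):
        spec = PowerSpec()
        records = [
            DeRecord("A", 0.0, "f", 1.0, 0.1, n_replicates=3, cohens_d=3.5),
            DeRecord("B", 0.0, "f", 1.0, 0.1, n_replicates=5, cohens_d=1.6),
            DeRecord("C", 0.0, "f", 0.0, 0.1, n_replicates=6, cohens_d=0.0),
        ]
        selected = tmt.select_significant(records, spec)
        assert {r.protein for r in selected} == {"A"}
        assert records[0].significant and not records[1].significant

    def test_selection_falls_back_to_power_analysis(self):
        spec = PowerSpec()
        rec = DeRecord("A", 0.0, "f", 1.0, 0.1, n_replicates=12, cohens_d=1.4)
        tmt.select_significant([rec], spec)
        assert rec.significant == (1.4 > tmt.min_detectable_effect(n=12))


class TestStratifiedPvalues:
    def test_pools_strata_into_single_bh_pass(self):
        cube, _ = synthdata.simulate_fraction_timecourse(
            n_proteins=30, fractions=("f1",), n_translocators=0, n_changers=5,
            noise_sd=0.2, seed=11)
        # knock one replicate out for a third of the entities
        cube.values[:10, :, :, 2] = np.nan
        res = tmt.stratified_timecourse_pvalues(cube, n_permutations=100, seed=1)
        assert set(res["n_replicates"]) == {2, 3}
        assert len(res) == 30
        from perturbkit.timecourse import benjamini_hochberg
        np.testing.assert_allclose(
            res["q"], benjamini_hochberg(res["p"].to_numpy()))
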