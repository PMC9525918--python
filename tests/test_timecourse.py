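import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perturbkit import synthdata, timecourse as tc
from perturbkit.datamodel import AbundanceCube
from perturbkit.timecourse import (
    MergeCriteria,
    anticorrelation_calls,
    benjamini_hochberg,
    filter_de_genes,
    filter_go_terms,
    merge_omics,
    natural_spline_basis,
    pca_denoise,
    timecourse_significance,
)


def flat_cube(n_entities, noise_sd, seed, T=15, R=3):
    rng = np.random.default_rng(seed)
    values = rng.normal(0, noise_sd, (n_entities, 1, T, R))
    return AbundanceCube([f"P{i}" for i in range(n_entities)], ["f"],
                         np.arange(T, dtype=float) * 3600,
                         [f"r{j}" for j in range(R)], values)


class TestSplineFTest:
    def test_f_matches_least_squares_oracle(self, rng):
        cube = flat_cube(5, 1.0, 7)
        res = timecourse_significance(cube, n_permutations=10, seed=0)
        # direct dense least-squares oracle
        T, R = 15, 3
        t_obs = np.repeat(cube.time_points_s, R)
        X1 = np.column_stack([np.ones(T * R), natural_spline_basis(t_obs, 3)])
        for i in range(5):
            y = cube.values[i, 0].reshape(-1)
            beta1, rss1, *_ = np.linalg.lstsq(X1, y, rcond=None)
            rss1 = float(np.sum((y - X1 @ beta1) ** 2))
            rss0 = float(np.sum((y - y.mean()) ** 2))
            f_expected = ((rss0 - rss1) / 3) / (rss1 / (T * R - 4))
            assert res["F"].iloc[i] == pytest.approx(f_expected, abs=1e-10)

    def test_strong_ramp_attains_minimal_pvalue(self):
        cube = flat_cube(3, 0.1, 1)
        ramp = np.linspace(0, 1, 15) * 0.5  # signal/noise = 5
        cube.values[0, 0] += ramp[:, None]
        res = timecourse_significance(cube, n_permutations=200, seed=2)
        assert res["p"].iloc[0] == pytest.approx(1.0 / 201.0)

    def test_null_calibration(self):
        cube = flat_cube(1000, 0.3, 3)
        res = timecourse_significance(cube, n_permutations=200, seed=4)
        from scipy.stats import binom
        for alpha in (0.01, 0.05, 0.1):
            rate = float((res["p"] <= alpha).mean())
            lo, hi = binom.interval(0.95, 1000, alpha)
            assert lo / 1000 <= rate <= hi / 1000 + 1e-12

    def test_input_validation(self):
        with pytest.raises(ValueError, match="time points"):
            timecourse_significance(flat_cube(2, 1.0, 1, T=3), n_permutations=10)
        with pytest.raises(ValueError, match="replicates"):
            timecourse_significance(flat_cube(2, 1.0, 1, R=1), n_permutations=10)
        cube = flat_cube(2, 1.0, 1)
        cube.values[1, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="P1"):
            timecourse_significance(cube, n_permutations=10)


class TestBenjaminiHochberg:
    def test_known_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_degenerate_cases(self):
        np.testing.assert_allclose(benjamini_hochberg([1.0, 1.0]), [1.0, 1.0])
        np.testing.assert_allclose(benjamini_hochberg([0.37]), [0.37])
        assert len(benjamini_hochberg([])) == 0

    def brute_force(self, p):
        m = len(p)
        order = np.argsort(p, kind="stable")
        q = np.empty(m)
        for rank_pos, idx in enumerate(order, start=1):
            candidates = [m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)]
            q[idx] = min(1.0, min(candidates))
        return q

    def test_matches_brute_force_on_permutations(self, rng):
        base = rng.random(6)
        for perm in itertools.permutations(range(6)):
            p = base[list(perm)]
            np.testing.assert_allclose(benjamini_hochberg(p),
                                       self.brute_force(p), atol=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=12))
    def test_matches_brute_force_hypothesis(self, p):
        np.testing.assert_allclose(benjamini_hochberg(p),
                                   self.brute_force(np.array(p)), atol=1e-12)

    def test_order_stability(self, rng):
        p = rng.random(10)
        perm = rng.permutation(10)
        q = benjamini_hochberg(p)
        q_perm = benjamini_hochberg(p[perm])
        np.testing.assert_allclose(q_perm, q[perm], atol=1e-12)


class TestPcaDenoise:
    def test_rank_one_exact(self, rng):
        matrix = np.outer(rng.normal(size=8), rng.normal(size=5))
        rec, k = pca_denoise(matrix, 0.9)
        assert k == 1
        np.testing.assert_allclose(rec, matrix, atol=1e-10)

    def test_full_variance_is_identity(self, rng):
        matrix = rng.normal(size=(10, 6))
        rec, k = pca_denoise(matrix, 1.0)
        np.testing.assert_allclose(rec, matrix, atol=1e-10)

    def test_error_monotone_in_k(self, rng):
        matrix = rng.normal(size=(12, 8))
        errors = []
        for target in (0.3, 0.6, 0.9, 1.0):
            rec, k = pca_denoise(matrix, target)
            errors.append((k, float(np.linalg.norm(matrix - rec))))
        ks, errs = zip(*sorted(errors))
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))


class TestAnticorrelation:
    def two_fraction_cube(self, profile_a, profile_b):
        T = len(profile_a)
        values = np.zeros((1, 2, T, 1))
        values[0, 0, :, 0] = profile_a
        values[0, 1, :, 0] = profile_b
        return AbundanceCube(["P0"], ["fa", "fb"], np.arange(T, dtype=float),
                             ["r1"], values)

    def test_exact_negation_gives_minus_one(self):
        p = np.linspace(0, 1, 15)
        cube = self.two_fraction_cube(p, -p)
        calls = anticorrelation_calls(cube, variance_target=1.0)
        assert calls[0].pearson_r == pytest.approx(-1.0, abs=1e-12)
        assert calls[0].called

    def test_identical_profiles_not_called(self):
        p = np.linspace(0, 1, 15)
        calls = anticorrelation_calls(self.two_fraction_cube(p, p),
                                      variance_target=1.0)
        assert calls[0].pearson_r == pytest.approx(1.0, abs=1e-12)
        assert not calls[0].called

    def test_affine_rescaling_invariance(self):
        p = np.linspace(0, 1, 15)
        r1 = anticorrelation_calls(self.two_fraction_cube(p, -p),
                                   variance_target=1.0)[0].pearson_r
        r2 = anticorrelation_calls(self.two_fraction_cube(p, -3.0 * p + 2.0),
                                   variance_target=1.0)[0].pearson_r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_pipeline_recovers_planted_translocators(self):
        cube, truth = synthdata.simulate_fraction_timecourse(seed=19)
        calls = tc.translocation_pipeline(cube, seed=19)
        called = {c.protein for c in calls if c.called}
        translocators = {p for p, *_ in truth.translocators}
        flat = (set(cube.entity_ids) - translocators - set(truth.changers))
        sensitivity = len(called & translocators) / len(translocators)
        false_rate = len(called & flat) / len(flat)
        assert sensitivity >= 0.95
        assert false_rate <= 0.05


class TestMergeAndFilters:
    def test_merge_rules(self):
        protein_hits = pd.DataFrame({"protein": ["A", "B"], "q": [0.009, 0.02]})
        rna = pd.DataFrame({
            "gene": ["g1", "g1", "g2", "g3"],
            "q": [0.005, 0.5, 0.005, 0.2],
            "log2fc": [0.4, 0.4, 0.8, 2.0]})
        merged = merge_omics(protein_hits, rna, MergeCriteria())
        # g1 fails |log2fc|, g3 fails q, protein B fails q
        assert merged == ["A", "g2"]
        assert merge_omics(pd.DataFrame(), pd.DataFrame(), MergeCriteria()) == []

    def test_de_gene_filter_inclusive_bounds(self):
        rna = pd.DataFrame({
            "gene": ["a", "b", "c"],
            "q": [0.04, 0.06, 0.01],
            "log2fc": [1.0, 3.0, -1.2]})
        assert filter_de_genes(rna) == ["a", "c"]

    def test_go_term_filter_strict_bounds(self):
        terms = pd.DataFrame({
            "term": ["t1", "t2", "t3"],
            "dispensability": [0.05, 0.1, 0.09],
            "q": [0.01, 0.01, 0.06]})
        assert filter_go_terms(terms) == ["t1"]
        assert filter_go_terms(pd.DataFrame()) == []
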