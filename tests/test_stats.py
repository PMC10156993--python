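"""Formulas and tests: occurrence frequencies, gene flow, Mantel, t, PCA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylounits.core import DistanceMatrix
from phylounits.stats import (gene_flow, gene_flow_matrix, mantel,
                              one_sample_t, of_sample, of_site, pca_select,
                              two_sample_t)


class TestOccurrenceFrequency:
    @pytest.mark.parametrize("n,N,expected", [(0, 228, 0.0), (228, 228, 100.0),
                                              (57, 228, 25.0)])
    def test_of_site_values(self, n, N, expected):
        assert of_site(n, N) == pytest.approx(expected)

    @pytest.mark.parametrize("s,S,expected", [(5, 10, 50.0), (0, 10, 0.0),
                                              (10, 10, 100.0)])
    def test_of_sample_values(self, s, S, expected):
        assert of_sample(s, S) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            of_site(1, 0)
        with pytest.raises(ValueError):
            of_site(5, 4)
        with pytest.raises(ValueError):
            of_sample(-1, 10)

    @given(st.integers(min_value=0, max_value=500), st.integers(min_value=1, max_value=500))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_monotone(self, n, N):
        if n > N:
            n = N
        v = of_site(n, N)
        assert 0.0 <= v <= 100.0
        if n < N:
            assert of_site(n + 1, N) > v


class TestGeneFlow:
    def test_scalar_values(self):
        assert gene_flow(1.0, 4.0, 4.0) == pytest.approx(1.0)
        assert gene_flow(0.0, 7.0) == 0.0

    def test_hand_arithmetic_pairs(self):
        vals = [gene_flow(0.8, 2.0), gene_flow(0.5, 1.6)]
        assert vals == [pytest.approx(0.4), pytest.approx(0.2)]
        assert np.mean(vals) == pytest.approx(0.3)

    def test_linear_in_theta_and_m(self):
        assert gene_flow(2 * 0.7, 1.3) == pytest.approx(2 * gene_flow(0.7, 1.3))
        assert gene_flow(0.7, 2 * 1.3) == pytest.approx(2 * gene_flow(0.7, 1.3))

    def test_invalid_fixation_factor(self):
        with pytest.raises(ValueError):
            gene_flow(1.0, 1.0, 0.0)

    def test_matrix_form_uses_receiving_theta(self):
        labels = ["p1", "p2"]
        theta = pd.Series([0.8, 0.5], index=labels)
        M = pd.DataFrame([[0.0, 2.0], [1.6, 0.0]], index=labels, columns=labels)
        gf = gene_flow_matrix(theta, M)
        # Nm(p1->p2) = theta_p2 * M / 4 = 0.5*2/4 = 0.25
        assert gf.nm.loc["p1", "p2"] == pytest.approx(0.25)
        assert gf.nm.loc["p2", "p1"] == pytest.approx(0.8 * 1.6 / 4)
        off = [0.25, 0.32]
        assert gf.mean == pytest.approx(np.mean(off))
        assert gf.sd == pytest.approx(np.std(off))
        assert gf.max_pair == ("p2", "p1")


def random_dm(rng, n, labels=None):
    a = rng.random((n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return DistanceMatrix(labels or [f"x{i}" for i in range(n)], a)


def mantel_oracle_exact(d1, d2):
    """Complete enumeration of all n! joint row/column permutations."""
    n = len(d1)
    iu = np.triu_indices(n, k=1)
    v1 = d1.values[iu]
    r_obs = np.corrcoef(v1, d2.values[iu])[0, 1]
    hits = 0
    for perm in itertools.permutations(range(n)):
        idx = np.array(perm)
        r_p = np.corrcoef(v1, d2.values[np.ix_(idx, idx)][iu])[0, 1]
        if abs(r_p) >= abs(r_obs) - 1e-12:
            hits += 1
    return r_obs, hits / math.factorial(n)


class TestMantel:
    def test_identical_matrices_have_r_one(self, rng):
        d = random_dm(rng, 6)
        res = mantel(d, d, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [4, 5])
    def test_exact_mode_matches_enumeration_oracle(self, rng, n):
        d1, d2 = random_dm(rng, n), random_dm(rng, n)
        res = mantel(d1, d2, method="exact")
        r_oracle, p_oracle = mantel_oracle_exact(d1, d2)
        assert res.r == pytest.approx(r_oracle)
        assert res.p_value == pytest.approx(p_oracle)
        assert res.n_perm == math.factorial(n)

    @pytest.mark.parametrize("n", [4, 5])
    def test_monte_carlo_converges_to_exact(self, rng, n):
        d1, d2 = random_dm(rng, n), random_dm(rng, n)
        exact = mantel(d1, d2, method="exact")
        mc = mantel(d1, d2, n_perm=20_000, seed=1)
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.02)

    def test_r_invariant_to_constant_shift(self, rng):
        d1, d2 = random_dm(rng, 8), random_dm(rng, 8)
        shifted = d2.values + 0.7
        np.fill_diagonal(shifted, 0.0)
        d2s = DistanceMatrix(d2.labels, shifted)
        assert mantel(d1, d2s, n_perm=9, seed=0).r == pytest.approx(
            mantel(d1, d2, n_perm=9, seed=0).r)

    def test_label_alignment_not_order(self, rng):
        d1 = random_dm(rng, 5)
        d2 = random_dm(rng, 5)
        shuffled = d2.reorder(d2.labels[::-1])
        assert mantel(d1, shuffled, n_perm=9, seed=0).r == pytest.approx(
            mantel(d1, d2, n_perm=9, seed=0).r)

    def test_label_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            mantel(random_dm(rng, 4), random_dm(rng, 4, labels=list("abcd")))

    def test_zero_variance_rejected(self):
        n = 4
        flat = np.ones((n, n)) - np.eye(n)
        d1 = DistanceMatrix(list("abcd"), flat)
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="variance"):
            mantel(d1, random_dm(rng, 4, labels=list("abcd")), n_perm=9)

    def test_type_one_error_rate_near_nominal(self):
        # independent random matrices: rejection rate at alpha=0.05 within
        # the binomial CI over replicates
        reps, n = 200, 12
        rej = 0
        for i in range(reps):
            r = np.random.default_rng(5000 + i)
            rej += mantel(random_dm(r, n), random_dm(r, n),
                          n_perm=199, seed=i).p_value <= 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) < 4 * se

    def test_agrees_with_scikit_bio(self, rng):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        d1, d2 = random_dm(rng, 10), random_dm(rng, 10)
        ours = mantel(d1, d2, n_perm=999, seed=0)
        r_ref, p_ref, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(d1.values, ids=d1.labels),
            skbio_distance.DistanceMatrix(d2.values, ids=d2.labels),
            method="pearson", permutations=999, alternative="two-sided")
        assert ours.r == pytest.approx(r_ref, abs=1e-12)
        # both p-values are independent 999-permutation Monte-Carlo
        # estimates; allow 4 standard errors of their difference
        se_diff = np.sqrt(2 * p_ref * (1 - p_ref) / 999)
        assert abs(ours.p_value - p_ref) < max(4 * se_diff, 0.01)


class TestTTests:
    def test_symmetric_values_give_zero_t(self):
        res = one_sample_t([1.0, 2.0, 3.0], mu0=2.0)
        assert res.t == pytest.approx(0.0)
        assert res.df == 2
        assert res.mean_diff == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_closed_form(self):
        x = np.array([0.1, 0.4, 0.35, 0.2, 0.5])
        res = one_sample_t(x, mu0=0.25)
        t_manual = (x.mean() - 0.25) / (x.std(ddof=1) / np.sqrt(len(x)))
        assert res.t == pytest.approx(t_manual)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([0.5, 0.5, 0.5], mu0=0.4)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([1.0], mu0=0.0)

    def test_two_sample_form_available(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)
        res = two_sample_t(a, b)
        assert res.df == 58
        assert res.mean_diff == pytest.approx(a.mean() - b.mean())


class TestPCASelect:
    def test_uncorrelated_covariates_all_selected(self, rng):
        n = 500
        table = pd.DataFrame({f"v{i}": rng.normal(size=n) for i in range(4)})
        sel = pca_select(table, k=4)
        assert sorted(sel.selected) == ["v0", "v1", "v2", "v3"]

    def test_duplicate_never_selected_twice(self, rng):
        n = 200
        base = rng.normal(size=n)
        table = pd.DataFrame({"a": base, "a_copy": base,
                              "b": rng.normal(size=n), "c": rng.normal(size=n),
                              "d": rng.normal(size=n)})
        sel = pca_select(table, k=4)
        assert len(set(sel.selected)) == 4
        assert not {"a", "a_copy"} <= set(sel.selected)

    def test_constant_covariate_dropped_with_warning(self, rng, caplog):
        import logging
        table = pd.DataFrame({"flat": np.ones(50),
                              **{f"v{i}": rng.normal(size=50) for i in range(4)}})
        with caplog.at_level(logging.WARNING, logger="phylounits.stats"):
            sel = pca_select(table, k=4)
        assert "flat" not in sel.selected
        assert any("constant" in rec.message for rec in caplog.records)

    def test_planted_two_factor_structure_recovered(self):
        # two latent factors, each expressed near-perfectly by one driver
        # covariate and diluted in two noisy echoes; PCA must pick the
        # drivers (three indicators per factor, so loading order follows
        # the factor loadings — with only two a 2x2 correlation block has
        # symmetric eigenvectors and drivers are not identifiable)
        hits = 0
        seeds = range(40)
        for seed in seeds:
            r = np.random.default_rng(seed)
            n = 500
            f1, f2 = r.normal(size=n), r.normal(size=n)
            table = pd.DataFrame({
                "driver1": f1 + 0.05 * r.normal(size=n),
                "echo1a": 0.5 * f1 + r.normal(size=n),
                "echo1b": 0.5 * f1 + r.normal(size=n),
                "driver2": f2 + 0.05 * r.normal(size=n),
                "echo2a": 0.5 * f2 + r.normal(size=n),
                "echo2b": 0.5 * f2 + r.normal(size=n),
            })
            sel = pca_select(table, k=2)
            hits += {"driver1", "driver2"} <= set(sel.selected)
        assert hits / len(seeds) >= 0.95
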