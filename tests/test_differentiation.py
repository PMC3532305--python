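"""Differentiation estimators, geography and Mantel tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import invadiv as iv
from invadiv.differentiation import PairwiseMatrix
from invadiv.io import SiteMetadata

from conftest import make_dataset, random_dataset
from oracles import anova_components_statsmodels, wc_theta_transcription


class TestWcTheta:
    def test_fixed_populations_fully_differentiated(self):
        ds = make_dataset(
            {"p1": [{"l": (100, 100)}] * 3, "p2": [{"l": (102, 102)}] * 3}
        )
        assert iv.wc_theta(ds).global_value == pytest.approx(1.0)

    def test_hand_evaluated_components(self):
        # pop1 = {AA, AA}, pop2 = {AA, BB}: a = 0, c = 0, theta = 0
        ds = make_dataset(
            {
                "p1": [{"l": (100, 100)}, {"l": (100, 100)}],
                "p2": [{"l": (100, 100)}, {"l": (102, 102)}],
            }
        )
        est = iv.wc_theta(ds)
        a, b, c = est.components.iloc[0]
        assert a == pytest.approx(0.0, abs=1e-12)
        assert b == pytest.approx(0.5, abs=1e-12)  # 0.25 per allele
        assert c == pytest.approx(0.0, abs=1e-12)
        assert est.global_value == pytest.approx(0.0, abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_independent_transcription(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_dataset(
            rng,
            n_pops=int(rng.integers(2, 4)),
            n_inds=int(rng.integers(2, 5)),
            n_loci=2,
            n_alleles=3,
        )
        est = iv.wc_theta(ds)
        a = b = c = 0.0
        for loc in ds.locus_names:
            ai, bi, ci = wc_theta_transcription(
                {p: ds.genotypes(p, loc) for p in ds.populations}
            )
            a, b, c = a + ai, b + bi, c + ci
        if a + b + c != 0:
            assert est.global_value == pytest.approx(a / (a + b + c), abs=1e-10)

    def test_monomorphic_everywhere_undefined(self):
        ds = make_dataset({"p1": [{"l": (100, 100)}], "p2": [{"l": (100, 100)}]})
        with pytest.raises(ValueError, match="monomorphic"):
            iv.wc_theta(ds)

    def test_subset_commutes_with_pairwise(self, rng):
        ds = random_dataset(rng, n_pops=4, n_inds=5, n_loci=2, n_alleles=4)
        full = iv.wc_theta(ds, pairwise=True).pairwise
        pair = iv.wc_theta(ds, ["pop1", "pop3"]).global_value
        assert full.value("pop1", "pop3") == pytest.approx(pair, abs=1e-12)
        assert np.allclose(full.values, full.values.T)

    def test_permutation_p_uniform_under_null(self):
        # no structure: rejection rate at 0.05 stays near 0.05
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 120
        for _ in range(n_rep):
            ds = random_dataset(rng, n_pops=2, n_inds=8, n_loci=2, n_alleles=4)
            est = iv.wc_theta(ds, n_perm=199, seed=int(rng.integers(2**31)))
            hits += est.global_p <= 0.05
        assert hits / n_rep == pytest.approx(0.05, abs=0.05)

    def test_bootstrap_ci_brackets_point_for_many_loci(self, rng):
        ds = random_dataset(rng, n_pops=3, n_inds=8, n_loci=6, n_alleles=4)
        est = iv.wc_theta(ds, n_boot=500, seed=5)
        lo, hi = est.ci
        assert lo <= est.global_value <= hi


class TestJostD:
    def test_identical_frequencies_flagged_nonpositive(self):
        ds = make_dataset(
            {
                "p1": [{"l": (100, 102)}, {"l": (100, 102)}],
                "p2": [{"l": (100, 102)}, {"l": (100, 102)}],
            }
        )
        est = iv.jost_d(ds)
        assert est.per_locus.iloc[0] <= 0
        assert est.global_value == 0.0
        assert est.excluded_loci == ["l"]

    def test_fixed_populations(self):
        ds = make_dataset(
            {"p1": [{"l": (100, 100)}] * 3, "p2": [{"l": (102, 102)}] * 3}
        )
        assert iv.jost_d(ds).global_value == pytest.approx(1.0, abs=1e-12)

    def test_harmonic_mean(self):
        from invadiv.differentiation import _harmonic_mean_positive

        assert _harmonic_mean_positive(np.array([0.1, 0.3])) == pytest.approx(0.15)
        assert _harmonic_mean_positive(np.array([-0.2, 0.1, 0.3])) == pytest.approx(0.15)

    def test_bootstrap_resample_converges_to_small_d(self, rng):
        # one population resampled from the other: D_est -> ~0 as n grows
        vals = []
        for rep in range(20):
            base = rng.choice([100, 102, 104, 106, 108], size=200)
            pick = rng.choice(base, size=200)
            p1 = [
                {"l": (int(base[2 * i]), int(base[2 * i + 1]))} for i in range(50)
            ]
            p2 = [
                {"l": (int(pick[2 * i]), int(pick[2 * i + 1]))} for i in range(50)
            ]
            ds = make_dataset({"p1": p1, "p2": p2})
            vals.append(iv.jost_d(ds).global_value)
        assert np.mean(vals) <= 0.05


class TestRst:
    def test_monomorphic_distinct_sizes(self):
        ds = make_dataset(
            {"p1": [{"l": (100, 100)}] * 3, "p2": [{"l": (120, 120)}] * 3}
        )
        assert iv.rst(ds).global_value == pytest.approx(1.0)

    def test_identical_multisets_not_positive(self):
        genos = [{"l": (100, 104)}, {"l": (108, 100)}]
        ds = make_dataset({"p1": list(genos), "p2": list(genos)})
        assert iv.rst(ds).global_value <= 0

    @given(st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_matches_statsmodels_anova_components(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_dataset(
            rng, n_pops=3, n_inds=int(rng.integers(3, 6)), n_loci=1, n_alleles=4
        )
        est = iv.rst(ds, standardize=False)
        sizes = []
        groups = []
        for p in ds.populations:
            for a, b in ds.genotypes(p, "loc0"):
                sizes.extend([a, b])
                groups.extend([p, p])
        sizes = np.array(sizes, dtype=float)
        if sizes.std() == 0:
            return
        among, within = anova_components_statsmodels(sizes, np.array(groups))
        assert est.global_value == pytest.approx(
            among / (among + within), abs=1e-10
        )

    def test_standardisation_changes_locus_weighting_only(self, rng):
        ds = random_dataset(rng, n_pops=3, n_inds=6, n_loci=1, n_alleles=4)
        raw = iv.rst(ds, standardize=False).global_value
        std = iv.rst(ds, standardize=True).global_value
        # single locus: standardisation is a linear map, ratio unchanged
        assert std == pytest.approx(raw, abs=1e-10)


class TestGeography:
    def test_haversine_reference_points(self):
        eq = iv.great_circle_matrix(
            [SiteMetadata("a", 0.0, 0.0), SiteMetadata("b", 0.0, 1.0)]
        )
        assert eq.value("a", "b") == pytest.approx(111.195, abs=1e-3)
        pole = iv.great_circle_matrix(
            [SiteMetadata("a", 0.0, 0.0), SiteMetadata("b", 90.0, 0.0)]
        )
        assert pole.value("a", "b") == pytest.approx(10007.54, abs=1e-2)
        same = iv.great_circle_matrix(
            [SiteMetadata("a", -15.0, -47.0), SiteMetadata("b", -15.0, -47.0)]
        )
        assert same.value("a", "b") == 0.0


class TestMantel:
    def test_identity_gives_r_one(self):
        m = iv.published.pairwise_fst_brazil()
        res = iv.mantel(m, m, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p >= 1 / 100

    def test_published_fst_dest_correlation(self):
        res = iv.mantel(
            iv.published.pairwise_fst_brazil(),
            iv.published.pairwise_dest_brazil(),
            n_perm=999,
            seed=1,
        )
        assert res.r == pytest.approx(0.79, abs=0.005)
        assert res.p < 0.05

    def test_three_site_p_equals_exact_enumeration(self):
        labels = ["a", "b", "c"]
        A = PairwiseMatrix(labels, np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]]))
        B = PairwiseMatrix(labels, np.array([[0, 2, 1], [2, 0, 5], [1, 5, 0.0]]))
        iu = np.triu_indices(3, 1)
        x = A.values[iu]
        r_obs = np.corrcoef(x, B.values[iu])[0, 1]
        exact_hits = sum(
            np.corrcoef(x, B.values[np.ix_(p, p)][iu])[0, 1] >= r_obs - 1e-12
            for p in map(list, itertools.permutations(range(3)))
        )
        exact = exact_hits / 6
        res = iv.mantel(A, B, n_perm=6000, seed=3)
        assert res.p == pytest.approx(exact, abs=0.02)

    def test_relabeling_invariance(self):
        f = iv.published.pairwise_fst_brazil()
        d = iv.published.pairwise_dest_brazil()
        order = list(reversed(f.labels))
        r1 = iv.mantel(f, d, n_perm=0).r
        r2 = iv.mantel(f.subset(order), d.subset(order), n_perm=0).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_ln_transform_requires_positive(self):
        m = iv.published.pairwise_fst_brazil()
        zero = PairwiseMatrix(m.labels, np.zeros_like(m.values))
        with pytest.raises(ValueError, match="positive"):
            iv.mantel(m, zero, transform_b="ln", n_perm=0)

    def test_mismatched_labels_rejected(self):
        with pytest.raises(ValueError):
            iv.mantel(
                iv.published.pairwise_fst_brazil(),
                iv.published.pairwise_fst_europe(),
                n_perm=0,
            )


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,n,expected",
        [(0.05, 15, 0.0033), (0.05, 6, 0.0083), (0.05, 1, 0.05)],
    )
    def test_thresholds(self, alpha, n, expected):
        assert round(iv.bonferroni_threshold(alpha, n), 4) == expected
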