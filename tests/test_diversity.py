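"""Diversity panel: UHe/Ho/F_IS, rarefaction, exact HWE, helpers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import invadiv as iv
from invadiv.diversity import HweResult, _enumerate_tables, _log_table_prob

from conftest import make_dataset
from oracles import hwe_distribution_by_pairing, rarefaction_enumeration


class TestDiversitySummary:
    def test_monomorphic_cell(self):
        ds = make_dataset({"p": [{"l": (100, 100)}] * 10})
        row = iv.diversity_summary(ds).per_locus.iloc[0]
        assert row.Na == 1 and row.Ho == 0 and row.UHe == 0
        assert math.isnan(row.Fis)

    def test_two_individual_hand_calc(self):
        # {150/152, 150/150}: sum p^2 = 0.625, UHe = (4/3)(0.375) = 0.5
        ds = make_dataset({"p": [{"l": (150, 152)}, {"l": (150, 150)}]})
        row = iv.diversity_summary(ds).per_locus.iloc[0]
        assert row.Ho == pytest.approx(0.5)
        assert row.UHe == pytest.approx(0.5)
        assert row.Fis == pytest.approx(0.0)

    def test_all_heterozygous_equifrequent(self):
        ds = make_dataset({"p": [{"l": (100, 102)}] * 10})
        row = iv.diversity_summary(ds).per_locus.iloc[0]
        assert row.Ho == 1.0
        assert row.UHe == pytest.approx(20 / 19 * 0.5)
        assert row.Fis == pytest.approx(1 - 1 / (20 / 19 * 0.5))

    def test_uhe_equals_probability_two_distinct_copies(self, rng):
        # oracle: UHe = P(two gene copies drawn without replacement differ)
        from itertools import permutations

        ds = make_dataset(
            {"p": [{"l": (100, 102)}, {"l": (100, 100)}, {"l": (104, 102)}]}
        )
        copies = [x for g in ds.genotypes("p", "l") for x in g]
        pairs = list(permutations(range(len(copies)), 2))
        frac = sum(copies[i] != copies[j] for i, j in pairs) / len(pairs)
        row = iv.diversity_summary(ds).per_locus.iloc[0]
        assert row.UHe == pytest.approx(frac, abs=1e-12)


class TestRarefaction:
    def test_full_sample_recovers_allele_count(self):
        ds = make_dataset({"p": [{"l": (100, 102)}, {"l": (104, 100)}]})
        f = iv.allele_frequencies(ds)
        out = iv.rarefied_richness(f, g=4)
        assert out.Ar.iloc[0] == pytest.approx(3.0, abs=1e-12)

    def test_small_counts_hand_enumeration(self):
        # counts {A:3, B:1}, g=2: of C(4,2)=6 subsamples 3 have 1 allele
        ds = make_dataset({"p": [{"l": (150, 152)}, {"l": (150, 150)}]})
        out = iv.rarefied_richness(iv.allele_frequencies(ds), g=2)
        assert out.Ar.iloc[0] == pytest.approx(1.5, abs=1e-12)

    def test_private_allele_two_pop_hand_calc(self):
        # pop1 {A:2,B:2}, pop2 {A:4}: Par_2(pop1) = 1 - C(2,2)/C(4,2) = 5/6
        ds = make_dataset(
            {
                "p1": [{"l": (100, 102)}, {"l": (100, 102)}],
                "p2": [{"l": (100, 100)}, {"l": (100, 100)}],
            }
        )
        out = iv.rarefied_richness(iv.allele_frequencies(ds), g=2)
        par = out.set_index("population").Par
        assert par["p1"] == pytest.approx(5 / 6, abs=1e-12)
        # A counts as private-in-sample for p2 when p1's subsample misses it
        assert par["p2"] == pytest.approx(1 / 6, abs=1e-12)

    def test_g_too_large_reports_offending_cells(self):
        ds = make_dataset({"p": [{"l": (100, 102)}]})
        with pytest.raises(ValueError, match="exceeds gene copies"):
            iv.rarefied_richness(iv.allele_frequencies(ds), g=4)

    @given(st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_pops = int(rng.integers(2, 4))
        g = int(rng.integers(1, 7))
        counts_by_pop = {}
        pops = {}
        for p in range(n_pops):
            n_copies = int(rng.integers(g, 13))
            if n_copies % 2:
                n_copies += 1
            sizes = rng.choice([100, 102, 104, 106], n_copies, replace=True)
            inds = [
                {"l": (int(sizes[2 * i]), int(sizes[2 * i + 1]))}
                for i in range(n_copies // 2)
            ]
            pops[f"p{p}"] = inds
            c = {}
            for s in sizes:
                c[int(s)] = c.get(int(s), 0) + 1
            counts_by_pop[f"p{p}"] = c
        ds = make_dataset(pops)
        out = iv.rarefied_richness(iv.allele_frequencies(ds), g=g)
        ar_o, par_o = rarefaction_enumeration(counts_by_pop, g)
        for row in out.itertuples(index=False):
            assert row.Ar == pytest.approx(ar_o[row.population], abs=1e-10)
            assert row.Par == pytest.approx(par_o[row.population], abs=1e-10)

    def test_ar_monotone_in_g(self, rng):
        from conftest import random_dataset

        ds = random_dataset(rng, n_pops=1, n_inds=6, n_loci=1, n_alleles=4)
        f = iv.allele_frequencies(ds)
        ars = [iv.rarefied_richness(f, g).Ar.iloc[0] for g in range(1, 13)]
        assert all(b >= a - 1e-12 for a, b in zip(ars, ars[1:]))


class TestHweExact:
    def _four_ind_dataset(self, n_het):
        n_aa = (4 - n_het) // 2
        genos = (
            [(100, 100)] * n_aa + [(100, 102)] * n_het + [(102, 102)] * n_aa
        )
        return make_dataset({"p": [{"l": g} for g in genos]})

    def test_zero_heterozygotes_two_sided(self):
        res = iv.hwe_exact_test(self._four_ind_dataset(0), "p", "l")
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(6 / 70, abs=1e-12)

    def test_four_heterozygotes_excess_one_sided(self):
        res = iv.hwe_exact_test(self._four_ind_dataset(4), "p", "l")
        assert res.p_excess == pytest.approx(16 / 70, abs=1e-12)

    def test_modal_table_two_sided_at_least_half(self):
        # perfect Hardy-Weinberg proportions: the observed table is modal
        genos = [(100, 100)] * 25 + [(100, 102)] * 50 + [(102, 102)] * 25
        ds = make_dataset({"p": [{"l": g} for g in genos]})
        res = iv.hwe_exact_test(ds, "p", "l")
        assert res.p_two_sided >= 0.5

    def test_enumerated_probabilities_sum_to_one(self, rng):
        from conftest import random_dataset

        ds = random_dataset(rng, n_pops=1, n_inds=5, n_loci=1, n_alleles=3)
        genos = ds.genotypes("pop0", "loc0")
        allele_counts = {}
        for a, b in genos:
            allele_counts[a] = allele_counts.get(a, 0) + 1
            allele_counts[b] = allele_counts.get(b, 0) + 1
        total = sum(
            math.exp(_log_table_prob(t, allele_counts))
            for t in _enumerate_tables(allele_counts, 10**6)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    @given(st.integers(0, 10_000))
    @settings(max_examples=8, deadline=None, derandomize=True)
    def test_matches_pairing_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sizes = [100, 102, 104][: int(rng.integers(2, 4))]
        genos = [
            tuple(sorted(int(x) for x in rng.choice(sizes, 2, replace=True)))
            for _ in range(4)
        ]
        if len({x for g in genos for x in g}) < 2:
            genos[0] = (100, 102)
        ds = make_dataset({"p": [{"l": g} for g in genos]})
        res = iv.hwe_exact_test(ds, "p", "l")
        dist = hwe_distribution_by_pairing(ds.genotypes("p", "l"))
        obs = {}
        for a, b in ds.genotypes("p", "l"):
            key = (min(a, b), max(a, b))
            obs[key] = obs.get(key, 0) + 1
        p_obs = dist[frozenset(obs.items())]
        expected_two = sum(p for p in dist.values() if p <= p_obs + 1e-12)
        assert res.p_two_sided == pytest.approx(expected_two, abs=1e-10)

    def test_monomorphic_undefined(self):
        ds = make_dataset({"p": [{"l": (100, 100)}] * 3})
        with pytest.raises(ValueError, match="monomorphic"):
            iv.hwe_exact_test(ds, "p", "l")

    def test_monte_carlo_close_to_exact(self):
        genos = [(100, 100)] * 4 + [(100, 102)] * 2 + [(102, 102)] * 4
        ds = make_dataset({"p": [{"l": g} for g in genos]})
        exact = iv.hwe_exact_test(ds, "p", "l")
        mc = iv.hwe_exact_test(ds, "p", "l", max_tables=1, mc_reps=20000, seed=7)
        assert mc.method == "monte_carlo"
        assert mc.p_two_sided == pytest.approx(exact.p_two_sided, abs=0.02)


class TestSmallHelpers:
    def test_null_allele_closed_form(self):
        assert iv.null_allele_estimate(0.3, 0.5) == pytest.approx(0.2 / 1.5)
        assert iv.null_allele_estimate(0.5, 0.5) == 0.0
        assert iv.null_allele_estimate(0.6, 0.5) == 0.0  # floored

    def test_time_correlation(self):
        # x = (1, 2, 3), y = (2, 4, 5) -> r = 0.982
        r, df, p = iv.time_correlation([2, 4, 5], [2011, 2010, 2009], 2012)
        assert r == pytest.approx(0.982, abs=1e-3)
        assert df == 1
        r2, _, _ = iv.time_correlation([3, 3, 3], [2011, 2010, 2009], 2012)
        assert math.isnan(r2)
        perfect, _, _ = iv.time_correlation([1, 2, 3], [2011, 2010, 2009], 2012)
        assert perfect == pytest.approx(1.0)

    def test_group_rank_sum(self):
        _, p = iv.group_diversity_test([1, 2, 3], [4, 5, 6], alternative="less")
        assert p == pytest.approx(0.05, abs=1e-12)
        _, p2 = iv.group_diversity_test([1, 2, 3], [1, 2, 3])
        assert p2 == pytest.approx(1.0)
        with pytest.raises(ValueError):
            iv.group_diversity_test([5], [1])
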