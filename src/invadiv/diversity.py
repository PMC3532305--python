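"""Per-population diversity statistics for microsatellite data.

Covers the descriptive panel reported for each sampling site: allele counts
(Na), observed heterozygosity (Ho), unbiased expected heterozygosity (UHe,
Nei's gene diversity with the 2n/(2n-1) correction), the inbreeding
coefficient F_IS = 1 - Ho/UHe, rarefied allelic richness (Ar) and private
allelic richness (Par), an exact Hardy-Weinberg test conditional on allele
counts, a null-allele frequency estimator, diversity-vs-time-since-
colonisation correlation, and rank-sum comparisons between site groups
(e.g. introduced vs native range).

Rarefaction works in gene copies: a sample standardised to g copies, so
"28 alleles" in the hierarchical-rarefaction sense equals 14 diploid
individuals.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .io import AlleleFrequencyTable, GenotypeDataset, allele_frequencies

__all__ = [
    "DiversitySummary",
    "diversity_summary",
    "unbiased_heterozygosity",
    "rarefied_richness",
    "hwe_exact_test",
    "HweResult",
    "null_allele_estimate",
    "time_correlation",
    "group_diversity_test",
]


def unbiased_heterozygosity(counts: dict[int, int] | "pd.Series") -> float:
    """Nei's unbiased gene diversity from gene-copy counts.

    UHe = (2n / (2n - 1)) * (1 - sum p_i^2) with 2n = total gene copies.
    """
    n_genes = sum(counts.values())
    if n_genes < 2:
        return math.nan
    p2 = sum((k / n_genes) ** 2 for k in counts.values())
    return n_genes / (n_genes - 1) * (1.0 - p2)


@dataclass
class DiversitySummary:
    """Per-(population, locus) diversity panel and per-population means."""

    per_locus: pd.DataFrame  # population, locus, n, Na, Ho, UHe, Fis
    per_population: pd.DataFrame  # population-level means over loci

    def to_csv(self, path) -> None:
        self.per_locus.to_csv(path, index=False)


def diversity_summary(
    ds: GenotypeDataset, apply_offsets: bool = False
) -> DiversitySummary:
    """Na, Ho, UHe and F_IS per (population, locus), plus population means.

    Cells with fewer than one typed individual are reported missing;
    monomorphic cells have UHe = 0 and F_IS undefined.
    """
    rows = []
    for pop in ds.populations:
        for loc in ds.locus_names:
            genos = ds.genotypes(pop, loc, apply_offsets=apply_offsets)
            n = len(genos)
            if n == 0:
                rows.append(
                    dict(population=pop, locus=loc, n=0, Na=0, Ho=math.nan,
                         UHe=math.nan, Fis=math.nan)
                )
                continue
            counts: dict[int, int] = {}
            het = 0
            for a, b in genos:
                counts[a] = counts.get(a, 0) + 1
                counts[b] = counts.get(b, 0) + 1
                het += a != b
            ho = het / n
            uhe = unbiased_heterozygosity(counts)
            fis = 1.0 - ho / uhe if uhe and uhe > 0 else math.nan
            rows.append(
                dict(population=pop, locus=loc, n=n, Na=len(counts), Ho=ho,
                     UHe=uhe, Fis=fis)
            )
    per_locus = pd.DataFrame(rows)
    per_pop = (
        per_locus.groupby("population", sort=False)[["Na", "Ho", "UHe", "Fis"]]
        .mean()
        .reset_index()
    )
    n_ind = per_locus.groupby("population", sort=False)["n"].max().reset_index()
    per_pop = n_ind.merge(per_pop, on="population")
    return DiversitySummary(per_locus=per_locus, per_population=per_pop)


# -- rarefaction --------------------------------------------------------------


def _log_comb(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _p_present(n_total: int, n_allele: int, g: int) -> float:
    """Probability an allele with n_allele copies appears in a rarefied
    sample of g copies drawn without replacement from n_total."""
    if n_allele == 0:
        return 0.0
    if n_total - n_allele < g:
        return 1.0
    return 1.0 - math.exp(_log_comb(n_total - n_allele, g) - _log_comb(n_total, g))


def rarefied_richness(
    freqs: AlleleFrequencyTable,
    g: int,
    populations: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Rarefied allelic richness Ar_g and private allelic richness Par_g.

    Ar_g = sum_i P(allele i present in a hypergeometric subsample of g gene
    copies).  Par_g for population j additionally requires the allele to be
    absent from every other population's independent rarefied sample of g
    copies.  Raises if any included (population, locus) cell has fewer than
    g gene copies.
    """
    pops = list(populations) if populations is not None else list(freqs.populations)
    bad = [
        (p, loc)
        for p in pops
        for loc in freqs.locus_names
        if freqs.n_genes(p, loc) < g
    ]
    if bad:
        raise ValueError(
            f"rarefaction size g={g} exceeds gene copies in cells: {bad}"
        )
    rows = []
    for loc in freqs.locus_names:
        alleles = sorted(
            {a for p in pops for a in freqs.counts[(p, loc)]}
        )
        pres = {
            p: {
                a: _p_present(freqs.n_genes(p, loc), freqs.counts[(p, loc)].get(a, 0), g)
                for a in alleles
            }
            for p in pops
        }
        for p in pops:
            ar = sum(pres[p].values())
            par = sum(
                pres[p][a] * math.prod(1.0 - pres[q][a] for q in pops if q != p)
                for a in alleles
            )
            rows.append(dict(population=p, locus=loc, g=g, Ar=ar, Par=par))
    return pd.DataFrame(rows)


# -- exact HWE test -----------------------------------------------------------


@dataclass
class HweResult:
    p_two_sided: float
    p_deficit: float  # heterozygote deficiency (fewer hets than expected)
    p_excess: float  # heterozygote excess
    n_tables: int | None  # enumerated table count, None if Monte Carlo
    method: str  # "exact" | "monte_carlo"


def _log_table_prob(table: dict[tuple[int, int], int], allele_counts: dict[int, int]) -> float:
    """Levene's conditional probability of a genotype table given allele
    counts, on the log scale."""
    n = sum(table.values())
    two_n = 2 * n
    h = sum(v for (a, b), v in table.items() if a != b)
    lp = (
        gammaln(n + 1)
        - gammaln(two_n + 1)
        + sum(gammaln(c + 1) for c in allele_counts.values())
        + h * math.log(2.0)
        - sum(gammaln(v + 1) for v in table.values())
    )
    return lp


def _enumerate_tables(allele_counts: dict[int, int], limit: int):
    """Yield all genotype tables consistent with the allele counts.

    Backtracking over ordered allele pairs; raises OverflowError past
    ``limit`` tables.
    """
    alleles = sorted(allele_counts)
    pairs = [
        (alleles[i], alleles[j])
        for i in range(len(alleles))
        for j in range(i, len(alleles))
    ]
    remaining = dict(allele_counts)
    n_found = 0
    table: dict[tuple[int, int], int] = {}

    def usage(pair, count):
        a, b = pair
        if a == b:
            return {a: 2 * count}
        return {a: count, b: count}

    def rec(idx):
        nonlocal n_found
        if idx == len(pairs):
            if all(v == 0 for v in remaining.values()):
                n_found += 1
                if n_found > limit:
                    raise OverflowError
                yield dict(table)
            return
        a, b = pairs[idx]
        if a == b:
            cap = remaining[a] // 2
        else:
            cap = min(remaining[a], remaining[b])
        # alleles not in any later pair must be exhausted now
        for cnt in range(cap, -1, -1):
            for al, used in usage((a, b), cnt).items():
                remaining[al] -= used
            if cnt:
                table[(a, b)] = cnt
            feasible = all(v >= 0 for v in remaining.values())
            if feasible:
                later = set()
                for p in pairs[idx + 1:]:
                    later.update(p)
                feasible = all(
                    remaining[al] == 0 for al in alleles if al not in later
                )
            if feasible:
                yield from rec(idx + 1)
            for al, used in usage((a, b), cnt).items():
                remaining[al] += used
            table.pop((a, b), None)

    yield from rec(0)


def hwe_exact_test(
    ds: GenotypeDataset,
    population: str,
    locus: str,
    max_tables: int = 1_000_000,
    mc_reps: int = 100_000,
    seed: int | None = None,
) -> HweResult:
    """Exact Hardy-Weinberg test conditional on allele counts (Levene).

    The two-sided p-value is the total conditional probability of genotype
    tables no more probable than the observed one; the one-sided p-values
    use the heterozygote count as the test statistic (deficit: as few or
    fewer heterozygotes; excess: as many or more).  The table space is
    enumerated exactly up to ``max_tables``; beyond that a seeded
    Monte-Carlo shuffle of gene copies is used.
    """
    genos = ds.genotypes(population, locus)
    if len(genos) < 2:
        raise ValueError("need at least 2 typed individuals")
    obs: dict[tuple[int, int], int] = {}
    allele_counts: dict[int, int] = {}
    for a, b in genos:
        key = (min(a, b), max(a, b))
        obs[key] = obs.get(key, 0) + 1
        allele_counts[a] = allele_counts.get(a, 0) + 1
        allele_counts[b] = allele_counts.get(b, 0) + 1
    if len(allele_counts) < 2:
        raise ValueError("monomorphic locus: HWE test undefined")
    lp_obs = _log_table_prob(obs, allele_counts)
    h_obs = sum(v for (a, b), v in obs.items() if a != b)
    tol = 1e-9

    try:
        lps, hs = [], []
        for table in _enumerate_tables(allele_counts, max_tables):
            lps.append(_log_table_prob(table, allele_counts))
            hs.append(sum(v for (a, b), v in table.items() if a != b))
        lps_arr = np.array(lps)
        hs_arr = np.array(hs)
        probs = np.exp(lps_arr)
        probs /= probs.sum()  # guard rounding; sums to 1 analytically
        two = probs[lps_arr <= lp_obs + tol].sum()
        deficit = probs[hs_arr <= h_obs].sum()
        excess = probs[hs_arr >= h_obs].sum()
        return HweResult(float(two), float(deficit), float(excess), len(lps), "exact")
    except OverflowError:
        pass

    rng = np.random.default_rng(seed)
    copies = np.array([a for g in genos for a in g])
    n = len(genos)
    hits_two = hits_def = hits_exc = 0
    for _ in range(mc_reps):
        rng.shuffle(copies)
        tab: dict[tuple[int, int], int] = {}
        for i in range(n):
            a, b = copies[2 * i], copies[2 * i + 1]
            key = (min(a, b), max(a, b))
            tab[key] = tab.get(key, 0) + 1
        lp = _log_table_prob(tab, allele_counts)
        h = sum(v for (a, b), v in tab.items() if a != b)
        hits_two += lp <= lp_obs + tol
        hits_def += h <= h_obs
        hits_exc += h >= h_obs
    corr = mc_reps + 1
    return HweResult(
        (hits_two + 1) / corr, (hits_def + 1) / corr, (hits_exc + 1) / corr,
        None, "monte_carlo",
    )


# -- null alleles, time correlation, group tests ------------------------------


def null_allele_estimate(ho: float, uhe: float) -> float:
    """Brookfield's estimator 1 of null-allele frequency.

    r = (UHe - Ho) / (1 + UHe), floored at zero (an observed-heterozygosity
    excess cannot be null-driven).
    """
    if not uhe > 0:
        raise ValueError("UHe must be positive")
    return max(0.0, (uhe - ho) / (1.0 + uhe))


def time_correlation(
    values: Sequence[float],
    arrival_years: Sequence[float],
    reference_year: int = 2012,
) -> tuple[float, int, float]:
    """Pearson correlation of a diversity index with time since colonisation.

    Time = reference_year - arrival_year.  Returns (r, df, p) with
    df = n - 2; r is NaN when either variable has zero variance.
    """
    y = np.asarray(values, dtype=float)
    x = reference_year - np.asarray(arrival_years, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 sites with both values")
    df = len(x) - 2
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, df, math.nan
    r, p = stats.pearsonr(x, y)
    return float(r), df, float(p)


def group_diversity_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon rank-sum comparison of a diversity index between two site
    groups; returns (W, p) with W the Mann-Whitney statistic of group A
    (as reported by R's ``wilcox.test``).  Exact distribution for small
    samples without ties, mid-ranks otherwise."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="auto")
    return float(res.statistic), float(res.pvalue)
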