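"""Population differentiation estimators and isolation-by-distance tests.

Implements the three differentiation measures used for highly polymorphic
microsatellites:

* Weir & Cockerham's theta (the moment estimator of F_ST from the a/b/c
  variance components, valid under unequal sample sizes), with a
  genotype-permutation significance test and a bootstrap-over-loci CI;
* Jost's D_est from Nei & Chesser's sample-size-corrected H_S and H_T,
  summarised across loci by the harmonic mean of positive per-locus values;
* R_ST, the F_ST analogue for variance in allele size (repeat units),
  estimated by a two-level ANOVA on gene copies, optionally with per-locus
  standardisation of sizes.

Geography: great-circle (haversine) distances on a sphere of radius
6371 km, and Mantel matrix-permutation tests (optionally on log distances)
for isolation by distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenotypeDataset, SiteMetadata

__all__ = [
    "PairwiseMatrix",
    "DifferentiationEstimate",
    "wc_theta",
    "jost_d",
    "rst",
    "great_circle_matrix",
    "mantel",
    "MantelResult",
    "bonferroni_threshold",
    "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class PairwiseMatrix:
    """Symmetric site-by-site matrix of a distance or differentiation
    measure; the diagonal is undefined (kept at 0)."""

    labels: list[str]
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix is not symmetric")

    @classmethod
    def from_pairs(cls, labels: Sequence[str], pairs: dict, name: str = "") -> "PairwiseMatrix":
        labels = list(labels)
        k = len(labels)
        m = np.zeros((k, k))
        for (a, b), v in pairs.items():
            i, j = labels.index(a), labels.index(b)
            m[i, j] = m[j, i] = v
        return cls(labels, m, name)

    def offdiag(self) -> np.ndarray:
        """Condensed upper-triangle vector (row-major pair order)."""
        iu = np.triu_indices(len(self.labels), 1)
        return self.values[iu]

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def subset(self, labels: Sequence[str]) -> "PairwiseMatrix":
        idx = [self.labels.index(l) for l in labels]
        return PairwiseMatrix(list(labels), self.values[np.ix_(idx, idx)], self.name)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class DifferentiationEstimate:
    """A differentiation statistic with its uncertainty summaries."""

    statistic: str  # "theta" | "d_est" | "r_st"
    global_value: float
    per_locus: pd.Series
    pairwise: PairwiseMatrix | None = None
    global_p: float | None = None
    pairwise_p: PairwiseMatrix | None = None
    ci: tuple[float, float] | None = None  # bootstrap over loci, 95%
    components: pd.DataFrame | None = None  # per-locus a, b, c (theta) etc.
    excluded_loci: list[str] = field(default_factory=list)


# -- Weir & Cockerham theta ---------------------------------------------------


def _wc_locus_components(ds: GenotypeDataset, pops: Sequence[str], locus: str):
    """Summed a, b, c variance components over alleles at one locus.

    Follows the unequal-sample-size moment formulas with r populations,
    sample sizes n_i (typed individuals), allele frequencies p_i and
    heterozygote frequencies h_i per population.
    """
    per_pop = []
    for p in pops:
        genos = ds.genotypes(p, locus)
        if genos:
            per_pop.append((p, genos))
    r = len(per_pop)
    if r < 2:
        return 0.0, 0.0, 0.0
    ns = np.array([len(g) for _, g in per_pop], dtype=float)
    nbar = ns.mean()
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    n_c = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
    alleles = sorted({x for _, g in per_pop for ab in g for x in ab})
    a_sum = b_sum = c_sum = 0.0
    for allele in alleles:
        p_i = np.array(
            [sum((a == allele) + (b == allele) for a, b in g) / (2 * len(g))
             for _, g in per_pop]
        )
        h_i = np.array(
            [sum((a != b) and (allele in (a, b)) for a, b in g) / len(g)
             for _, g in per_pop]
        )
        pbar = (ns * p_i).sum() / (r * nbar)
        s2 = (ns * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ns * h_i).sum() / (r * nbar)
        a = (nbar / n_c) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def _theta_from_components(comp: pd.DataFrame) -> float:
    tot = (comp["a"] + comp["b"] + comp["c"]).sum()
    return float(comp["a"].sum() / tot) if tot != 0 else math.nan


def _permuted_dataset(ds: GenotypeDataset, pops: Sequence[str], rng) -> GenotypeDataset:
    """Shuffle whole multilocus genotypes among populations (sizes kept)."""
    inds = [(p, i) for p in pops for i in ds.individuals(p)]
    rows = [ds.calls[p][i] for p, i in inds]
    order = rng.permutation(len(rows))
    calls: dict = {p: {} for p in pops}
    j = 0
    for p in pops:
        for _ in ds.individuals(p):
            calls[p][f"ind{j}"] = rows[order[j]]
            j += 1
    return GenotypeDataset(list(pops), list(ds.loci), calls,
                           offset_populations=frozenset())


def wc_theta(
    ds: GenotypeDataset,
    pops: Sequence[str] | None = None,
    n_perm: int = 0,
    n_boot: int = 0,
    pairwise: bool = False,
    pairwise_perm: int = 0,
    seed: int | None = None,
) -> DifferentiationEstimate:
    """Multi-locus Weir-Cockerham theta with permutation p and bootstrap CI.

    The permutation null shuffles whole genotypes among populations
    (preserving within-individual allele pairing); p is one-sided with the
    +1/(n_perm+1) correction.  The 95% CI resamples loci with replacement.
    """
    pops = list(pops) if pops is not None else list(ds.populations)
    if len(pops) < 2:
        raise ValueError("theta needs at least 2 populations")
    rng = np.random.default_rng(seed)
    comp = pd.DataFrame(
        [_wc_locus_components(ds, pops, loc) for loc in ds.locus_names],
        columns=["a", "b", "c"],
        index=ds.locus_names,
    )
    informative = (comp.sum(axis=1) != 0)
    if not informative.any():
        raise ValueError("all loci monomorphic: theta undefined")
    per_locus = comp["a"] / comp.sum(axis=1).where(informative)
    theta = _theta_from_components(comp)

    global_p = None
    if n_perm > 0:
        hits = 0
        for _ in range(n_perm):
            perm = _permuted_dataset(ds, pops, rng)
            pcomp = pd.DataFrame(
                [_wc_locus_components(perm, pops, loc) for loc in ds.locus_names],
                columns=["a", "b", "c"],
            )
            hits += _theta_from_components(pcomp) >= theta
        global_p = (hits + 1) / (n_perm + 1)

    ci = None
    if n_boot > 0 and informative.sum() > 1:
        loci = np.array(ds.locus_names)
        boots = np.empty(n_boot)
        for i in range(n_boot):
            pick = rng.integers(0, len(loci), len(loci))
            boots[i] = _theta_from_components(comp.iloc[pick])
        ci = (float(np.nanpercentile(boots, 2.5)),
              float(np.nanpercentile(boots, 97.5)))

    pw = pw_p = None
    if pairwise:
        k = len(pops)
        m = np.zeros((k, k))
        mp = np.full((k, k), np.nan)
        for i in range(k):
            for j in range(i + 1, k):
                sub = wc_theta(ds, [pops[i], pops[j]], n_perm=pairwise_perm,
                               seed=int(rng.integers(2**31)))
                m[i, j] = m[j, i] = sub.global_value
                if pairwise_perm:
                    mp[i, j] = mp[j, i] = sub.global_p
        pw = PairwiseMatrix(pops, m, "theta")
        if pairwise_perm:
            np.fill_diagonal(mp, 0.0)
            pw_p = PairwiseMatrix(pops, mp, "theta_p")

    return DifferentiationEstimate(
        "theta", theta, per_locus, pairwise=pw, global_p=global_p,
        pairwise_p=pw_p, ci=ci, components=comp,
    )


# -- Jost's D_est -------------------------------------------------------------


def _dest_locus(ds: GenotypeDataset, pops: Sequence[str], locus: str) -> float:
    """Per-locus D_est from Nei & Chesser's corrected H_S and H_T."""
    stats = []
    for p in pops:
        genos = ds.genotypes(p, locus)
        if genos:
            n = len(genos)
            counts: dict[int, int] = {}
            het = 0
            for a, b in genos:
                counts[a] = counts.get(a, 0) + 1
                counts[b] = counts.get(b, 0) + 1
                het += a != b
            freqs = {al: c / (2 * n) for al, c in counts.items()}
            stats.append((n, freqs, het / n))
    k = len(stats)
    if k < 2:
        return math.nan
    ntilde = k / sum(1 / n for n, _, _ in stats)  # harmonic mean sample size
    ho = sum(h for _, _, h in stats) / k
    mean_sum_p2 = sum(sum(f**2 for f in fr.values()) for _, fr, _ in stats) / k
    hs = ntilde / (ntilde - 1) * (1 - mean_sum_p2 - ho / (2 * ntilde))
    alleles = {al for _, fr, _ in stats for al in fr}
    sum_pbar2 = sum(
        (sum(fr.get(al, 0.0) for _, fr, _ in stats) / k) ** 2 for al in alleles
    )
    ht = 1 - sum_pbar2 + hs / (ntilde * k) - ho / (2 * ntilde * k)
    if 1 - hs <= 0:
        return math.nan
    return (ht - hs) / (1 - hs) * k / (k - 1)


def _harmonic_mean_positive(values: np.ndarray) -> float:
    pos = values[values > 0]
    if len(pos) == 0:
        return 0.0
    return float(len(pos) / (1.0 / pos).sum())


def jost_d(
    ds: GenotypeDataset,
    pops: Sequence[str] | None = None,
    n_boot: int = 0,
    pairwise: bool = False,
    seed: int | None = None,
    summary: str = "harmonic",
) -> DifferentiationEstimate:
    """Jost's D_est per locus with a multi-locus harmonic-mean summary.

    Non-positive per-locus values are excluded from the harmonic mean and
    listed in ``excluded_loci`` (an arithmetic mean over all loci is
    available via ``summary="arithmetic"``).  CI by bootstrap over loci.
    """
    pops = list(pops) if pops is not None else list(ds.populations)
    if len(pops) < 2:
        raise ValueError("D_est needs at least 2 populations")
    rng = np.random.default_rng(seed)
    per_locus = pd.Series(
        [_dest_locus(ds, pops, loc) for loc in ds.locus_names],
        index=ds.locus_names, dtype=float,
    )
    usable = per_locus.dropna()
    excluded = list(usable.index[usable <= 0])

    def summarise(vals: np.ndarray) -> float:
        if summary == "harmonic":
            return _harmonic_mean_positive(vals)
        return float(np.nanmean(vals))

    d_global = summarise(usable.to_numpy())
    ci = None
    if n_boot > 0 and len(usable) > 1:
        vals = usable.to_numpy()
        boots = np.array(
            [summarise(vals[rng.integers(0, len(vals), len(vals))])
             for _ in range(n_boot)]
        )
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))

    pw = None
    if pairwise:
        k = len(pops)
        m = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                sub = jost_d(ds, [pops[i], pops[j]], summary=summary)
                m[i, j] = m[j, i] = sub.global_value
        pw = PairwiseMatrix(pops, m, "d_est")

    return DifferentiationEstimate(
        "d_est", d_global, per_locus, pairwise=pw, ci=ci, excluded_loci=excluded,
    )


# -- R_ST ---------------------------------------------------------------------


def _size_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Among/within variance components from a one-way unequal-n ANOVA on
    gene-copy values; returns (sigma2_among, sigma2_within)."""
    ns = np.array([len(g) for g in groups], dtype=float)
    k = len(groups)
    n_total = ns.sum()
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = sum(((g - m) ** 2).sum() for g, m in zip(groups, means))
    msb = ssb / (k - 1)
    msw = ssw / (n_total - k) if n_total > k else 0.0
    n0 = (n_total - (ns**2).sum() / n_total) / (k - 1)
    return (msb - msw) / n0, msw


def rst(
    ds: GenotypeDataset,
    pops: Sequence[str] | None = None,
    standardize: bool = True,
    pairwise: bool = False,
    seed: int | None = None,
) -> DifferentiationEstimate:
    """R_ST: differentiation in allele size under stepwise mutation.

    Allele sizes are converted to repeat units when the locus declares a
    motif length (falling back to raw bp otherwise), optionally centred and
    scaled per locus by the global mean/sd over the included populations.
    Variance components come from a one-way unequal-n ANOVA on gene copies;
    R_ST = among / (among + within), summed over loci for the multi-locus
    value.  Loci with no size variance are skipped.
    """
    pops = list(pops) if pops is not None else list(ds.populations)
    if len(pops) < 2:
        raise ValueError("R_ST needs at least 2 populations")
    per_locus = {}
    among_total = within_total = 0.0
    skipped = []
    for loc in ds.loci:
        groups = []
        for p in pops:
            sizes = [
                float(x) for a, b in ds.genotypes(p, loc.name) for x in (a, b)
            ]
            if sizes:
                groups.append(np.array(sizes))
        if len(groups) < 2:
            skipped.append(loc.name)
            continue
        if loc.motif_length:
            groups = [
                np.round((g - loc.size_reference) / loc.motif_length) for g in groups
            ]
        allv = np.concatenate(groups)
        if allv.std() == 0:
            skipped.append(loc.name)
            continue
        if standardize:
            mu, sd = allv.mean(), allv.std(ddof=1)
            groups = [(g - mu) / sd for g in groups]
        among, within = _size_anova(groups)
        denom = among + within
        per_locus[loc.name] = among / denom if denom != 0 else math.nan
        among_total += among
        within_total += within
    if not per_locus:
        raise ValueError("no locus with allele-size variance")
    global_rst = among_total / (among_total + within_total)

    pw = None
    if pairwise:
        k = len(pops)
        m = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                sub = rst(ds, [pops[i], pops[j]], standardize=standardize)
                m[i, j] = m[j, i] = sub.global_value
        pw = PairwiseMatrix(pops, m, "r_st")

    return DifferentiationEstimate(
        "r_st", float(global_rst), pd.Series(per_locus), pairwise=pw,
        excluded_loci=skipped,
    )


# -- geography and Mantel -----------------------------------------------------


def great_circle_matrix(sites: Sequence[SiteMetadata]) -> PairwiseMatrix:
    """Haversine great-circle distances in km (sphere radius 6371 km)."""
    lat = np.radians([s.latitude for s in sites])
    lon = np.radians([s.longitude for s in sites])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (
        np.sin(dlat / 2) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    )
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return PairwiseMatrix([s.site for s in sites], d, "great_circle_km")


@dataclass
class MantelResult:
    r: float
    p: float | None
    n_perm: int
    alternative: str


def mantel(
    a: PairwiseMatrix,
    b: PairwiseMatrix,
    n_perm: int = 999,
    transform_b: str | None = None,
    alternative: str = "one-sided",
    seed: int | None = None,
) -> MantelResult:
    """Mantel matrix-correlation test.

    r is the Pearson correlation over the n(n-1)/2 unordered off-diagonal
    pairs.  Significance permutes B's site labels jointly over rows and
    columns; the default one-sided p is taken in the sign of the observed r,
    with the +1/(n_perm+1) correction.  ``transform_b="ln"`` takes natural
    logs of B's off-diagonal values (errors on non-positive entries).
    """
    if a.labels != b.labels:
        raise ValueError("matrices must share the same site labels in order")
    bv = b.values.copy()
    if transform_b == "ln":
        off = ~np.eye(len(b.labels), dtype=bool)
        if np.any(bv[off] <= 0):
            raise ValueError("ln transform requires positive distances")
        bv[off] = np.log(bv[off])
    elif transform_b is not None:
        raise ValueError(f"unknown transform {transform_b!r}")
    iu = np.triu_indices(len(a.labels), 1)
    x = a.values[iu]

    def corr(m):
        y = m[iu]
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(bv)
    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(a.labels))
            r_perm = corr(bv[np.ix_(perm, perm)])
            if alternative == "two-sided":
                hits += abs(r_perm) >= abs(r_obs) - 1e-12
            elif r_obs >= 0:
                hits += r_perm >= r_obs - 1e-12
            else:
                hits += r_perm <= r_obs + 1e-12
        p = (hits + 1) / (n_perm + 1)
    return MantelResult(r_obs, p, n_perm, alternative)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Bonferroni-adjusted per-test significance threshold alpha/n."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
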