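"""Independent brute-force oracles used to validate the estimators.

Everything here is deliberately written from first principles —
enumeration, permutation counting, eigen-decomposition, or a second
transcription of the published formulas — and never calls the package's
own computational path for the quantity it checks.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np


def rarefaction_enumeration(counts_by_pop: dict[str, dict[str, int]], g: int):
    """Exhaustive Ar_g and Par_g by enumerating every C(N, g) subsample.

    ``counts_by_pop``: population -> allele -> gene-copy count.  Returns
    (ar, par) dicts keyed by population.  Ar is the mean number of distinct
    alleles over subsamples; Par combines, per allele, the exhaustively
    computed presence probabilities of independent subsamples.
    """
    presence: dict[str, dict[str, float]] = {}
    ar: dict[str, float] = {}
    alleles = sorted({a for c in counts_by_pop.values() for a in c})
    for pop, counts in counts_by_pop.items():
        copies = [a for a, k in counts.items() for _ in range(k)]
        subs = list(itertools.combinations(range(len(copies)), g))
        n_distinct = []
        present = Counter()
        for sub in subs:
            seen = {copies[i] for i in sub}
            n_distinct.append(len(seen))
            for a in seen:
                present[a] += 1
        ar[pop] = float(np.mean(n_distinct))
        presence[pop] = {a: present[a] / len(subs) for a in alleles}
    par = {
        pop: sum(
            presence[pop][a]
            * math.prod(1.0 - presence[q][a] for q in counts_by_pop if q != pop)
            for a in alleles
        )
        for pop in counts_by_pop
    }
    return ar, par


def hwe_distribution_by_pairing(genotypes: list[tuple[int, int]]):
    """Exact Levene distribution by enumerating all pairings of gene copies.

    Returns {table (frozenset of ((a,b), count)): probability} computed by
    counting how many of the (2n)! orderings of the gene copies produce
    each genotype table when paired consecutively.
    """
    copies = [x for g in genotypes for x in g]
    tally: Counter = Counter()
    total = 0
    for perm in itertools.permutations(copies):
        table = Counter()
        for i in range(0, len(perm), 2):
            a, b = sorted(perm[i : i + 2])
            table[(a, b)] += 1
        tally[frozenset(table.items())] += 1
        total += 1
    return {t: c / total for t, c in tally.items()}


def wc_theta_transcription(pop_genotypes: dict[str, list[tuple[int, int]]]):
    """Second, independent transcription of the Weir-Cockerham (1984)
    variance components; returns (a, b, c) summed over alleles."""
    pops = [p for p, g in pop_genotypes.items() if g]
    r = len(pops)
    n = {p: len(pop_genotypes[p]) for p in pops}
    nbar = sum(n.values()) / r
    nc = (r * nbar - sum(v * v for v in n.values()) / (r * nbar)) / (r - 1)
    alleles = sorted({x for g in pop_genotypes.values() for ab in g for x in ab})
    A = B = C = 0.0
    for al in alleles:
        p_tilde = {}
        h_tilde = {}
        for p in pops:
            genos = pop_genotypes[p]
            p_tilde[p] = sum((a == al) + (b == al) for a, b in genos) / (2 * n[p])
            h_tilde[p] = sum(
                1 for a, b in genos if a != b and al in (a, b)
            ) / n[p]
        pbar = sum(n[p] * p_tilde[p] for p in pops) / (r * nbar)
        s2 = sum(n[p] * (p_tilde[p] - pbar) ** 2 for p in pops) / ((r - 1) * nbar)
        hbar = sum(n[p] * h_tilde[p] for p in pops) / (r * nbar)
        A += (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) * s2 / r - hbar / 4) / (nbar - 1)
        )
        B += (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) * s2 / r - (2 * nbar - 1) * hbar / (4 * nbar)
        )
        C += hbar / 2
    return A, B, C


def pillai_eigen(y: np.ndarray, groups: np.ndarray) -> float:
    """Pillai trace by explicit eigen-decomposition of (H+E)^-1 H."""
    grand = y.mean(axis=0)
    p = y.shape[1]
    h = np.zeros((p, p))
    e = np.zeros((p, p))
    for lev in np.unique(groups):
        sub = y[groups == lev]
        d = (sub.mean(axis=0) - grand)[:, None]
        h += len(sub) * (d @ d.T)
        resid = sub - sub.mean(axis=0)
        e += resid.T @ resid
    eigvals = np.linalg.eigvals(np.linalg.inv(h + e) @ h)
    return float(np.real(eigvals).sum())


def anova_components_statsmodels(values: np.ndarray, groups: np.ndarray):
    """Among/within variance components via statsmodels' ANOVA table."""
    import pandas as pd
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame({"y": values, "g": groups.astype(str)})
    fit = ols("y ~ C(g)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=1)
    msb = tab.loc["C(g)", "sum_sq"] / tab.loc["C(g)", "df"]
    msw = tab.loc["Residual", "sum_sq"] / tab.loc["Residual", "df"]
    ns = pd.Series(groups).value_counts().to_numpy(dtype=float)
    n_tot = ns.sum()
    k = len(ns)
    n0 = (n_tot - (ns**2).sum() / n_tot) / (k - 1)
    return (msb - msw) / n0, msw
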