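"""P_ST: phenotypic differentiation and its sensitivity to c/h^2.

P_ST is the phenotypic analogue of Q_ST computed from a one-way
ANOVA/ANCOVA decomposition of a trait into among-site (sigma^2_B) and
within-site (sigma^2_W) variance components:

    P_ST = (r * sigma^2_B) / (r * sigma^2_B + 2 * sigma^2_W),   r = c / h^2

where h^2 is the within-population heritability and c the proportion of
the between-population variance attributable to additive genetic effects.
Because neither c nor h^2 is knowable for wild populations, P_ST is traced
over a grid of the ratio r in [0, 2]; the *critical ratio* is the smallest
r at which the lower 95% confidence bound of P_ST exceeds the upper 95%
confidence bound of the neutral F_ST interval.  A small critical ratio
(<< 1) is robust evidence that divergent selection, not drift, shaped the
trait.

Confidence intervals take P_ST approximately normal with critical values
of t at df = k - 1 (k sites).  The standard error can come from a
parametric (delta-method) treatment of the ANOVA mean squares — the
default, since it propagates the between-site sampling of the k site
means — or from a nonparametric bootstrap over individuals within sites
(``ci_method="bootstrap"``), which conditions on the observed site
effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VarianceComponents",
    "PstCurve",
    "variance_components",
    "pst_value",
    "critical_ratio",
    "pst_sensitivity",
]


def critical_ratio(
    ratios: np.ndarray, lower: np.ndarray, fst_upper: float
) -> float | None:
    """Smallest grid ratio whose lower P_ST bound exceeds the F_ST upper
    bound, or None if the bound is never cleared."""
    above = np.nonzero(np.asarray(lower) > fst_upper)[0]
    return float(np.asarray(ratios)[above[0]]) if above.size else None


@dataclass
class VarianceComponents:
    """One-way ANCOVA variance components for one trait (one sex)."""

    trait: str
    sex: str | None
    sigma2_b: float  # among-site component, truncated at 0
    sigma2_w: float  # residual mean square
    sigma2_b_raw: float  # untruncated (MS_site - MS_res)/n0
    k: int
    group_sizes: list[int]
    n0: float
    ms_site: float
    ms_residual: float
    df_site: int
    df_residual: int


def _ancova_ms(y: np.ndarray, site_codes: np.ndarray, covariate: np.ndarray | None):
    """Mean squares for the site factor (adjusted for the covariate) and the
    residual, via least squares on dummy-coded design matrices."""
    n = len(y)
    k = int(site_codes.max()) + 1
    dummies = np.zeros((n, k))
    dummies[np.arange(n), site_codes] = 1.0
    base = [np.ones((n, 1))]
    extra_df = 0
    if covariate is not None:
        base.append(covariate[:, None])
        extra_df = 1
    x_reduced = np.hstack(base)
    x_full = np.hstack(base + [dummies[:, 1:]])  # drop one level

    def sse(x):
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        r = y - x @ beta
        return float(r @ r)

    sse_red = sse(x_reduced)
    sse_full = sse(x_full)
    df_site = k - 1
    df_res = n - k - extra_df
    if df_res <= 0:
        raise ValueError("not enough residual degrees of freedom")
    ms_site = (sse_red - sse_full) / df_site
    ms_res = sse_full / df_res
    return ms_site, ms_res, df_site, df_res


def variance_components(
    pheno: pd.DataFrame,
    trait: str,
    sex: str | None = None,
    covariate: str | None = "body_length",
    site_col: str = "site",
    sex_col: str = "sex",
) -> VarianceComponents:
    """Among- and within-site variance components for one trait.

    Fits a one-way ANCOVA with site as factor (and, by default, body length
    as covariate — pass ``covariate=None`` when analysing body length
    itself).  sigma^2_W is the residual mean square; the among component is
    (MS_site - MS_residual)/n0 with the unequal-n effective group size
    n0 = (N - sum n_i^2 / N) / (k - 1), truncated at zero (the raw value is
    retained in ``sigma2_b_raw``).
    """
    if covariate == trait:
        raise ValueError("covariate must differ from the trait")
    df = pheno
    if sex is not None:
        df = df[df[sex_col] == sex]
    cols = [site_col, trait] + ([covariate] if covariate else [])
    df = df.dropna(subset=cols)
    sites, codes = np.unique(df[site_col].to_numpy(), return_inverse=True)
    k = len(sites)
    if k < 2:
        raise ValueError("need at least 2 sites")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        raise ValueError("every site needs at least 2 individuals")
    y = df[trait].to_numpy(dtype=float)
    cov = df[covariate].to_numpy(dtype=float) if covariate else None
    ms_site, ms_res, df_site, df_res = _ancova_ms(y, codes, cov)
    n_total = sizes.sum()
    n0 = (n_total - (sizes.astype(float) ** 2).sum() / n_total) / (k - 1)
    raw = (ms_site - ms_res) / n0
    return VarianceComponents(
        trait=trait, sex=sex, sigma2_b=max(0.0, raw), sigma2_w=ms_res,
        sigma2_b_raw=raw, k=k, group_sizes=sizes.tolist(), n0=float(n0),
        ms_site=ms_site, ms_residual=ms_res, df_site=df_site, df_residual=df_res,
    )


def pst_value(vc: VarianceComponents, ratio: float) -> float:
    """P_ST at one c/h^2 ratio: (r*s2B) / (r*s2B + 2*s2W)."""
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    denom = ratio * vc.sigma2_b + 2.0 * vc.sigma2_w
    if denom == 0:
        return math.nan
    return ratio * vc.sigma2_b / denom


@dataclass
class PstCurve:
    """P_ST and its 95% CI along the c/h^2 grid, vs an F_ST interval."""

    trait: str
    sex: str | None
    ratios: np.ndarray
    pst: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    fst_interval: tuple[float, float]
    critical_ratio: float | None  # None when the lower CI never clears F_ST
    components: VarianceComponents | None = None
    ci_method: str = "anova"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(ratio=self.ratios, pst=self.pst, lower=self.lower, upper=self.upper)
        )


def _pst_se_delta(vc: VarianceComponents, ratios: np.ndarray) -> np.ndarray:
    """Delta-method SE of P_ST from the sampling variances of the ANOVA
    mean squares (chi-square theory for a one-way random-effects layout)."""
    var_msb = 2.0 * vc.ms_site**2 / vc.df_site
    var_msw = 2.0 * vc.ms_residual**2 / vc.df_residual
    var_b = (var_msb + var_msw) / vc.n0**2
    var_w = var_msw
    cov_bw = -var_msw / vc.n0
    b, w = vc.sigma2_b, vc.sigma2_w
    denom = (ratios * b + 2.0 * w) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        dpdb = 2.0 * ratios * w / denom
        dpdw = -2.0 * ratios * b / denom
    var_p = dpdb**2 * var_b + dpdw**2 * var_w + 2.0 * dpdb * dpdw * cov_bw
    return np.sqrt(np.clip(var_p, 0.0, None))


def _pst_se_bootstrap(
    pheno, trait, sex, covariate, site_col, sex_col, ratios, n_boot, rng
) -> np.ndarray:
    df = pheno
    if sex is not None:
        df = df[df[sex_col] == sex]
    cols = [site_col, trait] + ([covariate] if covariate else [])
    df = df.dropna(subset=cols).reset_index(drop=True)
    groups = {s: sub.index.to_numpy() for s, sub in df.groupby(site_col)}
    curves = np.empty((n_boot, len(ratios)))
    for i in range(n_boot):
        for _ in range(100):  # redraw degenerate resamples
            idx = np.concatenate(
                [rng.choice(ix, size=len(ix), replace=True) for ix in groups.values()]
            )
            try:
                vc = variance_components(
                    df.loc[idx], trait, sex=None, covariate=covariate,
                    site_col=site_col, sex_col=sex_col,
                )
            except (ValueError, np.linalg.LinAlgError):
                continue
            curves[i] = [pst_value(vc, r) for r in ratios]
            break
        else:
            raise RuntimeError("bootstrap failed to produce a valid resample")
    return curves.std(axis=0, ddof=1)


def pst_sensitivity(
    pheno: pd.DataFrame,
    trait: str,
    sex: str | None,
    fst_interval: tuple[float, float],
    covariate: str | None = "body_length",
    grid_step: float = 0.01,
    grid_max: float = 2.0,
    n_boot: int = 1000,
    seed: int | None = None,
    ci_method: str = "anova",
    site_col: str = "site",
    sex_col: str = "sex",
) -> PstCurve:
    """P_ST with 95% CIs across the c/h^2 grid and the critical ratio.

    The CI at each grid point is point +/- t(0.975, k-1) * SE, with SE from
    the delta method on the ANOVA mean squares (``ci_method="anova"``,
    default) or a stratified bootstrap over individuals within sites
    (``ci_method="bootstrap"``).  The critical ratio is the smallest grid
    value whose lower bound exceeds the upper end of ``fst_interval``; by
    monotonicity of P_ST in the ratio it then stays above for every larger
    ratio.
    """
    vc = variance_components(
        pheno, trait, sex=sex, covariate=covariate, site_col=site_col, sex_col=sex_col
    )
    ratios = np.round(np.arange(0.0, grid_max + grid_step / 2, grid_step), 10)
    pst = np.array([pst_value(vc, r) for r in ratios])
    if ci_method == "anova":
        se = _pst_se_delta(vc, ratios)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        se = _pst_se_bootstrap(
            pheno, trait, sex, covariate, site_col, sex_col, ratios, n_boot, rng
        )
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    tcrit = stats.t.ppf(0.975, df=vc.k - 1)
    lower = np.clip(pst - tcrit * se, 0.0, 1.0)
    upper = np.clip(pst + tcrit * se, 0.0, 1.0)
    critical = critical_ratio(ratios, lower, fst_interval[1])
    return PstCurve(
        trait=trait, sex=sex, ratios=ratios, pst=pst, lower=lower, upper=upper,
        fst_interval=tuple(fst_interval), critical_ratio=critical,
        components=vc, ci_method=ci_method,
    )
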