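"""Plumage reflectance colorimetry, morphometrics and MANOVA.

Reflectance processing follows standard avian colorimetry practice:
replicate spectra are linearly interpolated onto the 1-nm grid 300-700 nm
(401 points), averaged per sample x patch, and negative reflectance is
clipped to zero.  Two metrics summarise each processed spectrum:

* brightness: mean % reflectance over the band, so a flat 0% spectrum
  (black) scores 0 and a flat 100% spectrum (white) scores 100 — identical
  to trapezoid area divided by bandwidth on this uniform grid;
* UV-chroma: proportion of total reflectance falling in the ultraviolet
  band 300-400 nm (inclusive endpoints, 101 of the 401 points).

Morphometric screening uses robust Mahalanobis distances from a minimum
covariance determinant (MCD) fit with a chi-square cutoff; divergence of
site centroids is tested with MANOVA (Pillai trace and its standard
approximate F).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import MinCovDet

__all__ = [
    "WAVELENGTH_GRID",
    "SPECTRA_CSV_COLUMNS",
    "process_spectra",
    "color_metrics",
    "color_table",
    "outlier_filter",
    "ManovaResult",
    "manova_pillai",
]

WAVELENGTH_GRID = np.arange(300, 701)  # 1-nm grid, 401 points
_UV_MASK = WAVELENGTH_GRID <= 400

SPECTRA_CSV_COLUMNS = ["id", "patch", "replicate", "wavelength_nm", "reflectance_pct"]


def process_spectra(raw: pd.DataFrame) -> pd.DataFrame:
    """Average replicate spectra onto the 1-nm 300-700 nm grid.

    ``raw`` is long-form with columns ``SPECTRA_CSV_COLUMNS``.  Each
    replicate is interpolated linearly onto the grid, replicates are
    averaged pointwise per (id, patch), and negative values are clipped to
    zero.  Raises if any replicate's wavelength range does not cover
    [300, 700] nm.

    Returns a wide DataFrame indexed by (id, patch) with one column per
    wavelength.
    """
    missing = [c for c in SPECTRA_CSV_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"spectra table missing columns {missing}")
    out = {}
    for (sid, patch), grp in raw.groupby(["id", "patch"], sort=False):
        reps = []
        for _, rep in grp.groupby("replicate", sort=True):
            wl = rep["wavelength_nm"].to_numpy(dtype=float)
            refl = rep["reflectance_pct"].to_numpy(dtype=float)
            order = np.argsort(wl)
            wl, refl = wl[order], refl[order]
            if wl.min() > 300 or wl.max() < 700:
                raise ValueError(
                    f"replicate for {sid}/{patch} covers [{wl.min()}, {wl.max()}] nm, "
                    "not the full 300-700 nm band"
                )
            reps.append(np.interp(WAVELENGTH_GRID, wl, refl))
        out[(sid, patch)] = np.clip(np.mean(reps, axis=0), 0.0, None)
    idx = pd.MultiIndex.from_tuples(out.keys(), names=["id", "patch"])
    return pd.DataFrame(list(out.values()), index=idx, columns=WAVELENGTH_GRID)


def color_metrics(spectrum: np.ndarray) -> tuple[float, float]:
    """Brightness and UV-chroma of one processed spectrum (401 points).

    Brightness is the mean % reflectance; UV-chroma the share of summed
    reflectance in 300-400 nm.  An all-zero spectrum has brightness 0 and
    undefined (NaN) UV-chroma.
    """
    r = np.asarray(spectrum, dtype=float)
    if r.shape != WAVELENGTH_GRID.shape:
        raise ValueError(f"expected {len(WAVELENGTH_GRID)} points, got {r.shape}")
    brightness = float(r.mean())
    total = r.sum()
    uv = float(r[_UV_MASK].sum() / total) if total > 0 else math.nan
    return brightness, uv


def color_table(processed: pd.DataFrame) -> pd.DataFrame:
    """Per (id, patch) brightness and UV-chroma from processed spectra."""
    rows = []
    for (sid, patch), row in processed.iterrows():
        b, uv = color_metrics(row.to_numpy())
        rows.append(dict(id=sid, patch=patch, brightness=b, uv_chroma=uv))
    return pd.DataFrame(rows)


def outlier_filter(
    traits: pd.DataFrame | np.ndarray,
    quantile: float = 0.975,
    random_state: int = 0,
) -> np.ndarray:
    """Flag multivariate outliers by robust Mahalanobis distance.

    Fits a minimum-covariance-determinant estimator and flags rows whose
    squared robust distance exceeds the chi-square ``quantile`` at
    df = number of traits.  Apply per stratum (e.g. per sex); requires
    more rows than traits.
    """
    x = np.asarray(traits, dtype=float)
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than traits ({p})")
    try:
        mcd = MinCovDet(random_state=random_state).fit(x)
    except Exception as exc:  # singular robust covariance
        raise ValueError(
            "singular robust covariance; reduce the trait set or check for "
            "constant/collinear traits"
        ) from exc
    d2 = mcd.mahalanobis(x)
    return d2 > stats.chi2.ppf(quantile, df=p)


@dataclass
class ManovaResult:
    pillai: float
    f_value: float
    df1: int
    df2: int
    p: float
    n_obs: int
    n_groups: int
    n_responses: int


def manova_pillai(responses: pd.DataFrame | np.ndarray, groups) -> ManovaResult:
    """One-way MANOVA: Pillai trace V with the standard approximate F.

    V = trace(H (H + E)^-1) from the between-group (H) and within-group (E)
    cross-product matrices; the F approximation uses the usual
    s = min(p, g-1), m = (|p-g+1|-1)/2, n = (N-g-p-1)/2 parameterisation
    with df = (s(2m+s+1), s(2n+s+1)).
    """
    y = np.asarray(responses, dtype=float)
    g = np.asarray(groups)
    if y.ndim == 1:
        y = y[:, None]
    n_obs, p = y.shape
    levels = pd.unique(g)
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    grand = y.mean(axis=0)
    h = np.zeros((p, p))
    e = np.zeros((p, p))
    for lev in levels:
        sub = y[g == lev]
        mean = sub.mean(axis=0)
        d = (mean - grand)[:, None]
        h += len(sub) * d @ d.T
        r = sub - mean
        e += r.T @ r
    he = h + e
    try:
        v = float(np.trace(np.linalg.solve(he, h)))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular H + E matrix") from exc
    s = min(p, k - 1)
    m = (abs(p - k + 1) - 1) / 2.0
    n_par = (n_obs - k - p - 1) / 2.0
    df1 = int(round(s * (2 * m + s + 1)))
    df2 = int(round(s * (2 * n_par + s + 1)))
    if df2 <= 0 or v >= s:
        f_value = math.inf if v >= s else math.nan
        p_value = 0.0 if v >= s else math.nan
    else:
        f_value = (df2 / df1) * (v / (s - v))
        p_value = float(stats.f.sf(f_value, df1, df2))
    return ManovaResult(v, float(f_value), df1, df2, p_value, n_obs, k, p)
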