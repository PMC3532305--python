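"""Published summary data for the Brazilian house sparrow introduction.

The original study of introduced house sparrows (*Passer domesticus*) in
Brazil deposited no raw genotypes, but its printed summary tables — site
coordinates and arrival years, per-site diversity panels, and the pairwise
F_ST / D_est / R_ST matrices for the six Brazilian and four European
populations — are sufficient inputs for the matrix-level analyses
(isolation by distance, cross-statistic Mantel correlations, Bonferroni
thresholds).  This module ships those tables as ready-made objects, in the
spirit of a ``datasets`` submodule.

Coordinates are given as printed (degrees + minutes + hemisphere) and
parsed to signed decimal degrees.
"""

from __future__ import annotations

import pandas as pd

from .differentiation import PairwiseMatrix
from .io import SiteMetadata, parse_coordinates

__all__ = [
    "BRAZIL_SITES",
    "EUROPE_SITES",
    "brazil_sites",
    "europe_sites",
    "brazil_site_metadata",
    "pairwise_fst_brazil",
    "pairwise_dest_brazil",
    "pairwise_rst_brazil",
    "pairwise_fst_europe",
    "pairwise_dest_europe",
]

BRAZIL_SITES = ["Brasilia", "Caceres", "Belem", "Recife", "Niteroi", "Canoas"]
EUROPE_SITES = ["Sweden", "Bulgaria", "Italy", "Spain"]

# site, longitude, latitude, arrival year, and the per-site diversity panel
# (Na, Ar, Par, Ho, UHe, Fis; Ar3/Par3 use only the three cross-study loci)
_BRAZIL_ROWS = [
    ("Brasilia", "47° 53' W", "15° 47' S", 1957, 12.00, 11.65, 6.98, 1.63, 0.00, 0.81, 0.89, 0.08),
    ("Caceres", "57° 41' W", "16° 05' S", 1998, 11.17, 10.85, 7.75, 0.84, 0.00, 0.77, 0.79, 0.03),
    ("Belem", "48° 29' W", "01° 27' S", 1978, 11.83, 11.46, 7.69, 1.80, 0.11, 0.80, 0.83, 0.05),
    ("Recife", "34° 55' W", "08° 05' S", 1963, 11.33, 11.23, 7.55, 0.93, 0.33, 0.71, 0.84, 0.16),
    ("Niteroi", "43° 08' W", "22° 54' S", 1905, 12.00, 11.65, 6.92, 1.64, 0.27, 0.84, 0.84, -0.01),
    ("Canoas", "51° 11' W", "29° 55' S", 1925, 10.50, 10.16, 5.94, 0.98, 0.00, 0.70, 0.76, 0.08),
]

_EUROPE_ROWS = [
    ("Sweden", "13° E", "55° N", None, 11.50, 8.88, 8.00, 2.91, 0.77, 0.75, 0.89, 0.17),
    ("Bulgaria", "26° E", "44° N", None, 10.50, 8.92, 8.77, 2.37, 0.65, 0.83, 0.89, 0.08),
    ("Italy", "14° E", "41° N", None, 17.67, 10.02, 8.45, 3.41, 1.30, None, 0.91, 0.02),
    ("Spain", "06° W", "39° N", None, 18.00, 10.48, 9.64, 3.64, 1.83, 0.81, 0.93, 0.13),
]

_COLUMNS = [
    "site", "longitude_dms", "latitude_dms", "arrival_year",
    "Na", "Ar", "Ar3", "Par", "Par3", "Ho", "UHe", "Fis",
]


def _sites_frame(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df["longitude"] = df["longitude_dms"].map(parse_coordinates)
    df["latitude"] = df["latitude_dms"].map(parse_coordinates)
    return df


def brazil_sites() -> pd.DataFrame:
    """Brazilian sites: coordinates, arrival year, diversity panel."""
    return _sites_frame(_BRAZIL_ROWS)


def europe_sites() -> pd.DataFrame:
    """European (native-range) sites and their diversity panel."""
    return _sites_frame(_EUROPE_ROWS)


def brazil_site_metadata() -> list[SiteMetadata]:
    return [
        SiteMetadata(r.site, r.latitude, r.longitude, r.arrival_year)
        for r in brazil_sites().itertuples(index=False)
    ]


# pairwise matrices: keyed (row-site, column-site), one entry per unordered pair

_FST_BRAZIL = {
    ("Caceres", "Brasilia"): 0.0355, ("Belem", "Brasilia"): 0.0235,
    ("Belem", "Caceres"): 0.0050, ("Recife", "Brasilia"): 0.0183,
    ("Recife", "Caceres"): 0.0098, ("Recife", "Belem"): 0.0128,
    ("Niteroi", "Brasilia"): 0.0405, ("Niteroi", "Caceres"): 0.0313,
    ("Niteroi", "Belem"): 0.0175, ("Niteroi", "Recife"): 0.0278,
    ("Canoas", "Brasilia"): 0.0400, ("Canoas", "Caceres"): 0.0316,
    ("Canoas", "Belem"): 0.0361, ("Canoas", "Recife"): 0.0268,
    ("Canoas", "Niteroi"): 0.0695,
}

_DEST_BRAZIL = {
    ("Brasilia", "Caceres"): 0.0580, ("Brasilia", "Belem"): 0.1233,
    ("Brasilia", "Recife"): 0.0558, ("Brasilia", "Niteroi"): 0.1221,
    ("Brasilia", "Canoas"): 0.1646, ("Caceres", "Belem"): 0.0161,
    ("Caceres", "Recife"): 0.0532, ("Caceres", "Niteroi"): 0.1888,
    ("Caceres", "Canoas"): 0.0878, ("Belem", "Recife"): 0.0803,
    ("Belem", "Niteroi"): 0.1112, ("Belem", "Canoas"): 0.1382,
    ("Recife", "Niteroi"): 0.1130, ("Recife", "Canoas"): 0.1644,
    ("Niteroi", "Canoas"): 0.2510,
}

_RST_BRAZIL = {
    ("Caceres", "Brasilia"): -0.0073, ("Belem", "Brasilia"): 0.0107,
    ("Belem", "Caceres"): 0.0300, ("Recife", "Brasilia"): -0.0046,
    ("Recife", "Caceres"): -0.0063, ("Recife", "Belem"): 0.0262,
    ("Niteroi", "Brasilia"): 0.0024, ("Niteroi", "Caceres"): 0.0490,
    ("Niteroi", "Belem"): 0.0037, ("Niteroi", "Recife"): 0.0373,
    ("Canoas", "Brasilia"): 0.0512, ("Canoas", "Caceres"): 0.0326,
    ("Canoas", "Belem"): 0.0912, ("Canoas", "Recife"): 0.0407,
    ("Canoas", "Niteroi"): 0.1448,
}

_FST_EUROPE = {
    ("Bulgaria", "Sweden"): 0.0258, ("Italy", "Sweden"): 0.0219,
    ("Italy", "Bulgaria"): 0.0328, ("Spain", "Sweden"): 0.0176,
    ("Spain", "Bulgaria"): 0.0262, ("Spain", "Italy"): 0.0043,
}

_DEST_EUROPE = {
    ("Sweden", "Bulgaria"): 0.2000, ("Sweden", "Italy"): 0.2002,
    ("Sweden", "Spain"): 0.1210, ("Bulgaria", "Italy"): 0.2844,
    ("Bulgaria", "Spain"): 0.2491, ("Italy", "Spain"): 0.0461,
}

# the study's reported global estimates (with 95% CIs) for reference use
GLOBAL_FST_BRAZIL = (0.028, (0.016, 0.046))
GLOBAL_FST_EUROPE = (0.019, (0.010, 0.031))
GLOBAL_RST_BRAZIL = (0.033, (0.031, 0.1111))


def pairwise_fst_brazil() -> PairwiseMatrix:
    return PairwiseMatrix.from_pairs(BRAZIL_SITES, _FST_BRAZIL, "theta")


def pairwise_dest_brazil() -> PairwiseMatrix:
    return PairwiseMatrix.from_pairs(BRAZIL_SITES, _DEST_BRAZIL, "d_est")


def pairwise_rst_brazil() -> PairwiseMatrix:
    return PairwiseMatrix.from_pairs(BRAZIL_SITES, _RST_BRAZIL, "r_st")


def pairwise_fst_europe() -> PairwiseMatrix:
    return PairwiseMatrix.from_pairs(EUROPE_SITES, _FST_EUROPE, "theta")


def pairwise_dest_europe() -> PairwiseMatrix:
    return PairwiseMatrix.from_pairs(EUROPE_SITES, _DEST_EUROPE, "d_est")
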