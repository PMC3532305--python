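"""Microsatellite genotype containers and readers/writers.

The central container is :class:`GenotypeDataset`: diploid allele-size calls
(base pairs) for a set of populations, individuals and loci, with explicit
missing-data support.  GenePop is the canonical interchange format; an
equivalent long-form CSV reader/writer is provided for spreadsheet workflows.
Column schemas for all CSV interfaces are documented in ``docs/schemas.md``.

A genotype is either fully missing or has both alleles present; half-calls
are rejected on construction.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Locus",
    "SiteMetadata",
    "GenotypeDataset",
    "AlleleFrequencyTable",
    "GenePopError",
    "parse_genepop",
    "write_genepop",
    "parse_coordinates",
    "read_long_csv",
    "write_long_csv",
    "read_site_metadata",
    "allele_frequencies",
]


class GenePopError(ValueError):
    """Raised for malformed GenePop content."""


@dataclass(frozen=True)
class Locus:
    """Descriptor of one microsatellite locus.

    Parameters
    ----------
    name
        Locus label.
    motif_length
        Repeat motif length in bp (e.g. 2 for a dinucleotide).  Required only
        for analyses in repeat units (R_ST); ``None`` means "analyse raw
        sizes".
    size_offset
        Calibration offset in bp added to allele sizes of the dataset's
        ``offset_populations`` when frequencies are computed with
        ``apply_offsets=True`` (cross-platform allele-size harmonisation).
    size_reference
        Reference size in bp subtracted before conversion to repeat units.
    """

    name: str
    motif_length: int | None = None
    size_offset: int = 0
    size_reference: int = 0


@dataclass(frozen=True)
class SiteMetadata:
    """One sampling site: label, decimal coordinates and arrival year."""

    site: str
    latitude: float
    longitude: float
    arrival_year: int | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")


Genotype = tuple[int, int]
CallMap = Mapping[str, Mapping[str, Mapping[str, Genotype | None]]]


@dataclass
class GenotypeDataset:
    """Diploid microsatellite calls for populations x individuals x loci.

    ``calls[pop][ind][locus]`` is an unordered pair of allele sizes in bp, or
    ``None`` for a missing genotype.  Populations and loci keep file order.
    """

    populations: list[str]
    loci: list[Locus]
    calls: dict[str, dict[str, dict[str, Genotype | None]]]
    offset_populations: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        locus_names = {l.name for l in self.loci}
        if len(locus_names) != len(self.loci):
            raise ValueError("duplicate locus names")
        if len(set(self.populations)) != len(self.populations):
            raise ValueError("duplicate population labels")
        for pop in self.calls:
            if pop not in self.populations:
                raise ValueError(f"call references undeclared population {pop!r}")
            for ind, by_locus in self.calls[pop].items():
                for loc, g in by_locus.items():
                    if loc not in locus_names:
                        raise ValueError(f"call references undeclared locus {loc!r}")
                    if g is None:
                        continue
                    a, b = g
                    if (
                        float(a) != int(a) or float(b) != int(b)
                        or a <= 0 or b <= 0
                    ):
                        raise ValueError(
                            f"allele sizes must be positive integers, got {g!r} "
                            f"({pop}/{ind}/{loc})"
                        )
                    by_locus[loc] = (int(a), int(b))
        unknown = self.offset_populations - set(self.populations)
        if unknown:
            raise ValueError(f"offset_populations not in dataset: {sorted(unknown)}")

    # -- convenience accessors -------------------------------------------------

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def locus(self, name: str) -> Locus:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(name)

    def individuals(self, pop: str) -> list[str]:
        return list(self.calls.get(pop, {}))

    def genotypes(
        self, pop: str, locus: str, apply_offsets: bool = False
    ) -> list[Genotype]:
        """Non-missing genotypes for one (population, locus) cell."""
        off = 0
        if apply_offsets and pop in self.offset_populations:
            off = self.locus(locus).size_offset
        out = []
        for by_locus in self.calls.get(pop, {}).values():
            g = by_locus.get(locus)
            if g is not None:
                out.append((g[0] + off, g[1] + off))
        return out

    def subset(self, pops: Sequence[str]) -> "GenotypeDataset":
        missing = [p for p in pops if p not in self.populations]
        if missing:
            raise KeyError(f"unknown populations: {missing}")
        return GenotypeDataset(
            populations=list(pops),
            loci=list(self.loci),
            calls={p: {i: dict(g) for i, g in self.calls[p].items()} for p in pops},
            offset_populations=self.offset_populations & set(pops),
        )

    def with_loci(self, names: Sequence[str]) -> "GenotypeDataset":
        keep = set(names)
        unknown = keep - set(self.locus_names)
        if unknown:
            raise KeyError(f"unknown loci: {sorted(unknown)}")
        return GenotypeDataset(
            populations=list(self.populations),
            loci=[l for l in self.loci if l.name in keep],
            calls={
                p: {
                    i: {loc: g for loc, g in by.items() if loc in keep}
                    for i, by in self.calls[p].items()
                }
                for p in self.calls
            },
            offset_populations=self.offset_populations,
        )


# -- GenePop ------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def parse_genepop(text: str) -> GenotypeDataset:
    """Parse GenePop-format content (2- or 3-digit allele encoding).

    Allele codes are interpreted directly as fragment sizes in bp; an
    all-zero code ("0000"/"000000") marks a missing genotype.  A population
    is labelled by its first individual's id; ids written as
    ``label:individual`` (the convention of :func:`write_genepop`) are split
    so that population labels round-trip.
    """
    lines = text.splitlines()
    if len(lines) < 3:
        raise GenePopError("file too short to be GenePop")
    body = lines[1:]
    # locus names: either one per line until the first "Pop", or one
    # comma-separated line
    locus_names: list[str] = []
    i = 0
    while i < len(body) and not _POP_RE.match(body[i]):
        chunk = [s.strip() for s in body[i].split(",") if s.strip()]
        locus_names.extend(chunk)
        i += 1
    if not locus_names:
        raise GenePopError("no locus names before first 'Pop'")
    if i == len(body):
        raise GenePopError("no 'Pop' separator found")

    pops: list[str] = []
    calls: dict[str, dict[str, dict[str, Genotype | None]]] = {}
    width: int | None = None
    cur: str | None = None
    for lineno, raw in enumerate(body[i:], start=i + 2):
        if not raw.strip():
            continue
        if _POP_RE.match(raw):
            cur = None
            continue
        if "," not in raw:
            raise GenePopError(f"line {lineno}: expected 'id , genotypes'")
        ind_part, geno_part = raw.split(",", 1)
        ind_id = ind_part.strip()
        tokens = geno_part.split()
        if len(tokens) != len(locus_names):
            raise GenePopError(
                f"line {lineno}: {len(tokens)} genotypes for {len(locus_names)} loci"
            )
        if ":" in ind_id:
            pop_label, ind_id = ind_id.split(":", 1)
        else:
            pop_label = None
        if cur is None:
            cur = pop_label if pop_label is not None else ind_id
            if cur in calls:
                cur = f"{cur}_{len(pops) + 1}"
            pops.append(cur)
            calls[cur] = {}
        row: dict[str, Genotype | None] = {}
        for loc, tok in zip(locus_names, tokens):
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise GenePopError(
                    f"line {lineno}: genotype {tok!r} is not 4 or 6 digits"
                )
            w = len(tok) // 2
            if width is None:
                width = w
            elif w != width:
                raise GenePopError(
                    f"line {lineno}: mixed allele encoding widths ({w} vs {width})"
                )
            a, b = int(tok[:w]), int(tok[w:])
            if a == 0 and b == 0:
                row[loc] = None
            elif a == 0 or b == 0:
                raise GenePopError(
                    f"line {lineno}: half-missing genotype {tok!r} at {loc}"
                )
            else:
                row[loc] = (a, b)
        calls[cur][ind_id] = row
    loci = [Locus(name) for name in locus_names]
    return GenotypeDataset(populations=pops, loci=loci, calls=calls)


def write_genepop(ds: GenotypeDataset, title: str = "invadiv export") -> str:
    """Serialise to GenePop; inverse of :func:`parse_genepop`.

    Individual ids are written as ``population:individual`` so that labels
    survive a round trip.  Encoding width is 3 digits unless every allele
    fits in 2.
    """
    sizes = [
        s
        for pop in ds.populations
        for by in ds.calls[pop].values()
        for g in by.values()
        if g is not None
        for s in g
    ]
    width = 2 if sizes and max(sizes) < 100 else 3
    if sizes and max(sizes) >= 10**width:
        raise ValueError("allele size too large for GenePop 3-digit encoding")
    out = [title]
    out.extend(ds.locus_names)
    for pop in ds.populations:
        out.append("Pop")
        for ind, by in ds.calls[pop].items():
            toks = []
            for loc in ds.locus_names:
                g = by.get(loc)
                if g is None:
                    toks.append("0" * (2 * width))
                else:
                    toks.append(f"{g[0]:0{width}d}{g[1]:0{width}d}")
            out.append(f"{pop}:{ind} , " + " ".join(toks))
    return "\n".join(out) + "\n"


# -- coordinates --------------------------------------------------------------

_DMS_RE = re.compile(
    r"""^\s*(\d+(?:\.\d+)?)\s*[°º]?\s*(?:(\d+(?:\.\d+)?)\s*['′]?\s*)?([NSEW])\s*$""",
    re.IGNORECASE,
)


def parse_coordinates(dms: str) -> float:
    """Convert a degrees(+minutes)+hemisphere string to signed decimal degrees.

    ``"47° 53' W"`` -> -47.8833...; south and west are negative.
    """
    m = _DMS_RE.match(dms)
    if not m:
        raise ValueError(f"cannot parse coordinate {dms!r} (missing hemisphere?)")
    deg = float(m.group(1))
    minutes = float(m.group(2)) if m.group(2) else 0.0
    if minutes >= 60:
        raise ValueError(f"minutes must be < 60 in {dms!r}")
    val = deg + minutes / 60.0
    if m.group(3).upper() in ("S", "W"):
        val = -val
    return val


# -- CSV interfaces -----------------------------------------------------------

LONG_CSV_COLUMNS = ["population", "individual", "locus", "allele1", "allele2"]


def read_long_csv(path_or_buf) -> GenotypeDataset:
    """Read long-form genotype CSV (columns in ``LONG_CSV_COLUMNS``).

    Missing genotypes carry empty/NA in both allele columns; a half-filled
    row is rejected.
    """
    df = pd.read_csv(path_or_buf)
    missing_cols = [c for c in LONG_CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"genotype CSV missing columns {missing_cols}")
    pops = list(dict.fromkeys(df["population"].astype(str)))
    loci = [Locus(n) for n in dict.fromkeys(df["locus"].astype(str))]
    calls: dict[str, dict[str, dict[str, Genotype | None]]] = {p: {} for p in pops}
    for row in df.itertuples(index=False):
        pop, ind, loc = str(row.population), str(row.individual), str(row.locus)
        a, b = row.allele1, row.allele2
        a_na, b_na = pd.isna(a), pd.isna(b)
        if a_na != b_na:
            raise ValueError(f"half-missing genotype for {pop}/{ind}/{loc}")
        g = None if a_na else (int(a), int(b))
        calls[pop].setdefault(ind, {})[loc] = g
    return GenotypeDataset(populations=pops, loci=loci, calls=calls)


def write_long_csv(ds: GenotypeDataset, path) -> None:
    rows = []
    for pop in ds.populations:
        for ind, by in ds.calls[pop].items():
            for loc in ds.locus_names:
                g = by.get(loc)
                rows.append(
                    {
                        "population": pop,
                        "individual": ind,
                        "locus": loc,
                        "allele1": None if g is None else g[0],
                        "allele2": None if g is None else g[1],
                    }
                )
    pd.DataFrame(rows, columns=LONG_CSV_COLUMNS).to_csv(path, index=False)


def read_site_metadata(path_or_buf, analysis_year: int | None = None) -> list[SiteMetadata]:
    """Read site metadata CSV (site, latitude, longitude, arrival_year).

    Coordinates may be decimal degrees or degree+minute strings such as
    ``47° 53' W``.
    """
    df = pd.read_csv(path_or_buf)
    for c in ("site", "latitude", "longitude"):
        if c not in df.columns:
            raise ValueError(f"site metadata CSV missing column {c!r}")
    out = []
    for row in df.itertuples(index=False):
        lat, lon = row.latitude, row.longitude
        if isinstance(lat, str):
            try:
                lat = float(lat)
            except ValueError:
                lat = parse_coordinates(lat)
        if isinstance(lon, str):
            try:
                lon = float(lon)
            except ValueError:
                lon = parse_coordinates(lon)
        year = getattr(row, "arrival_year", None)
        year = None if year is None or pd.isna(year) else int(year)
        if year is not None and analysis_year is not None and year > analysis_year:
            raise ValueError(f"arrival year {year} is after analysis year")
        out.append(SiteMetadata(str(row.site), float(lat), float(lon), year))
    return out


# -- allele frequencies -------------------------------------------------------

@dataclass
class AlleleFrequencyTable:
    """Gene-copy counts per (population, locus).

    ``counts[(pop, locus)]`` maps allele size -> number of gene copies;
    ``n_genes`` is twice the number of typed individuals in that cell.
    """

    populations: list[str]
    locus_names: list[str]
    counts: dict[tuple[str, str], Counter]

    def n_genes(self, pop: str, locus: str) -> int:
        return sum(self.counts[(pop, locus)].values())

    def frequencies(self, pop: str, locus: str) -> dict[int, float]:
        c = self.counts[(pop, locus)]
        n = sum(c.values())
        return {a: k / n for a, k in c.items()} if n else {}

    def alleles(self, locus: str) -> list[int]:
        seen: set[int] = set()
        for pop in self.populations:
            seen.update(self.counts[(pop, locus)])
        return sorted(seen)


def allele_frequencies(ds: GenotypeDataset, apply_offsets: bool = False) -> AlleleFrequencyTable:
    """Tabulate gene-copy counts per (population, locus).

    With ``apply_offsets`` each locus's declared size offset is added to the
    allele sizes of the dataset's ``offset_populations`` before counting.
    Missing genotypes are excluded cell-wise (no imputation).
    """
    counts: dict[tuple[str, str], Counter] = {}
    for pop in ds.populations:
        for loc in ds.locus_names:
            c: Counter = Counter()
            for a, b in ds.genotypes(pop, loc, apply_offsets=apply_offsets):
                c[a] += 1
                c[b] += 1
            counts[(pop, loc)] = c
    return AlleleFrequencyTable(list(ds.populations), list(ds.locus_names), counts)
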