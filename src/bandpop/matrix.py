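"""Band matrices and population metadata for dominant markers.

Dominant fingerprinting markers (ISSR, AFLP, RAPD) are scored as the
presence or absence of an electrophoretic band; heterozygotes cannot be
distinguished from band-presence homozygotes.  The universal input to
every analysis in this package is therefore a binary individual x locus
phenotype matrix with a population label per individual.

The canonical on-disk dialect is UTF-8 CSV with columns
``individual,population,<locus...>`` and cell codes ``1`` (band present),
``0`` (band absent) and ``NA`` (not scored).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BandMatrix",
    "PopulationTable",
    "GroupAssignment",
    "read_band_matrix",
    "write_band_matrix",
    "read_population_table",
    "read_group_assignment",
    "parse_dms",
    "drop_incomplete_individuals",
    "lynch_milligan_filter",
    "LociFilterReport",
]

MISSING = -1  # internal code for an unscored cell


class BandMatrixError(ValueError):
    """Raised for structurally invalid band matrices or metadata."""


@dataclass
class BandMatrix:
    """Individuals x loci dominant-marker phenotypes.

    Parameters
    ----------
    individuals
        Unique individual labels, one per row.
    populations
        Population label of each individual (parallel to ``individuals``).
    loci
        Unique locus (band) labels, one per column.
    data
        int8 array of shape ``(n_individuals, n_loci)`` with values
        1 (band present), 0 (band absent) or ``MISSING``.
    """

    individuals: list[str]
    populations: list[str]
    loci: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        n, L = self.data.shape
        if len(self.individuals) != n or len(self.populations) != n:
            raise BandMatrixError("individual/population labels do not match data rows")
        if len(self.loci) != L:
            raise BandMatrixError("locus labels do not match data columns")
        if len(set(self.individuals)) != n:
            raise BandMatrixError("duplicate individual labels")
        if len(set(self.loci)) != L:
            raise BandMatrixError("duplicate locus labels")
        bad = ~np.isin(self.data, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise BandMatrixError(
                f"invalid phenotype code {self.data[i, j]} at "
                f"individual {self.individuals[i]!r}, locus {self.loci[j]!r}"
            )

    # -- basic queries -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.data.shape[0]

    @property
    def n_loci(self) -> int:
        return self.data.shape[1]

    @property
    def population_names(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def population_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for p in self.populations:
            sizes[p] = sizes.get(p, 0) + 1
        return sizes

    def has_missing(self) -> bool:
        return bool((self.data == MISSING).any())

    def rows_of(self, population: str) -> np.ndarray:
        mask = np.array([p == population for p in self.populations])
        if not mask.any():
            raise BandMatrixError(f"unknown population {population!r}")
        return np.flatnonzero(mask)

    # -- derived matrices ----------------------------------------------
    def subset_populations(self, keep: Sequence[str]) -> "BandMatrix":
        keep_set = set(keep)
        idx = [i for i, p in enumerate(self.populations) if p in keep_set]
        return BandMatrix(
            [self.individuals[i] for i in idx],
            [self.populations[i] for i in idx],
            list(self.loci),
            self.data[idx],
        )

    def subset_loci(self, keep: Sequence[str]) -> "BandMatrix":
        pos = {l: j for j, l in enumerate(self.loci)}
        cols = [pos[l] for l in keep]
        return BandMatrix(
            list(self.individuals), list(self.populations), list(keep), self.data[:, cols]
        )

    def absent_counts(self, population: str | None = None) -> tuple[np.ndarray, int]:
        """Per-locus count of band-absent phenotypes and the sample size.

        ``population=None`` pools every individual into one sample.
        Missing cells are not allowed (drop them first).
        """
        rows = self.rows_of(population) if population is not None else np.arange(self.n_individuals)
        block = self.data[rows]
        if (block == MISSING).any():
            raise BandMatrixError("matrix contains missing values; drop incomplete individuals first")
        return (block == 0).sum(axis=0), len(rows)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data.astype(object), columns=self.loci)
        df = df.mask(df == MISSING, pd.NA)
        df.insert(0, "population", self.populations)
        df.insert(0, "individual", self.individuals)
        return df


@dataclass
class PopulationTable:
    """Sampling metadata: one row per population.

    ``table`` columns: ``population``, ``n`` (sampled individuals),
    ``latitude``/``longitude`` in signed decimal degrees (south/west
    negative), optional ``elevation_m`` and ``vegetation``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in ("population", "latitude", "longitude"):
            if col not in t.columns:
                raise BandMatrixError(f"population table lacks column {col!r}")
        if t["population"].duplicated().any():
            raise BandMatrixError("duplicate population names")
        if (t["latitude"].abs() > 90).any():
            raise BandMatrixError("latitude outside [-90, 90]")
        if (t["longitude"].abs() > 180).any():
            raise BandMatrixError("longitude outside [-180, 180]")

    @property
    def names(self) -> list[str]:
        return list(self.table["population"])

    def coordinates(self, order: Sequence[str] | None = None) -> np.ndarray:
        t = self.table.set_index("population")
        order = list(order) if order is not None else list(t.index)
        return t.loc[order, ["latitude", "longitude"]].to_numpy(dtype=float)

    def check_against(self, m: BandMatrix) -> None:
        """Verify recorded sample sizes against a band matrix."""
        if "n" not in self.table.columns:
            return
        sizes = m.population_sizes()
        for _, row in self.table.iterrows():
            name = row["population"]
            if name in sizes and int(row["n"]) != sizes[name]:
                raise BandMatrixError(
                    f"population {name!r}: table says n={int(row['n'])}, matrix has {sizes[name]}"
                )


@dataclass
class GroupAssignment:
    """Population -> group labels for hierarchical analyses."""

    group_of: dict[str, str]

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for pop, g in self.group_of.items():
            out.setdefault(g, []).append(pop)
        return out

    def validate(self, m: BandMatrix) -> None:
        missing = [p for p in m.population_names if p not in self.group_of]
        if missing:
            raise BandMatrixError(f"populations without a group: {missing}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_NA_CODES = {"", "na", "nan", "n/a", "?", "-", "."}


def read_band_matrix(source, sep: str = ",") -> BandMatrix:
    """Read a band matrix from delimited text.

    Expects a header ``individual,population,<locus...>`` followed by one
    row per individual with 0/1/NA phenotype codes.  Any non-binary cell
    is rejected with its location.
    """
    df = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise BandMatrixError("band matrix needs individual, population and >=1 locus column")
    individuals = df.iloc[:, 0].astype(str).tolist()
    populations = df.iloc[:, 1].astype(str).tolist()
    loci = [str(c) for c in df.columns[2:]]
    raw = df.iloc[:, 2:].to_numpy(dtype=object)
    data = np.empty(raw.shape, dtype=np.int8)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = str(raw[i, j]).strip()
            if cell in ("0", "1"):
                data[i, j] = int(cell)
            elif cell.lower() in _NA_CODES:
                data[i, j] = MISSING
            else:
                raise BandMatrixError(
                    f"non-binary cell {cell!r} at individual {individuals[i]!r}, "
                    f"locus {loci[j]!r}"
                )
    return BandMatrix(individuals, populations, loci, data)


def write_band_matrix(m: BandMatrix, target) -> None:
    """Write the canonical CSV dialect (codes 1/0/NA)."""
    df = m.to_dataframe()
    df.to_csv(target, index=False, na_rep="NA")


_DMS_RE = re.compile(
    r"""^\s*(?P<deg>\d+(?:\.\d+)?)\s*[°º]?\s*
        (?:(?P<min>\d+(?:\.\d+)?)\s*[´'′`]{1}\s*)?
        (?:(?P<sec>\d+(?:\.\d+)?)\s*(?:[´'′`]{2}|[″"])\s*)?
        (?P<hem>[NSEWnsew])?\s*$""",
    re.VERBOSE,
)


def parse_dms(text: str | float, hemisphere: str | None = None) -> float:
    """Parse a coordinate given in degrees/minutes/seconds or decimal degrees.

    West and south hemispheres (suffix letter or explicit ``hemisphere``)
    yield negative decimal degrees.  Minutes or seconds >= 60 are rejected.
    """
    if isinstance(text, (int, float)) and not isinstance(text, bool):
        value = float(text)
    else:
        s = str(text).strip()
        try:
            value = float(s)
        except ValueError:
            match = _DMS_RE.match(s)
            if match is None:
                raise BandMatrixError(f"cannot parse coordinate {text!r}")
            deg = float(match.group("deg"))
            minutes = float(match.group("min") or 0.0)
            seconds = float(match.group("sec") or 0.0)
            if minutes >= 60 or seconds >= 60:
                raise BandMatrixError(f"minutes/seconds >= 60 in coordinate {text!r}")
            value = deg + minutes / 60.0 + seconds / 3600.0
            hemisphere = match.group("hem") or hemisphere
    if hemisphere and hemisphere.upper() in ("S", "W"):
        value = -abs(value)
    return value


def read_population_table(source, sep: str = ",") -> PopulationTable:
    """Read population metadata with DMS or decimal coordinates.

    Recognised column headers (case-insensitive): ``population``/``name``,
    ``n``, ``latitude``/``latitude_n``, ``longitude``/``longitude_w``,
    ``elevation``/``elevation_m``, ``vegetation``.  A ``_n``/``_w`` suffix
    declares the hemisphere convention of unsigned values.
    """
    df = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    cols = {c.lower().strip(): c for c in df.columns}

    def find(*names: str) -> str | None:
        for n in names:
            if n in cols:
                return cols[n]
        return None

    name_col = find("population", "name")
    lat_col = find("latitude", "latitude_n", "lat")
    lon_col = find("longitude", "longitude_w", "lon")
    if name_col is None or lat_col is None or lon_col is None:
        raise BandMatrixError("population table needs population, latitude, longitude columns")
    lat_hem = "N" if lat_col.lower().endswith("_n") else None
    lon_hem = "W" if lon_col.lower().endswith("_w") else None

    out = pd.DataFrame({"population": df[name_col].astype(str)})
    n_col = find("n", "sample_size")
    if n_col is not None:
        out["n"] = df[n_col].astype(int)
    out["latitude"] = [parse_dms(v, lat_hem) for v in df[lat_col]]
    out["longitude"] = [parse_dms(v, lon_hem) for v in df[lon_col]]
    elev_col = find("elevation", "elevation_m")
    if elev_col is not None:
        out["elevation_m"] = pd.to_numeric(df[elev_col])
    veg_col = find("vegetation")
    if veg_col is not None:
        out["vegetation"] = df[veg_col]
    return PopulationTable(out)


def read_group_assignment(source, sep: str = ",") -> GroupAssignment:
    """Read a two-column ``population,group`` CSV."""
    df = pd.read_csv(source, sep=sep, dtype=str)
    return GroupAssignment(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def drop_incomplete_individuals(
    m: BandMatrix, primer_of: Mapping[str, str] | None = None
) -> tuple[BandMatrix, pd.DataFrame]:
    """Remove individuals with unscored phenotypes.

    With ``primer_of`` (locus -> primer), an individual is removed when it
    failed to amplify for at least one primer, i.e. it has a missing value
    at any locus of that primer.  Without it, any missing value removes
    the individual.  Returns the cleaned matrix and a removal log with one
    row per dropped individual and the reason.
    """
    missing = m.data == MISSING
    drop = missing.any(axis=1)
    reasons: dict[int, str] = {}
    if primer_of is not None:
        primers = sorted({primer_of.get(l, "?") for l in m.loci})
        for i in np.flatnonzero(drop):
            failed = sorted(
                {primer_of.get(m.loci[j], "?") for j in np.flatnonzero(missing[i])}
            )
            reasons[i] = "failed primer(s): " + ", ".join(failed)
        del primers
    else:
        for i in np.flatnonzero(drop):
            n_miss = int(missing[i].sum())
            reasons[i] = f"{n_miss} unscored locus/loci"
    keep = np.flatnonzero(~drop)
    kept_pops = {m.populations[i] for i in keep}
    lost = [p for p in m.population_names if p not in kept_pops]
    if lost:
        raise BandMatrixError(f"dropping incomplete individuals empties population(s): {lost}")
    log = pd.DataFrame(
        {
            "individual": [m.individuals[i] for i in sorted(reasons)],
            "population": [m.populations[i] for i in sorted(reasons)],
            "reason": [reasons[i] for i in sorted(reasons)],
        }
    )
    cleaned = BandMatrix(
        [m.individuals[i] for i in keep],
        [m.populations[i] for i in keep],
        list(m.loci),
        m.data[keep],
    )
    return cleaned, log


@dataclass
class LociFilterReport:
    """Exclusion report of the high-band-frequency filter."""

    unit: str
    N: int
    threshold: float
    excluded: pd.DataFrame  # columns: locus, presence_freq

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"LociFilterReport(unit={self.unit!r}, N={self.N}, "
            f"threshold={self.threshold:.4f}, excluded={len(self.excluded)})"
        )


def lynch_milligan_filter(
    m: BandMatrix, unit: str = "pooled"
) -> tuple[BandMatrix, LociFilterReport]:
    """Exclude loci whose band-presence frequency exceeds 1 - 3/N.

    The square-root estimator of the null-allele frequency from the
    band-absence phenotype frequency x is badly biased when x is tiny;
    Lynch & Milligan's remedy is to analyse only loci observed in at
    least three band-absent individuals, i.e. to drop loci whose
    presence frequency exceeds ``1 - 3/N`` in the sample over which the
    statistic is computed (``unit``: a population label, or ``"pooled"``
    for the whole matrix).
    """
    if unit == "pooled":
        absent, N = m.absent_counts(None)
    else:
        absent, N = m.absent_counts(unit)
    if N < 4:
        raise BandMatrixError(f"filter degenerate for N={N} < 4")
    presence_freq = 1.0 - absent / N
    threshold = 1.0 - 3.0 / N
    drop = presence_freq > threshold + 1e-12
    report = LociFilterReport(
        unit=unit,
        N=int(N),
        threshold=float(threshold),
        excluded=pd.DataFrame(
            {
                "locus": [m.loci[j] for j in np.flatnonzero(drop)],
                "presence_freq": presence_freq[drop],
            }
        ),
    )
    kept = [l for j, l in enumerate(m.loci) if not drop[j]]
    if not kept:
        raise BandMatrixError("filter would remove every locus")
    return m.subset_loci(kept), report
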