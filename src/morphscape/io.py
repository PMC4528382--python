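"""Readers, writers and validated containers for the pipeline's tabular artifacts.

Canonical morph order is ``orange, orange_yellow, yellow, grey`` everywhere;
all distance and frequency vectors follow it.

Formats: Genepop for diploid microsatellite genotypes (2- or 3-digit allele
codes, ``POP``-delimited populations, zero codes = missing), CSV for morph
counts, site covariates, distance matrices and clustering log-likelihood
summaries. Readers validate invariants and raise rather than coerce.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Fixed canonical order of the four throat-colour morphs.
MORPH_ORDER: tuple[str, ...] = ("orange", "orange_yellow", "yellow", "grey")

MISSING = 0  # allele code used for missing data


class FormatError(ValueError):
    """A file violated its format contract or a container invariant."""


# ---------------------------------------------------------------------------
# Morph counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MorphCountTable:
    """Per-population (optionally per-year) counts of the four morphs.

    ``data`` holds one row per (population, year) with non-negative integer
    columns in canonical morph order plus a derived total ``N``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for m in MORPH_ORDER:
            if m not in df.columns:
                raise FormatError(f"morph count table missing column {m!r}")
            col = df[m]
            if (col < 0).any():
                raise FormatError(f"negative count in column {m!r}")
            if not np.allclose(col, col.astype(int)):
                raise FormatError(f"non-integer count in column {m!r}")
        key = ["population"] + (["year"] if "year" in df.columns else [])
        if df.duplicated(subset=key).any():
            raise FormatError("duplicate (population, year) rows")
        n = df[list(MORPH_ORDER)].sum(axis=1)
        if "N" in df.columns and not np.array_equal(df["N"].to_numpy(), n.to_numpy()):
            raise FormatError("N column does not equal the sum of morph counts")
        object.__setattr__(self, "data", df.assign(N=n))

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.data["population"]))

    @property
    def has_years(self) -> bool:
        return "year" in self.data.columns

    def counts_matrix(self, year: int | None = None) -> pd.DataFrame:
        """Populations x morphs integer matrix (optionally one year)."""
        df = self.data
        if year is not None:
            if not self.has_years:
                raise FormatError("table has no year column")
            df = df[df["year"] == year]
        return df.set_index("population")[list(MORPH_ORDER)].astype(int)

    def for_year(self, year: int) -> "MorphCountTable":
        sub = self.data[self.data["year"] == year].drop(columns=["year", "N"])
        return MorphCountTable(sub.reset_index(drop=True))


def read_morph_counts(path: str | Path) -> MorphCountTable:
    df = pd.read_csv(path)
    if "population" not in df.columns:
        raise FormatError(f"{path}: missing 'population' column")
    return MorphCountTable(df)


def write_morph_counts(table: MorphCountTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypePanel:
    """Diploid multi-locus genotypes grouped by population.

    ``genotypes`` has shape ``(n_individuals, n_loci, 2)`` with positive
    integer allele codes and 0 for a missing call (a missing genotype has
    both alleles 0).
    """

    individual_ids: tuple[str, ...]
    populations: tuple[str, ...]  # per individual
    loci: tuple[str, ...]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.int64)
        if g.shape != (len(self.individual_ids), len(self.loci), 2):
            raise FormatError("genotype array shape does not match ids/loci")
        if (g < 0).any():
            raise FormatError("allele codes must be non-negative integers")
        half = (g == MISSING).sum(axis=2)
        if ((half == 1)).any():
            raise FormatError("half-missing genotype (exactly one allele zero)")
        if len(self.populations) != len(self.individual_ids):
            raise FormatError("population labels must match individuals")
        object.__setattr__(self, "genotypes", g)

    @property
    def population_order(self) -> list[str]:
        return list(dict.fromkeys(self.populations))

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def subset(self, populations: Sequence[str]) -> "GenotypePanel":
        keep = [i for i, p in enumerate(self.populations) if p in set(populations)]
        return GenotypePanel(
            tuple(self.individual_ids[i] for i in keep),
            tuple(self.populations[i] for i in keep),
            self.loci,
            self.genotypes[keep],
        )

    def population_genotypes(self, population: str, locus_index: int) -> np.ndarray:
        """Non-missing (n, 2) genotype rows for one population at one locus."""
        mask = np.array([p == population for p in self.populations])
        g = self.genotypes[mask, locus_index, :]
        return g[(g != MISSING).all(axis=1)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypePanel):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.populations == other.populations
            and self.loci == other.loci
            and np.array_equal(self.genotypes, other.genotypes)
        )


def _parse_allele_pair(token: str, lineno: int) -> tuple[int, int]:
    token = token.strip()
    if len(token) not in (4, 6) or not token.isdigit():
        raise FormatError(f"line {lineno}: bad genotype token {token!r}")
    w = len(token) // 2
    return int(token[:w]), int(token[w:])


def read_genepop(path: str | Path) -> GenotypePanel:
    """Parse a Genepop file (2- or 3-digit alleles, POP-delimited)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    # header: title line, then locus names (one per line or comma-separated)
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        chunk = [s.strip() for s in lines[i].split(",") if s.strip()]
        if not chunk:
            raise FormatError(f"line {i + 1}: blank line in locus list")
        loci.extend(chunk)
        i += 1
    if i == len(lines):
        raise FormatError(f"{path}: no POP delimiter found")
    ids: list[str] = []
    pops: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    block_start: list[int] = []
    pop_index = 0
    while i < len(lines):
        if lines[i].strip().upper() == "POP":
            pop_index += 1
            block_start.append(len(ids))
            i += 1
            continue
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if "," not in line:
            raise FormatError(f"line {i + 1}: expected 'id , genotypes'")
        ind_id, geno_part = line.split(",", 1)
        tokens = geno_part.split()
        if len(tokens) != len(loci):
            raise FormatError(
                f"line {i + 1}: {len(tokens)} genotypes for {len(loci)} loci"
            )
        ids.append(ind_id.strip())
        pops.append(f"pop{pop_index}")
        rows.append([_parse_allele_pair(t, i + 1) for t in tokens])
        i += 1
    if not ids:
        raise FormatError(f"{path}: no individuals")
    # Recover population labels from a shared "<pop>_<n>" id prefix per block.
    block_start.append(len(ids))
    for b in range(len(block_start) - 1):
        seg = ids[block_start[b] : block_start[b + 1]]
        prefixes = {s.rsplit("_", 1)[0] for s in seg if "_" in s}
        if len(prefixes) == 1 and all("_" in s for s in seg):
            label = prefixes.pop()
            for j in range(block_start[b], block_start[b + 1]):
                pops[j] = label
    g = np.array(rows, dtype=np.int64)
    # normalise half-missing calls to fully missing
    half = (g == MISSING).any(axis=2) & ~(g == MISSING).all(axis=2)
    g[half] = MISSING
    return GenotypePanel(tuple(ids), tuple(pops), tuple(loci), g)


def write_genepop(panel: GenotypePanel, path: str | Path, title: str = "morphscape export") -> None:
    """Write a 3-digit-allele Genepop file; round-trips with read_genepop."""
    if panel.genotypes.max(initial=0) > 999:
        raise FormatError("allele codes exceed 3-digit Genepop encoding")
    out = [title]
    out.extend(panel.loci)
    for pop in panel.population_order:
        out.append("POP")
        for i, p in enumerate(panel.populations):
            if p != pop:
                continue
            ind = panel.individual_ids[i]
            if not ind.startswith(f"{pop}_"):
                ind = f"{pop}_{ind}"
            geno = " ".join(
                f"{a:03d}{b:03d}" for a, b in panel.genotypes[i]
            )
            out.append(f"{ind} , {geno}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Sites
# ---------------------------------------------------------------------------

SITE_COVARIATES = ("aridity", "topography", "vegetation", "rock")
_PROPORTION_COVARIATES = ("vegetation", "rock")


@dataclass(frozen=True)
class SiteTable:
    """Site coordinates and environmental covariates.

    One row per site with decimal-degree ``lat``/``lon``, site-level
    covariates (aridity index — lower is drier; topographic relief) and
    per-site mean microhabitat proportions (vegetation, rock) in [0, 1].
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("site", "lat", "lon"):
            if col not in df.columns:
                raise FormatError(f"site table missing column {col!r}")
        if df["site"].duplicated().any():
            raise FormatError("duplicate site labels")
        if ((df["lat"] < -90) | (df["lat"] > 90)).any():
            raise FormatError("latitude outside [-90, 90]")
        if ((df["lon"] < -180) | (df["lon"] > 180)).any():
            raise FormatError("longitude outside [-180, 180]")
        for col in _PROPORTION_COVARIATES:
            if col in df.columns and ((df[col] < 0) | (df[col] > 1)).any():
                raise FormatError(f"{col!r} proportion outside [0, 1]")

    @property
    def sites(self) -> list[str]:
        return list(self.data["site"])

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("site", "lat", "lon")]

    def values(self, variable: str) -> pd.Series:
        if variable not in self.data.columns:
            raise FormatError(f"unknown site variable {variable!r}")
        s = self.data.set_index("site")[variable]
        if s.isna().any():
            raise FormatError(f"missing values in {variable!r}")
        return s


def read_sites(path: str | Path) -> SiteTable:
    return SiteTable(pd.read_csv(path))


def write_sites(sites: SiteTable, path: str | Path) -> None:
    sites.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric non-negative matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray
    atol: float = field(default=1e-9, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise FormatError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=self.atol):
            raise FormatError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=self.atol):
            raise FormatError("diagonal is not zero")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Lower-triangle (i > j) vector in row-major pair order."""
        idx = np.triu_indices(self.n, k=1)
        return self.values[idx]

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        if set(labels) != set(self.labels):
            raise FormatError("label sets differ")
        perm = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(perm, perm)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DistanceMatrix):
            return NotImplemented
        return self.labels == other.labels and np.allclose(
            self.values, other.values, atol=1e-12
        )


def pair_labels(labels: Sequence[str]) -> list[tuple[str, str]]:
    """Row-major (i < j) label pairs matching DistanceMatrix.condensed order."""
    return [
        (labels[i], labels[j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column labels differ")
    v = df.to_numpy(dtype=float)
    if not np.allclose(v, v.T, atol=1e-6):
        raise FormatError(f"{path}: asymmetry beyond 1e-6")
    return DistanceMatrix(tuple(str(l) for l in df.index), v, atol=1e-6)


def write_distance_matrix(m: DistanceMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path)


# ---------------------------------------------------------------------------
# Clustering likelihood summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LikelihoodSeries:
    """Replicate log-likelihoods per number of clusters K.

    ``replicates`` maps K to a 1-D array of replicate ln P(X|K) values from
    an external admixture-clustering program; K values must be consecutive.
    """

    replicates: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        ks = sorted(self.replicates)
        if not ks:
            raise FormatError("empty likelihood series")
        if ks != list(range(ks[0], ks[-1] + 1)):
            raise FormatError("K values must be consecutive integers")
        reps = {int(k): np.asarray(v, dtype=float).ravel() for k, v in self.replicates.items()}
        for k, v in reps.items():
            if v.size < 2:
                raise FormatError(f"K={k}: need >=2 replicates for a sd")
        object.__setattr__(self, "replicates", reps)

    @property
    def k_values(self) -> list[int]:
        return sorted(self.replicates)


def read_likelihoods(path: str | Path) -> LikelihoodSeries:
    """Read a two-column CSV with header ``K,log_likelihood`` (one row per run)."""
    df = pd.read_csv(path)
    if not {"K", "log_likelihood"} <= set(df.columns):
        raise FormatError(f"{path}: need columns K, log_likelihood")
    groups = {int(k): g["log_likelihood"].to_numpy() for k, g in df.groupby("K")}
    return LikelihoodSeries(groups)


def write_likelihoods(series: LikelihoodSeries, path: str | Path) -> None:
    rows = [
        {"K": k, "log_likelihood": v}
        for k in series.k_values
        for v in series.replicates[k]
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
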