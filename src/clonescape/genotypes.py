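"""Polyploid microsatellite genotypes: reading, dominant coding, clones, diversity.

Microsatellite calls in a polyploid are dosage-ambiguous: an individual shows a
*set* of allele sizes at each locus, but the copy number of each allele is
unknown.  The standard workaround is to treat every (locus, allele) pair as a
dominant presence/absence marker.  This module holds the genotype container,
the dominant (binary) conversion, exact-match clone (genet) assignment, and
per-population diversity statistics (NA, ENA, Nei's sample-size-corrected
genotype diversity D).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Missing-data token in the canonical genotype dialect.
MISSING_TOKEN = "."

__all__ = [
    "MISSING_TOKEN",
    "GenotypeTable",
    "BinaryMatrix",
    "GenetAssignment",
    "read_genotypes",
    "to_dominant_binary",
    "assign_genets",
    "diversity_stats",
]


@dataclass
class GenotypeTable:
    """Individuals x loci table of dosage-ambiguous allele sets.

    Parameters
    ----------
    individuals
        Ordered unique individual IDs.
    populations
        Population label per individual (parallel to ``individuals``).
    loci
        Ordered locus names.
    calls
        ``calls[i][l]`` is the frozenset of allele sizes observed for
        individual *i* at locus *l*; the empty set means missing data.
    ploidy
        Maximum number of distinct alleles an individual may carry at one
        locus (default 6, a hexaploid).
    """

    individuals: list[str]
    populations: list[str]
    loci: list[str]
    calls: list[tuple[frozenset[int], ...]]
    ploidy: int = 6

    def __post_init__(self) -> None:
        if self.ploidy < 2:
            raise ValueError(f"ploidy must be >= 2, got {self.ploidy}")
        if len(self.populations) != len(self.individuals):
            raise ValueError("populations must parallel individuals")
        if len(self.calls) != len(self.individuals):
            raise ValueError("calls must parallel individuals")
        seen: set[str] = set()
        for ind in self.individuals:
            if ind in seen:
                raise ValueError(f"duplicate individual ID {ind!r}")
            seen.add(ind)
        for ind, row in zip(self.individuals, self.calls):
            if len(row) != len(self.loci):
                raise ValueError(f"individual {ind!r} has {len(row)} calls, expected {len(self.loci)}")
            for locus, alleles in zip(self.loci, row):
                if len(alleles) > self.ploidy:
                    raise ValueError(
                        f"individual {ind!r}, locus {locus!r}: {len(alleles)} alleles exceeds ploidy {self.ploidy}"
                    )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def population_indices(self) -> dict[str, list[int]]:
        """Population label -> row indices, in first-appearance order."""
        out: dict[str, list[int]] = {}
        for i, pop in enumerate(self.populations):
            out.setdefault(pop, []).append(i)
        return out

    def subset(self, indices: list[int] | np.ndarray) -> "GenotypeTable":
        """New table containing only the given rows, in the given order."""
        idx = list(indices)
        return GenotypeTable(
            individuals=[self.individuals[i] for i in idx],
            populations=[self.populations[i] for i in idx],
            loci=list(self.loci),
            calls=[self.calls[i] for i in idx],
            ploidy=self.ploidy,
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Canonical delimited-text layout (slash-separated alleles, '.' missing)."""
        rows = []
        for ind, pop, row in zip(self.individuals, self.populations, self.calls):
            rec = {"individual": ind, "population": pop}
            for locus, alleles in zip(self.loci, row):
                rec[locus] = "/".join(str(a) for a in sorted(alleles)) if alleles else MISSING_TOKEN
            rows.append(rec)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class BinaryMatrix:
    """Dominant presence/absence coding: rows are individuals (or genets),
    columns are (locus, allele) pairs observed anywhere in the dataset.

    ``values`` is float64 with entries 1.0 (present), 0.0 (absent) or NaN
    (the individual has no data at that column's locus — masked, not absent).
    """

    ids: list[str]
    columns: list[tuple[str, int]]
    values: np.ndarray
    loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.columns)):
            raise ValueError("values shape must be (n_ids, n_columns)")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError("binary matrix entries must be 0, 1 or NaN")
        if not self.loci:
            seen: list[str] = []
            for locus, _ in self.columns:
                if not seen or seen[-1] != locus:
                    seen.append(locus)
            self.loci = seen

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def locus_columns(self, locus: str) -> np.ndarray:
        return np.array([j for j, (loc, _) in enumerate(self.columns) if loc == locus], dtype=int)

    def subset_rows(self, indices: list[int] | np.ndarray) -> "BinaryMatrix":
        idx = np.asarray(list(indices), dtype=int)
        return BinaryMatrix(
            ids=[self.ids[i] for i in idx],
            columns=list(self.columns),
            values=self.values[idx].copy(),
            loci=list(self.loci),
        )

    def to_dataframe(self) -> pd.DataFrame:
        headers = [f"{locus}:{allele}" for locus, allele in self.columns]
        return pd.DataFrame(self.values, index=pd.Index(self.ids, name="id"), columns=headers)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)


@dataclass
class GenetAssignment:
    """Partition of individuals into genets (clonal lineages).

    Two individuals share a genet iff their multilocus genotypes — including
    the missing-data pattern — are identical at every locus.  The first
    individual (input order) of each genet is its representative.
    """

    individuals: list[str]
    genet_ids: list[str]
    representative: np.ndarray  # bool per individual
    populations: list[str]

    @property
    def n_genets(self) -> int:
        return len(set(self.genet_ids))

    def representative_indices(self) -> list[int]:
        return [i for i, rep in enumerate(self.representative) if rep]

    def genets_per_population(self) -> dict[str, int]:
        seen: dict[str, set[str]] = {}
        for pop, gid in zip(self.populations, self.genet_ids):
            seen.setdefault(pop, set()).add(gid)
        return {pop: len(gids) for pop, gids in seen.items()}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual": self.individuals,
                "population": self.populations,
                "genet_id": self.genet_ids,
                "representative": self.representative.astype(int),
            }
        )


def _parse_cell(cell: str, ploidy: int, row_label: str, locus: str) -> frozenset[int]:
    cell = cell.strip()
    if cell == MISSING_TOKEN or cell == "":
        return frozenset()
    parts = cell.split("/")
    alleles = set()
    for part in parts:
        part = part.strip()
        try:
            alleles.add(int(part))
        except ValueError:
            raise ValueError(
                f"malformed allele {part!r} in cell {cell!r} (individual {row_label!r}, locus {locus!r})"
            ) from None
    if len(alleles) > ploidy:
        raise ValueError(
            f"{len(alleles)} distinct alleles exceeds ploidy {ploidy} "
            f"(individual {row_label!r}, locus {locus!r})"
        )
    return frozenset(alleles)


def read_genotypes(path: str | Path, ploidy: int = 6, delimiter: str = ",") -> GenotypeTable:
    """Read the canonical genotype dialect.

    The file is UTF-8 delimited text with header
    ``individual,population,<locus1>,<locus2>,...``; allele cells are
    slash-separated integer fragment sizes (``150/158``), and ``.`` marks
    missing data.  Datasets in a two-columns-per-allele layout should be
    converted first (see :func:`wide_to_canonical`).
    """
    df = pd.read_csv(path, dtype=str, sep=delimiter, keep_default_na=False)
    if df.empty and df.columns.size == 0:
        raise ValueError(f"empty genotype file: {path}")
    expected = ["individual", "population"]
    if list(df.columns[:2]) != expected:
        raise ValueError(f"genotype file must start with columns {expected}, got {list(df.columns[:2])}")
    if df.shape[0] == 0:
        raise ValueError(f"genotype file has a header but no rows: {path}")
    loci = list(df.columns[2:])
    if not loci:
        raise ValueError("genotype file has no locus columns")
    calls: list[tuple[frozenset[int], ...]] = []
    for _, rec in df.iterrows():
        ind = rec["individual"]
        calls.append(tuple(_parse_cell(rec[locus], ploidy, ind, locus) for locus in loci))
    return GenotypeTable(
        individuals=list(df["individual"]),
        populations=list(df["population"]),
        loci=loci,
        calls=calls,
        ploidy=ploidy,
    )


def wide_to_canonical(df: pd.DataFrame, n_allele_cols: int, loci: list[str]) -> pd.DataFrame:
    """Converter stub for two-column-per-allele (GenAlEx-style) layouts.

    ``df`` must start with ``individual, population`` followed by
    ``n_allele_cols`` columns per locus in ``loci`` order; 0 or empty marks a
    missing allele slot.  Returns a frame in the canonical dialect.
    """
    out = df.iloc[:, :2].copy()
    out.columns = ["individual", "population"]
    col = 2
    for locus in loci:
        block = df.iloc[:, col : col + n_allele_cols]
        col += n_allele_cols
        cells = []
        for _, row in block.iterrows():
            alleles = sorted(
                {int(v) for v in row if str(v).strip() not in ("", "0", MISSING_TOKEN, "nan")}
            )
            cells.append("/".join(map(str, alleles)) if alleles else MISSING_TOKEN)
        out[locus] = cells
    return out


def to_dominant_binary(gt: GenotypeTable) -> BinaryMatrix:
    """Convert to dominant presence/absence coding.

    One column per (locus, allele) pair observed anywhere in the dataset;
    loci keep input order, alleles ascend within a locus.  An individual
    missing a locus gets NaN over that locus's columns (masked, never
    zero-filled: absence of data is not absence of the allele).
    """
    alleles_by_locus: dict[str, set[int]] = {locus: set() for locus in gt.loci}
    for row in gt.calls:
        for locus, alleles in zip(gt.loci, row):
            alleles_by_locus[locus].update(alleles)
    for locus, alleles in alleles_by_locus.items():
        if not alleles:
            raise ValueError(f"locus {locus!r} has no non-missing call in the dataset")
    columns = [(locus, a) for locus in gt.loci for a in sorted(alleles_by_locus[locus])]
    col_index = {pair: j for j, pair in enumerate(columns)}
    values = np.zeros((gt.n_individuals, len(columns)))
    for i, row in enumerate(gt.calls):
        for locus, alleles in zip(gt.loci, row):
            if not alleles:
                for a in alleles_by_locus[locus]:
                    values[i, col_index[(locus, a)]] = np.nan
            else:
                for a in alleles:
                    values[i, col_index[(locus, a)]] = 1.0
    return BinaryMatrix(ids=list(gt.individuals), columns=columns, values=values, loci=list(gt.loci))


def assign_genets(gt: GenotypeTable) -> GenetAssignment:
    """Exact-match clone calling: identical multilocus genotypes form one genet.

    The match covers the full profile including the missing pattern, so an
    individual with any missing locus never merges with a complete one —
    deliberately conservative.  Genet IDs are assigned in first-appearance
    order and the first member of each genet is flagged as representative.
    """
    genet_of: dict[tuple, str] = {}
    genet_ids: list[str] = []
    representative = np.zeros(gt.n_individuals, dtype=bool)
    for i, row in enumerate(gt.calls):
        key = tuple(row)
        gid = genet_of.get(key)
        if gid is None:
            gid = f"G{len(genet_of) + 1:04d}"
            genet_of[key] = gid
            representative[i] = True
        genet_ids.append(gid)
    return GenetAssignment(
        individuals=list(gt.individuals),
        genet_ids=genet_ids,
        representative=representative,
        populations=list(gt.populations),
    )


def diversity_stats(gt: GenotypeTable) -> pd.DataFrame:
    """Per-population diversity: NA, ENA, Nei's corrected genotype diversity D.

    Allele frequencies are estimated from dominant presence counts: at each
    locus, the number of individuals carrying each allele, normalized to sum
    to 1 (individuals missing the locus are excluded from the denominator).
    Per-locus effective allele number is 1/sum(p^2); NA and ENA are sums over
    loci.  D = (n/(n-1)) * (1 - sum(f_g^2)) with f_g the relative frequencies
    of distinct multilocus genotypes and n the population sample size; D is
    defined as 0 for n = 1.

    Returns a frame with columns
    ``pop, n, n_genets, NA, ENA, D, n_genotypes`` (one row per population, in
    first-appearance order).
    """
    pops = gt.population_indices()
    records = []
    for pop, idx in pops.items():
        n = len(idx)
        na = 0
        ena = 0.0
        for l, locus in enumerate(gt.loci):
            counts: dict[int, int] = {}
            for i in idx:
                for a in gt.calls[i][l]:
                    counts[a] = counts.get(a, 0) + 1
            if not counts:
                logger.warning("population %s: locus %s entirely missing; contributes 0 to NA/ENA", pop, locus)
                continue
            total = sum(counts.values())
            p = np.array(list(counts.values()), dtype=float) / total
            na += len(counts)
            ena += 1.0 / float(np.sum(p**2))
        profiles: dict[tuple, int] = {}
        for i in idx:
            key = tuple(gt.calls[i])
            profiles[key] = profiles.get(key, 0) + 1
        f = np.array(list(profiles.values()), dtype=float) / n
        if n > 1:
            d = (n / (n - 1)) * (1.0 - float(np.sum(f**2)))
        else:
            d = 0.0
        records.append(
            {
                "pop": pop,
                "n": n,
                "n_genets": len(profiles),
                "NA": na,
                "ENA": ena,
                "D": d,
                "n_genotypes": len(profiles),
            }
        )
    return pd.DataFrame(records)
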