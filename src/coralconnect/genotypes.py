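"""Genotype container, GenePop I/O, and the sample/population filters.

Microsatellite genotypes are unphased, so every diploid call is stored as a
sorted pair of positive integer allele labels (fragment sizes); ``(0, 0)``
marks a missing call.  A call with one missing allele is treated as wholly
missing.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

REGION_CLASSES = ("recent_temperate", "pre_existing_temperate", "subtropical")


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeTable:
    """Individuals x loci diploid microsatellite calls with population metadata.

    Attributes
    ----------
    individuals : list of str
        Ordered individual identifiers (unique).
    loci : list of str
        Ordered locus names.
    calls : ndarray, shape (n_individuals, n_loci, 2), int
        Sorted allele pairs; 0 encodes a missing allele, and calls are
        canonicalised so a half-missing call becomes (0, 0).
    populations : ndarray of str, per individual
        Population code of each individual (block membership).
    region : dict population -> region class
        One of ``recent_temperate``, ``pre_existing_temperate``,
        ``subtropical``; optional (empty dict allowed).
    coords : dict population -> (lat, lon) in decimal degrees; optional.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray
    populations: np.ndarray
    region: dict[str, str] = field(default_factory=dict)
    coords: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int32)
        self.populations = np.asarray(self.populations, dtype=object)
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise GenotypeError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)"
            )
        if len(self.populations) != n:
            raise GenotypeError("populations length mismatch")
        if len(set(self.individuals)) != n:
            raise GenotypeError("duplicate individual identifiers")
        if (self.calls < 0).any():
            raise GenotypeError("allele labels must be non-negative integers")
        # canonical form: sorted pair, half-missing -> fully missing
        self.calls = np.sort(self.calls, axis=2)
        half = (self.calls[:, :, 0] == 0) & (self.calls[:, :, 1] != 0)
        self.calls[half] = 0

    # -- basic views ------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def pop_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def pop_indices(self, pop: str) -> np.ndarray:
        return np.flatnonzero(self.populations == pop)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci): True where the call is missing."""
        return self.calls[:, :, 0] == 0

    def mlg_key(self, i: int) -> tuple:
        """Hashable multilocus genotype of individual ``i``."""
        return tuple(map(tuple, self.calls[i]))

    # -- subsetting -------------------------------------------------------
    def take_individuals(self, idx: Sequence[int]) -> "GenotypeTable":
        idx = np.asarray(idx, dtype=int)
        pops = set(self.populations[idx])
        return GenotypeTable(
            [self.individuals[i] for i in idx],
            list(self.loci),
            self.calls[idx],
            self.populations[idx],
            {p: r for p, r in self.region.items() if p in pops},
            {p: c for p, c in self.coords.items() if p in pops},
        )

    def take_loci(self, names: Sequence[str]) -> "GenotypeTable":
        idx = [self.loci.index(n) for n in names]
        return GenotypeTable(
            list(self.individuals),
            list(names),
            self.calls[:, idx],
            self.populations,
            dict(self.region),
            dict(self.coords),
        )

    def with_metadata(self, meta: pd.DataFrame) -> "GenotypeTable":
        """Attach per-population region/coords from a per-individual metadata table.

        ``meta`` must have columns individual, population, lat, lon, region.
        """
        meta = meta.set_index("individual") if "individual" in meta else meta
        region, coords = {}, {}
        for ind, pop in zip(self.individuals, self.populations):
            if ind not in meta.index:
                raise GenotypeError(f"individual {ind!r} missing from metadata")
            row = meta.loc[ind]
            if str(row["population"]) != str(pop):
                raise GenotypeError(
                    f"metadata population {row['population']!r} disagrees with "
                    f"GenePop block {pop!r} for {ind!r}"
                )
            if "region" in row and pd.notna(row["region"]):
                region[pop] = str(row["region"])
            if "lat" in row and pd.notna(row["lat"]):
                coords[pop] = (float(row["lat"]), float(row["lon"]))
        return GenotypeTable(
            list(self.individuals), list(self.loci), self.calls.copy(),
            self.populations, region, coords,
        )

    def equals(self, other: "GenotypeTable") -> bool:
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
            and list(self.populations) == list(other.populations)
        )


@dataclass
class FilterReport:
    """Accounting of what a filter removed and why."""

    removed_individuals: dict[str, str] = field(default_factory=dict)
    removed_populations: dict[str, str] = field(default_factory=dict)
    removed_loci: list[str] = field(default_factory=list)
    n_input: int = 0
    n_retained: int = 0

    def check_balance(self) -> None:
        if self.n_input != self.n_retained + len(self.removed_individuals):
            raise GenotypeError("filter accounting does not balance")

    def to_frame(self) -> pd.DataFrame:
        rows = [("individual", k, v) for k, v in self.removed_individuals.items()]
        rows += [("population", k, v) for k, v in self.removed_populations.items()]
        rows += [("locus", k, "named exclusion") for k in self.removed_loci]
        return pd.DataFrame(rows, columns=["kind", "identifier", "reason"])


# ---------------------------------------------------------------------------
# GenePop format
# ---------------------------------------------------------------------------

def _parse_allele_string(tok: str, line_no: int) -> tuple[int, int]:
    if len(tok) == 4:
        w = 2
    elif len(tok) == 6:
        w = 3
    else:
        raise GenotypeError(
            f"line {line_no}: allele string {tok!r} has odd length "
            f"(expected 4 or 6 digits)"
        )
    if not tok.isdigit():
        raise GenotypeError(f"line {line_no}: non-numeric allele string {tok!r}")
    return int(tok[:w]), int(tok[w:])


def read_genepop(path) -> GenotypeTable:
    """Read a GenePop file (2- or 3-digit allele encoding).

    Locus names may be comma-separated on one line or one per line; population
    blocks are introduced by a line equal to ``pop`` (case-insensitive).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise GenotypeError(f"{path}: empty file")
    loci: list[str] = []
    i = 1  # skip title line
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            loci.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if not loci:
        raise GenotypeError(f"{path}: no locus names before first 'pop'")
    individuals: list[str] = []
    pops: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_counter = 0
    current_pop = None
    while i < len(lines):
        line = lines[i]
        i += 1
        if not line.strip():
            continue
        if line.strip().lower() == "pop":
            pop_counter += 1
            current_pop = None
            continue
        if current_pop is None and "," not in line:
            raise GenotypeError(f"line {i}: expected 'id , genotypes' row")
        ident, _, rest = line.partition(",")
        ident = ident.strip()
        toks = rest.split()
        if len(toks) != len(loci):
            raise GenotypeError(
                f"line {i}: ragged row for {ident!r}: {len(toks)} genotypes, "
                f"{len(loci)} loci declared"
            )
        calls = [_parse_allele_string(t, i) for t in toks]
        if current_pop is None:
            # GenePop convention: the population is named after its last
            # individual, but files in the wild prefix ids with the site code;
            # use the id's leading token as the population code.
            current_pop = re.split(r"[_\-\s]", ident)[0] or f"pop{pop_counter}"
        individuals.append(ident)
        pops.append(current_pop)
        rows.append(calls)
    if not individuals:
        raise GenotypeError(f"{path}: no individuals")
    calls = np.array(rows, dtype=np.int32)
    return GenotypeTable(individuals, loci, calls, np.array(pops, dtype=object))


def write_genepop(table: GenotypeTable, path, title: str = "coralconnect export",
                  digits: int = 3) -> None:
    if digits not in (2, 3):
        raise GenotypeError("digits must be 2 or 3")
    if int(table.calls.max(initial=0)) >= 10 ** digits:
        raise GenotypeError(f"allele labels too large for {digits}-digit encoding")
    out = [title]
    out.extend(table.loci)
    for pop in table.pop_names:
        out.append("pop")
        for i in table.pop_indices(pop):
            toks = [
                f"{a:0{digits}d}{b:0{digits}d}" for a, b in table.calls[i]
            ]
            out.append(f"{table.individuals[i]} ,  " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


def read_metadata(path) -> pd.DataFrame:
    """Per-individual metadata CSV: individual, population, lat, lon, region."""
    df = pd.read_csv(path, dtype={"individual": str, "population": str})
    need = {"individual", "population"}
    if not need.issubset(df.columns):
        raise GenotypeError(f"metadata must have columns {sorted(need)}")
    return df


def write_metadata(table: GenotypeTable, path) -> None:
    rows = []
    for ind, pop in zip(table.individuals, table.populations):
        lat, lon = table.coords.get(pop, (np.nan, np.nan))
        rows.append((ind, pop, lat, lon, table.region.get(pop, "")))
    pd.DataFrame(
        rows, columns=["individual", "population", "lat", "lon", "region"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Q-matrix (cluster membership coefficients)
# ---------------------------------------------------------------------------

def read_qmatrix(path) -> pd.DataFrame:
    """Whitespace-delimited membership table: individual id, then one column
    per cluster.  Rows must sum to 1 within 1e-6."""
    df = pd.read_csv(path, sep=r"\s+", header=None, index_col=0)
    df.index = df.index.astype(str)
    df.columns = [f"cluster{k}" for k in range(df.shape[1])]
    sums = df.sum(axis=1)
    bad = sums[(sums - 1.0).abs() > 1e-6]
    if len(bad):
        raise GenotypeError(
            f"Q-matrix rows do not sum to 1: {list(bad.index[:5])}"
        )
    return df


def write_qmatrix(q: pd.DataFrame, path) -> None:
    q.to_csv(path, sep=" ", header=False)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_lineage(
    table: GenotypeTable,
    qblocks: Mapping[int, pd.DataFrame],
    target_cluster: Mapping[int, int] | int,
    threshold: float = 0.70,
) -> tuple[GenotypeTable, FilterReport]:
    """Keep individuals whose membership in the target cluster is >= threshold
    in *every* supplied K block (boundary inclusive)."""
    if isinstance(target_cluster, int):
        target_cluster = {k: target_cluster for k in qblocks}
    missing = [
        ind for ind in table.individuals
        if any(ind not in q.index for q in qblocks.values())
    ]
    if missing:
        raise GenotypeError(f"individuals missing from Q-matrix: {missing[:10]}")
    keep, report = [], FilterReport(n_input=table.n_individuals)
    for i, ind in enumerate(table.individuals):
        ok = all(
            float(qblocks[k].loc[ind].iloc[target_cluster[k]]) >= threshold
            for k in qblocks
        )
        if ok:
            keep.append(i)
        else:
            report.removed_individuals[ind] = (
                f"lineage membership < {threshold:g} in at least one K block"
            )
    report.n_retained = len(keep)
    report.check_balance()
    return table.take_individuals(keep), report


def filter_populations(
    table: GenotypeTable, min_mlg: int = 9
) -> tuple[GenotypeTable, FilterReport]:
    """Drop whole populations whose distinct-MLG count is below ``min_mlg``
    (boundary inclusive: a population with exactly ``min_mlg`` MLGs stays)."""
    from .popgen.clones import mlg_counts

    counts = mlg_counts(table)
    report = FilterReport(n_input=table.n_individuals)
    keep_idx: list[int] = []
    for pop in table.pop_names:
        if counts[pop] < min_mlg:
            report.removed_populations[pop] = (
                f"{counts[pop]} MLGs < minimum {min_mlg}"
            )
            for i in table.pop_indices(pop):
                report.removed_individuals[table.individuals[i]] = (
                    f"population {pop} dropped ({counts[pop]} MLGs)"
                )
        else:
            keep_idx.extend(table.pop_indices(pop))
    keep_idx.sort()
    report.n_retained = len(keep_idx)
    report.check_balance()
    return table.take_individuals(keep_idx), report


def exclude_loci(table: GenotypeTable, names: Iterable[str]) -> GenotypeTable:
    names = list(names)
    unknown = [n for n in names if n not in table.loci]
    if unknown:
        raise GenotypeError(f"unknown loci: {unknown}")
    remaining = [l for l in table.loci if l not in names]
    if not remaining:
        raise GenotypeError("refusing to exclude every locus")
    return table.take_loci(remaining)
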