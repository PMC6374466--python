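"""Clone (multilocus genotype) detection and probability of identity.

Colonies sharing an identical multilocus genotype (MLG) are putative ramets
of one genet, produced by fragmentation.  A duplicate group is flagged as a
true clone only when the probability that two independent sexual recruits
would share that MLG by chance (probability of identity, PI) falls below a
threshold; one ramet per genet is retained downstream.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._encode import allele_freqs, encode_loci, pop_onehot


@dataclass
class ClonePartition:
    """Partition of each population's individuals into genets."""

    genets: dict[str, list[list[str]]]        # population -> groups of ids
    pi: dict[str, float]                      # representative id -> MLG PI
    clone_groups: list[list[str]]             # flagged groups (PI < threshold)
    clonal_fraction: dict[str, float]         # population -> 1 - MLG/N
    representatives: list[str]                # one id per genet, input order

    def n_mlg(self, pop: str) -> int:
        return len(self.genets[pop])


def mlg_counts(table) -> dict[str, int]:
    """Distinct multilocus genotypes per population (exact-call grouping)."""
    counts: dict[str, int] = {}
    for pop in table.pop_names:
        idx = table.pop_indices(pop)
        keys = {table.mlg_key(i) for i in idx}
        counts[pop] = len(keys)
    return counts


def _match(table, i: int, j: int) -> bool:
    """True when i and j agree at every locus where both are genotyped."""
    a, b = table.calls[i], table.calls[j]
    both = (a[:, 0] != 0) & (b[:, 0] != 0)
    if not both.any():
        return False
    return bool((a[both] == b[both]).all())


def _locus_pi(freqs: np.ndarray) -> float:
    """Population-level per-locus PI: sum(p_i^4) + sum_{i<j} (2 p_i p_j)^2."""
    p = np.asarray(freqs, dtype=float)
    p = p[p > 0]
    s2 = float((p ** 2).sum())
    s4 = float((p ** 4).sum())
    # sum_{i<j} (2 p_i p_j)^2 = 2 * ((sum p^2)^2 - sum p^4) / 2 * 2 ... expand:
    # (sum p^2)^2 = sum p^4 + 2 sum_{i<j} p_i^2 p_j^2
    cross = 4.0 * (s2 ** 2 - s4) / 2.0
    return s4 + cross


def detect_clones(table, pid_threshold: float = 0.001) -> ClonePartition:
    """Group identical MLGs within each population.

    Individuals match when their calls agree at every locus where both are
    genotyped (missing-tolerant, transitively closed by union-find).  An
    all-missing individual is excluded with a warning.  The PI of a genet is
    the product over genotyped loci of the per-locus population PI.
    """
    if table.n_individuals < 1:
        raise ValueError("need at least one individual")
    loci = encode_loci(table)
    onehot = pop_onehot(table.populations, table.pop_names)
    pop_freqs = {}
    for li, loc in enumerate(loci):
        freqs, _ = allele_freqs(loc, onehot)
        pop_freqs[li] = freqs

    all_missing = table.missing_mask().all(axis=1)
    if all_missing.any():
        bad = [table.individuals[i] for i in np.flatnonzero(all_missing)]
        warnings.warn(f"excluding all-missing individuals: {bad}")

    genets: dict[str, list[list[str]]] = {}
    clonal_fraction: dict[str, float] = {}
    pi: dict[str, float] = {}
    clone_groups: list[list[str]] = []
    representatives: list[str] = []

    for pi_pop, pop in enumerate(table.pop_names):
        idx = [i for i in table.pop_indices(pop) if not all_missing[i]]
        parent = {i: i for i in idx}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a_i, i in enumerate(idx):
            for j in idx[a_i + 1:]:
                if _match(table, i, j):
                    parent[find(i)] = find(j)
        groups: dict[int, list[int]] = {}
        for i in idx:
            groups.setdefault(find(i), []).append(i)
        pop_groups = sorted(groups.values(), key=lambda g: min(g))
        genets[pop] = [[table.individuals[i] for i in g] for g in pop_groups]
        n = len(idx)
        clonal_fraction[pop] = 1.0 - len(pop_groups) / n if n else 0.0
        for g in pop_groups:
            rep = min(g)
            representatives.append(table.individuals[rep])
            typed = ~table.missing_mask()[rep]
            val = 1.0
            for li in np.flatnonzero(typed):
                val *= _locus_pi(pop_freqs[li][pi_pop])
            pi[table.individuals[rep]] = val
            if len(g) > 1 and val < pid_threshold:
                clone_groups.append([table.individuals[i] for i in g])

    representatives = [
        ind for ind in table.individuals if ind in set(representatives)
    ]
    return ClonePartition(genets, pi, clone_groups, clonal_fraction,
                          representatives)


def remove_clones(table, pid_threshold: float = 0.001):
    """Return (table with one ramet per genet, ClonePartition)."""
    part = detect_clones(table, pid_threshold)
    keep = set(part.representatives)
    idx = [i for i, ind in enumerate(table.individuals) if ind in keep]
    return table.take_individuals(idx), part
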