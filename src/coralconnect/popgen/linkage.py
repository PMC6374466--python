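"""Genotypic linkage-disequilibrium permutation test for a pair of loci.

The statistic is the G (log-likelihood-ratio) statistic of the two-locus
genotype contingency table, summed over populations; the null distribution
comes from shuffling one locus's genotypes among individuals within each
population, which breaks inter-locus association while preserving genotype
frequencies at both loci.
"""
from __future__ import annotations

import numpy as np


def _g_statistic(x_codes: np.ndarray, y_codes: np.ndarray) -> float:
    """G statistic of the contingency table of two integer code vectors."""
    nx = x_codes.max() + 1
    ny = y_codes.max() + 1
    tab = np.zeros((nx, ny))
    np.add.at(tab, (x_codes, y_codes), 1.0)
    n = tab.sum()
    row = tab.sum(axis=1, keepdims=True)
    col = tab.sum(axis=0, keepdims=True)
    expected = row * col / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(tab > 0, tab * np.log(tab / expected), 0.0)
    return float(2.0 * terms.sum())


def linkage_disequilibrium_test(table, pair_of_loci: tuple[str, str],
                                n_perm: int = 1000,
                                seed: int | None = None) -> float:
    """Permutation p-value for genotypic association between two loci."""
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    la, lb = pair_of_loci
    ia, ib = table.loci.index(la), table.loci.index(lb)
    rng = np.random.default_rng(seed)

    def codes(locus_idx, keep):
        calls = [tuple(table.calls[i, locus_idx]) for i in keep]
        uniq = sorted(set(calls))
        if len(uniq) < 2:
            return None
        m = {c: j for j, c in enumerate(uniq)}
        return np.array([m[c] for c in calls])

    per_pop = []
    for pop in table.pop_names:
        idx = table.pop_indices(pop)
        keep = [
            i for i in idx
            if table.calls[i, ia, 0] != 0 and table.calls[i, ib, 0] != 0
        ]
        if len(keep) < 2:
            continue
        xa = codes(ia, keep)
        xb = codes(ib, keep)
        if xa is not None and xb is not None:
            per_pop.append((xa, xb))
    if not per_pop:
        raise ValueError(
            f"LD test undefined: locus pair {pair_of_loci} monomorphic or "
            "untyped in every population"
        )
    observed = sum(_g_statistic(xa, xb) for xa, xb in per_pop)
    hits = 0
    for _ in range(n_perm):
        stat = sum(
            _g_statistic(xa, rng.permutation(xb)) for xa, xb in per_pop
        )
        if stat >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)
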