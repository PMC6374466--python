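"""Nei's standard genetic distance and neighbour-joining trees with
locus-bootstrap support values.

Nei's (1972) standard distance between populations X and Y is D = -ln(I)
with the normalised identity I = Jxy / sqrt(Jx * Jy), where Jxy, Jx and Jy
are arithmetic means over loci of sum_a(x_a y_a), sum_a(x_a^2) and
sum_a(y_a^2).  Support values come from bootstrapping loci: the NJ topology
is rebuilt per resample and internal-edge bipartitions are counted.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from ..matrices import PairwiseMatrix
from ._encode import allele_freqs, encode_loci, pop_onehot


@dataclass
class NJTreeResult:
    tree: TreeNode
    newick: str
    support: dict[frozenset, float]     # bipartition (smaller side) -> % support
    distance: PairwiseMatrix


def _locus_products(table, loci_idx: np.ndarray):
    """Per-locus (Jxy matrix, Jx vector) terms for the chosen loci."""
    pops = table.pop_names
    loci = encode_loci(table)
    onehot = pop_onehot(table.populations, pops)
    jxy_terms, jx_terms = [], []
    for li in loci_idx:
        loc = loci[li]
        freqs, n_typed = allele_freqs(loc, onehot)
        if (n_typed == 0).any() or loc.n_alleles == 0:
            continue
        jxy_terms.append(freqs @ freqs.T)          # (r, r)
        jx_terms.append((freqs ** 2).sum(axis=1))  # (r,)
    return jxy_terms, jx_terms


def nei_distance(table, loci_idx: np.ndarray | None = None) -> PairwiseMatrix:
    """Nei standard genetic distance matrix D = -ln(I) between populations."""
    pops = table.pop_names
    if loci_idx is None:
        loci_idx = np.arange(table.n_loci)
    jxy_terms, jx_terms = _locus_products(table, loci_idx)
    if not jxy_terms:
        raise ValueError("no usable loci (some population untyped everywhere?)")
    jxy = np.mean(jxy_terms, axis=0)
    jx = np.mean(jx_terms, axis=0)
    eye = np.sqrt(np.outer(jx, jx))
    with np.errstate(divide="ignore"):
        d = -np.log(np.clip(jxy / eye, 1e-12, None))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    d[d < 0] = 0.0
    return PairwiseMatrix(pops, d, diagonal="zero", name="nei_D")


def _bipartitions(tree: TreeNode, taxa: frozenset) -> set[frozenset]:
    out = set()
    for node in tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            out.add(min(side, taxa - side, key=lambda s: (len(s), sorted(s))))
    return out


def nei_nj_tree(table, n_bootstrap: int = 1000,
                seed: int | None = None) -> NJTreeResult:
    """NJ tree on Nei distances with bootstrap-over-loci support.

    With exactly two populations a single-edge tree is returned (no NJ, no
    support values).
    """
    pops = table.pop_names
    dist = nei_distance(table)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    if len(pops) == 2:
        d = dist.values[0, 1]
        nwk = f"({pops[0]}:{d / 2:.6f},{pops[1]}:{d / 2:.6f});"
        return NJTreeResult(TreeNode.read([nwk]), nwk, {}, dist)
    tree = nj(DistanceMatrix(dist.values, ids=pops))
    taxa = frozenset(pops)
    base_parts = _bipartitions(tree, taxa)
    counts = {p: 0 for p in base_parts}
    rng = np.random.default_rng(seed)
    for _ in range(n_bootstrap):
        li = rng.integers(0, table.n_loci, size=table.n_loci)
        bdist = nei_distance(table, li)
        btree = nj(DistanceMatrix(bdist.values, ids=pops))
        for p in _bipartitions(btree, taxa):
            if p in counts:
                counts[p] += 1
    support = (
        {p: 100.0 * c / n_bootstrap for p, c in counts.items()}
        if n_bootstrap else {}
    )
    # annotate internal nodes with support
    for node in tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        key = min(side, taxa - side, key=lambda s: (len(s), sorted(s)))
        if key in support:
            node.name = f"{support[key]:.0f}"
    nwk = str(tree).strip()
    return NJTreeResult(tree, nwk, support, dist)
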