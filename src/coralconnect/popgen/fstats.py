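"""Population differentiation: Weir-Cockerham theta and Jost's D.

Theta is the variance-components estimator of FST: per locus and allele the
among-population (a), among-individual-within-population (b) and
within-individual (c) components are computed from sample allele frequencies
and observed heterozygosities; the multilocus estimate sums components over
alleles and loci, theta = sum(a) / sum(a + b + c).  Permutation p-values
reallocate individuals among populations.

Jost's D uses Nei-Chesser small-sample-corrected heterozygosities:
D = (k/(k-1)) (Ht - Hs) / (1 - Hs), per locus, averaged over loci.
"""
from __future__ import annotations

import numpy as np

from ..matrices import PairwiseMatrix
from ._encode import LocusArrays, encode_loci, pop_onehot


def _wc_components(loci: list[LocusArrays], onehot: np.ndarray):
    """Summed (a, b, c) variance components over all loci and alleles."""
    A = B = C = 0.0
    for loc in loci:
        typed = (~loc.missing).astype(float)
        n_i = onehot @ typed                               # (r,)
        use = n_i > 0
        r = int(use.sum())
        if r < 2 or loc.n_alleles < 2:
            continue
        sub = onehot[use]
        n = n_i[use]
        counts = sub @ loc.dosage.astype(float)            # (r, k)
        p = counts / (2.0 * n[:, None])
        h_cnt = sub @ loc.het.astype(float)                # het carriers per allele
        h = h_cnt / n[:, None]
        nbar = n.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - (n ** 2).sum() / (r * nbar)) / (r - 1)
        if nc <= 0:
            continue
        pbar = (n[:, None] * p).sum(axis=0) / (r * nbar)   # (k,)
        s2 = (n[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n[:, None] * h).sum(axis=0) / (r * nbar)
        pq = pbar * (1 - pbar)
        a = (nbar / nc) * (
            s2 - (pq - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pq - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
        A += a.sum()
        B += b.sum()
        C += c.sum()
    return A, B, C


def _theta_from_components(A: float, B: float, C: float) -> float:
    denom = A + B + C
    return A / denom if denom != 0 else 0.0


def wc_theta(table, pops: list[str] | None = None) -> float:
    """Multilocus Weir-Cockerham theta over the given (default: all) populations."""
    pops = pops or table.pop_names
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    loci = encode_loci(table)
    _check_populations(loci, table, pops)
    onehot = pop_onehot(table.populations, pops)
    return _theta_from_components(*_wc_components(loci, onehot))


def _check_populations(loci, table, pops) -> None:
    for p in pops:
        idx = table.pop_indices(p)
        if len(idx) == 0:
            raise ValueError(f"population {p} has no individuals")
        if table.missing_mask()[idx].all():
            raise ValueError(f"population {p} has no non-missing calls")


def _perm_pvalue(stat_fn, labels: np.ndarray, observed: float,
                 n_perm: int, rng: np.random.Generator) -> float:
    count = 0
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        if stat_fn(lab) >= observed:
            count += 1
    return (1 + count) / (n_perm + 1)


def global_fst(table, n_perm: int = 0, seed: int | None = None):
    """Global multilocus theta and (optionally) a permutation p-value.

    Returns (theta, p) with p=None when n_perm == 0.  Default permutation
    count for publication-grade runs is 9999.
    """
    pops = table.pop_names
    loci = encode_loci(table)
    _check_populations(loci, table, pops)
    onehot_cols = {p: i for i, p in enumerate(pops)}
    labels = np.array([onehot_cols[p] for p in table.populations])

    def theta_of(lab):
        oh = np.array([(lab == i) for i in range(len(pops))], dtype=float)
        return _theta_from_components(*_wc_components(loci, oh))

    observed = theta_of(labels)
    if n_perm == 0:
        return observed, None
    rng = np.random.default_rng(seed)
    p = _perm_pvalue(theta_of, labels, observed, n_perm, rng)
    return observed, p


def pairwise_fst(table, n_perm: int = 0, seed: int | None = None):
    """Pairwise multilocus theta; returns (PairwiseMatrix, PairwiseMatrix|None)."""
    pops = table.pop_names
    r = len(pops)
    if r < 2:
        raise ValueError("need at least two populations")
    loci = encode_loci(table)
    _check_populations(loci, table, pops)
    vals = np.zeros((r, r))
    pvals = np.full((r, r), np.nan)
    rng = np.random.default_rng(seed)
    for i in range(r):
        for j in range(i + 1, r):
            idx = np.concatenate([table.pop_indices(pops[i]),
                                  table.pop_indices(pops[j])])
            sub = table.take_individuals(idx)
            sub_loci = encode_loci(sub)
            labels = (sub.populations == pops[j]).astype(int)

            def theta_of(lab):
                oh = np.array([lab == 0, lab == 1], dtype=float)
                return _theta_from_components(*_wc_components(sub_loci, oh))

            obs = theta_of(labels)
            vals[i, j] = vals[j, i] = obs
            if n_perm:
                p = _perm_pvalue(theta_of, labels, obs, n_perm, rng)
                pvals[i, j] = pvals[j, i] = p
    fst = PairwiseMatrix(pops, vals, diagonal="zero", name="FST")
    pmat = (
        PairwiseMatrix(pops, pvals, diagonal="undefined", name="FST_p")
        if n_perm else None
    )
    return fst, pmat


# ---------------------------------------------------------------------------
# Jost's D
# ---------------------------------------------------------------------------

def _dest_locus(loc: LocusArrays, onehot: np.ndarray) -> float | None:
    typed = (~loc.missing).astype(float)
    n_i = onehot @ typed
    use = n_i > 0
    k_pops = int(use.sum())
    if k_pops < 2 or loc.n_alleles < 2:
        return None
    sub = onehot[use]
    n = n_i[use]
    counts = sub @ loc.dosage.astype(float)
    p = counts / (2.0 * n[:, None])
    ho = float(((sub @ loc.het.any(axis=1).astype(float)) / n).mean())
    n_harm = k_pops / (1.0 / n).sum()
    hs_raw = 1.0 - float((p ** 2).sum(axis=1).mean())
    pbar = p.mean(axis=0)
    ht_raw = 1.0 - float((pbar ** 2).sum())
    hs = (n_harm / (n_harm - 1.0)) * (hs_raw - ho / (2.0 * n_harm))
    ht = ht_raw + hs / (k_pops * n_harm) - ho / (2.0 * k_pops * n_harm)
    if 1.0 - hs <= 0:
        return None
    return (k_pops / (k_pops - 1.0)) * (ht - hs) / (1.0 - hs)


def jost_dest_value(table, pops: list[str]) -> float:
    """Multilocus Jost D for a population subset (mean of per-locus D)."""
    idx = np.concatenate([table.pop_indices(p) for p in pops])
    sub = table.take_individuals(idx)
    loci = encode_loci(sub)
    onehot = pop_onehot(sub.populations, pops)
    per_locus = [_dest_locus(loc, onehot) for loc in loci]
    per_locus = [d for d in per_locus if d is not None]
    if not per_locus:
        raise ValueError("no polymorphic locus shared by the populations")
    return float(np.mean(per_locus))


def jost_dest(table) -> PairwiseMatrix:
    """Pairwise Jost D matrix (Nei-Chesser corrected, averaged over loci)."""
    pops = table.pop_names
    r = len(pops)
    if r < 2:
        raise ValueError("need at least two populations")
    vals = np.zeros((r, r))
    for i in range(r):
        for j in range(i + 1, r):
            vals[i, j] = vals[j, i] = jost_dest_value(table, [pops[i], pops[j]])
    return PairwiseMatrix(pops, vals, diagonal="zero", name="DEST")
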