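"""Exact tests of genic differentiation and Fisher's combination over loci.

Per locus the test conditions on the allele-count contingency table
(alleles x 2 populations): the statistic is the multivariate hypergeometric
probability of the observed table, and the p-value is the Monte-Carlo
fraction of fixed-margin resamples whose table is no more probable.  Loci
are combined with Fisher's method, -2 sum(ln p) ~ chi2(2L).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

from ._encode import encode_loci


@dataclass
class ExactTestResult:
    per_locus: dict[str, float]     # locus -> Monte-Carlo p (skipped loci absent)
    skipped: list[str]              # monomorphic-across-both loci
    combined_p: float


def _log_table_prob(counts: np.ndarray) -> float:
    """log multivariate hypergeometric probability of an alleles x pops table."""
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    n = counts.sum()
    return float(
        gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(n + 1)
        - gammaln(counts + 1).sum()
    )


def exact_locus_test(counts: np.ndarray, n_resamples: int = 10_000,
                     seed: int | None = None,
                     rng: np.random.Generator | None = None) -> float:
    """Monte-Carlo exact probability test on an alleles x pops count table."""
    counts = np.asarray(counts, dtype=int)
    if rng is None:
        rng = np.random.default_rng(seed)
    obs = _log_table_prob(counts)
    k, r = counts.shape
    # pooled allele copies with population labels; permute labels, recount
    allele_ids = np.repeat(np.arange(k), counts.sum(axis=1))
    col_sizes = counts.sum(axis=0)
    hits = 0
    for _ in range(n_resamples):
        perm = rng.permutation(allele_ids)
        tab = np.zeros((k, r), dtype=int)
        start = 0
        for c, sz in enumerate(col_sizes):
            seg = perm[start:start + sz]
            tab[:, c] = np.bincount(seg, minlength=k)
            start += sz
        if _log_table_prob(tab) <= obs + 1e-12:
            hits += 1
    return (1 + hits) / (n_resamples + 1)


def exact_differentiation_test(table, pair: tuple[str, str],
                               n_resamples: int = 10_000,
                               seed: int | None = None) -> ExactTestResult:
    """Genic differentiation between two populations, per locus + combined."""
    a, b = pair
    idx = np.concatenate([table.pop_indices(a), table.pop_indices(b)])
    if len(table.pop_indices(a)) == 0 or len(table.pop_indices(b)) == 0:
        raise ValueError(f"empty population in pair {pair}")
    sub = table.take_individuals(idx)
    loci = encode_loci(sub)
    in_b = sub.populations == b
    rng = np.random.default_rng(seed)
    per_locus: dict[str, float] = {}
    skipped: list[str] = []
    for loc in loci:
        if loc.n_alleles < 2:
            skipped.append(loc.name)
            continue
        counts = np.stack(
            [
                loc.dosage[~in_b & ~loc.missing].sum(axis=0),
                loc.dosage[in_b & ~loc.missing].sum(axis=0),
            ],
            axis=1,
        )
        if (counts.sum(axis=1) > 0).sum() < 2 or (counts.sum(axis=0) == 0).any():
            skipped.append(loc.name)
            continue
        per_locus[loc.name] = exact_locus_test(counts, n_resamples, rng=rng)
    if not per_locus:
        raise ValueError("no testable (polymorphic) locus for this pair")
    stat = -2.0 * sum(np.log(p) for p in per_locus.values())
    combined = float(chi2.sf(stat, 2 * len(per_locus)))
    return ExactTestResult(per_locus, skipped, combined)
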