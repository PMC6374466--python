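"""Per-population genetic diversity: Na, Ho, He, allelic richness, FIS,
fixed loci and private alleles.

Allelic richness is standardised to a common genet count g by hypergeometric
rarefaction: A_g = sum over alleles of [1 - C(2N - n_i, 2g) / C(2N, 2g)],
the expected number of alleles in a random subsample of 2g gene copies.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._encode import allele_freqs, encode_loci, pop_onehot


@dataclass
class DiversitySummary:
    per_locus: pd.DataFrame    # rows (population, locus), columns Na/Ho/He/uHe/A/Fis
    means: pd.DataFrame        # per-population means over loci + fixed-locus count
    private_carriers: dict[str, list[str]]  # population -> individuals w/ private alleles
    rarefaction_g: int

    def to_csv(self, path) -> None:
        self.per_locus.to_csv(path)


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where(n >= k, out, -np.inf)


def rarefied_richness(counts: np.ndarray, n_copies: int, g2: int) -> float:
    """Expected allele count in a subsample of g2 gene copies.

    counts: allele copy counts (sum = n_copies).  Brute-force check: equals
    the mean allele count over all C(n_copies, g2) subsamples.
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    if n_copies < g2:
        raise ValueError("subsample larger than sample")
    with np.errstate(invalid="ignore"):
        log_absent = _log_comb(n_copies - counts, g2) - _log_comb(n_copies, g2)
    return float(np.sum(1.0 - np.exp(log_absent)))


def diversity(table, rarefaction_g: int | None = None) -> DiversitySummary:
    """Diversity summary per population x locus (clones assumed removed).

    He = 1 - sum p_i^2; uHe = He * 2N/(2N-1); Ho = fraction heterozygous among
    genotyped; FIS = (He - Ho)/He where He > 0, else NaN.  ``rarefaction_g``
    defaults to the smallest per-population genet count; it must not exceed
    the smallest number of genotyped individuals at any (population, locus).
    """
    pops = table.pop_names
    loci = encode_loci(table)
    onehot = pop_onehot(table.populations, pops)
    pop_sizes = {p: len(table.pop_indices(p)) for p in pops}
    if rarefaction_g is None:
        rarefaction_g = min(pop_sizes.values())
    for p in pops:
        if rarefaction_g > pop_sizes[p]:
            raise ValueError(
                f"rarefaction_g={rarefaction_g} exceeds population {p} "
                f"(n={pop_sizes[p]})"
            )

    rows = []
    for loc in loci:
        freqs, n_typed = allele_freqs(loc, onehot)
        counts = onehot @ loc.dosage.astype(float)
        n_het = onehot @ (loc.het.any(axis=1).astype(float))
        for pi, pop in enumerate(pops):
            n = n_typed[pi]
            if n == 0:
                rows.append((pop, loc.name, 0, np.nan, np.nan, np.nan,
                             np.nan, np.nan))
                continue
            p = freqs[pi]
            na = int((counts[pi] > 0).sum())
            he = 1.0 - float((p ** 2).sum())
            uhe = he * (2 * n) / (2 * n - 1) if n > 0.5 else np.nan
            ho = float(n_het[pi] / n)
            g2 = 2 * min(rarefaction_g, int(n))
            a = rarefied_richness(counts[pi], int(2 * n), g2)
            fis = (he - ho) / he if he > 0 else np.nan
            rows.append((pop, loc.name, na, ho, he, uhe, a, fis))
    per_locus = pd.DataFrame(
        rows, columns=["population", "locus", "Na", "Ho", "He", "uHe", "A", "Fis"]
    ).set_index(["population", "locus"])

    means = per_locus.groupby(level="population").mean(numeric_only=True)
    fixed = (
        per_locus["Na"].eq(1).groupby(level="population").sum().rename("n_fixed_loci")
    )
    means = means.join(fixed).loc[pops]

    # private alleles: present in exactly one population
    private: dict[str, list[str]] = {p: [] for p in pops}
    for loc in loci:
        counts = onehot @ loc.dosage.astype(float)
        present = counts > 0
        only_one = present.sum(axis=0) == 1
        for ai in np.flatnonzero(only_one):
            pi = int(np.argmax(present[:, ai]))
            carriers = np.flatnonzero(
                (loc.dosage[:, ai] > 0) & (table.populations == pops[pi])
            )
            private[pops[pi]].extend(table.individuals[i] for i in carriers)
    private = {p: sorted(set(v)) for p, v in private.items()}
    return DiversitySummary(per_locus, means, private, rarefaction_g)
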