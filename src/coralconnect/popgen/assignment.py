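"""Bayesian individual assignment (Rannala-Mountain criterion).

For each candidate population the likelihood of an individual's multilocus
genotype is computed from the population's posterior allele frequencies
under a Dirichlet prior that adds 1/k to each allele count (k = number of
alleles observed at the locus across the whole dataset).  Drawing the two
gene copies sequentially gives, with reference counts n_a at total n:

    hom aa:  (n_a + 1/k)(n_a + 1 + 1/k) / ((n + 1)(n + 2))
    het ab:  2 (n_a + 1/k)(n_b + 1/k) / ((n + 1)(n + 2))

The individual's own alleles are removed from its home population's counts
(leave-one-out).  Likelihoods are normalised over candidates; an individual
is assigned when the top probability exceeds the threshold, and flagged as
an immigrant when the assigned population's region class differs from its
sampling region.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._encode import encode_loci, pop_onehot


@dataclass
class AssignmentResult:
    probabilities: pd.DataFrame   # individuals x populations, rows sum to 1
    assigned: pd.Series           # population label or "unassigned"
    immigrant: pd.Series          # bool (False when unassigned or regions unknown)
    log_likelihoods: pd.DataFrame

    def to_csv(self, path) -> None:
        out = self.probabilities.copy()
        out["assigned"] = self.assigned
        out["immigrant"] = self.immigrant
        out.to_csv(path)


def assign_individuals(table, threshold: float = 0.70) -> AssignmentResult:
    """Leave-one-out Rannala-Mountain assignment of every individual."""
    pops = table.pop_names
    loci = encode_loci(table)
    onehot = pop_onehot(table.populations, pops)
    n_ind = table.n_individuals
    home = {p: i for i, p in enumerate(pops)}
    logL = np.zeros((n_ind, len(pops)))

    for loc in loci:
        k = loc.n_alleles
        if k == 0:
            continue
        prior = 1.0 / k
        counts = onehot @ loc.dosage.astype(float)       # (r, k) copies
        totals = counts.sum(axis=1)                      # (r,)
        for i in range(n_ind):
            if loc.missing[i]:
                continue
            dos = loc.dosage[i].astype(float)
            hp = home[table.populations[i]]
            for pi in range(len(pops)):
                c = counts[pi].copy()
                t = totals[pi]
                if pi == hp:
                    c = c - dos
                    t = t - 2.0
                carried = np.flatnonzero(dos)
                if len(carried) == 2:      # heterozygote
                    a, b = carried
                    lik = 2.0 * (c[a] + prior) * (c[b] + prior)
                else:                      # homozygote
                    a = carried[0]
                    lik = (c[a] + prior) * (c[a] + 1.0 + prior)
                lik /= (t + 1.0) * (t + 2.0)
                logL[i, pi] += np.log(lik)

    probs = np.exp(logL - logL.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    probs_df = pd.DataFrame(probs, index=table.individuals, columns=pops)
    best = probs_df.idxmax(axis=1)
    best_p = probs_df.max(axis=1)
    assigned = best.where(best_p > threshold, "unassigned")
    immigrant = pd.Series(False, index=table.individuals)
    if table.region:
        for ind, pop, dest in zip(table.individuals, table.populations, assigned):
            if dest != "unassigned":
                r_home = table.region.get(pop)
                r_dest = table.region.get(dest)
                immigrant[ind] = (
                    r_home is not None and r_dest is not None and r_home != r_dest
                )
    logL_df = pd.DataFrame(logL, index=table.individuals, columns=pops)
    return AssignmentResult(probs_df, assigned, immigrant, logL_df)
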