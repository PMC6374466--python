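"""Internal per-locus allele-count encoding.

Frequency-based statistics all start from the same arrays: per locus, an
individuals x alleles dosage matrix (0/1/2 copies), a heterozygote-carrier
indicator, and a missing mask.  Permutation tests then reduce to regrouping
row sums by population label, which keeps resampling loops cheap.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LocusArrays:
    name: str
    alleles: np.ndarray          # sorted unique allele labels, shape (k,)
    dosage: np.ndarray           # (n_ind, k) int8, copies of each allele
    het: np.ndarray              # (n_ind, k) bool, heterozygous AND carries allele
    missing: np.ndarray          # (n_ind,) bool

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)


def encode_loci(table) -> list[LocusArrays]:
    out = []
    for li, name in enumerate(table.loci):
        calls = table.calls[:, li, :]           # (n, 2)
        missing = calls[:, 0] == 0
        alleles = np.unique(calls[~missing])
        alleles = alleles[alleles > 0]
        n, k = calls.shape[0], len(alleles)
        dosage = np.zeros((n, k), dtype=np.int8)
        if k:
            pos = {a: j for j, a in enumerate(alleles)}
            for copy in (0, 1):
                col = calls[:, copy]
                for i in np.flatnonzero(~missing):
                    dosage[i, pos[col[i]]] += 1
        het_ind = (~missing) & (calls[:, 0] != calls[:, 1])
        het = (dosage == 1) & het_ind[:, None]
        out.append(LocusArrays(name, alleles, dosage, het, missing))
    return out


def pop_onehot(populations: np.ndarray, pops: list[str]) -> np.ndarray:
    """(r, n) float indicator matrix of population membership."""
    return np.array([(populations == p) for p in pops], dtype=float)


def allele_freqs(loc: LocusArrays, onehot: np.ndarray):
    """Per-population allele frequencies at one locus.

    Returns (freqs (r,k), n_typed (r,)) where n_typed is the number of
    genotyped individuals per population (locus-wise pairwise deletion).
    """
    typed = (~loc.missing).astype(float)
    n_typed = onehot @ typed
    counts = onehot @ loc.dosage.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = counts / (2.0 * n_typed[:, None])
    return freqs, n_typed
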