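"""Hierarchical analysis of molecular variance (AMOVA).

The decomposition operates on gene copies: per locus every genotyped
individual contributes two allelic units and the inter-unit distance is
allele identity (0 same / 1 different).  Sums of squares for any set of m
units then reduce to m (1 - sum f_a^2) / 2 via the pairwise identity
SS = sum_{i<j} d_ij / m, variance components use the standard
unequal-sample-size coefficients, components are summed over loci, and the
fixation indices are

    FCT = sa / (sa+sb+sc),  FSC = sb / (sb+sc),  FST = (sa+sb) / (sa+sb+sc).

Permutation p-values move whole individuals: among populations (FST),
among populations within groups (FSC), and whole populations among groups
(FCT).

``allele_distance_matrix`` (number of non-shared alleles between diploid
genotypes, summed over loci) is retained for individual-level ordination.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._encode import encode_loci, pop_onehot


@dataclass
class AMOVAResult:
    components: dict[str, float]       # variance components (sigma^2)
    percentages: dict[str, float]      # % of total variance
    indices: dict[str, float]          # FCT, FSC, FST (NaN when undefined)
    pvalues: dict[str, float]
    df: dict[str, int]


def allele_distance_matrix(table) -> np.ndarray:
    """n x n matrix of non-shared allele counts between diploid genotypes,
    summed over loci scored in both individuals."""
    n = table.n_individuals
    d = np.zeros((n, n))
    calls = table.calls
    missing = table.missing_mask()
    for i in range(n):
        for j in range(i + 1, n):
            both = ~(missing[i] | missing[j])
            if not both.any():
                continue
            a, b = calls[i][both], calls[j][both]
            eq = (a == b).all(axis=1)
            share = (
                (a[:, 0] == b[:, 0]) | (a[:, 0] == b[:, 1])
                | (a[:, 1] == b[:, 0]) | (a[:, 1] == b[:, 1])
            )
            diff = np.where(eq, 0, np.where(share, 1, 2))
            d[i, j] = d[j, i] = diff.sum()
    return d


def _locus_components(counts: np.ndarray, group_of_pop: np.ndarray,
                      n_groups: int):
    """(sa, sb, sc) for one locus from per-population allele copy counts.

    counts: (r, k) allele copies per population; populations with zero
    typed copies are dropped.  Returns NaN components where a level has no
    degrees of freedom.
    """
    m_p = counts.sum(axis=1)
    use = m_p > 0
    counts = counts[use]
    gids = group_of_pop[use]
    m_p = m_p[use]
    r = len(m_p)
    groups = np.unique(gids)
    g = len(groups)
    if r < 2:
        return np.nan, np.nan, np.nan
    M = m_p.sum()
    pooled = counts.sum(axis=0)

    def ss_of(cnt):
        m = cnt.sum()
        return (m - (cnt ** 2).sum() / m) / 2.0 if m > 0 else 0.0

    ss_total = ss_of(pooled)
    ss_wp = sum(ss_of(c) for c in counts)
    grp_counts = {gn: counts[gids == gn].sum(axis=0) for gn in groups}
    ss_wg = sum(ss_of(c) for c in grp_counts.values())
    ss_ap = ss_wg - ss_wp
    ss_ag = ss_total - ss_wg

    df_ag, df_ap, df_wp = g - 1, r - g, M - r
    m_g = {gn: m_p[gids == gn].sum() for gn in groups}
    sum_m2_by_group = {gn: (m_p[gids == gn] ** 2).sum() for gn in groups}

    sc = ss_wp / df_wp if df_wp > 0 else np.nan
    if df_ap > 0 and not np.isnan(sc):
        n1 = (M - sum(sum_m2_by_group[gn] / m_g[gn] for gn in groups)) / df_ap
        sb = (ss_ap / df_ap - sc) / n1
    else:
        sb = np.nan
    if df_ag > 0 and not np.isnan(sc):
        n2 = (sum(sum_m2_by_group[gn] / m_g[gn] for gn in groups)
              - (m_p ** 2).sum() / M) / df_ag
        n3 = (M - sum(v ** 2 for v in m_g.values()) / M) / df_ag
        sb_eff = 0.0 if np.isnan(sb) else sb
        sa = (ss_ag / df_ag - sc - n2 * sb_eff) / n3
    else:
        sa = np.nan
    return sa, sb, sc


def _components(loci, onehot, group_of_pop, n_groups):
    """Components summed over loci for one labelling of individuals."""
    SA = SB = SC = 0.0
    any_a = any_b = False
    for loc in loci:
        counts = onehot @ loc.dosage.astype(float)
        sa, sb, sc = _locus_components(counts, group_of_pop, n_groups)
        if np.isnan(sc):
            continue
        SC += sc
        if not np.isnan(sb):
            SB += sb
            any_b = True
        if not np.isnan(sa):
            SA += sa
            any_a = True
    return (SA if any_a else np.nan, SB if any_b else np.nan, SC)


def _indices(sa, sb, sc):
    sa_e = 0.0 if np.isnan(sa) else sa
    sb_e = 0.0 if np.isnan(sb) else sb
    tot = sa_e + sb_e + sc
    fct = sa_e / tot if tot else 0.0
    fsc = sb_e / (sb_e + sc) if (sb_e + sc) else 0.0
    fst = (sa_e + sb_e) / tot if tot else 0.0
    return fct, fsc, fst


def amova(table, grouping: dict[str, str] | None = None,
          n_perm: int = 999, seed: int | None = None) -> AMOVAResult:
    """Two- or three-level AMOVA on allele-identity distances.

    ``grouping`` maps population -> group label; None (or a single group)
    yields the two-level global decomposition whose FST is the global
    fixation index.
    """
    pops = table.pop_names
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    single_group = grouping is None or len(set(grouping.values())) == 1
    if grouping is None:
        grouping = {p: "all" for p in pops}
    missing = [p for p in pops if p not in grouping]
    if missing:
        raise ValueError(f"populations without a group: {missing}")

    loci = encode_loci(table)
    rng = np.random.default_rng(seed)
    pop_index = {p: i for i, p in enumerate(pops)}
    labels = np.array([pop_index[p] for p in table.populations])
    group_names = list(dict.fromkeys(grouping[p] for p in pops))
    gid_of_pop = np.array([group_names.index(grouping[p]) for p in pops])

    def onehot_of(lab):
        return np.array([(lab == i) for i in range(len(pops))], dtype=float)

    if single_group:
        # two-level: treat each population as its own "group"
        own = np.arange(len(pops))
        sa, sb, sc = _components(loci, onehot_of(labels), own, len(pops))
        comp = {"among_pops": 0.0 if np.isnan(sa) else sa, "within_pops": sc}
        tot = sum(comp.values())
        pct = {k: 100.0 * v / tot for k, v in comp.items()}
        fst_obs = comp["among_pops"] / tot if tot else 0.0
        indices = {"FCT": np.nan, "FSC": np.nan, "FST": fst_obs}
        n_typed = int((~table.missing_mask()).sum())
        df = {"among_pops": len(pops) - 1,
              "within_pops": 2 * n_typed // len(loci) - len(pops)
              if loci else 0}
        pvalues = {}
        if n_perm:
            count = 0
            lab = labels.copy()
            for _ in range(n_perm):
                rng.shuffle(lab)
                sa2, _, sc2 = _components(loci, onehot_of(lab), own, len(pops))
                sa2 = 0.0 if np.isnan(sa2) else sa2
                tot2 = sa2 + sc2
                if (sa2 / tot2 if tot2 else 0.0) >= fst_obs:
                    count += 1
            pvalues["FST"] = (1 + count) / (n_perm + 1)
        return AMOVAResult(comp, pct, indices, pvalues, df)

    sa, sb, sc = _components(loci, onehot_of(labels), gid_of_pop,
                             len(group_names))
    one_pop_groups = all(
        (gid_of_pop == g).sum() == 1 for g in range(len(group_names))
    )
    sa_e = 0.0 if np.isnan(sa) else sa
    sb_e = 0.0 if np.isnan(sb) else sb
    comp = {
        "among_groups": sa_e,
        "among_pops_within_groups": sb_e,
        "within_pops": sc,
    }
    tot = sa_e + sb_e + sc
    pct = {k: 100.0 * v / tot for k, v in comp.items()}
    fct_obs, fsc_obs, fst_obs = _indices(sa, sb, sc)
    indices = {
        "FCT": fct_obs,
        "FSC": np.nan if one_pop_groups else fsc_obs,
        "FST": fst_obs,
    }
    df = {
        "among_groups": len(group_names) - 1,
        "among_pops_within_groups": len(pops) - len(group_names),
        "within_pops": int((~table.missing_mask()).sum() * 2 / max(len(loci), 1)
                           ) - len(pops),
    }
    pvalues: dict[str, float] = {}
    if n_perm:
        c_fct = c_fsc = c_fst = 0
        lab_global = labels.copy()
        for _ in range(n_perm):
            # FCT: permute whole populations among groups
            g_perm = rng.permutation(gid_of_pop)
            fct, _, _ = _indices(*_components(
                loci, onehot_of(labels), g_perm, len(group_names)))
            if fct >= fct_obs:
                c_fct += 1
            # FSC: permute individuals among populations within groups
            lab = labels.copy()
            for g in range(len(group_names)):
                members = np.flatnonzero(gid_of_pop == g)
                idx = np.flatnonzero(np.isin(labels, members))
                lab[idx] = rng.permutation(lab[idx])
            _, fsc, _ = _indices(*_components(
                loci, onehot_of(lab), gid_of_pop, len(group_names)))
            if not one_pop_groups and fsc >= fsc_obs:
                c_fsc += 1
            # FST: permute individuals among all populations
            rng.shuffle(lab_global)
            _, _, fst = _indices(*_components(
                loci, onehot_of(lab_global), gid_of_pop, len(group_names)))
            if fst >= fst_obs:
                c_fst += 1
        pvalues = {
            "FCT": (1 + c_fct) / (n_perm + 1),
            "FST": (1 + c_fst) / (n_perm + 1),
        }
        if not one_pop_groups:
            pvalues["FSC"] = (1 + c_fsc) / (n_perm + 1)
    return AMOVAResult(comp, pct, indices, pvalues, df)
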