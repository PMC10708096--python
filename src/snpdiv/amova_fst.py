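"""Distance-based AMOVA and pairwise F_ST with permutation significance.

Individuals are expanded into 2N allele copies ("gametes", 0/1 per locus).
Squared-Euclidean distances between gametes, summed over loci where both
copies are called and rescaled by n_loci / n_comparable, feed the standard
distance-partition identities:

    SS(group of size m) = (1/m) * sum_{i<j in group} d2_ij

Strata are populations / individuals within populations / allele copies
within individuals, with df P-1 / N-P / N (summing to 2N-1). Variance
components come from the mean squares with the unbalanced-design coefficient
n0 computed on gamete counts. Weir-Cockerham theta is available as an
alternative F_ST estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .io_formats import MISSING, GenotypeMatrix


@dataclass
class AmovaResult:
    strata: list[str]  # among_populations, among_individuals_within_populations, within_individuals
    df: dict[str, int]
    ss: dict[str, float]
    variance_components: dict[str, float]  # as computed (may be negative)
    pct_variation: dict[str, float]  # percentages, negatives floored before scaling
    phi: dict[str, float]  # phi_PT analogue per level
    p_values: dict[str, float]
    n_permutations: int

    @property
    def total_ss(self) -> float:
        return sum(self.ss.values())


@dataclass
class FstMatrix:
    labels: list[str]
    fst: np.ndarray  # symmetric, NaN diagonal
    p_values: np.ndarray
    n_permutations: int


_STRATA = [
    "among_populations",
    "among_individuals_within_populations",
    "within_individuals",
]


def _gamete_matrix(g: GenotypeMatrix) -> np.ndarray:
    """2N x L allele-copy matrix (NaN for missing); het = copies (0, 1)."""
    d = g.dosage
    a = np.where(d == 2, 1.0, 0.0)
    b = np.where(d >= 1, 1.0, 0.0)
    a[d == MISSING] = np.nan
    b[d == MISSING] = np.nan
    out = np.empty((2 * g.n_accessions, g.n_loci))
    out[0::2] = a
    out[1::2] = b
    return out


def _gamete_sq_distances(gam: np.ndarray, n_loci: int) -> np.ndarray:
    """Pairwise squared Euclidean distances over comparable loci, rescaled by
    n_loci / n_comparable."""
    present = ~np.isnan(gam)
    filled = np.where(present, gam, 0.0)
    m = gam.shape[0]
    d2 = np.zeros((m, m))
    for i in range(m):
        both = present[i] & present
        diff = (filled[i] - filled) ** 2
        diff[~both] = 0.0
        comp = both.sum(axis=1)
        if (comp == 0).any():
            j = int(np.argwhere(comp == 0)[0])
            raise ValueError(f"zero comparable loci between allele copies {i} and {j}")
        d2[i] = diff.sum(axis=1) * (n_loci / comp)
    return (d2 + d2.T) / 2.0


def _group_ss(d2: np.ndarray, members: np.ndarray) -> float:
    sub = d2[np.ix_(members, members)]
    m = len(members)
    return float(sub[np.triu_indices(m, k=1)].sum() / m)


def _amova_components(
    d2: np.ndarray, pop_of: np.ndarray, n_pops: int
) -> tuple[dict[str, float], dict[str, float], dict[str, int]]:
    """Core three-level decomposition on gamete squared distances.

    ``pop_of`` maps each individual to a population index; gametes 2i, 2i+1
    belong to individual i.
    """
    n = len(pop_of)
    gam_pop = np.repeat(pop_of, 2)
    all_idx = np.arange(2 * n)

    ss_total = _group_ss(d2, all_idx)
    ss_within_pops = 0.0
    gamete_counts = []
    for p in range(n_pops):
        members = all_idx[gam_pop == p]
        gamete_counts.append(len(members))
        ss_within_pops += _group_ss(d2, members)
    ss_within_indiv = 0.0
    for i in range(n):
        ss_within_indiv += d2[2 * i, 2 * i + 1] / 2.0
    ss_among_pops = ss_total - ss_within_pops
    ss_among_indiv = ss_within_pops - ss_within_indiv

    df_ap = n_pops - 1
    df_ai = n - n_pops
    df_wi = n
    ms_ap = ss_among_pops / df_ap
    ms_ai = ss_among_indiv / df_ai if df_ai > 0 else 0.0
    ms_wi = ss_within_indiv / df_wi

    g_total = 2 * n
    n0 = (g_total - sum(c**2 for c in gamete_counts) / g_total) / df_ap

    sigma_c = ms_wi
    sigma_b = (ms_ai - ms_wi) / 2.0
    sigma_a = (ms_ap - ms_ai) / n0

    ss = {
        "among_populations": ss_among_pops,
        "among_individuals_within_populations": ss_among_indiv,
        "within_individuals": ss_within_indiv,
    }
    comps = {
        "among_populations": sigma_a,
        "among_individuals_within_populations": sigma_b,
        "within_individuals": sigma_c,
    }
    df = {
        "among_populations": df_ap,
        "among_individuals_within_populations": df_ai,
        "within_individuals": df_wi,
    }
    return ss, comps, df


def _encode_grouping(
    g: GenotypeMatrix, grouping: Mapping[str, str]
) -> tuple[np.ndarray, list[str]]:
    labels = sorted(set(grouping[aid] for aid in g.accession_ids))
    label_idx = {lab: i for i, lab in enumerate(labels)}
    pop_of = np.array([label_idx[grouping[aid]] for aid in g.accession_ids])
    return pop_of, labels


def amova(
    g: GenotypeMatrix,
    grouping: Mapping[str, str],
    n_permutations: int = 9999,
    seed: int = 0,
) -> AmovaResult:
    """Three-level AMOVA with whole-individual permutation of the top level.

    p-values are (1 + #{permuted component >= observed}) / (1 + n_perm),
    i.e. the observed arrangement is included in both counts.
    """
    missing_ids = [aid for aid in g.accession_ids if aid not in grouping]
    if missing_ids:
        raise KeyError(f"accessions without group label: {missing_ids[:5]}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    pop_of, labels = _encode_grouping(g, grouping)
    n_pops = len(labels)
    if n_pops < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(pop_of, minlength=n_pops)
    if (sizes < 2).any():
        small = [labels[i] for i in np.where(sizes < 2)[0]]
        raise ValueError(f"groups of size < 2: {small}")

    gam = _gamete_matrix(g)
    d2 = _gamete_sq_distances(gam, g.n_loci)
    ss, comps, df = _amova_components(d2, pop_of, n_pops)

    floored = {k: max(v, 0.0) for k, v in comps.items()}
    total = sum(floored.values())
    pct = {k: (100.0 * v / total if total > 0 else 0.0) for k, v in floored.items()}

    total_raw = sum(floored.values())
    sigma_a = floored["among_populations"]
    sigma_b = floored["among_individuals_within_populations"]
    phi = {
        "among_populations": sigma_a / total_raw if total_raw > 0 else 0.0,
        "among_individuals_within_populations": (
            sigma_b / (total_raw - sigma_a) if total_raw - sigma_a > 0 else 0.0
        ),
        "within_individuals": (
            (sigma_a + sigma_b) / total_raw if total_raw > 0 else 0.0
        ),
    }

    rng = np.random.default_rng(seed)
    observed = comps["among_populations"]
    n_ge = 1  # observed arrangement counted
    for _ in range(n_permutations):
        perm = rng.permutation(len(pop_of))
        _, pcomp, _ = _amova_components(d2, pop_of[perm], n_pops)
        if pcomp["among_populations"] >= observed:
            n_ge += 1
    p_among = n_ge / (n_permutations + 1)

    return AmovaResult(
        strata=list(_STRATA),
        df=df,
        ss=ss,
        variance_components=comps,
        pct_variation=pct,
        phi=phi,
        p_values={"among_populations": p_among},
        n_permutations=n_permutations,
    )


def _two_level_fst(d2: np.ndarray, pop_of: np.ndarray, n_pops: int) -> float:
    """F_ST = sigma_among / (sigma_among + sigma_within) from a two-level
    collapsed AMOVA on gametes (individual level merged into within)."""
    n = len(pop_of)
    gam_pop = np.repeat(pop_of, 2)
    all_idx = np.arange(2 * n)
    ss_total = _group_ss(d2, all_idx)
    ss_within = 0.0
    gamete_counts = []
    for p in range(n_pops):
        members = all_idx[gam_pop == p]
        gamete_counts.append(len(members))
        ss_within += _group_ss(d2, members)
    ss_among = ss_total - ss_within
    g_total = 2 * n
    df_ap = n_pops - 1
    df_w = g_total - n_pops
    ms_ap = ss_among / df_ap
    sigma_w = ss_within / df_w if df_w > 0 else 0.0
    n0 = (g_total - sum(c**2 for c in gamete_counts) / g_total) / df_ap
    sigma_a = (ms_ap - sigma_w) / n0
    denom = sigma_a + sigma_w
    if denom <= 0:
        return 0.0
    return float(sigma_a / denom)


def pairwise_fst(
    g: GenotypeMatrix,
    grouping: Mapping[str, str],
    n_permutations: int = 999,
    seed: int = 0,
) -> FstMatrix:
    """Pairwise distance-based F_ST (Phi-statistic analogue) between groups,
    with whole-individual permutation p-values."""
    pop_of, labels = _encode_grouping(g, grouping)
    n_pops = len(labels)
    if n_pops < 2:
        raise ValueError("need at least two groups")
    gam = _gamete_matrix(g)
    d2_full = _gamete_sq_distances(gam, g.n_loci)

    k = n_pops
    fst = np.full((k, k), np.nan)
    pvals = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    for a in range(k):
        for b in range(a + 1, k):
            rows = np.where((pop_of == a) | (pop_of == b))[0]
            sub_pop = (pop_of[rows] == b).astype(int)
            gam_rows = np.sort(np.concatenate([2 * rows, 2 * rows + 1]))
            d2 = d2_full[np.ix_(gam_rows, gam_rows)]
            observed = _two_level_fst(d2, sub_pop, 2)
            n_ge = 1
            for _ in range(n_permutations):
                perm = rng.permutation(len(sub_pop))
                if _two_level_fst(d2, sub_pop[perm], 2) >= observed:
                    n_ge += 1
            fst[a, b] = fst[b, a] = observed
            pvals[a, b] = pvals[b, a] = n_ge / (n_permutations + 1)
    return FstMatrix(labels=labels, fst=fst, p_values=pvals, n_permutations=n_permutations)


def weir_cockerham_fst(
    g: GenotypeMatrix, grouping: Mapping[str, str]
) -> float:
    """Multi-locus Weir-Cockerham theta (ratio of averages) across all groups.

    Cross-check estimator for the distance-based F_ST; ignores loci where a
    group has no called individuals.
    """
    pop_of, labels = _encode_grouping(g, grouping)
    r = len(labels)
    if r < 2:
        raise ValueError("need at least two groups")
    num_sum = 0.0
    den_sum = 0.0
    d = g.dosage
    for j in range(g.n_loci):
        n_i = np.zeros(r)
        p_i = np.zeros(r)
        h_i = np.zeros(r)
        ok = True
        for p in range(r):
            rows = d[pop_of == p, j]
            rows = rows[rows != MISSING]
            if rows.size == 0:
                ok = False
                break
            n_i[p] = rows.size
            p_i[p] = rows.mean() / 2.0
            h_i[p] = (rows == 1).mean()
        if not ok:
            continue
        n_bar = n_i.mean()
        n_c = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1)
        p_bar = (n_i * p_i).sum() / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum() / (r * n_bar)
        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1.0))
            * (p_bar * (1 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
        c = h_bar / 2.0
        num_sum += a
        den_sum += a + b + c
    if den_sum == 0:
        return 0.0
    return float(num_sum / den_sum)
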