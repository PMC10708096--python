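"""Post-genotyping QC cascade, heterozygosity summaries and multilocus
matching for synonym/hybrid discrimination."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .io_formats import MISSING, GenotypeMatrix


@dataclass
class FilterReport:
    """Outcome of the sequential locus filter cascade.

    Each removed locus is counted in exactly one category (the first it
    triggers, in cascade order), so
    ``n_input - n_design_failed - n_monomorphic - n_high_missing - n_low_maf
    == len(retained_locus_ids)`` is an identity.
    """

    n_input: int
    n_design_failed: int
    n_monomorphic: int
    n_high_missing: int
    n_low_maf: int
    retained_locus_ids: list[str]
    category_of: dict[str, str] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return len(self.retained_locus_ids)


@dataclass
class DiversitySummary:
    locus_ids: list[str]
    he: np.ndarray  # per locus
    ho: np.ndarray  # per locus
    group_means: dict[str, tuple[float, float]]  # label -> (mean He, mean Ho)
    overall: tuple[float, float]


@dataclass
class MatchReport:
    accession_ids: list[str]
    mismatches: np.ndarray  # symmetric int matrix, zero diagonal
    comparable: np.ndarray  # loci with both calls present, per pair
    synonym_groups: list[set[str]]  # multi-member components only


def apply_filter_cascade(
    g: GenotypeMatrix,
    design_failed_ids: Iterable[str] = (),
    missing_max: float = 0.10,
    maf_min: float = 0.05,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove loci in cascade order: design-failed, monomorphic (one observed
    allele), missingness > ``missing_max``, MAF < ``maf_min``. A locus is
    assigned to the first category it triggers."""
    if not (0.0 <= missing_max <= 1.0 and 0.0 <= maf_min <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    failed = set(design_failed_ids)
    miss = g.missing_fraction()
    maf = g.maf()
    alt = g.alt_freq()
    counts = {"design_failed": 0, "monomorphic": 0, "high_missing": 0, "low_maf": 0}
    retained: list[str] = []
    category: dict[str, str] = {}
    for j, lid in enumerate(g.locus_ids):
        if lid in failed:
            cat = "design_failed"
        elif np.isnan(alt[j]) or alt[j] in (0.0, 1.0):
            cat = "monomorphic"
        elif miss[j] > missing_max:
            cat = "high_missing"
        elif maf[j] < maf_min:
            cat = "low_maf"
        else:
            retained.append(lid)
            continue
        counts[cat] += 1
        category[lid] = cat
    report = FilterReport(
        n_input=g.n_loci,
        n_design_failed=counts["design_failed"],
        n_monomorphic=counts["monomorphic"],
        n_high_missing=counts["high_missing"],
        n_low_maf=counts["low_maf"],
        retained_locus_ids=retained,
        category_of=category,
    )
    return g.subset_loci(retained), report


def _he_ho(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus He = 2p(1-p) and Ho over non-missing calls; NaN if none."""
    present = dosage != MISSING
    n_obs = present.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(present, dosage, 0).sum(axis=0) / (2.0 * n_obs)
        he = 2.0 * p * (1.0 - p)
        ho = (dosage == 1).sum(axis=0) / n_obs
    he[n_obs == 0] = np.nan
    ho[n_obs == 0] = np.nan
    return he, ho


def heterozygosity(
    g: GenotypeMatrix,
    groups: Mapping[str, str] | None = None,
    unbiased: bool = False,
) -> DiversitySummary:
    """Expected (2p(1-p)) and observed heterozygosity per locus, with
    unweighted across-locus means per group and overall.

    ``unbiased`` applies the 2N/(2N-1) small-sample correction to He.
    Loci with all calls missing inside a group are excluded from that
    group's mean.
    """
    if g.n_loci < 1:
        raise ValueError("need at least one locus")
    he, ho = _he_ho(g.dosage)
    if unbiased:
        n_obs = (g.dosage != MISSING).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            he = he * (2.0 * n_obs) / (2.0 * n_obs - 1.0)
    overall = (float(np.nanmean(he)), float(np.nanmean(ho)))
    group_means: dict[str, tuple[float, float]] = {}
    if groups is not None:
        for label in sorted(set(groups.values())):
            members = [aid for aid, lab in groups.items() if lab == label]
            sub = g.subset_accessions(members)
            ghe, gho = _he_ho(sub.dosage)
            if unbiased:
                n_obs = (sub.dosage != MISSING).sum(axis=0).astype(float)
                with np.errstate(invalid="ignore", divide="ignore"):
                    ghe = ghe * (2.0 * n_obs) / (2.0 * n_obs - 1.0)
            group_means[label] = (float(np.nanmean(ghe)), float(np.nanmean(gho)))
    return DiversitySummary(
        locus_ids=list(g.locus_ids), he=he, ho=ho, group_means=group_means, overall=overall
    )


def multilocus_match(g: GenotypeMatrix, require_complete: bool = False) -> MatchReport:
    """Pairwise multilocus comparison.

    Mismatches are counted over loci where both calls are present. A pair is
    matched iff it has zero mismatches and at least one comparable locus;
    with ``require_complete`` the pair must additionally be comparable at
    every locus. Synonym groups are connected components of the matched
    relation (multi-member components only).
    """
    if g.n_accessions < 2:
        raise ValueError("need at least two accessions")
    d = g.dosage
    present = d != MISSING
    n = g.n_accessions
    mismatches = np.zeros((n, n), dtype=int)
    comparable = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = present[i] & present
        diff = (d[i] != d) & both
        mismatches[i] = diff.sum(axis=1)
        comparable[i] = both.sum(axis=1)
    np.fill_diagonal(mismatches, 0)

    matched = (mismatches == 0) & (comparable >= 1)
    if require_complete:
        matched &= comparable == g.n_loci
    np.fill_diagonal(matched, False)

    # connected components via union-find
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if matched[i, j]:
                parent[find(i)] = find(j)
    comps: dict[int, set[str]] = {}
    for i, aid in enumerate(g.accession_ids):
        comps.setdefault(find(i), set()).add(aid)
    groups = sorted(
        (c for c in comps.values() if len(c) > 1), key=lambda c: sorted(c)[0]
    )
    return MatchReport(
        accession_ids=list(g.accession_ids),
        mismatches=mismatches,
        comparable=comparable,
        synonym_groups=groups,
    )


def discriminate_set(g: GenotypeMatrix, ids: list[str]) -> bool:
    """True iff every pair among ``ids`` differs at >= 1 comparable locus."""
    unknown = [aid for aid in ids if aid not in g.accession_ids]
    if unknown:
        raise KeyError(f"unknown accession ids: {unknown}")
    if len(ids) < 2:
        return True
    report = multilocus_match(g.subset_accessions(ids))
    m = report.mismatches
    iu = np.triu_indices(len(ids), k=1)
    return bool((m[iu] >= 1).all())
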