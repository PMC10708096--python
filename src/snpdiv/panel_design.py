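"""Genome-wide panel selection: evenly spaced, flank-isolated, polymorphic.

Three eligibility/placement criteria: (1) even spacing, operationalized as
equal-length bins per chromosome with the eligible candidate nearest each
bin midpoint selected; (2) no other candidate within ``flank_bp`` up- or
downstream; (3) MAF strictly above ``maf_min``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import MISSING, SnpLocus


@dataclass(frozen=True)
class PanelConfig:
    per_chromosome_quota: int = 10
    flank_bp: int = 150
    maf_min: float = 0.05
    n_chromosomes_expected: int = 15

    def __post_init__(self) -> None:
        if self.per_chromosome_quota < 1:
            raise ValueError("quota must be >= 1")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")
        if not (0.0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must lie in [0, 0.5)")


@dataclass
class PanelSelection:
    selected: list[SnpLocus]
    bin_index: list[tuple[str, int]]  # (chromosome, bin) per selected locus
    unfilled_bins: list[tuple[str, int]]

    @property
    def per_chromosome_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for chrom, _ in self.bin_index:
            counts[chrom] = counts.get(chrom, 0) + 1
        return counts


def compute_maf(calls: np.ndarray) -> float:
    """Minor allele frequency of one locus column of dosage calls.

    Missing calls are excluded from numerator and denominator.
    """
    calls = np.asarray(calls)
    obs = calls[calls != MISSING]
    if obs.size == 0:
        raise ValueError("MAF undefined: all calls missing")
    p = float(obs.sum()) / (2.0 * obs.size)
    return min(p, 1.0 - p)


def flank_isolated(loci: list[SnpLocus], flank_bp: int) -> list[bool]:
    """Flag each locus isolated iff no other candidate on the same chromosome
    lies within ``flank_bp`` (inclusive: a neighbour exactly flank_bp away
    violates isolation)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i, loc in enumerate(loci):
        by_chrom.setdefault(loc.chromosome, []).append((loc.position, i))
    flags = [True] * len(loci)
    for chrom, entries in by_chrom.items():
        entries.sort()
        positions = [p for p, _ in entries]
        if len(set(positions)) != len(positions):
            raise ValueError(f"duplicate positions on {chrom}")
        for rank, (pos, i) in enumerate(entries):
            near_prev = rank > 0 and pos - entries[rank - 1][0] <= flank_bp
            near_next = rank + 1 < len(entries) and entries[rank + 1][0] - pos <= flank_bp
            if near_prev or near_next:
                flags[i] = False
    return flags


def select_panel(
    candidates: list[SnpLocus],
    chromosome_lengths: dict[str, int],
    cfg: PanelConfig,
) -> PanelSelection:
    """Pick up to ``quota`` eligible loci per chromosome, one per equal-length
    bin, nearest to the bin midpoint (ties: higher MAF, then lower position).

    Candidates must carry a MAF (from VCF sample calls or the caller).
    Unfilled bins are reported, never fatal.
    """
    for loc in candidates:
        if loc.maf is None:
            raise ValueError(f"{loc.locus_id}: candidate lacks MAF")
        if loc.chromosome not in chromosome_lengths:
            raise ValueError(f"{loc.locus_id}: no length for {loc.chromosome}")

    isolated = flank_isolated(candidates, cfg.flank_bp)
    quota = cfg.per_chromosome_quota

    eligible_by_chrom: dict[str, list[SnpLocus]] = {}
    for loc, iso in zip(candidates, isolated):
        if iso and loc.maf > cfg.maf_min:
            eligible_by_chrom.setdefault(loc.chromosome, []).append(loc)

    selected: list[SnpLocus] = []
    bin_index: list[tuple[str, int]] = []
    unfilled: list[tuple[str, int]] = []
    chroms = sorted(
        {loc.chromosome for loc in candidates},
        key=lambda c: (len(c), c),  # chr2 before chr10
    )
    for chrom in chroms:
        length = chromosome_lengths[chrom]
        bin_width = length / quota
        bins: dict[int, list[SnpLocus]] = {b: [] for b in range(quota)}
        for loc in eligible_by_chrom.get(chrom, []):
            b = min(int((loc.position - 1) / bin_width), quota - 1)
            bins[b].append(loc)
        for b in range(quota):
            if not bins[b]:
                unfilled.append((chrom, b))
                continue
            midpoint = (b + 0.5) * bin_width
            best = min(
                bins[b],
                key=lambda loc: (abs(loc.position - midpoint), -loc.maf, loc.position),
            )
            selected.append(best)
            bin_index.append((chrom, b))
    return PanelSelection(selected=selected, bin_index=bin_index, unfilled_bins=unfilled)
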