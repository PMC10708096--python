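"""Seeded genotype simulators with verifiable ground truth.

Accessions are drawn from K differentiated ancestral populations under the
F-model: ancestral allele frequency p_A ~ Uniform(0.1, 0.9) per locus and
population frequency ~ Beta(p_A (1-F)/F, (1-p_A) (1-F)/F), so a single drift
parameter F tunes differentiation. On top of the base draw the generator can
inject defective loci (monomorphic / high-missingness / low-MAF), clone rows
and pedigree hybrids, each verifiable post hoc from the matrix alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io_formats import MISSING, AccessionRecord, GenotypeMatrix, SnpLocus, load_packaged_metadata

CLEAN = "clean"
MONOMORPHIC = "monomorphic"
HIGH_MISSING = "high_missing"
LOW_MAF = "low_maf"

_MAX_COLUMN_TRIES = 500


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for :func:`simulate`; fully deterministic given ``seed``."""

    k_true: int = 2
    drift_f: float | tuple[float, ...] = 0.3  # scalar, or one F per population
    n_accessions: int = 84
    n_loci: int = 150
    n_chromosomes: int = 15
    chromosome_length_bp: int = 30_000_000
    admixture_alpha: float = 0.0  # 0 means one-hot (pure-population) q
    missing_rate: float = 0.0
    n_monomorphic: int = 0
    n_high_missing: int = 0
    n_low_maf: int = 0
    n_clone_pairs: int = 0
    hybrid_specs: tuple[tuple[str, str], ...] = ()
    seed: int = 0
    # optional overrides (used by reference_fixture)
    accession_ids: tuple[str, ...] | None = None
    q_fixed: tuple[tuple[float, ...], ...] | None = None  # per-accession q
    clone_specs: tuple[tuple[str, str], ...] | None = None  # (source, copy)

    def __post_init__(self) -> None:
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        drifts = self.drift_f if isinstance(self.drift_f, tuple) else (self.drift_f,)
        if isinstance(self.drift_f, tuple) and len(self.drift_f) != self.k_true:
            raise ValueError("per-population drift_f length != k_true")
        if any(not (0.0 < f < 1.0) for f in drifts):
            raise ValueError("drift_f must lie in (0, 1)")
        n_defects = self.n_monomorphic + self.n_high_missing + self.n_low_maf
        if n_defects > self.n_loci:
            raise ValueError("defect counts exceed n_loci")
        for frac in (self.missing_rate,):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if self.accession_ids is not None and len(self.accession_ids) != self.n_accessions:
            raise ValueError("accession_ids length != n_accessions")


@dataclass
class SimulationTruth:
    """Everything the generator knows that downstream stages must recover."""

    ancestral_freqs: np.ndarray  # per locus
    population_freqs: np.ndarray  # k_true x loci
    q_true: np.ndarray  # accessions x k_true, rows sum to 1
    defect_labels: list[str]  # per locus
    clone_map: dict[str, str]  # copy -> source
    pedigree: dict[str, tuple[str, str]]  # hybrid -> (mother, father)
    design_failed_ids: list[str] = field(default_factory=list)


def _draw_genotypes(rng: np.random.Generator, q: np.ndarray, pops: np.ndarray) -> np.ndarray:
    """Draw dosage for one locus for all accessions; q (N,K), pops (K,)."""
    n, k = q.shape
    dosage = np.zeros(n, dtype=np.int8)
    for _copy in range(2):
        z = (rng.random((n, 1)) > np.cumsum(q, axis=1)).sum(axis=1).clip(max=k - 1)
        dosage += (rng.random(n) < pops[z]).astype(np.int8)
    return dosage


def _apply_relations(
    col: np.ndarray,
    clone_idx: Sequence[tuple[int, int]],
    hybrid_idx: Sequence[tuple[int, int, int]],
    rng: np.random.Generator,
) -> None:
    """Re-derive clone and hybrid rows of one column in place."""
    for src, dst in clone_idx:
        col[dst] = col[src]
    for child, mother, father in hybrid_idx:
        alleles = []
        for parent in (mother, father):
            d = col[parent]
            if d == MISSING:
                alleles = None
                break
            if d == 0:
                alleles.append(0)
            elif d == 2:
                alleles.append(1)
            else:
                alleles.append(int(rng.random() < 0.5))
        col[child] = MISSING if alleles is None else alleles[0] + alleles[1]


def _column_ok(col: np.ndarray, label: str) -> bool:
    obs = col[col != MISSING]
    miss_frac = 1.0 - obs.size / col.size
    if obs.size == 0:
        return False
    p = obs.mean() / 2.0
    maf = min(p, 1.0 - p)
    polymorphic = 0 < obs.sum() < 2 * obs.size
    if label == CLEAN:
        return polymorphic and maf >= 0.05 and miss_frac <= 0.10
    if label == MONOMORPHIC:
        return not polymorphic and miss_frac == 0.0
    if label == HIGH_MISSING:
        return polymorphic and maf >= 0.05 and miss_frac > 0.10
    if label == LOW_MAF:
        return polymorphic and maf < 0.05 and miss_frac <= 0.10
    raise ValueError(f"unknown defect label {label!r}")


def simulate(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, list[AccessionRecord], SimulationTruth]:
    """Generate a genotype matrix with known ancestry, defects and pedigree.

    Derivation order per locus column: base F-model draw (or defect
    overwrite), then clone rows copied verbatim, then hybrid rows re-drawn
    from their parents. Each column is re-drawn from its own substream until
    it verifies its defect label post hoc, so injected defects are always
    detectable from the matrix alone.
    """
    n, L, k = cfg.n_accessions, cfg.n_loci, cfg.k_true
    root = np.random.SeedSequence(cfg.seed)
    ss_layout, ss_q, ss_defects, ss_cols = root.spawn(4)
    rng_layout = np.random.default_rng(ss_layout)

    # locus placement: distinct uniform positions, round-robin chromosomes
    per_chrom = [L // cfg.n_chromosomes + (c < L % cfg.n_chromosomes) for c in range(cfg.n_chromosomes)]
    loci: list[SnpLocus] = []
    nts = np.array(list("ACGT"))
    idx = 0
    for c, count in enumerate(per_chrom):
        positions = np.sort(
            rng_layout.choice(cfg.chromosome_length_bp, size=count, replace=False) + 1
        )
        for pos in positions:
            ref, alt = rng_layout.choice(4, size=2, replace=False)
            idx += 1
            loci.append(
                SnpLocus(
                    locus_id=f"snp{idx:04d}",
                    chromosome=f"chr{c + 1}",
                    position=int(pos),
                    ref_allele=str(nts[ref]),
                    alt_allele=str(nts[alt]),
                )
            )

    accession_ids = (
        list(cfg.accession_ids)
        if cfg.accession_ids is not None
        else [f"acc{i + 1:03d}" for i in range(n)]
    )
    row_of = {aid: i for i, aid in enumerate(accession_ids)}

    # ancestry proportions
    rng_q = np.random.default_rng(ss_q)
    if cfg.q_fixed is not None:
        q = np.asarray(cfg.q_fixed, dtype=float)
        if q.shape != (n, k):
            raise ValueError("q_fixed shape mismatch")
    elif cfg.admixture_alpha == 0.0:
        q = np.zeros((n, k))
        q[np.arange(n), np.arange(n) % k] = 1.0
    else:
        q = rng_q.dirichlet([cfg.admixture_alpha] * k, size=n)

    # clone and hybrid bookkeeping
    if cfg.clone_specs is not None:
        clone_pairs = list(cfg.clone_specs)
    else:
        flat = [accession_ids[i] for i in rng_layout.permutation(n)[: 2 * cfg.n_clone_pairs]]
        clone_pairs = [(flat[2 * i], flat[2 * i + 1]) for i in range(cfg.n_clone_pairs)]
    clone_map = {copy: src for src, copy in clone_pairs}
    hybrid_ids = [accession_ids[n - len(cfg.hybrid_specs) + i] for i in range(len(cfg.hybrid_specs))]
    pedigree: dict[str, tuple[str, str]] = {}
    hybrid_idx: list[tuple[int, int, int]] = []
    for hid, (mother, father) in zip(hybrid_ids, cfg.hybrid_specs):
        for parent in (mother, father):
            if parent not in row_of:
                raise ValueError(f"hybrid parent {parent!r} not among accessions")
        pedigree[hid] = (mother, father)
        hybrid_idx.append((row_of[hid], row_of[mother], row_of[father]))
    clone_idx = [(row_of[src], row_of[copy]) for src, copy in clone_pairs]
    for src, copy in clone_pairs:
        q[row_of[copy]] = q[row_of[src]]
    for hid, (mother, father) in pedigree.items():
        q[row_of[hid]] = 0.5 * (q[row_of[mother]] + q[row_of[father]])

    # defect layout (disjoint by construction)
    rng_defects = np.random.default_rng(ss_defects)
    labels = [CLEAN] * L
    n_defects = cfg.n_monomorphic + cfg.n_high_missing + cfg.n_low_maf
    defect_cols = rng_defects.permutation(L)[:n_defects]
    cursor = 0
    for label, count in (
        (MONOMORPHIC, cfg.n_monomorphic),
        (HIGH_MISSING, cfg.n_high_missing),
        (LOW_MAF, cfg.n_low_maf),
    ):
        for j in defect_cols[cursor : cursor + count]:
            labels[j] = label
        cursor += count

    dosage = np.zeros((n, L), dtype=np.int8)
    ancestral = np.zeros(L)
    pop_freqs = np.zeros((k, L))
    drifts = np.array(
        cfg.drift_f if isinstance(cfg.drift_f, tuple) else [cfg.drift_f] * k
    )
    shape = (1.0 - drifts) / drifts  # per population
    for j, col_ss in enumerate(ss_cols.spawn(L)):
        rng = np.random.default_rng(col_ss)
        label = labels[j]
        for _try in range(_MAX_COLUMN_TRIES):
            p_a = rng.uniform(0.1, 0.9)
            pops = rng.beta(p_a * shape, (1.0 - p_a) * shape, size=k)
            col = _draw_genotypes(rng, q, pops)
            if label == MONOMORPHIC:
                col[:] = 0
            elif label == LOW_MAF:
                col[:] = 0
                max_alt = int(np.ceil(0.05 * 2 * n)) - 1  # alt copies with MAF < 0.05
                n_alt = int(rng.integers(1, max(max_alt, 1) + 1))
                carriers = rng.choice(n, size=min(n_alt, n), replace=False)
                col[carriers] = 1
            else:
                rate = cfg.missing_rate
                if label == HIGH_MISSING:
                    rate = rng.uniform(0.11, 0.5)
                if rate > 0:
                    n_miss = int(np.ceil(rate * n))
                    col[rng.choice(n, size=n_miss, replace=False)] = MISSING
            _apply_relations(col, clone_idx, hybrid_idx, rng)
            if _column_ok(col, label):
                break
        else:
            raise RuntimeError(f"could not realize defect label {label} at locus {j}")
        dosage[:, j] = col
        ancestral[j] = p_a
        pop_freqs[:, j] = pops

    matrix = GenotypeMatrix(
        accession_ids=accession_ids,
        locus_ids=[loc.locus_id for loc in loci],
        dosage=dosage,
        loci=loci,
    )
    metadata = [
        AccessionRecord(
            name=aid,
            status="hybrid" if aid in pedigree else "old_cultivar",
            origin="-",
            maturation="EEM",
        )
        for aid in accession_ids
    ]
    truth = SimulationTruth(
        ancestral_freqs=ancestral,
        population_freqs=pop_freqs,
        q_true=q,
        defect_labels=labels,
        clone_map=clone_map,
        pedigree=pedigree,
    )
    return matrix, metadata, truth


def candidate_vcf(
    path,
    seed: int = 0,
    n_chromosomes: int = 15,
    per_chromosome: int = 100,
    n_samples: int = 100,
    chromosome_length_bp: int = 30_000_000,
) -> dict[str, int]:
    """Write a dense candidate VCF for panel design.

    Candidates are near-evenly spread (spacing >> 150 bp) with per-locus
    allele frequency drawn Uniform(0.1, 0.5), so every equal-length bin holds
    flank-isolated, polymorphic candidates. Returns the contig-length map.
    """
    from .io_formats import write_vcf

    rng = np.random.default_rng(seed)
    nts = np.array(list("ACGT"))
    loci: list[SnpLocus] = []
    columns: list[np.ndarray] = []
    spacing = chromosome_length_bp / per_chromosome
    i = 0
    for c in range(n_chromosomes):
        for slot in range(per_chromosome):
            jitter = rng.integers(-int(spacing // 4), int(spacing // 4))
            pos = int((slot + 0.5) * spacing) + int(jitter)
            ref, alt = rng.choice(4, size=2, replace=False)
            i += 1
            loci.append(
                SnpLocus(
                    locus_id=f"cand{i:05d}",
                    chromosome=f"chr{c + 1}",
                    position=max(1, pos),
                    ref_allele=str(nts[ref]),
                    alt_allele=str(nts[alt]),
                )
            )
            freq = rng.uniform(0.1, 0.5)
            columns.append(rng.binomial(2, freq, size=n_samples).astype(np.int8))
    matrix = GenotypeMatrix(
        accession_ids=[f"s{j + 1:03d}" for j in range(n_samples)],
        locus_ids=[loc.locus_id for loc in loci],
        dosage=np.stack(columns, axis=1),
        loci=loci,
    )
    lengths = {f"chr{c + 1}": chromosome_length_bp for c in range(n_chromosomes)}
    write_vcf(matrix, path, contig_lengths=lengths)
    return lengths


REFERENCE_SEED = 20231123

_FIXTURE_CLONES = (
    ("Sanyuehong", "Yuhebao"),
    ("Shuidong", "Nanxizaosheng"),
    ("Dazao", "Dahongpao"),
    ("Dazao", "Siyuehong"),
    ("Zengchengjinfeng", "Lanzhu"),
    ("Yuanhong", "Dachenzi"),
)

_FIXTURE_PEDIGREE = {
    "Guinuo-1": ("Guiwei", "Nuomici"),
    "Guinuo-2": ("Guiwei", "Nuomici"),
    "Guinuo-3": ("Guiwei", "Nuomici"),
    "Zaogui": ("Zaoli1hao", "Guiwei"),
    "Zaonuo": ("Zaoli1hao", "Nuomici"),
    "Honggui": ("Hongxiuqiu", "Guiwei"),
    "Guihong": ("Guiwei", "Hongxiuqiu"),
    "06-9": ("Heiye", "Feizixiao"),
    "08-1": ("YNW01", "Feizixiao"),
}

_Q_BY_MATURATION = {"EEM": (1.0, 0.0), "MLM": (0.0, 1.0), "EM": (0.5, 0.5)}


def reference_fixture() -> tuple[GenotypeMatrix, list[AccessionRecord], SimulationTruth]:
    """Deterministic 84 x 150 dataset matching the study's shape.

    Two differentiated source populations (mapped to maturation period, with
    the early-maturing accessions admixed 50/50), 150 loci over 15
    chromosomes with exactly 28 monomorphic, 10 high-missingness and 20
    low-MAF loci plus 1 clean locus flagged design-failed, six clone
    relations and nine pedigree hybrids.
    """
    metadata = load_packaged_metadata()
    names = tuple(rec.name for rec in metadata)
    q_fixed = tuple(_Q_BY_MATURATION[rec.maturation] for rec in metadata)

    # hybrids must sit at the tail of the accession list for simulate();
    # reorder so pedigree hybrids are last, then restore Table-4 order below.
    ped_names = [nm for nm in names if nm in _FIXTURE_PEDIGREE]
    others = [nm for nm in names if nm not in _FIXTURE_PEDIGREE]
    sim_order = others + ped_names
    order_q = {nm: q for nm, q in zip(names, q_fixed)}

    cfg = SimulationConfig(
        k_true=2,
        drift_f=0.3,
        n_accessions=84,
        n_loci=150,
        n_chromosomes=15,
        missing_rate=0.02,
        n_monomorphic=28,
        n_high_missing=10,
        n_low_maf=20,
        hybrid_specs=tuple(_FIXTURE_PEDIGREE[nm] for nm in ped_names),
        clone_specs=_FIXTURE_CLONES,
        seed=REFERENCE_SEED,
        accession_ids=tuple(sim_order),
        q_fixed=tuple(order_q[nm] for nm in sim_order),
    )
    matrix, _, truth = simulate(cfg)
    matrix = matrix.subset_accessions(list(names))
    row_of = {nm: i for i, nm in enumerate(sim_order)}
    truth.q_true = truth.q_true[[row_of[nm] for nm in names]]

    # flag one clean locus as design-failed (metadata-only defect)
    rng = np.random.default_rng(np.random.SeedSequence(REFERENCE_SEED).spawn(5)[4])
    clean_cols = [j for j, lab in enumerate(truth.defect_labels) if lab == CLEAN]
    failed = int(rng.choice(clean_cols))
    truth.design_failed_ids = [matrix.locus_ids[failed]]
    return matrix, metadata, truth
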