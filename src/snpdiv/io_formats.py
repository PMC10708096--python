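"""Readers and writers for every external representation the pipeline touches.

Covers a minimal VCF 4.x subset (CHROM/POS/REF/ALT/GT), two genotype-matrix
CSV dialects, the STRUCTURE two-row text format, Newick trees with branch
lengths, and the accession metadata table.

Conventions used throughout the package:

* allele 0 = REF, allele 1 = ALT; the "A/B" CSV dialect maps A -> 0, B -> 1;
* diploid calls are unordered, stored as alt-allele dosage (0, 1, 2);
* missing calls use the dedicated sentinel :data:`MISSING` (never an allele).
"""

from __future__ import annotations

import csv
import importlib.resources
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: Sentinel dosage value for a missing diploid call.
MISSING: int = -1

STATUS_VOCAB = frozenset({"old_cultivar", "modern_cultivar", "hybrid", "wild"})
ORIGIN_VOCAB = frozenset(
    {"GD", "GX", "FJ", "HN", "SC", "YN", "DX-GX", "BB-GX", "TW", "VN", "TL", "-"}
)
MATURATION_VOCAB = frozenset({"EEM", "EM", "MLM"})

_NUCLEOTIDES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


class ValidationError(ValueError):
    """Raised when parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpLocus:
    """One candidate biallelic SNP marker."""

    locus_id: str
    chromosome: str
    position: int  # 1-based bp
    ref_allele: str
    alt_allele: str
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"{self.locus_id}: position must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"{self.locus_id}: ref and alt alleles identical")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValidationError(f"{self.locus_id}: MAF {self.maf} outside [0, 0.5]")


@dataclass
class GenotypeMatrix:
    """Diploid calls for accessions x loci, coded as alt-allele dosage.

    ``dosage[i, j]`` is 0 ({0,0}), 1 ({0,1}), 2 ({1,1}) or :data:`MISSING`.
    ``loci`` optionally carries per-locus metadata aligned with ``locus_ids``
    (CSV round-trips preserve calls and ordering, not positions).
    """

    accession_ids: list[str]
    locus_ids: list[str]
    dosage: np.ndarray
    loci: list[SnpLocus] | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, l = len(self.accession_ids), len(self.locus_ids)
        if self.dosage.shape != (n, l):
            raise ValidationError(
                f"dosage grid {self.dosage.shape} != ({n} accessions, {l} loci)"
            )
        if len(set(self.accession_ids)) != n:
            raise ValidationError("accession ids not unique")
        if len(set(self.locus_ids)) != l:
            raise ValidationError("locus ids not unique")
        bad = ~np.isin(self.dosage, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValidationError("dosage values outside {-1, 0, 1, 2}")
        if self.loci is not None and [lc.locus_id for lc in self.loci] != self.locus_ids:
            raise ValidationError("loci metadata misaligned with locus_ids")

    # -- shape ------------------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    # -- per-locus summaries ----------------------------------------------
    def missing_fraction(self) -> np.ndarray:
        return (self.dosage == MISSING).mean(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Alt-allele frequency per locus over non-missing calls (NaN if none)."""
        present = self.dosage != MISSING
        n_obs = present.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(present, self.dosage, 0).sum(axis=0) / (2.0 * n_obs)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    # -- subsetting ---------------------------------------------------------
    def subset_loci(self, keep: Sequence[str]) -> "GenotypeMatrix":
        index = {lid: j for j, lid in enumerate(self.locus_ids)}
        cols = [index[lid] for lid in keep]
        return GenotypeMatrix(
            accession_ids=list(self.accession_ids),
            locus_ids=list(keep),
            dosage=self.dosage[:, cols].copy(),
            loci=None if self.loci is None else [self.loci[j] for j in cols],
        )

    def subset_accessions(self, keep: Sequence[str]) -> "GenotypeMatrix":
        index = {aid: i for i, aid in enumerate(self.accession_ids)}
        rows = [index[aid] for aid in keep]
        return GenotypeMatrix(
            accession_ids=list(keep),
            locus_ids=list(self.locus_ids),
            dosage=self.dosage[rows, :].copy(),
            loci=None if self.loci is None else list(self.loci),
        )


@dataclass(frozen=True)
class AccessionRecord:
    """Accession metadata row: name, status, geographic origin, maturation."""

    name: str
    status: str
    origin: str
    maturation: str

    def __post_init__(self) -> None:
        if self.status not in STATUS_VOCAB:
            raise ValidationError(f"{self.name}: unknown status {self.status!r}")
        if self.maturation not in MATURATION_VOCAB:
            raise ValidationError(f"{self.name}: unknown maturation {self.maturation!r}")


# ---------------------------------------------------------------------------
# VCF (subset)
# ---------------------------------------------------------------------------


@dataclass
class VcfData:
    """Result of :func:`read_vcf`: loci in file order plus the call grid."""

    loci: list[SnpLocus]
    sample_ids: list[str]
    dosage: np.ndarray  # samples x loci, MISSING for ./.
    n_skipped: int
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def records(self) -> list[tuple[SnpLocus, np.ndarray]]:
        return [(loc, self.dosage[:, j]) for j, loc in enumerate(self.loci)]

    def to_genotype_matrix(self) -> GenotypeMatrix:
        return GenotypeMatrix(
            accession_ids=list(self.sample_ids),
            locus_ids=[loc.locus_id for loc in self.loci],
            dosage=self.dosage.copy(),
            loci=list(self.loci),
        )


_CONTIG_RE = re.compile(r"##contig=<(?P<body>.*)>")


def read_vcf(path: str | Path, biallelic_snps_only: bool = True) -> VcfData:
    """Parse a plain-text VCF (CHROM/POS/REF/ALT/GT subset).

    ``/`` and ``|`` genotype separators are treated identically (phase is
    discarded); ``./.`` maps to :data:`MISSING`. With ``biallelic_snps_only``
    set, multi-allelic records and non-SNPs are skipped and counted.
    """
    path = Path(path)
    contig_lengths: dict[str, int] = {}
    sample_ids: list[str] = []
    loci: list[SnpLocus] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    saw_column_header = False

    with path.open() as fh:
        first = fh.readline()
        if not first.startswith("##fileformat=VCF"):
            raise FormatError(f"{path}: missing ##fileformat=VCF header")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                m = _CONTIG_RE.match(line)
                if m:
                    fields = dict(
                        kv.split("=", 1) for kv in m.group("body").split(",") if "=" in kv
                    )
                    if "ID" in fields and "length" in fields:
                        contig_lengths[fields["ID"]] = int(fields["length"])
                continue
            if line.startswith("#CHROM"):
                header = line.lstrip("#").split("\t")
                if header[:8] != ["CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]:
                    raise FormatError(f"{path}:{lineno}: malformed #CHROM header line")
                sample_ids = header[9:]
                saw_column_header = True
                continue
            if not saw_column_header:
                raise FormatError(f"{path}:{lineno}: data before #CHROM header line")
            parts = line.split("\t")
            if len(parts) < 8 + (2 if sample_ids else 0):
                raise FormatError(f"{path}:{lineno}: too few columns")
            chrom, pos, vid, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            alts = alt.split(",")
            is_snp = len(ref) == 1 and all(len(a) == 1 and a != "." for a in alts)
            if biallelic_snps_only and (len(alts) != 1 or not is_snp):
                n_skipped += 1
                continue
            n_alleles = 1 + len(alts)
            col = np.full(len(sample_ids), MISSING, dtype=np.int8)
            if sample_ids:
                fmt = parts[8].split(":")
                try:
                    gt_idx = fmt.index("GT")
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: FORMAT lacks GT") from None
                for s, cell in enumerate(parts[9:]):
                    gt = cell.split(":")[gt_idx]
                    alleles = re.split(r"[/|]", gt)
                    if len(alleles) != 2:
                        raise FormatError(
                            f"{path}:{lineno}: sample {sample_ids[s]}: non-diploid GT {gt!r}"
                        )
                    if "." in alleles:
                        continue
                    a, b = int(alleles[0]), int(alleles[1])
                    if not (0 <= a < n_alleles and 0 <= b < n_alleles):
                        raise FormatError(
                            f"{path}:{lineno}: GT allele index out of range in {gt!r}"
                        )
                    col[s] = a + b
            locus_id = vid if vid not in (".", "") else f"{chrom}_{pos}"
            obs = col[col != MISSING]
            maf = None
            if obs.size:
                p = float(obs.mean() / 2.0)
                maf = min(p, 1.0 - p)
            loci.append(
                SnpLocus(
                    locus_id=locus_id,
                    chromosome=chrom,
                    position=int(pos),
                    ref_allele=ref,
                    alt_allele=alts[0],
                    maf=maf,
                )
            )
            columns.append(col)
    if not saw_column_header:
        raise FormatError(f"{path}: no #CHROM header line")
    dosage = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((len(sample_ids), 0), dtype=np.int8)
    )
    return VcfData(loci, sample_ids, dosage, n_skipped, contig_lengths)


_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    g: GenotypeMatrix,
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write a minimal VCF 4.2 text file; requires per-locus metadata."""
    if g.loci is None:
        raise ValidationError("GenotypeMatrix lacks locus metadata (chrom/pos/alleles)")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=snpdiv\n")
        for contig, length in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.accession_ids)
            + "\n"
        )
        order = sorted(
            range(g.n_loci), key=lambda j: (g.loci[j].chromosome, g.loci[j].position)
        )
        for j in order:
            loc = g.loci[j]
            cells = "\t".join(_DOSAGE_TO_GT[int(d)] for d in g.dosage[:, j])
            fh.write(
                f"{loc.chromosome}\t{loc.position}\t{loc.locus_id}\t"
                f"{loc.ref_allele}\t{loc.alt_allele}\t.\t.\t.\tGT\t{cells}\n"
            )


# ---------------------------------------------------------------------------
# genotype CSV (two dialects, auto-detected per file)
# ---------------------------------------------------------------------------

_AB_CODES = {"AA": 0, "AB": 1, "BB": 2, "NA": MISSING}
_GT_CODES = {"0/0": 0, "0/1": 1, "1/1": 2, "./.": MISSING}


def read_genotype_csv(path: str | Path) -> GenotypeMatrix:
    """Read an accessions x loci genotype CSV.

    Header row = locus ids, first column = accession id. Cells must all use
    one dialect: {AA, AB, BB, NA} or {0/0, 0/1, 1/1, ./.}.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    locus_ids = header[1:]
    data = rows[1:]
    if not data:
        raise FormatError(f"{path}: empty data section")
    width = len(header)
    cells: set[str] = set()
    for i, row in enumerate(data, start=2):
        if len(row) != width:
            raise FormatError(f"{path}: row {i} has {len(row)} fields, expected {width}")
        cells.update(row[1:])
    in_ab = cells <= set(_AB_CODES)
    in_gt = cells <= set(_GT_CODES)
    if not (in_ab or in_gt):
        if cells & set(_AB_CODES) and cells & set(_GT_CODES):
            raise FormatError(f"{path}: mixed genotype dialects in one file")
        bad = sorted(cells - set(_AB_CODES) - set(_GT_CODES))
        raise FormatError(f"{path}: unrecognised genotype cells {bad[:5]}")
    codes = _AB_CODES if in_ab else _GT_CODES
    accession_ids = [row[0] for row in data]
    dosage = np.array([[codes[c] for c in row[1:]] for row in data], dtype=np.int8)
    return GenotypeMatrix(accession_ids, locus_ids, dosage)


def write_genotype_csv(g: GenotypeMatrix, path: str | Path, dialect: str = "AB") -> None:
    if dialect == "AB":
        rev = {0: "AA", 1: "AB", 2: "BB", MISSING: "NA"}
    elif dialect == "GT":
        rev = dict(_DOSAGE_TO_GT)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["accession"] + g.locus_ids)
        for i, aid in enumerate(g.accession_ids):
            w.writerow([aid] + [rev[int(d)] for d in g.dosage[i]])


# ---------------------------------------------------------------------------
# STRUCTURE two-row format
# ---------------------------------------------------------------------------

_STRUCTURE_ALLELES = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (-9, -9)}


def write_structure_format(g: GenotypeMatrix, path: str | Path) -> None:
    """Two rows per individual, alleles 0/1 (sorted), -9 missing."""
    with Path(path).open("w") as fh:
        fh.write("\t".join(g.locus_ids) + "\n")
        for i, aid in enumerate(g.accession_ids):
            pairs = [_STRUCTURE_ALLELES[int(d)] for d in g.dosage[i]]
            for copy in (0, 1):
                fh.write(aid + "\t" + "\t".join(str(p[copy]) for p in pairs) + "\n")


def read_structure_format(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    locus_ids = lines[0].split("\t")
    body = [ln.split("\t") for ln in lines[1:]]
    if len(body) % 2:
        raise FormatError(f"{path}: odd number of allele rows")
    accession_ids: list[str] = []
    dosage_rows: list[list[int]] = []
    for r in range(0, len(body), 2):
        row_a, row_b = body[r], body[r + 1]
        if row_a[0] != row_b[0]:
            raise FormatError(f"{path}: unpaired individual rows at line {r + 2}")
        if len(row_a) != len(locus_ids) + 1 or len(row_b) != len(locus_ids) + 1:
            raise FormatError(f"{path}: ragged row for {row_a[0]}")
        accession_ids.append(row_a[0])
        dos: list[int] = []
        for a_str, b_str in zip(row_a[1:], row_b[1:]):
            a, b = int(a_str), int(b_str)
            if a == -9 or b == -9:
                dos.append(MISSING)
            elif a in (0, 1) and b in (0, 1):
                dos.append(a + b)
            else:
                raise FormatError(f"{path}: bad allele code {a_str}/{b_str}")
        dosage_rows.append(dos)
    return GenotypeMatrix(accession_ids, locus_ids, np.array(dosage_rows, dtype=np.int8))


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

_PLAIN_LABEL_RE = re.compile(r"^[A-Za-z0-9_.|-]+$")


def _newick_label(name: str) -> str:
    if _PLAIN_LABEL_RE.match(name):
        return name
    return "'" + name.replace("'", "''") + "'"


def _newick_node(node) -> str:
    if not node.children:
        if not node.name:
            raise ValidationError("unlabeled leaf in tree")
        body = _newick_label(node.name)
    else:
        body = "(" + ",".join(_newick_node(c) for c in node.children) + ")"
    if node.length is not None:
        body += f":{node.length:.12g}"
    return body


def write_newick(tree, path: str | Path) -> None:
    """Serialize a rooted tree (duck-typed: .children/.name/.length) to Newick."""
    text = newick_string(tree)
    Path(path).write_text(text)


def newick_string(tree) -> str:
    if not tree.children:
        if not tree.name:
            raise ValidationError("unlabeled leaf in tree")
        return _newick_label(tree.name) + ";\n"
    return "(" + ",".join(_newick_node(c) for c in tree.children) + ");\n"


# ---------------------------------------------------------------------------
# accession metadata
# ---------------------------------------------------------------------------


def read_metadata(path: str | Path) -> list[AccessionRecord]:
    """Read an accession metadata CSV (name,status,origin,maturation)."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"name", "status", "origin", "maturation"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(f"{path}: header must contain {sorted(required)}")
        records: list[AccessionRecord] = []
        for i, row in enumerate(reader, start=2):
            try:
                records.append(
                    AccessionRecord(
                        name=row["name"],
                        status=row["status"],
                        origin=row["origin"],
                        maturation=row["maturation"],
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: row {i}: {exc}") from None
    return records


def packaged_metadata_path() -> Path:
    """Path of the packaged 84-accession metadata table."""
    return Path(importlib.resources.files("snpdiv.data") / "accessions.csv")


def load_packaged_metadata() -> list[AccessionRecord]:
    return read_metadata(packaged_metadata_path())
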