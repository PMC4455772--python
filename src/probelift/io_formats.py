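"""Readers and writers for the external table and sequence formats.

Five input formats (probe manifest CSV, genome FASTA, per-CpG bisulfite
count TSV, beta-value matrix CSV, ortholog gene-name map TSV) plus the
probe-annotation output CSV and an optional gene BED.

Coordinate convention: every on-disk format is 1-based inclusive on the
+ strand; alignment-layer coordinates are 0-based half-open.  Records read
here keep the on-disk (1-based) positions; the conversion happens exactly
where genomic arithmetic starts (projection and joining).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROBE_LEN = 50
_VALID_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ProbeRecord:
    """One array probe: 50-mer body sequence plus its assayed-CpG anchor.

    ``cpg_pos`` is the 1-based + strand coordinate of the C of the assayed
    CpG in the *design* (human) genome, as manifests state it; it is
    metadata and plays no role in cross-species mapping.
    """

    probe_id: str
    probe_seq: str
    chrom: str
    cpg_pos: int
    strand: str
    probe_type: str  # "I" or "II"
    gene_names: list[str] = field(default_factory=list)
    polymorphic_flag: bool = False

    def validate(self) -> None:
        if len(self.probe_seq) != PROBE_LEN:
            raise FormatError(
                f"probe {self.probe_id}: sequence length {len(self.probe_seq)} != {PROBE_LEN}"
            )
        if not set(self.probe_seq) <= _VALID_BASES:
            bad = sorted(set(self.probe_seq) - _VALID_BASES)
            raise FormatError(f"probe {self.probe_id}: invalid bases {bad}")
        if self.strand not in ("+", "-"):
            raise FormatError(f"probe {self.probe_id}: bad strand {self.strand!r}")
        if self.probe_type not in ("I", "II"):
            raise FormatError(f"probe {self.probe_id}: bad probe_type {self.probe_type!r}")
        if self.cpg_pos < 1:
            raise FormatError(f"probe {self.probe_id}: cpg_pos must be >= 1")


@dataclass
class GenomeSequence:
    """Target genome as an ordered contig-name -> upper-case sequence map."""

    contigs: dict[str, str]

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def fetch(self, contig: str, start: int, end: int) -> str:
        """0-based half-open slice of a contig (clipped to the contig)."""
        seq = self.contigs[contig]
        return seq[max(0, start):max(0, end)]


@dataclass
class MethylationCall:
    """Per-CpG bisulfite counts; ``pos`` is the 1-based + strand C."""

    chrom: str
    pos: int
    meth_count: int
    total_count: int

    @property
    def ratio(self) -> float:
        return self.meth_count / self.total_count if self.total_count > 0 else math.nan


@dataclass
class BetaMatrix:
    """Array beta values (probe x sample), optional detection p-values.

    ``beta`` and ``detection_p`` are DataFrames indexed by probe_id with
    sample_id columns; missing betas are NaN.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)

    def validate(self) -> None:
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise FormatError("beta values outside [0, 1]")
        if self.detection_p is not None:
            if list(self.detection_p.index) != self.probe_ids or list(
                self.detection_p.columns
            ) != self.sample_ids:
                raise FormatError("detection_p matrix shape/labels differ from beta")


# ---------------------------------------------------------------------------
# probe manifest


def read_manifest(path) -> list[ProbeRecord]:
    """Read a manifest CSV into validated ProbeRecords.

    Gene annotations are ';'-separated; duplicates are dropped with order
    preserved.  Duplicate probe IDs and malformed sequences are hard errors.
    """
    records: list[ProbeRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"probe_id", "probe_seq", "chrom", "cpg_pos", "strand", "probe_type"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            missing = required - set(reader.fieldnames or [])
            raise FormatError(f"manifest missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            pid = row["probe_id"]
            if pid in seen:
                raise FormatError(f"duplicate probe_id {pid!r} (row {i})")
            seen.add(pid)
            genes: list[str] = []
            for g in (row.get("gene_names") or "").split(";"):
                g = g.strip()
                if g and g not in genes:
                    genes.append(g)
            rec = ProbeRecord(
                probe_id=pid,
                probe_seq=row["probe_seq"].strip().upper(),
                chrom=row["chrom"],
                cpg_pos=int(row["cpg_pos"]),
                strand=row["strand"],
                probe_type=row["probe_type"].strip(),
                gene_names=genes,
                polymorphic_flag=_parse_bool(row.get("polymorphic_flag", "")),
            )
            try:
                rec.validate()
            except FormatError as exc:
                raise FormatError(f"row {i}: {exc}") from None
            records.append(rec)
    return records


def write_manifest(records: list[ProbeRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            [
                "probe_id",
                "probe_seq",
                "chrom",
                "cpg_pos",
                "strand",
                "probe_type",
                "gene_names",
                "polymorphic_flag",
            ]
        )
        for r in records:
            w.writerow(
                [
                    r.probe_id,
                    r.probe_seq,
                    r.chrom,
                    r.cpg_pos,
                    r.strand,
                    r.probe_type,
                    ";".join(r.gene_names),
                    int(r.polymorphic_flag),
                ]
            )


def _parse_bool(s: str) -> bool:
    return str(s).strip().lower() in ("1", "true", "t", "yes")


# ---------------------------------------------------------------------------
# genome FASTA


def read_genome(path) -> GenomeSequence:
    """Read a (multi-)FASTA genome, upper-casing bases.

    Ambiguity codes are preserved; the aligner scores any non-ACGT base as
    mismatching everything.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise FormatError(f"duplicate contig name {rec.id!r}")
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise FormatError(f"no sequences found in {path}")
    return GenomeSequence(contigs=contigs)


def write_genome(genome: GenomeSequence, path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.contigs.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# bisulfite methylation counts


def read_meth_table(path, min_coverage: int = 10) -> list[MethylationCall]:
    """Read a per-CpG count TSV, dropping rows with coverage < min_coverage.

    The coverage boundary is inclusive ("at least 10x" keeps exactly-10x
    rows).  Returned sorted by (chrom, pos).
    """
    calls: list[MethylationCall] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for i, row in enumerate(reader, start=2):
            meth = int(row["meth_count"])
            total = int(row["total_count"])
            if meth > total:
                raise FormatError(f"row {i}: meth_count {meth} > total_count {total}")
            if total < min_coverage:
                continue
            calls.append(
                MethylationCall(
                    chrom=row["chrom"], pos=int(row["pos"]), meth_count=meth, total_count=total
                )
            )
    calls.sort(key=lambda c: (c.chrom, c.pos))
    return calls


def write_meth_table(calls: list[MethylationCall], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["chrom", "pos", "meth_count", "total_count"])
        for c in calls:
            w.writerow([c.chrom, c.pos, c.meth_count, c.total_count])


# ---------------------------------------------------------------------------
# beta matrix


def read_beta_matrix(path, detection_path=None) -> BetaMatrix:
    """Read a probe x sample beta CSV (first column probe_id); empty cells
    are missing.  An optional parallel detection p-value CSV may accompany it."""
    beta = pd.read_csv(path, index_col=0)
    beta.index = beta.index.astype(str)
    det = None
    if detection_path is not None:
        det = pd.read_csv(detection_path, index_col=0)
        det.index = det.index.astype(str)
    bm = BetaMatrix(beta=beta, detection_p=det)
    bm.validate()
    return bm


def write_beta_matrix(bm: BetaMatrix, path, detection_path=None) -> None:
    bm.beta.to_csv(path, index_label="probe_id", float_format="%.6f")
    if detection_path is not None and bm.detection_p is not None:
        bm.detection_p.to_csv(detection_path, index_label="probe_id", float_format="%.6f")


# ---------------------------------------------------------------------------
# ortholog map / gene BED


def read_ortholog_map(path) -> dict[str, str]:
    """Two-column TSV: human gene name -> target-species gene name."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"ortholog map line {i}: expected 2 columns")
            mapping[parts[0]] = parts[1]
    return mapping


def write_ortholog_map(mapping: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for k, v in mapping.items():
            fh.write(f"{k}\t{v}\n")


def read_gene_bed(path) -> list[tuple[str, int, int, str]]:
    """BED4 gene intervals (chrom, 0-based start, end, name)."""
    rows: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"gene BED line {i}: expected 4 columns")
            rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
    return rows


def write_gene_bed(rows: list[tuple[str, int, int, str]], path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


# ---------------------------------------------------------------------------
# annotation output (File-S1-style deliverable)

ANNOTATION_COLUMNS = [
    "probe_id",
    "contig",
    "start",
    "end",
    "strand",
    "raw_score",
    "bitscore",
    "evalue",
    "percent_identity",
    "n_mismatch",
    "n_gaps",
    "cpg_present",
    "cpg_mismatch",
    "near_cpg_mismatch",
    "n_hits",
    "unique",
    "gene_match_class",
    "pass_bitscore",
    "pass_unique",
    "pass_mismatch",
    "pass_all",
    # extension columns (kept after the fixed set):
    "probe_type",
    "target_cpg_pos",
]

_FLOAT4 = ("bitscore", "percent_identity")
_BOOL_COLS = (
    "cpg_present",
    "cpg_mismatch",
    "near_cpg_mismatch",
    "unique",
    "pass_bitscore",
    "pass_unique",
    "pass_mismatch",
    "pass_all",
)


def write_annotation(records, path) -> None:
    """Write ProbeAnnotationRecords as the fixed-column annotation CSV.

    Unmapped probes carry empty alignment fields.  Floats are written with
    4 decimals (e-values in scientific notation to preserve magnitude);
    genomic positions are 1-based inclusive on disk.
    """
    if not records:
        raise FormatError("write_annotation: empty record list")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(ANNOTATION_COLUMNS)
        for r in records:
            w.writerow(_annotation_row(r))


def _annotation_row(r) -> list:
    mapped = r.n_hits > 0
    row = [
        r.probe_id,
        r.contig if mapped else "",
        (r.start + 1) if mapped else "",  # 1-based inclusive on disk
        r.end if mapped else "",
        r.strand if mapped else "",
        r.raw_score if mapped else "",
        f"{r.bitscore:.4f}" if mapped else "",
        f"{r.evalue:.4e}" if mapped else "",
        f"{r.percent_identity:.4f}" if mapped else "",
        r.n_mismatch if mapped else "",
        r.n_gaps if mapped else "",
        int(r.cpg_present),
        int(r.cpg_mismatch),
        int(r.near_cpg_mismatch),
        r.n_hits,
        int(r.unique),
        r.gene_match_class,
        int(r.pass_bitscore),
        int(r.pass_unique),
        int(r.pass_mismatch),
        int(r.pass_all),
        r.probe_type,
        (r.target_cpg_pos + 1) if (mapped and r.target_cpg_pos is not None) else "",
    ]
    return row


def read_annotation(path) -> pd.DataFrame:
    """Read the annotation CSV back into a typed DataFrame (internal 0-based
    coordinates restored)."""
    df = pd.read_csv(path, dtype={"probe_id": str, "contig": str})
    for col in _BOOL_COLS:
        df[col] = df[col].astype(bool)
    if "start" in df:
        df["start"] = df["start"] - 1  # back to 0-based half-open
    if "target_cpg_pos" in df:
        df["target_cpg_pos"] = df["target_cpg_pos"] - 1
    return df
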