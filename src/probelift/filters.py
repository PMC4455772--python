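"""Probe admissibility, the three-step retention filter, uniqueness, and
gene-name reconciliation.

The three-step filter retains a probe when (1) its best-hit bitscore
exceeds ``bitscore_min`` (strict, "bitscore > 70"), (2) it has exactly one
admissible alignment below the e-value threshold, and (3) it has no
mismatch at or adjacent to the assayed CpG.  Admissibility itself caps the
per-alignment divergence at up to four mismatches and up to two gap runs
of up to 4 bp each.

A "CM probe" (conserved-CpG mapped probe) is one that maps at all and whose
assayed CpG dinucleotide is intact in the target: mapped and cpg_present
and not cpg_mismatch.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import pandas as pd

from .alignment import Alignment, ScoringParams, align_probe
from .cpg_projection import classify_mismatches, locate_cpg
from .io_formats import GenomeSequence, ProbeRecord

_TOKEN_RE = re.compile(r"[^A-Za-z0-9]+")


@dataclass(frozen=True)
class FilterConfig:
    bitscore_min: float = 70.0
    require_unique: bool = True
    exclude_near_cpg: bool = True
    max_mismatches: int = 4
    max_gap_runs: int = 2
    max_gap_len: int = 4
    evalue_max: float = math.exp(-10)

    def __post_init__(self):
        if self.bitscore_min < 0:
            raise ValueError("bitscore_min must be >= 0")
        if min(self.max_mismatches, self.max_gap_runs, self.max_gap_len) < 0:
            raise ValueError("max_* fields must be >= 0")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")


@dataclass
class ProbeAnnotationRecord:
    """One output row of the probe annotation deliverable."""

    probe_id: str
    contig: str = ""
    start: int = -1
    end: int = -1
    strand: str = ""
    raw_score: int = 0
    bitscore: float = 0.0
    evalue: float = math.inf
    percent_identity: float = 0.0
    n_mismatch: int = 0
    n_gaps: int = 0
    cpg_present: bool = False
    cpg_mismatch: bool = False
    near_cpg_mismatch: bool = False
    mismatch_category: str = "cpg_absent"
    n_hits: int = 0
    unique: bool = False
    gene_match_class: str = "unannotated"
    pass_bitscore: bool = False
    pass_unique: bool = False
    pass_mismatch: bool = False
    pass_all: bool = False
    probe_type: str = ""
    target_cpg_pos: int | None = None  # 0-based + strand C of the projected CpG
    target_gene: str | None = None
    has_annotation: bool = False

    @property
    def mapped(self) -> bool:
        return self.n_hits > 0

    @property
    def is_cm_probe(self) -> bool:
        return self.mapped and self.cpg_present and not self.cpg_mismatch


# ---------------------------------------------------------------------------
# admissibility


def admit(alignments: list[Alignment], cfg: FilterConfig | None = None) -> list[Alignment]:
    """Keep alignments within the divergence caps (inclusive boundaries)."""
    cfg = cfg or FilterConfig()
    return [
        a
        for a in alignments
        if a.n_mismatch <= cfg.max_mismatches
        and a.n_gaps <= cfg.max_gap_runs
        and all(g <= cfg.max_gap_len for g in a.gap_lengths)
        and a.evalue < cfg.evalue_max
    ]


# ---------------------------------------------------------------------------
# three-step filter


def three_step_filter(
    record: ProbeAnnotationRecord, cfg: FilterConfig | None = None
) -> ProbeAnnotationRecord:
    """Set the sequential pass flags on a record (flags only; nothing else
    is mutated).  An unmapped record fails every step."""
    cfg = cfg or FilterConfig()
    if record.mapped and record.mismatch_category is None:
        raise ValueError(f"record {record.probe_id} lacks a mismatch annotation")
    if not record.mapped:
        return replace(
            record, pass_bitscore=False, pass_unique=False, pass_mismatch=False, pass_all=False
        )
    pass_bitscore = record.bitscore > cfg.bitscore_min  # strict, per ">70"
    pass_unique = record.unique if cfg.require_unique else True
    if cfg.exclude_near_cpg:
        pass_mismatch = record.mismatch_category == "clean"
    else:
        pass_mismatch = record.mismatch_category not in ("at_cpg", "cpg_absent")
    return replace(
        record,
        pass_bitscore=pass_bitscore,
        pass_unique=pass_unique,
        pass_mismatch=pass_mismatch,
        pass_all=pass_bitscore and pass_unique and pass_mismatch,
    )


# ---------------------------------------------------------------------------
# gene-name reconciliation


def _tokens(name: str) -> set[str]:
    return {t.lower() for t in _TOKEN_RE.split(name) if t}


def match_gene(
    probe_genes: list[str],
    target_gene: str | None,
    ortholog_map: dict[str, str] | None = None,
) -> str:
    """Classify the probe-gene vs target-gene relationship.

    Precedence: exact > ortholog > partial > none; probes without any human
    gene annotation are 'unannotated'.  Comparison is case-insensitive;
    'partial' means the two names share a token after splitting on
    non-alphanumeric characters.
    """
    if not probe_genes:
        return "unannotated"
    if target_gene is None or target_gene == "":
        return "none"
    ortholog_map = ortholog_map or {}
    tgt = target_gene.lower()
    if any(g.lower() == tgt for g in probe_genes):
        return "exact"
    lower_map = {k.lower(): v.lower() for k, v in ortholog_map.items()}
    if any(lower_map.get(g.lower()) == tgt for g in probe_genes):
        return "ortholog"
    tgt_tokens = _tokens(target_gene)
    if any(_tokens(g) & tgt_tokens for g in probe_genes):
        return "partial"
    return "none"


def nearest_gene(
    contig: str, pos: int, gene_bed: list[tuple[str, int, int, str]]
) -> str | None:
    """Gene whose interval is closest to ``pos`` (0 if inside); ties go to
    the alphabetically first name.  None when no gene is on the contig."""
    best: tuple[int, str] | None = None
    for chrom, start, end, name in gene_bed:
        if chrom != contig:
            continue
        if start <= pos < end:
            dist = 0
        elif pos < start:
            dist = start - pos
        else:
            dist = pos - end + 1
        if best is None or (dist, name) < best:
            best = (dist, name)
    return best[1] if best else None


# ---------------------------------------------------------------------------
# end-to-end per-probe annotation


def annotate_probe_set(
    probes: list[ProbeRecord],
    genome: GenomeSequence,
    cfg: FilterConfig | None = None,
    ortholog_map: dict[str, str] | None = None,
    gene_bed: list[tuple[str, int, int, str]] | None = None,
    scoring: ScoringParams | None = None,
    progress=None,
) -> list[ProbeAnnotationRecord]:
    """Full pipeline per probe: align -> admit -> uniqueness -> best hit ->
    CpG projection/classification -> nearest-gene match -> three-step
    filter.  Probes with no admissible hit get n_hits 0 and all-false
    pass flags."""
    cfg = cfg or FilterConfig()
    scoring = scoring or ScoringParams(evalue_max=cfg.evalue_max)
    records: list[ProbeAnnotationRecord] = []
    for i, probe in enumerate(probes):
        records.append(
            _annotate_one(probe, genome, cfg, ortholog_map, gene_bed, scoring)
        )
        if progress is not None and (i + 1) % 1000 == 0:
            progress(i + 1)
    return records


def _annotate_one(
    probe: ProbeRecord,
    genome: GenomeSequence,
    cfg: FilterConfig,
    ortholog_map,
    gene_bed,
    scoring: ScoringParams,
) -> ProbeAnnotationRecord:
    hits = admit(align_probe(probe, genome, scoring), cfg)
    base = ProbeAnnotationRecord(
        probe_id=probe.probe_id,
        probe_type=probe.probe_type,
        has_annotation=bool(probe.gene_names),
    )
    if not hits:
        base.gene_match_class = match_gene(probe.gene_names, None, ortholog_map)
        return three_step_filter(base, cfg)
    best = hits[0]
    anchor = locate_cpg(probe)
    ann = classify_mismatches(best, anchor, genome)
    target_cpg = ann.target_interval[0] if ann.target_interval else None
    target_gene = None
    if gene_bed is not None and target_cpg is not None:
        target_gene = nearest_gene(best.contig, target_cpg, gene_bed)
    elif gene_bed is not None:
        target_gene = nearest_gene(best.contig, best.start, gene_bed)
    rec = replace(
        base,
        contig=best.contig,
        start=best.start,
        end=best.end,
        strand=best.strand,
        raw_score=best.raw_score,
        bitscore=best.bitscore,
        evalue=best.evalue,
        percent_identity=best.percent_identity,
        n_mismatch=best.n_mismatch,
        n_gaps=best.n_gaps,
        cpg_present=ann.cpg_present,
        cpg_mismatch=ann.cpg_mismatch,
        near_cpg_mismatch=ann.near_cpg_mismatch,
        mismatch_category=ann.category,
        n_hits=len(hits),
        unique=len(hits) == 1,
        gene_match_class=match_gene(probe.gene_names, target_gene, ortholog_map),
        target_cpg_pos=target_cpg,
        target_gene=target_gene,
    )
    return three_step_filter(rec, cfg)


# ---------------------------------------------------------------------------
# cohort bookkeeping


def summarize_annotation(records: list[ProbeAnnotationRecord]) -> dict:
    """Cohort-level bookkeeping: mapping rate, CpG-mismatch rate, the CM
    probe count (mapped minus CpG-compromised), uniqueness and gene-match
    rates among CM probes, and the sequential three-step pass counts."""
    n = len(records)
    mapped = [r for r in records if r.mapped]
    cpg_bad = [r for r in mapped if r.cpg_mismatch or not r.cpg_present]
    cm = [r for r in mapped if r.is_cm_probe]
    cm_unique = [r for r in cm if r.unique]
    cm_annotated = [r for r in cm if r.has_annotation]
    cm_gene_match = [
        r for r in cm_annotated if r.gene_match_class in ("exact", "partial", "ortholog")
    ]
    after_bitscore = [r for r in records if r.pass_bitscore]
    after_unique = [r for r in after_bitscore if r.pass_unique]
    after_mismatch = [r for r in after_unique if r.pass_mismatch]
    return {
        "n_probes": n,
        "n_mapped": len(mapped),
        "mapped_pct": _pct(len(mapped), n),
        "n_cpg_mismatch_or_absent": len(cpg_bad),
        "cpg_mismatch_pct": _pct(len(cpg_bad), len(mapped)),
        "n_cm": len(cm),
        "cm_pct": _pct(len(cm), n),
        "unique_pct_of_cm": _pct(len(cm_unique), len(cm)),
        "n_cm_annotated": len(cm_annotated),
        "gene_match_pct": _pct(len(cm_gene_match), len(cm_annotated)),
        "n_after_bitscore": len(after_bitscore),
        "n_after_unique": len(after_unique),
        "n_after_mismatch": len(after_mismatch),
        "n_pass_all": sum(r.pass_all for r in records),
        "coverage_pct": _pct(len(after_mismatch), n),
    }


def cm_probe_count(n_mapped: int, n_cpg_mismatch: int) -> int:
    """CM probes = mapped probes minus those with a compromised CpG."""
    return n_mapped - n_cpg_mismatch


def _pct(k: int, n: int) -> float:
    return 100.0 * k / n if n else math.nan


def frame_to_records(df: pd.DataFrame) -> list[ProbeAnnotationRecord]:
    """Rebuild annotation records from a previously written annotation CSV
    (as loaded by io_formats.read_annotation)."""
    records = []
    for row in df.itertuples(index=False):
        n_hits = int(row.n_hits)
        mapped = n_hits > 0
        if row.cpg_mismatch:
            category = "at_cpg"
        elif not row.cpg_present:
            category = "cpg_absent"
        elif row.near_cpg_mismatch:
            category = "near_cpg"
        else:
            category = "clean"
        records.append(
            ProbeAnnotationRecord(
                probe_id=str(row.probe_id),
                contig=str(row.contig) if mapped else "",
                start=int(row.start) if mapped else -1,
                end=int(row.end) if mapped else -1,
                strand=str(row.strand) if mapped else "",
                raw_score=int(row.raw_score) if mapped else 0,
                bitscore=float(row.bitscore) if mapped else 0.0,
                evalue=float(row.evalue) if mapped else math.inf,
                percent_identity=float(row.percent_identity) if mapped else 0.0,
                n_mismatch=int(row.n_mismatch) if mapped else 0,
                n_gaps=int(row.n_gaps) if mapped else 0,
                cpg_present=bool(row.cpg_present),
                cpg_mismatch=bool(row.cpg_mismatch),
                near_cpg_mismatch=bool(row.near_cpg_mismatch),
                mismatch_category=category,
                n_hits=n_hits,
                unique=bool(row.unique),
                gene_match_class=str(row.gene_match_class),
                pass_bitscore=bool(row.pass_bitscore),
                pass_unique=bool(row.pass_unique),
                pass_mismatch=bool(row.pass_mismatch),
                pass_all=bool(row.pass_all),
                probe_type=str(row.probe_type),
                target_cpg_pos=(
                    int(row.target_cpg_pos)
                    if mapped and pd.notna(row.target_cpg_pos)
                    else None
                ),
            )
        )
    return records


def records_to_frame(records: list[ProbeAnnotationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = dict(r.__dict__)
        d["mapped"] = r.mapped
        d["is_cm_probe"] = r.is_cm_probe
        rows.append(d)
    return pd.DataFrame(rows)


__all__ = [
    "FilterConfig",
    "ProbeAnnotationRecord",
    "admit",
    "three_step_filter",
    "match_gene",
    "nearest_gene",
    "annotate_probe_set",
    "summarize_annotation",
    "cm_probe_count",
    "records_to_frame",
]
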