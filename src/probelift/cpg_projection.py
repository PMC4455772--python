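"""Locate the assayed CpG of each probe, project it through a gapped
alignment into the target genome, and classify mismatches by their signed
distance from the CpG.

Anchor convention (Infinium chemistry, 3'-anchored): a type I probe's 3'
terminus covers the C of the assayed CpG (design offset 49 within the
50-mer); for a type II probe the CpG is the dinucleotide immediately 3' of
the probe on its design strand.  Signed mismatch offsets are measured in
design-strand coordinates from the CpG C: offset 0 is the C itself, +1 the
G, negative offsets lie 5' of the CpG.  "Near-CpG" means the two bases
flanking the CG dinucleotide, offsets -1 and +2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment import Alignment
from .io_formats import GenomeSequence, ProbeRecord, PROBE_LEN

OUTSIDE_3PRIME = "OUTSIDE_3PRIME"

#: design-strand offsets (relative to the CpG C) counted as "near" the CpG
NEAR_OFFSETS = (-1, 2)

_GAP = object()  # marker: probe base aligned into a target gap


@dataclass(frozen=True)
class CpgAnchor:
    """Position of the assayed CpG C in probe coordinates (0..49) or the
    OUTSIDE_3PRIME sentinel for type II probes."""

    probe_offset: int | str
    derivation: str

    @property
    def design_c_pos(self) -> int:
        """Design-strand position of the CpG C (may be PROBE_LEN when the
        CpG lies immediately 3' of the probe)."""
        if self.probe_offset == OUTSIDE_3PRIME:
            return PROBE_LEN
        return int(self.probe_offset)


@dataclass
class MismatchAnnotation:
    """Per-alignment CpG conservation status and mismatch geometry."""

    cpg_present: bool
    cpg_mismatch: bool
    near_cpg_mismatch: bool
    mismatch_offsets: list[int] = field(default_factory=list)
    n_gaps_overlapping_cpg: int = 0
    category: str = "cpg_absent"  # clean | near_cpg | at_cpg | cpg_absent
    target_interval: tuple[int, int] | None = None  # projected CG, 0-based half-open


def locate_cpg(probe: ProbeRecord) -> CpgAnchor:
    """Anchor the assayed CpG in probe coordinates from the chemistry type."""
    if probe.probe_type == "I":
        return CpgAnchor(probe_offset=PROBE_LEN - 1, derivation="type_I_terminal")
    if probe.probe_type == "II":
        return CpgAnchor(probe_offset=OUTSIDE_3PRIME, derivation="type_II_adjacent")
    raise ValueError(f"unknown probe_type {probe.probe_type!r} for {probe.probe_id}")


# ---------------------------------------------------------------------------
# coordinate walking


def _column_map(aln: Alignment) -> dict[int, object]:
    """Oriented-probe position -> genome + strand position (or _GAP when the
    probe base falls in a target insertion)."""
    mapping: dict[int, object] = {}
    q, s = aln.qstart, aln.start
    for a, b in zip(aln.probe_aln, aln.subject_aln):
        if a != "-" and b != "-":
            mapping[q] = s
            q += 1
            s += 1
        elif a == "-":  # deletion in probe: genome base consumed
            s += 1
        else:  # insertion in probe: no genome base under this probe position
            mapping[q] = _GAP
            q += 1
    return mapping


def _design_to_oriented(p: int, strand: str) -> int:
    return p if strand == "+" else PROBE_LEN - 1 - p


def _map_oriented(q: int, aln: Alignment, colmap: dict[int, object]):
    """Genome position of oriented-probe position q, extrapolating linearly
    beyond the aligned extent; _GAP when inside a target insertion."""
    if q < aln.qstart:
        return aln.start - (aln.qstart - q)
    if q >= aln.qend:
        return aln.end + (q - aln.qend)
    return colmap.get(q, _GAP)


def project_cpg(
    aln: Alignment, anchor: CpgAnchor, genome: GenomeSequence | None = None
) -> tuple[int, int] | None:
    """Project the assayed CpG dinucleotide into + strand target coordinates.

    Returns the 0-based half-open 2-bp interval on the alignment's contig,
    or None when either base lands in a target gap, the two bases are not
    adjacent in the target, or the interval runs off the contig.
    """
    colmap = _column_map(aln)
    p_c = anchor.design_c_pos
    g_c = _map_oriented(_design_to_oriented(p_c, aln.strand), aln, colmap)
    g_g = _map_oriented(_design_to_oriented(p_c + 1, aln.strand), aln, colmap)
    if g_c is _GAP or g_g is _GAP:
        return None
    lo, hi = (g_c, g_g) if g_c < g_g else (g_g, g_c)
    if hi - lo != 1:
        return None  # CpG interrupted by an indel in the target
    if lo < 0:
        return None
    if genome is not None and hi + 1 > len(genome.contigs[aln.contig]):
        return None
    return (lo, hi + 1)


# ---------------------------------------------------------------------------
# mismatch classification


def classify_mismatches(
    aln: Alignment,
    anchor: CpgAnchor,
    genome: GenomeSequence,
    near_offsets: tuple[int, ...] = NEAR_OFFSETS,
) -> MismatchAnnotation:
    """Classify every mismatch of an alignment by signed offset from the
    CpG C and derive the probe's CpG conservation category.

    Categories: ``at_cpg`` — a probe-covered CpG base mismatches or is
    gapped; ``cpg_absent`` — the projected target dinucleotide is not CG
    (or the projection fails) without such a covered mismatch; ``near_cpg``
    — a mismatch at a flanking offset; ``clean`` — none of the above.
    """
    p_c = anchor.design_c_pos
    offsets: list[int] = []
    # Local alignment trims terminal mismatches; mismatch localisation must
    # still see them, so probe flanks outside the aligned extent are
    # compared to the genome by ungapped extrapolation (end-to-end style).
    if aln.query_seq:
        contig_seq = genome.contigs[aln.contig]
        for q_out in list(range(0, aln.qstart)) + list(
            range(aln.qend, len(aln.query_seq))
        ):
            if q_out < aln.qstart:
                g = aln.start - (aln.qstart - q_out)
            else:
                g = aln.end + (q_out - aln.qend)
            base = aln.query_seq[q_out]
            gbase = contig_seq[g] if 0 <= g < len(contig_seq) else None
            if gbase is None or gbase != base or base not in "ACGT":
                offsets.append(_oriented_to_design(q_out, aln.strand) - p_c)
    # walk columns, assigning each mismatch / gap column a design offset
    q = aln.qstart
    for a, b in zip(aln.probe_aln, aln.subject_aln):
        if a != "-" and b != "-":
            if a != b or a not in "ACGT" or b not in "ACGT":
                p = _oriented_to_design(q, aln.strand)
                offsets.append(p - p_c)
            q += 1
        elif a == "-":
            # target insertion between probe positions q-1 and q: charge the
            # boundary probe position
            p = _oriented_to_design(q, aln.strand)
            offsets.append(p - p_c)
        else:
            p = _oriented_to_design(q, aln.strand)
            offsets.append(p - p_c)
            q += 1
    offsets.sort()

    cpg_mismatch = any(o in (0, 1) for o in offsets)
    n_gap_cpg = _count_gap_columns_at_cpg(aln, p_c)
    near = any(o in near_offsets for o in offsets)

    interval = project_cpg(aln, anchor, genome)
    if interval is None:
        cpg_present = False
    else:
        lo, hi = interval
        cpg_present = genome.fetch(aln.contig, lo, hi) == "CG"

    if cpg_mismatch:
        category = "at_cpg"
    elif not cpg_present:
        category = "cpg_absent"
    elif near:
        category = "near_cpg"
    else:
        category = "clean"
    return MismatchAnnotation(
        cpg_present=cpg_present,
        cpg_mismatch=cpg_mismatch,
        near_cpg_mismatch=near,
        mismatch_offsets=offsets,
        n_gaps_overlapping_cpg=n_gap_cpg,
        category=category,
        target_interval=interval,
    )


def _oriented_to_design(q: int, strand: str) -> int:
    return q if strand == "+" else PROBE_LEN - 1 - q


def _count_gap_columns_at_cpg(aln: Alignment, p_c: int) -> int:
    count = 0
    q = aln.qstart
    for a, b in zip(aln.probe_aln, aln.subject_aln):
        if a == "-" or b == "-":
            p = _oriented_to_design(q, aln.strand)
            if p - p_c in (0, 1):
                count += 1
        if a != "-":
            q += 1
    return count


__all__ = [
    "OUTSIDE_3PRIME",
    "NEAR_OFFSETS",
    "CpgAnchor",
    "MismatchAnnotation",
    "locate_cpg",
    "project_cpg",
    "classify_mismatches",
]
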