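"""Local alignment of 50-mer array probes against a target genome.

Two routes with one output contract:

* :func:`align_probe` — seed-and-extend: exact word seeds (default word
  size 11) locate candidate diagonals, a windowed affine-gap (Gotoh) local
  alignment extends each candidate, and Karlin-Altschul statistics convert
  raw scores into bitscores and e-values.
* :func:`brute_force_align` — exhaustive: a vectorised Gotoh row recurrence
  sweeps every position of the genome (no seeding), so nothing a word seed
  could miss is missed.  Quadratic; guarded to genomes <= 1 Mb and intended
  as the test oracle.

Scoring follows blastn conventions: match +2, mismatch -3, a gap of length
L costs gap_open + L*gap_extend.  Bitscore S' = (lambda*S - ln K)/ln 2 and
e-value = m * n_eff * 2**(-S') with n_eff = 2 * genome length (both strands
searched, no edge-effect corrections).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import GenomeSequence, ProbeRecord

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ScoringParams:
    """blastn-style scoring plus gapped Karlin-Altschul parameters.

    ``evalue_max`` defaults to exp(-10) (~4.54e-5), reading the e-value
    threshold "e^-10" as the number e raised to -10; pass 1e-10 for the
    power-of-ten reading.
    """

    reward: int = 2
    penalty: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    lambda_: float = 0.625
    K: float = 0.41
    word_size: int = 11
    evalue_max: float = math.exp(-10)
    band: int = 6  # half-width of the extension window around a seed diagonal

    def __post_init__(self):
        if not (self.reward > 0 > self.penalty):
            raise ValueError("require reward > 0 > penalty")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap costs must be >= 0")
        if self.lambda_ <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")


@dataclass
class Alignment:
    """One gapped local alignment of a probe to the + strand of a contig.

    ``start``/``end`` are 0-based half-open + strand coordinates whatever
    the matched strand; for strand '-', ``probe_aln`` holds the
    reverse-complemented probe and ``qstart``/``qend`` index into it.
    """

    probe_id: str
    contig: str
    start: int
    end: int
    strand: str
    raw_score: int
    bitscore: float
    evalue: float
    probe_aln: str
    subject_aln: str
    n_mismatch: int
    n_gaps: int
    gap_lengths: list[int] = field(default_factory=list)
    percent_identity: float = 0.0
    qstart: int = 0
    qend: int = 0
    query_seq: str = ""  # full oriented query (reverse-complemented for '-')


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics


def bitscore(raw_score: float, params: ScoringParams) -> float:
    """Normalised (bit) score: (lambda * S - ln K) / ln 2."""
    return (params.lambda_ * raw_score - math.log(params.K)) / math.log(2)


def evalue(bits: float, query_len: int, genome: GenomeSequence) -> float:
    """Expected chance hits at >= this bitscore: m * n_eff * 2**(-S'),
    n_eff counting both genome strands."""
    if query_len <= 0:
        raise ValueError("query_len must be positive")
    n_eff = 2 * genome.total_length
    return query_len * n_eff * math.pow(2.0, -bits)


def min_raw_score(query_len: int, genome: GenomeSequence, params: ScoringParams) -> int:
    """Smallest integer raw score whose e-value is below evalue_max."""
    n_eff = 2 * genome.total_length
    bits_needed = math.log2(query_len * n_eff / params.evalue_max)
    x = (bits_needed * math.log(2) + math.log(params.K)) / params.lambda_
    return int(math.floor(x + 1e-9)) + 1


# ---------------------------------------------------------------------------
# scoring helpers

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    out = np.full(len(seq), 4, dtype=np.int8)
    for base, code in _CODE.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return out


def _pair_score(a: str, b: str, params: ScoringParams) -> int:
    # any non-ACGT base mismatches everything, including itself
    if a == b and a in _CODE:
        return params.reward
    return params.penalty


def rescore(probe_aln: str, subject_aln: str, params: ScoringParams) -> int:
    """Recompute the raw score of a gapped alignment pair from scratch."""
    if len(probe_aln) != len(subject_aln):
        raise ValueError("gapped strings differ in length")
    score = 0
    in_gap = False
    for a, b in zip(probe_aln, subject_aln):
        if a == "-" or b == "-":
            if not in_gap:
                score -= params.gap_open
                in_gap = True
            score -= params.gap_extend
        else:
            in_gap = False
            score += _pair_score(a, b, params)
    return score


def _alignment_stats(probe_aln: str, subject_aln: str) -> tuple[int, int, list[int], float]:
    """(n_mismatch, n_gap_runs, gap_lengths, percent_identity) of a pair."""
    n_mm = 0
    matches = 0
    gap_lengths: list[int] = []
    run = 0
    for a, b in zip(probe_aln, subject_aln):
        if a == "-" or b == "-":
            run += 1
        else:
            if run:
                gap_lengths.append(run)
                run = 0
            if a == b and a in _CODE:
                matches += 1
            else:
                n_mm += 1
    if run:
        gap_lengths.append(run)
    cols = len(probe_aln)
    pid = 100.0 * matches / cols if cols else 0.0
    return n_mm, len(gap_lengths), gap_lengths, pid


# ---------------------------------------------------------------------------
# windowed Gotoh local alignment with traceback (the extension kernel)

_NEG = float("-inf")


def _gotoh_local(query: str, subject: str, params: ScoringParams):
    """Best local affine-gap alignment of query vs subject.

    Returns (score, q0, q1, s0, s1, qaln, saln) with 0-based half-open
    coordinates, or None when the best score is <= 0.
    """
    m, n = len(query), len(subject)
    oe = params.gap_open + params.gap_extend
    ext = params.gap_extend

    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[_NEG] * (n + 1) for _ in range(m + 1)]
    F = [[_NEG] * (n + 1) for _ in range(m + 1)]
    # pointers: tb_h 0=stop 1=diag 2=E 3=F; tb_e/tb_f True = extend existing gap
    tb_h = [[0] * (n + 1) for _ in range(m + 1)]
    tb_e = [[False] * (n + 1) for _ in range(m + 1)]
    tb_f = [[False] * (n + 1) for _ in range(m + 1)]

    best, bi, bj = 0.0, 0, 0
    for i in range(1, m + 1):
        qi = query[i - 1]
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Fi, Fi1 = E[i], F[i], F[i - 1]
        for j in range(1, n + 1):
            e_open = Hi[j - 1] - oe
            e_ext = Ei[j - 1] - ext
            if e_ext > e_open:
                Ei[j] = e_ext
                tb_e[i][j] = True
            else:
                Ei[j] = e_open
            f_open = Hi1[j] - oe
            f_ext = Fi1[j] - ext
            if f_ext > f_open:
                Fi[j] = f_ext
                tb_f[i][j] = True
            else:
                Fi[j] = f_open
            diag = Hi1[j - 1] + _pair_score(qi, subject[j - 1], params)
            h = 0.0
            ptr = 0
            if diag > h:
                h, ptr = diag, 1
            if Ei[j] > h:
                h, ptr = Ei[j], 2
            if Fi[j] > h:
                h, ptr = Fi[j], 3
            Hi[j] = h
            tb_h[i][j] = ptr
            if h > best:
                best, bi, bj = h, i, j

    if best <= 0:
        return None

    qaln_r: list[str] = []
    saln_r: list[str] = []
    i, j = bi, bj
    state = "H"
    while True:
        if state == "H":
            ptr = tb_h[i][j]
            if ptr == 0:
                break
            if ptr == 1:
                qaln_r.append(query[i - 1])
                saln_r.append(subject[j - 1])
                i -= 1
                j -= 1
            elif ptr == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ext_flag = tb_e[i][j]
            qaln_r.append("-")
            saln_r.append(subject[j - 1])
            j -= 1
            state = "E" if ext_flag else "H"
        else:  # F
            ext_flag = tb_f[i][j]
            qaln_r.append(query[i - 1])
            saln_r.append("-")
            i -= 1
            state = "F" if ext_flag else "H"

    return int(round(best)), i, bi, j, bj, "".join(reversed(qaln_r)), "".join(reversed(saln_r))


# ---------------------------------------------------------------------------
# seed index


def _kmer_index(genome: GenomeSequence, word_size: int) -> dict[str, list[tuple[str, int]]]:
    cache = getattr(genome, "_kmer_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(genome, "_kmer_cache", cache)
    if word_size in cache:
        return cache[word_size]
    index: dict[str, list[tuple[str, int]]] = {}
    for name, seq in genome.contigs.items():
        for pos in range(len(seq) - word_size + 1):
            word = seq[pos:pos + word_size]
            index.setdefault(word, []).append((name, pos))
    cache[word_size] = index
    return index


# ---------------------------------------------------------------------------
# building / merging alignments


def _make_alignment(
    probe_id: str,
    contig: str,
    strand: str,
    win_start: int,
    local,
    oriented: str,
    genome: GenomeSequence,
    params: ScoringParams,
) -> Alignment:
    query_len = len(oriented)
    score, q0, q1, s0, s1, qaln, saln = local
    n_mm, n_runs, gap_lengths, pid = _alignment_stats(qaln, saln)
    bits = bitscore(score, params)
    return Alignment(
        probe_id=probe_id,
        contig=contig,
        start=win_start + s0,
        end=win_start + s1,
        strand=strand,
        raw_score=score,
        bitscore=bits,
        evalue=evalue(bits, query_len, genome),
        probe_aln=qaln,
        subject_aln=saln,
        n_mismatch=n_mm,
        n_gaps=n_runs,
        gap_lengths=gap_lengths,
        percent_identity=pid,
        qstart=q0,
        qend=q1,
        query_seq=oriented,
    )


def _merge_overlapping(alignments: list[Alignment]) -> list[Alignment]:
    """Collapse overlapping hits on the same (contig, strand) to the single
    highest-scoring one; ties go to the lexicographically smallest
    (contig, start, strand)."""
    by_group: dict[tuple[str, str], list[Alignment]] = {}
    for aln in alignments:
        by_group.setdefault((aln.contig, aln.strand), []).append(aln)
    kept: list[Alignment] = []
    for group in by_group.values():
        group.sort(key=lambda a: (a.start, a.end))
        cluster: list[Alignment] = []
        cluster_end = -1
        for aln in group:
            if cluster and aln.start >= cluster_end:
                kept.append(_best_of(cluster))
                cluster = []
                cluster_end = -1
            cluster.append(aln)
            cluster_end = max(cluster_end, aln.end)
        if cluster:
            kept.append(_best_of(cluster))
    return kept


def _best_of(cluster: list[Alignment]) -> Alignment:
    return min(cluster, key=lambda a: (-a.bitscore, a.contig, a.start, a.strand))


def _finalize(alignments: list[Alignment], params: ScoringParams) -> list[Alignment]:
    passing = [a for a in alignments if a.evalue < params.evalue_max]
    merged = _merge_overlapping(passing)
    merged.sort(key=lambda a: (-a.bitscore, a.contig, a.start))
    return merged


# ---------------------------------------------------------------------------
# seed-and-extend search


def align_probe(
    probe: ProbeRecord, genome: GenomeSequence, params: ScoringParams | None = None
) -> list[Alignment]:
    """All local alignments of a probe with e-value < evalue_max.

    Both strands are searched (the reverse-complemented probe vs the +
    genome strand is reported as strand '-').  Output is sorted by
    descending bitscore, ties by (contig, start); overlapping hits on one
    diagonal band are merged to the highest-scoring one.
    """
    params = params or ScoringParams()
    return _seed_extend(probe.probe_id, probe.probe_seq, genome, params)


def _seed_extend(
    probe_id: str, probe_seq: str, genome: GenomeSequence, params: ScoringParams
) -> list[Alignment]:
    w = params.word_size
    index = _kmer_index(genome, w)
    results: list[Alignment] = []
    qlen = len(probe_seq)
    for strand, oriented in (("+", probe_seq.upper()), ("-", revcomp(probe_seq.upper()))):
        # seed diagonals per contig
        diags: dict[str, set[int]] = {}
        for q in range(qlen - w + 1):
            for contig, s in index.get(oriented[q:q + w], ()):
                diags.setdefault(contig, set()).add(s - q)
        for contig, dset in diags.items():
            seq = genome.contigs[contig]
            for d_lo, d_hi in _cluster_diagonals(sorted(dset), 2 * params.band):
                win_start = max(0, d_lo - params.band)
                win_end = min(len(seq), d_hi + qlen + params.band)
                local = _gotoh_local(oriented, seq[win_start:win_end], params)
                if local is None:
                    continue
                results.append(
                    _make_alignment(
                        probe_id, contig, strand, win_start, local, oriented, genome, params
                    )
                )
    return _finalize(results, params)


def _cluster_diagonals(diags: list[int], max_gap: int):
    if not diags:
        return
    lo = hi = diags[0]
    for d in diags[1:]:
        if d - hi <= max_gap:
            hi = d
        else:
            yield lo, hi
            lo = hi = d
    yield lo, hi


# ---------------------------------------------------------------------------
# exhaustive oracle

_ORACLE_MAX_GENOME = 10 ** 6


def brute_force_align(
    probe_seq: str, genome: GenomeSequence, params: ScoringParams | None = None,
    probe_id: str = "query",
) -> list[Alignment]:
    """Exhaustive affine-gap local alignment at every genome position.

    Same output contract as :func:`align_probe` but with no seeding, so no
    hit above the e-value threshold can be missed.  Quadratic in genome
    length; refuses genomes > 1 Mb.
    """
    params = params or ScoringParams()
    if genome.total_length > _ORACLE_MAX_GENOME:
        raise ValueError("brute_force_align: genome exceeds 1 Mb oracle guard")
    qlen = len(probe_seq)
    s_min = min_raw_score(qlen, genome, params)
    results: list[Alignment] = []
    for strand, oriented in (("+", probe_seq.upper()), ("-", revcomp(probe_seq.upper()))):
        qcodes = _encode(oriented)
        for contig, seq in genome.contigs.items():
            scodes = _encode(seq)
            colmax = _score_sweep(qcodes, scodes, params)
            for run_lo, run_hi in _candidate_runs(colmax, s_min):
                win_start = max(0, run_lo - qlen - 12)
                win_end = min(len(seq), run_hi + params.band + 1)
                local = _gotoh_local(oriented, seq[win_start:win_end], params)
                if local is None:
                    continue
                results.append(
                    _make_alignment(
                        probe_id, contig, strand, win_start, local, oriented, genome, params
                    )
                )
    return _finalize(results, params)


def _score_sweep(qcodes: np.ndarray, scodes: np.ndarray, params: ScoringParams) -> np.ndarray:
    """Column-wise best local Gotoh score over all query rows.

    Row recurrence vectorised over the subject axis; the within-row
    horizontal-gap dependency is solved exactly by iterating a prefix-max
    closure to its (monotone, bounded) fixpoint.
    """
    n = scodes.size
    m = qcodes.size
    oe = float(params.gap_open + params.gap_extend)
    ext = float(params.gap_extend)
    reward, penalty = float(params.reward), float(params.penalty)

    h_prev = np.zeros(n + 1)
    f_prev = np.full(n + 1, -1e18)
    colmax = np.zeros(n)
    jidx = np.arange(1, n + 1, dtype=float)
    for i in range(m):
        qc = qcodes[i]
        sub = np.where((scodes == qc) & (qc != 4), reward, penalty)
        diag = h_prev[:-1] + sub
        f_row = np.maximum(f_prev[1:] - ext, h_prev[1:] - oe)
        h = np.maximum(0.0, np.maximum(diag, f_row))
        # fixpoint for E[j] = max_{k<j} H[k] - open - (j-k)*ext
        while True:
            prefix = np.maximum.accumulate(h + jidx * ext)
            e = np.empty(n)
            e[0] = -1e18
            e[1:] = prefix[:-1]
            e -= oe - ext + jidx * ext  # = H[k] - open - (j-k)*ext
            h_new = np.maximum(h, e)
            if np.array_equal(h_new, h):
                break
            h = h_new
        colmax = np.maximum(colmax, h)
        f_prev = np.concatenate(([-1e18], f_row))
        h_prev = np.concatenate(([0.0], h))
    return colmax


def _candidate_runs(colmax: np.ndarray, s_min: int, max_gap: int = 8):
    """Consecutive runs of columns whose best score clears the threshold."""
    cols = np.flatnonzero(colmax >= s_min)
    if cols.size == 0:
        return
    lo = hi = int(cols[0])
    for j in cols[1:]:
        j = int(j)
        if j - hi <= max_gap:
            hi = j
        else:
            yield lo, hi
            lo = hi = j
    yield lo, hi


def write_alignments_tsv(alignments: list[Alignment], path) -> None:
    """Tabular (BLAST outfmt-6-like) alignment table with extension columns
    for the gapped strings.  1-based inclusive coordinates; subject
    coordinates are reported descending for '-' strand hits."""
    header = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
        "strand", "raw_score", "probe_aln", "subject_aln",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for a in alignments:
            if a.strand == "+":
                sstart, send = a.start + 1, a.end
            else:
                sstart, send = a.end, a.start + 1
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        a.probe_id, a.contig, f"{a.percent_identity:.2f}",
                        len(a.probe_aln), a.n_mismatch, a.n_gaps,
                        a.qstart + 1, a.qend, sstart, send,
                        f"{a.evalue:.3e}", f"{a.bitscore:.2f}",
                        a.strand, a.raw_score, a.probe_aln, a.subject_aln,
                    ]
                )
                + "\n"
            )


__all__ = [
    "ScoringParams",
    "Alignment",
    "align_probe",
    "brute_force_align",
    "bitscore",
    "evalue",
    "min_raw_score",
    "rescore",
    "revcomp",
    "write_alignments_tsv",
]
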