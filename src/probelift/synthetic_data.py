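"""Synthetic inputs with planted ground truth.

Generates everything the pipeline consumes — target genome, probe
manifest, ortholog gene-name map, gene BED, array beta matrix with
detection p-values, and per-sample bisulfite count tables — from a single
seed, with a truth table recording what was planted so every stage of the
pipeline can be checked against it.

Divergence classes planted per probe (proportions configurable):

* ``clean``     — probe matches the genome exactly, CpG conserved
* ``mm_far``    — 1-4 genome mismatches well away from the CpG
* ``mm_near``   — one genome mismatch flanking the CpG (offset -1)
* ``mm_cpg``    — mismatch in the CG itself: for type I probes the
  probe-side C diverges (target CpG intact, so sequencing still covers
  it); for type II the target C is mutated (CpG absent from the target)
* ``cpg_lost``  — the uncovered G of the target CG mutated away
* ``duplicated``— the probe's locus planted twice (multi-mapping)
* ``absent``    — probe sequence absent from the genome

Array signal model: uncorrupted probes report their (per-sample) true
methylation plus Gaussian noise; probes whose CpG assay is compromised
(mm_near, mm_cpg, cpg_lost, absent) report uniform noise; duplicated
probes report the mean of their two loci.  Sequencing counts are binomial
at Poisson depth.  True methylation follows a bimodal mixture
0.4*Beta(0.5,8) + 0.4*Beta(8,0.5) + 0.2*Uniform(0,1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    BetaMatrix,
    GenomeSequence,
    MethylationCall,
    PROBE_LEN,
    ProbeRecord,
    write_beta_matrix,
    write_gene_bed,
    write_genome,
    write_manifest,
    write_meth_table,
    write_ortholog_map,
)

CLASSES = ("clean", "mm_far", "mm_near", "mm_cpg", "cpg_lost", "duplicated", "absent")

DEFAULT_PROPORTIONS = {
    "clean": 0.40,
    "mm_far": 0.20,
    "mm_near": 0.10,
    "mm_cpg": 0.10,
    "cpg_lost": 0.05,
    "duplicated": 0.10,
    "absent": 0.05,
}

CORRUPTED_CLASSES = frozenset({"mm_near", "mm_cpg", "cpg_lost", "absent"})

DEFAULT_GENE_CLASS_PROPORTIONS = {
    "exact": 0.60,
    "ortholog": 0.15,
    "partial": 0.15,
    "none": 0.05,
    "unannotated": 0.05,
}

_SLOT_STRIDE = 80  # bp between planted probe windows
_SLOT_MARGIN = 3  # probe window starts this far into its slot
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class DivergenceSpec:
    """Per-class planting proportions plus the generator seed."""

    proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    gene_class_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_GENE_CLASS_PROPORTIONS)
    )
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        unknown = set(self.proportions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown divergence classes: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# genome


def generate_genome(
    seed: int, length: int = 150_000, gc: float = 0.45, contig_name: str = "chr1"
) -> GenomeSequence:
    """i.i.d. random genome at the given GC fraction; deterministic in seed."""
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    return GenomeSequence(contigs={contig_name: seq})


# ---------------------------------------------------------------------------
# planting


def _largest_remainder(proportions: dict, n: int, order) -> dict:
    counts = {}
    remainders = []
    total = 0
    for key in order:
        p = proportions.get(key, 0.0)
        exact = p * n
        c = int(math.floor(exact))
        counts[key] = c
        total += c
        remainders.append((-(exact - c), order.index(key), key))
    remainders.sort()
    for _, _, key in remainders[: n - total]:
        counts[key] += 1
    return counts


def _cpg_plus_positions(ws: int, strand: str, probe_type: str) -> tuple[int, int]:
    """+ strand genome positions (C_pos, G_pos-in-design-order) of the
    planted CpG for a probe window starting at ``ws``.

    Returns (pos of design C, pos of design G) on the + strand; the +
    strand CG dinucleotide occupies [min, min+2).
    """
    p_c = PROBE_LEN - 1 if probe_type == "I" else PROBE_LEN
    if strand == "+":
        return ws + p_c, ws + p_c + 1
    return ws + (PROBE_LEN - 1) - p_c, ws + (PROBE_LEN - 1) - (p_c + 1)


def _design_to_plus(ws: int, strand: str, p: int) -> int:
    return ws + p if strand == "+" else ws + (PROBE_LEN - 1) - p


def _draw_true_meth(rng) -> float:
    u = rng.random()
    if u < 0.4:
        return float(rng.beta(0.5, 8.0))
    if u < 0.8:
        return float(rng.beta(8.0, 0.5))
    return float(rng.random())


def plant_probes(
    genome: GenomeSequence, n_probes: int, spec: DivergenceSpec | None = None
) -> tuple[GenomeSequence, list[ProbeRecord], pd.DataFrame]:
    """Plant probes into a mutable copy of the genome.

    Each probe takes the exact sequence of a genomic window containing the
    planted CpG (per the 3'-anchor convention for its chemistry type and
    design strand), after which the genome copy — or for type I mm_cpg the
    probe — is mutated according to the probe's divergence class.  Returns
    the mutated genome, the manifest, and the truth table.
    """
    spec = spec or DivergenceSpec()
    rng = np.random.default_rng(spec.seed)
    counts = _largest_remainder(spec.proportions, n_probes, list(CLASSES))
    classes = [c for c in CLASSES for _ in range(counts[c])]
    classes = [classes[i] for i in rng.permutation(n_probes)]
    n_dup = sum(1 for c in classes if c == "duplicated")

    contig = next(iter(genome.contigs))
    seq = list(genome.contigs[contig])
    n_slots = n_probes + n_dup
    needed = n_slots * _SLOT_STRIDE + 2 * _SLOT_MARGIN + PROBE_LEN
    if len(seq) < needed:
        raise ValueError(
            f"genome too short: need >= {needed} bp for {n_probes} probes"
        )
    dup_slot_iter = iter(range(n_probes, n_slots))

    gene_counts = _largest_remainder(
        spec.gene_class_proportions, n_probes, list(DEFAULT_GENE_CLASS_PROPORTIONS)
    )
    gene_classes = [c for c in DEFAULT_GENE_CLASS_PROPORTIONS for _ in range(gene_counts[c])]
    gene_classes = [gene_classes[i] for i in rng.permutation(n_probes)]

    probes: list[ProbeRecord] = []
    truth_rows = []
    bed_rows: list[tuple[str, int, int, str]] = []
    ortholog_map: dict[str, str] = {}

    for i, cls in enumerate(classes):
        probe_id = f"cg{i:06d}"
        probe_type = "I" if i % 2 == 0 else "II"
        strand = "+" if rng.random() < 0.5 else "-"
        gene = f"GENE{i:04d}"
        gene_cls = gene_classes[i]
        p_c = PROBE_LEN - 1 if probe_type == "I" else PROBE_LEN

        if cls == "absent":
            probe_seq = "".join(rng.choice(_BASES, size=PROBE_LEN))
            if probe_type == "I":
                probe_seq = probe_seq[: PROBE_LEN - 1] + "C"
            probes.append(
                ProbeRecord(
                    probe_id=probe_id,
                    probe_seq=probe_seq,
                    chrom=contig,
                    cpg_pos=1,
                    strand=strand,
                    probe_type=probe_type,
                    gene_names=[] if gene_cls == "unannotated" else [gene],
                )
            )
            truth_rows.append(
                dict(
                    probe_id=probe_id,
                    cls=cls,
                    probe_type=probe_type,
                    design_strand=strand,
                    contig=contig,
                    start0=-1,
                    cpg_pos0=-1,
                    n_planted_mismatch=0,
                    corrupted=True,
                    true_meth=_draw_true_meth(rng),
                    dup_true_meth=math.nan,
                    gene_class=gene_cls,
                )
            )
            continue

        ws = i * _SLOT_STRIDE + _SLOT_MARGIN
        pos_c, pos_g = _cpg_plus_positions(ws, strand, probe_type)
        lo = min(pos_c, pos_g)
        seq[lo] = "C"
        seq[lo + 1] = "G"

        window = "".join(seq[ws:ws + PROBE_LEN])
        probe_seq = window if strand == "+" else _revcomp(window)

        n_mm = 0
        if cls == "mm_far":
            n_mm = int(rng.integers(1, 5))
            cand = np.arange(2, p_c - 2)  # interior, >= 3 bp 5' of the CpG C
            for p in rng.choice(cand, size=n_mm, replace=False):
                _mutate(seq, _design_to_plus(ws, strand, int(p)), rng)
        elif cls == "mm_near":
            # the defining flanking mismatch plus 0-3 extra far mismatches,
            # so corrupted probes span the admissible bitscore range
            n_extra = int(rng.integers(0, 4))
            n_mm = 1 + n_extra
            _mutate(seq, _design_to_plus(ws, strand, p_c - 1), rng)
            cand = np.arange(2, p_c - 2)
            for p in rng.choice(cand, size=n_extra, replace=False):
                _mutate(seq, _design_to_plus(ws, strand, int(p)), rng)
        elif cls == "mm_cpg":
            if probe_type == "I":
                # probe-side divergence at the covered C (probe_seq is in
                # design orientation, so the C is probe position 49 on
                # either strand): the target CpG stays assayable
                n_mm = 1
                probe_seq = probe_seq[: PROBE_LEN - 1] + "T"
            else:
                seq[pos_c] = "A"  # the CpG is outside the probe: lose it
        elif cls == "cpg_lost":
            seq[pos_g] = "A"
        elif cls == "duplicated":
            dup_ws = next(dup_slot_iter) * _SLOT_STRIDE + _SLOT_MARGIN
            src_lo, src_hi = ws - 2, ws + PROBE_LEN + 2
            seq[dup_ws - 2:dup_ws + PROBE_LEN + 2] = seq[src_lo:src_hi]

        probes.append(
            ProbeRecord(
                probe_id=probe_id,
                probe_seq=probe_seq,
                chrom=contig,
                cpg_pos=lo + 1,
                strand=strand,
                probe_type=probe_type,
                gene_names=[] if gene_cls == "unannotated" else [gene],
            )
        )
        target_name = {
            "exact": gene,
            "ortholog": f"CYN{i:04d}",
            "partial": f"{gene}-L1",
            "none": f"ZZX{i:04d}",
            "unannotated": gene,
        }[gene_cls]
        if gene_cls == "ortholog":
            ortholog_map[gene] = target_name
        bed_rows.append((contig, max(0, ws - 10), ws + PROBE_LEN + 12, target_name))
        truth_rows.append(
            dict(
                probe_id=probe_id,
                cls=cls,
                probe_type=probe_type,
                design_strand=strand,
                contig=contig,
                start0=ws,
                cpg_pos0=lo,
                n_planted_mismatch=n_mm,
                corrupted=cls in CORRUPTED_CLASSES,
                true_meth=_draw_true_meth(rng),
                dup_true_meth=_draw_true_meth(rng) if cls == "duplicated" else math.nan,
                gene_class=gene_cls,
            )
        )

    mutated = GenomeSequence(contigs={contig: "".join(seq)})
    truth = pd.DataFrame(truth_rows)
    truth.attrs["ortholog_map"] = ortholog_map
    truth.attrs["gene_bed"] = bed_rows
    return mutated, probes, truth


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _mutate(seq: list[str], pos: int, rng) -> None:
    cur = seq[pos]
    choices = [b for b in "ACGT" if b != cur]
    seq[pos] = choices[int(rng.integers(0, 3))]


def expected_pass_ids(truth: pd.DataFrame) -> set[str]:
    """Truth-derived expectation of the three-step filter's pass set."""
    keep = truth["cls"].isin(["clean", "mm_far"])
    return set(truth.loc[keep, "probe_id"])


# ---------------------------------------------------------------------------
# methylomes


def simulate_methylomes(
    truth: pd.DataFrame,
    n_samples: int = 12,
    depth_mean: float = 30.0,
    array_noise_sd: float = 0.05,
    seed: int = 0,
    indiv_sd: float = 0.03,
    missing_frac: float = 0.02,
    noise_per_mismatch: float = 0.75,
) -> tuple[BetaMatrix, dict[str, list[MethylationCall]]]:
    """Simulate the array beta matrix (with detection p-values) and the
    per-sample bisulfite count tables from the truth table.

    Sequencing counts exist only where the target genome still carries the
    planted CpG (which includes type I mm_cpg probes, whose divergence is
    probe-side); depths are gamma-Poisson with mean depth_mean, so the
    downstream >=10x coverage filter genuinely removes calls.  Array
    noise for uncorrupted probes grows with the planted mismatch count
    (sd * (1 + noise_per_mismatch * n_mismatch)), emulating the loss of
    hybridization efficiency with probe-target divergence.
    """
    rng = np.random.default_rng(seed)
    n = len(truth)
    samples = [f"S{j + 1:02d}" for j in range(n_samples)]
    conserved = (
        truth["cls"].isin(["clean", "mm_far", "mm_near", "duplicated"])
        | ((truth["cls"] == "mm_cpg") & (truth["probe_type"] == "I"))
    ).to_numpy()
    corrupted = truth["corrupted"].to_numpy()
    duplicated = (truth["cls"] == "duplicated").to_numpy()
    true_meth = truth["true_meth"].to_numpy(dtype=float)
    dup_meth = truth["dup_true_meth"].to_numpy(dtype=float)
    n_mm = truth["n_planted_mismatch"].to_numpy(dtype=float)
    mapped = (truth["cls"] != "absent").to_numpy()

    beta = np.empty((n, n_samples))
    det = np.empty((n, n_samples))
    calls: dict[str, list[MethylationCall]] = {}
    contigs = truth["contig"].to_numpy()
    cpg_pos0 = truth["cpg_pos0"].to_numpy()

    for j, sample in enumerate(samples):
        true_s = np.clip(true_meth + rng.normal(0.0, indiv_sd, size=n), 0.0, 1.0)
        dup_s = np.clip(dup_meth + rng.normal(0.0, indiv_sd, size=n), 0.0, 1.0)

        # sequencing at the primary planted CpG; gamma-Poisson (negative
        # binomial) depths reproduce RRBS coverage overdispersion, so the
        # >=10x filter removes a real fraction of calls
        depth = rng.poisson(rng.gamma(2.0, depth_mean / 2.0, size=n))
        meth_counts = rng.binomial(depth, np.where(np.isfinite(true_s), true_s, 0.0))
        sample_calls = []
        for i in np.flatnonzero(conserved):
            if depth[i] == 0:
                continue
            sample_calls.append(
                MethylationCall(
                    chrom=str(contigs[i]),
                    pos=int(cpg_pos0[i]) + 1,
                    meth_count=int(meth_counts[i]),
                    total_count=int(depth[i]),
                )
            )
        calls[sample] = sample_calls

        # array signal
        signal = true_s.copy()
        signal[duplicated] = 0.5 * (true_s[duplicated] + dup_s[duplicated])
        sd = array_noise_sd * (1.0 + noise_per_mismatch * n_mm)
        b = np.clip(signal + rng.normal(0.0, 1.0, size=n) * sd, 0.0, 1.0)
        b[corrupted] = rng.random(int(corrupted.sum()))
        b[rng.random(n) < missing_frac] = np.nan
        beta[:, j] = b

        # detection p: small, worsening with planted probe-genome divergence
        p = 0.002 + 0.01 * n_mm + np.abs(rng.normal(0.0, 0.004, size=n))
        p[~mapped] = rng.random(int((~mapped).sum()))
        det[:, j] = np.clip(p, 0.0, 1.0)

    idx = pd.Index(truth["probe_id"], name="probe_id")
    bm = BetaMatrix(
        beta=pd.DataFrame(beta, index=idx, columns=samples),
        detection_p=pd.DataFrame(det, index=idx, columns=samples),
    )
    return bm, calls


# ---------------------------------------------------------------------------
# one-shot cohort + file export


@dataclass
class SyntheticCohort:
    genome: GenomeSequence
    probes: list[ProbeRecord]
    truth: pd.DataFrame
    betas: BetaMatrix
    meth: dict[str, list[MethylationCall]]
    ortholog_map: dict[str, str]
    gene_bed: list[tuple[str, int, int, str]]


def generate_cohort(
    seed: int,
    n_probes: int = 400,
    genome_length: int = 150_000,
    gc: float = 0.45,
    spec: DivergenceSpec | None = None,
    n_samples: int = 12,
    depth_mean: float = 30.0,
    array_noise_sd: float = 0.05,
) -> SyntheticCohort:
    """Generate the full five-input synthetic study from one seed."""
    ss = np.random.SeedSequence(seed)
    s_genome, s_plant, s_meth = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    base = generate_genome(s_genome, length=genome_length, gc=gc)
    spec = spec or DivergenceSpec(seed=s_plant)
    genome, probes, truth = plant_probes(base, n_probes, spec)
    betas, meth = simulate_methylomes(
        truth,
        n_samples=n_samples,
        depth_mean=depth_mean,
        array_noise_sd=array_noise_sd,
        seed=s_meth,
    )
    return SyntheticCohort(
        genome=genome,
        probes=probes,
        truth=truth,
        betas=betas,
        meth=meth,
        ortholog_map=truth.attrs["ortholog_map"],
        gene_bed=truth.attrs["gene_bed"],
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write all input files (plus the truth table) to a directory; returns
    the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": str(out / "genome.fa"),
        "manifest": str(out / "manifest.csv"),
        "orthologs": str(out / "orthologs.tsv"),
        "gene_bed": str(out / "genes.bed"),
        "betas": str(out / "betas.csv"),
        "detection_p": str(out / "detection_p.csv"),
        "truth": str(out / "truth.csv"),
    }
    write_genome(cohort.genome, paths["genome"])
    write_manifest(cohort.probes, paths["manifest"])
    write_ortholog_map(cohort.ortholog_map, paths["orthologs"])
    write_gene_bed(cohort.gene_bed, paths["gene_bed"])
    write_beta_matrix(cohort.betas, paths["betas"], paths["detection_p"])
    cohort.truth.to_csv(paths["truth"], index=False)
    for sample, sample_calls in cohort.meth.items():
        p = str(out / f"meth_{sample}.tsv")
        write_meth_table(sample_calls, p)
        paths[f"meth_{sample}"] = p
    return paths


__all__ = [
    "CLASSES",
    "DEFAULT_PROPORTIONS",
    "CORRUPTED_CLASSES",
    "DivergenceSpec",
    "SyntheticCohort",
    "generate_genome",
    "plant_probes",
    "simulate_methylomes",
    "generate_cohort",
    "write_cohort",
    "expected_pass_ids",
]
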