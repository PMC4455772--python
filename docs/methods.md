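# Methods

## Problem

A methylation array probe designed against the human genome reports a
trustworthy value in another species only when (i) its 50-mer still
matches the target genome closely, (ii) it matches one locus only, and
(iii) the divergence that remains does not touch the assayed CpG or the
bases flanking it. `probelift` scores each of these conditions per probe
and quantifies — against bisulfite sequencing of the same samples — how
much each one buys in measurement agreement.

## Alignment model

Probes are aligned by seed-and-extend local alignment: exact words of
length 11 (configurable) locate candidate diagonals on both strands;
each diagonal cluster is extended by an affine-gap (Gotoh) local
alignment inside a window of half-width 6 around the diagonal band, wide
enough for the admissible two gaps of ≤ 4 bp. Scoring follows blastn
task defaults: match +2, mismatch −3, a gap of length L costs
5 + 2·L; any non-ACGT base mismatches everything. Raw scores are
normalised with gapped Karlin–Altschul parameters λ = 0.625 nats and
K = 0.41:

    S' = (λ·S − ln K) / ln 2          (bitscore)
    E  = m · n_eff · 2^(−S')          (e-value)

with m the probe length and n_eff = 2 × genome length (both strands, no
edge corrections — a deliberate simplification that is monotone in the
same direction as BLAST's corrected statistic). The e-value threshold
"e⁻¹⁰" is read literally as exp(−10) ≈ 4.54 × 10⁻⁵ by default; the
power-of-ten reading (1e−10) is one parameter away
(`ScoringParams(evalue_max=1e-10)`). Overlapping hits on one diagonal
band are merged to the highest-scoring one; equal-bitscore ties resolve
lexicographically by (contig, start, strand).

`brute_force_align` is the independent oracle: an exhaustive affine-gap
scan of every genome position with no seeding, implemented as a
vectorised row recurrence whose within-row gap dependency is solved by a
prefix-max fixpoint, followed by windowed traceback around every column
whose score clears the e-value threshold. It refuses genomes over 1 Mb
(it is quadratic) and exists so tests can prove the heuristic search
misses nothing whose best alignment contains an exact seed word. With
fewer than five mismatches in a 50-mer an exact 11-mer is not guaranteed
(four mismatches can split the probe into runs of ≤ 10), so equivalence
fixtures space planted mismatches ≥ 13 bp apart.

## CpG anchoring, projection, and mismatch offsets

Infinium chemistry ties the probe 3′ end to the assayed CpG. The package
encodes this as: type I — the probe 3′ terminus covers the CpG C (probe
offset 49); type II — the CpG is the dinucleotide immediately 3′ of the
probe on its design strand. The convention is isolated in `locate_cpg`
and can be swapped wholesale.

The CpG C and G are projected through the gapped alignment columns into
target + strand coordinates (reverse-strand hits are mirrored; the CG
dinucleotide is its own reverse complement, so the projected interval is
always reported on the + strand with its C first). Positions outside the
aligned extent extrapolate linearly; a projection that lands in a target
gap, is split by an indel, or runs off the contig is reported as absent.

Every mismatch is assigned a signed offset in design-strand coordinates
from the CpG C (0 = the C, +1 = the G, negative = 5′ of the CpG).
"Near-CpG" means offsets −1 and +2 — the bases flanking the CG —
configurable via `near_offsets`. A gap column overlapping the CpG or its
flanks counts as a mismatch at those offsets. Because local alignment
trims terminal mismatches, probe bases outside the aligned extent are
compared to the genome by ungapped extrapolation before classification
(end-to-end-style mismatch localisation); without this, a mismatch at
the 3′-terminal CpG C would silently vanish from the classification.

Category assignment: `at_cpg` when a probe-covered CpG base mismatches
or is gapped; otherwise `cpg_absent` when the projected target
dinucleotide is not CG (or projection failed); otherwise `near_cpg` when
a flanking mismatch exists; otherwise `clean`. Downstream accounting
treats `at_cpg` and `cpg_absent` as one excluded group ("CpG-site
mismatch, including sites that are not CpG in the target"), so the split
between them does not affect any headline count.

## Filters

Admissibility keeps alignments with ≤ 4 mismatches, ≤ 2 gap runs, each
run ≤ 4 bp (inclusive bounds), below the e-value threshold. A probe's
hit count is its number of admissible alignments; "unique" means exactly
one (no best-to-second-best margin rule). The three-step filter is
evaluated on the best hit:

1. bitscore strictly > 70 (default; the strictness follows the ">70"
   convention),
2. unique genomic match,
3. mismatch category `clean` (with `exclude_near_cpg=False`, `near_cpg`
   is also accepted).

`pass_all` is the conjunction, so the sequential pass counts are
non-increasing and order-independent. A CM probe ("conserved-CpG
mapped") is any mapped probe with `cpg_present` and no CpG mismatch;
CM count = mapped − CpG-compromised by construction.

Gene reconciliation: the target gene is the BED interval nearest the
projected CpG (distance 0 inside an interval; ties to the alphabetically
first name). Match classes, in precedence order: `exact`
(case-insensitive name equality), `ortholog` (via the two-column
human→target map), `partial` (shared token after splitting on
non-alphanumerics), `none`; probes with no human annotation are
`unannotated`.

## Concordance

Array betas and sequencing ratios are joined per (probe, sample) where
the projected target CpG coincides with a coverage-filtered call
(≥ 10×, inclusive); calls on the G of the CpG fold onto the C. Metrics
per stratum (bitscore bin with cuts {≤70, 70–80, >80}, uniqueness,
mismatch category, probe type, methylation tier low < 0.3 ≤ mid ≤ 0.7 <
high on the pair mean):

* Pearson r, computed per sample and averaged unweighted by default
  (`per_sample=False` pools pairs instead); undefined correlations
  (n < 2 or zero variance) are reported as NaN markers, never propagated.
* percent of pairs with |ratio − beta| ≤ 0.20 / 0.10 / 0.05 (inclusive,
  on the 0–1 scale) — nested by construction.
* Bland–Altman: per pair (mean, difference) with difference defined as
  sequencing − array, plus mean difference and 1.96·sd limits.
* Delta concordance: for every probe and unordered sample pair,
  |Δarray − Δseq| binned at 0.20/0.10/0.05 — agreement of
  inter-individual differences across platforms.
* Detection-p correlations: per-sample Spearman rho between detection
  p-values and e-value / percent identity / bitscore over mapped probes,
  optionally after excluding near-CpG-mismatch probes; average ranks for
  ties.

## Synthetic study design

The generator is the package's study bed: a uniform-random genome
(default 150 kb, GC 0.45) with 400 probes planted at 80 bp spacing,
class proportions clean 0.40, mm_far 0.20, mm_near 0.10, mm_cpg 0.10,
cpg_lost 0.05, duplicated 0.10, absent 0.05 (largest-remainder
rounding), both chemistries 50/50, design strands random. Each probe is
the exact sequence of its window (the CpG is written into the genome at
the anchor-consistent position); divergence is then created by mutating
the genome copy — except type I `mm_cpg`, where the probe-side C is
mutated so the target CpG stays assayable and the at-CpG stratum has
sequencing pairs at all. `mm_near` carries its defining flanking
mismatch plus 0–3 extra far mismatches so corrupted probes span the
admissible bitscore range rather than clustering at the top.
Far mismatches are planted ≥ 2 bp from the probe ends and ≥ 3 bp 5′ of
the CpG, so local alignment cannot trim them and planted counts match
alignment counts.

Methylomes: true methylation per CpG from the bimodal mixture
0.4·Beta(0.5, 8) + 0.4·Beta(8, 0.5) + 0.2·U(0, 1); per-sample values add
N(0, 0.03) inter-individual variation. Sequencing counts are binomial at
gamma-Poisson depth (mean 30, shape 2 — overdispersed like real RRBS, so
the ≥ 10× filter removes a real fraction of calls); calls are emitted
only where the target genome still carries the CpG. Array betas are
truth + N(0, sd) with sd = 0.05·(1 + 0.75·mismatches) for uncorrupted
probes (hybridization degrades with divergence), the mean of the two
loci for duplicated probes, and U(0, 1) for corrupted probes (near/at
CpG divergence or absent locus — the corruption model that makes
flanking mismatches as damaging as CpG mismatches). Detection p-values
grow with planted mismatch count for mapped probes and are U(0, 1) for
absent ones. 2% of betas are missing. Sample count defaults to 12
(eleven subjects plus one technical replicate, the design of the
motivating study).

What the generator does *not* emulate: read-level bisulfite chemistry
and conversion errors, restriction-fragment (MspI) coverage geometry,
repeat structure and CpG islands, probe color-channel/next-base
constraints, and polymorphism. Passing tests therefore demonstrate that
the pipeline's logic recovers planted divergence exactly and that the
filter's benefit is detectable under a plausible noise model — not that
real cross-species data will show these effect sizes. One known artifact:
because only type I probes can host an assayable at-CpG mismatch, the
synthetic type I stratum is noisier than type II, a difference the real
study did not observe.

## Numerical and scale choices

Default problem sizes — 400 probes / 150 kb / 12 samples for cohort
work, 100 probes / 50 kb for aligner-oracle equivalence, ten seeds for
the qualitative orderings — are chosen so every planted effect is
decisively detectable while the whole suite runs in about a minute.
Score arithmetic is exact (integer-valued floats); closed-form checks
are asserted at 1e−9. Tie-breaks are deterministic everywhere
(lexicographic hits, alphabetical genes), and all randomness flows from
explicit seeds through `numpy.random.default_rng`, so every output is
byte-reproducible.

## Limitations

* The aligner is not bit-compatible with NCBI blastn (no masking, no
  edge-corrected search space, banded extension); its statistics are
  monotone transforms of the same quantities, which is what the filter
  thresholds consume.
* Uniqueness counts admissible hits only; a second hit failing the
  mismatch/gap caps does not revoke uniqueness.
* The annotation file reports one best hit per probe; summaries count
  each probe once.
* The e⁻¹⁰ threshold ambiguity (exp(−10) vs 1e−10) is resolved by
  configuration, not evidence.
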