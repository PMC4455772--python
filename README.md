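# probelift

Cross-species transfer of Infinium HumanMethylation450 array probes to a
non-human genome, and validation of the transferred measurements against
bisulfite sequencing.

The 450K array measures DNA methylation with 50-mer probes designed
against the human genome. In a related species (the motivating case is
the cynomolgus macaque, *Macaca fascicularis*), a probe is only
trustworthy if its sequence still matches the target genome well, matches
it uniquely, and has no sequence divergence at or immediately next to the
assayed CpG. `probelift` implements that validation pipeline end to end:

1. **Alignment** — seed-and-extend local alignment of each 50-mer against
   the target genome with blastn-style scoring (match +2, mismatch −3,
   affine gaps 5 + 2·L) and Karlin–Altschul statistics: bitscore
   S′ = (λS − ln K)/ln 2 with λ = 0.625, K = 0.41, and e-value
   E = m·n·2^(−S′) over both strands. Hits are kept at E < e⁻¹⁰.
   An exhaustive Smith–Waterman oracle (`brute_force_align`) provides an
   independent check of the heuristic search.
2. **CpG projection** — the assayed CpG is anchored in probe coordinates
   (type I chemistry: the probe 3′ terminus covers the CpG C; type II:
   the CpG lies immediately 3′ of the probe), projected through the
   gapped alignment into target coordinates, and every mismatch is
   classified by its signed offset from the CpG C. Categories:
   `clean`, `near_cpg` (mismatch at the bases flanking the CG),
   `at_cpg` (mismatch in the CG itself), `cpg_absent` (target lacks the
   CG dinucleotide).
3. **Filtering** — probes admissible at ≤ 4 mismatches and ≤ 2 gaps of
   ≤ 4 bp are passed through the three-step filter:
   **bitscore > 70 → unique genomic match → no mismatch at/next to the
   CpG**. Gene annotations are reconciled against the target's nearest
   gene via exact / ortholog-map / partial (shared token) matching.
4. **Concordance** — array beta values are joined to per-CpG bisulfite
   methylation ratios (≥ 10× coverage) at shared CpGs and compared via
   Pearson correlation, percent-agreement bins (|Δ| ≤ 0.20/0.10/0.05),
   Bland–Altman differences (sequencing − array), inter-individual delta
   concordance, and detection-p vs alignment-quality rank correlations —
   stratified by bitscore bin, uniqueness, mismatch category, probe type
   and methylation tier.
5. **Synthetic studies** — a generator plants probes of known divergence
   classes (clean, far/near/at-CpG mismatches, lost CpG, duplicated,
   absent) into a random genome and simulates bimodal methylomes with
   binomial sequencing counts and divergence-graded array noise, so the
   whole pipeline is testable against planted truth with no downloads.

## Worked example

```
probelift run-all --seed 7 --out study/
```

simulates a 400-probe study (12 samples), annotates every probe and
writes `study/annotation.csv` plus concordance tables. The annotate stage
prints the cohort summary; with seed 7 it ends:

```
n_probes        400
n_mapped        380
mapped_pct      95.0000
n_cpg_mismatch_or_absent        60
cpg_mismatch_pct        15.7895
n_cm    320
...
n_after_bitscore        380
n_after_unique  340
n_after_mismatch        240
coverage_pct    60.0000
```

380/400 probes map (the 20 planted-absent probes do not); 60 mapped
probes have a compromised CpG, leaving 320 CM probes (mapped, CpG
conserved — note `n_cm = n_mapped − n_cpg_mismatch_or_absent`); the
sequential three-step filter retains 380 → 340 → 240 probes (60%
coverage — exactly the planted clean + far-mismatch fraction). The
concord stage then reports ~3400 shared (probe, sample) CpG pairs and,
in `study/concord_summary.tsv`, higher correlation and tighter error bins
for unique, high-bitscore, clean-CpG probes — the signal the three-step
filter exists to capture.

Every stage is also a library call (`align_probe`, `classify_mismatches`,
`annotate_probe_set`, `join_shared`, `summarize`, ...); see the module
docstrings.

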