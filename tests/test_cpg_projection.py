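import numpy as np
import pytest

from probelift import alignment as al
from probelift import cpg_projection as cp
from probelift.io_formats import GenomeSequence, ProbeRecord


def _probe(seq, ptype="I", pid="p1"):
    return ProbeRecord(pid, seq, "chr1", 1, "+", ptype)


def _ungapped(start, probe_aln, subject_aln, strand="+", qstart=0, contig="c1"):
    qend = qstart + sum(1 for c in probe_aln if c != "-")
    send = start + sum(1 for c in subject_aln if c != "-")
    qseq = probe_aln.replace("-", "")
    return al.Alignment(
        probe_id="p1", contig=contig, start=start, end=send, strand=strand,
        raw_score=0, bitscore=90.0, evalue=0.0, probe_aln=probe_aln,
        subject_aln=subject_aln, n_mismatch=0, n_gaps=0, gap_lengths=[],
        percent_identity=100.0, qstart=qstart, qend=qend, query_seq=qseq,
    )


class TestLocateCpg:
    def test_type_i_terminal_offset(self):
        a = cp.locate_cpg(_probe("A" * 50, "I"))
        assert a.probe_offset == 49 and a.derivation == "type_I_terminal"

    def test_type_ii_outside_3prime(self):
        a = cp.locate_cpg(_probe("A" * 50, "II"))
        assert a.probe_offset == cp.OUTSIDE_3PRIME
        assert a.derivation == "type_II_adjacent"

    def test_unknown_type_is_error(self):
        probe = _probe("A" * 50, "I")
        probe.probe_type = "III"
        with pytest.raises(ValueError):
            cp.locate_cpg(probe)


def _planted_genome(seed=20, length=20_000):
    rng = np.random.default_rng(seed)
    return list(rng.choice(list("ACGT"), size=length))


class TestProjectCpg:
    def test_ungapped_plus_strand_offset_arithmetic(self):
        seq = "A" * 50
        aln = _ungapped(100, seq, seq)
        anchor = cp.CpgAnchor(49, "type_I_terminal")
        assert cp.project_cpg(aln, anchor) == (149, 151)

    def test_type_ii_extends_beyond_alignment(self):
        seq = "A" * 50
        aln = _ungapped(100, seq, seq)
        anchor = cp.CpgAnchor(cp.OUTSIDE_3PRIME, "type_II_adjacent")
        assert cp.project_cpg(aln, anchor) == (150, 152)

    def test_minus_strand_mirrors_coordinates(self):
        # plant a + strand window whose reverse complement is the probe;
        # the design CpG C (probe position 49) then sits at the window start
        seq = _planted_genome()
        ws = 5000
        seq[ws - 1], seq[ws] = "C", "G"
        genome = GenomeSequence(contigs={"c1": "".join(seq)})
        probe_seq = al.revcomp("".join(seq[ws:ws + 50]))
        (hit,) = al.align_probe(_probe(probe_seq, "I"), genome)
        assert hit.strand == "-"
        anchor = cp.locate_cpg(_probe(probe_seq, "I"))
        assert cp.project_cpg(hit, anchor, genome) == (ws - 1, ws + 1)
        ann = cp.classify_mismatches(hit, anchor, genome)
        assert ann.cpg_present and ann.category == "clean"

    def test_target_deletion_5prime_of_cpg_shifts_projection(self):
        # 2-bp deletion in the target 10 bp into the probe: the CpG C at
        # probe position 49 projects 2 bp left of the naive start+49
        probe = "A" * 50
        probe_aln = probe
        subject_aln = probe[:10] + "--" + probe[12:]
        aln = _ungapped(100, probe_aln, subject_aln)
        aln.end = 100 + 48
        anchor = cp.CpgAnchor(49, "type_I_terminal")
        assert cp.project_cpg(aln, anchor) == (147, 149)

    def test_cpg_inside_target_gap_returns_none(self):
        probe = "A" * 50
        subject_aln = probe[:49] + "-"  # the CpG C column is a target gap
        aln = _ungapped(100, probe, subject_aln)
        aln.end = 100 + 49
        anchor = cp.CpgAnchor(49, "type_I_terminal")
        assert cp.project_cpg(aln, anchor) is None

    def test_projection_off_contig_returns_none(self):
        seq = "A" * 50
        genome = GenomeSequence(contigs={"c1": "T" * 150})
        aln = _ungapped(100, seq, seq)
        anchor = cp.CpgAnchor(cp.OUTSIDE_3PRIME, "type_II_adjacent")
        assert cp.project_cpg(aln, anchor, genome) is None


class TestClassify:
    def _aligned_case(self, mutate_design_offsets, ptype="I", seed=21):
        """Plant a type-anchored CpG window, mutate the genome at the given
        design offsets from the CpG C, and return the classification."""
        seq = _planted_genome(seed)
        ws = 7000
        p_c = 49 if ptype == "I" else 50
        seq[ws + p_c], seq[ws + p_c + 1] = "C", "G"
        probe_seq = "".join(seq[ws:ws + 50])
        for delta in mutate_design_offsets:
            pos = ws + p_c + delta
            seq[pos] = {"A": "C", "C": "T", "G": "A", "T": "G"}[seq[pos]]
        genome = GenomeSequence(contigs={"c1": "".join(seq)})
        probe = _probe(probe_seq, ptype)
        hits = al.align_probe(probe, genome)
        assert hits, "planted probe must map"
        return cp.classify_mismatches(hits[0], cp.locate_cpg(probe), genome)

    def test_conserved_cg_no_mismatch_is_clean(self):
        ann = self._aligned_case([])
        assert ann.category == "clean" and ann.mismatch_offsets == []
        assert ann.cpg_present and not ann.cpg_mismatch and not ann.near_cpg_mismatch

    def test_single_mismatch_at_minus_one_is_near_cpg(self):
        ann = self._aligned_case([-1])
        assert ann.category == "near_cpg"
        assert ann.near_cpg_mismatch and not ann.cpg_mismatch
        assert ann.mismatch_offsets == [-1]

    def test_far_mismatch_stays_clean_category(self):
        ann = self._aligned_case([-5])
        assert ann.category == "clean" and ann.mismatch_offsets == [-5]

    def test_mismatch_at_cpg_c_is_at_cpg_even_when_trimmed(self):
        # a terminal CpG-C mismatch is trimmed by local alignment but must
        # still be localised via the soft-clipped flank comparison
        ann = self._aligned_case([0])
        assert ann.category == "at_cpg" and ann.cpg_mismatch
        assert 0 in ann.mismatch_offsets

    def test_lost_cpg_without_covered_mismatch_is_absent(self):
        ann = self._aligned_case([1], ptype="II")  # mutate the uncovered G
        assert ann.category == "cpg_absent"
        assert not ann.cpg_present and not ann.cpg_mismatch

    def test_category_partition_over_cohort(self, cohort, annotated):
        cats = {"clean", "near_cpg", "at_cpg", "cpg_absent"}
        mapped = [r for r in annotated if r.mapped]
        assert all(r.mismatch_category in cats for r in mapped)
        counts = sum(1 for r in mapped if r.mismatch_category in cats)
        assert counts == len(mapped)

    def test_offsets_agree_with_independent_column_walk(self):
        """Re-derive mismatch offsets from the gapped strings by a separate
        column walk for many planted alignments."""
        rng = np.random.default_rng(31)
        for trial in range(60):
            ptype = "I" if trial % 2 == 0 else "II"
            k = int(rng.integers(0, 4))
            p_c = 49 if ptype == "I" else 50
            deltas = sorted(
                int(d) for d in rng.choice(np.arange(-45, -2), size=k, replace=False)
            )
            ann = self._aligned_case(deltas, ptype=ptype, seed=100 + trial)
            assert ann.mismatch_offsets == deltas

    def test_strand_invariance_of_categories(self):
        seq = _planted_genome(55)
        ws = 3000
        seq[ws + 49], seq[ws + 50] = "C", "G"
        probe_seq = "".join(seq[ws:ws + 50])
        seq[ws + 48] = {"A": "C", "C": "T", "G": "A", "T": "G"}[seq[ws + 48]]
        fwd = GenomeSequence(contigs={"c1": "".join(seq)})
        rev = GenomeSequence(contigs={"c1": al.revcomp("".join(seq))})
        probe = _probe(probe_seq, "I")
        anchor = cp.locate_cpg(probe)
        ann_f = cp.classify_mismatches(al.align_probe(probe, fwd)[0], anchor, fwd)
        ann_r = cp.classify_mismatches(al.align_probe(probe, rev)[0], anchor, rev)
        assert ann_f.category == ann_r.category == "near_cpg"
        assert ann_f.mismatch_offsets == ann_r.mismatch_offsets
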