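"""Demultiplexing, bisulfite-aware alignment, filtering and genotyping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cryptdrift.amplicon import AmpliconSpec, convert_reference
from cryptdrift.readproc import (AlignParams, Alignment, align_read,
                                 apply_coverage_filter,
                                 check_conversion_controls, demultiplex,
                                 genotype_cpgs, process_reads, read_fastq,
                                 reverse_complement, write_fastq)

from conftest import oracle_align_score


@pytest.fixture(scope="module")
def toy_ref(toy_spec):
    return convert_reference(toy_spec)


class TestDemultiplex:
    SPEC = AmpliconSpec("d", "AACGTT", (2,), (),
                        barcode_map={"ACGT": "c1", "TTTT": "c2"})

    def run(self, seq, max_mismatch=0):
        return list(demultiplex([("r1", seq)], self.SPEC, max_mismatch))[0]

    def test_exact_match(self):
        assert self.run("ACGT" + "AATGTT") == ("c1", "r1", "AATGTT")

    def test_one_mismatch_tolerated(self):
        assert self.run("ACGA" + "AATGTT", max_mismatch=1)[0] == "c1"

    def test_mismatch_beyond_budget_unassigned(self):
        assert self.run("ACAA" + "AATGTT", max_mismatch=1)[0] is None

    def test_equidistant_tie_unassigned(self):
        spec = AmpliconSpec("d", "AACGTT", (2,), (),
                            barcode_map={"AAAA": "c1", "AATT": "c2"})
        # AATA is at distance 1 from both barcodes
        out = list(demultiplex([("r1", "AATA" + "AATGTT")], spec, 1))[0]
        assert out[0] is None


class TestAligner:
    def test_identity_read_scores_full(self, toy_spec, toy_ref):
        aln = align_read(toy_ref.converted_seq, toy_ref)
        assert aln.score == len(toy_ref.converted_seq)
        assert aln.ref_bases == toy_ref.converted_seq

    def test_cpg_c_t_equivalence(self, toy_spec, toy_ref):
        read = list(toy_ref.converted_seq)
        for p in toy_spec.cpg_positions:
            read[p] = "T"
        aln = align_read("".join(read), toy_ref)
        assert aln.score == len(toy_ref.converted_seq)

    def test_mismatch_costs_two(self, toy_ref):
        read = list(toy_ref.converted_seq)
        read[3] = "A" if read[3] != "A" else "G"
        aln = align_read("".join(read), toy_ref)
        assert aln.score == len(toy_ref.converted_seq) - 2

    @settings(derandomize=True, max_examples=120, deadline=None)
    @given(st.data())
    def test_matches_exhaustive_dp_oracle(self, data):
        """Optimality on random read/reference pairs (amplicons <= 25 bp)."""
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        m = int(rng.integers(8, 26))
        refseq = "".join(rng.choice(list("ACGT"), m))
        cpg = frozenset(i for i in range(m - 1)
                        if refseq[i] == "C" and refseq[i + 1] == "G")
        spec = AmpliconSpec("h", refseq, tuple(sorted(cpg)), ())
        ref = convert_reference(spec)
        L = int(rng.integers(max(1, m - 4), m + 5))
        read = "".join(rng.choice(list("ACGT"), L))
        aln = align_read(read, ref)
        assert aln.score == oracle_align_score(read, ref.converted_seq, cpg)

    def test_orientation_recovers_revcomp_insert(self, toy_spec, toy_ref):
        """A read whose insert is reverse-complemented is flipped back and
        genotyped identically to its forward twin."""
        spec = AmpliconSpec("d", toy_spec.reference_seq, toy_spec.cpg_positions,
                            toy_spec.control_positions, barcode_map={"AAAA": "s1"})
        fwd = toy_ref.converted_seq
        calls, ledger, _ = process_reads(
            [("f", "AAAA" + fwd), ("r", "AAAA" + reverse_complement(fwd))],
            spec, toy_ref)
        assert ledger.passed == 2
        assert set(calls["pattern"]) == {"M" * toy_spec.n_cpg}


class TestFilters:
    def test_full_coverage_true(self, toy_spec, toy_ref):
        aln = align_read(toy_ref.converted_seq, toy_ref)
        assert apply_coverage_filter(aln, toy_spec, "strict")

    def test_truncated_read_fails_strict(self, toy_spec, toy_ref):
        aln = align_read(toy_ref.converted_seq[:-5], toy_ref)
        assert not apply_coverage_filter(aln, toy_spec, "strict")

    def test_deletion_at_nonsite_passes_sites_only(self, toy_spec, toy_ref):
        # drop a base far from any CpG/control site
        seq = toy_ref.converted_seq
        read = seq[:17] + seq[18:]
        aln = align_read(read, toy_ref)
        assert not apply_coverage_filter(aln, toy_spec, "strict")
        assert apply_coverage_filter(aln, toy_spec, "sites-only")

    @pytest.mark.parametrize("base,ok", [("T", True), ("C", False), ("A", False)])
    def test_conversion_controls(self, toy_spec, toy_ref, base, ok):
        read = list(toy_ref.converted_seq)
        read[toy_spec.control_positions[0]] = base
        aln = align_read("".join(read), toy_ref)
        assert check_conversion_controls(aln, toy_spec) is ok


class TestGenotyping:
    def make_read(self, toy_spec, toy_ref, cpg_base):
        read = list(toy_ref.converted_seq)
        for p in toy_spec.cpg_positions:
            read[p] = cpg_base
        return "".join(read)

    def test_fully_methylated(self, toy_spec, toy_ref):
        aln = align_read(self.make_read(toy_spec, toy_ref, "C"), toy_ref)
        assert genotype_cpgs(aln, toy_spec).pattern == "M" * toy_spec.n_cpg

    def test_fully_unmethylated(self, toy_spec, toy_ref):
        aln = align_read(self.make_read(toy_spec, toy_ref, "T"), toy_ref)
        assert genotype_cpgs(aln, toy_spec).pattern == "U" * toy_spec.n_cpg

    def test_non_bisulfite_base_is_ambiguous(self, toy_spec, toy_ref):
        read = list(toy_ref.converted_seq)
        read[toy_spec.cpg_positions[1]] = "G"
        aln = align_read("".join(read), toy_ref)
        call = genotype_cpgs(aln, toy_spec)
        assert call.pattern == "" and call.n_ambiguous_sites == 1


class TestBatchEngine:
    def _spec(self, toy_spec):
        return AmpliconSpec("b", toy_spec.reference_seq, toy_spec.cpg_positions,
                            toy_spec.control_positions,
                            barcode_map={"AAAA": "s1", "CCCC": "s2"})

    def test_ledger_conservation_and_fates(self, toy_spec, toy_ref):
        spec = self._spec(toy_spec)
        conv = toy_ref.converted_seq
        meth = list(conv)
        bad_ctrl = list(conv)
        bad_ctrl[toy_spec.control_positions[0]] = "C"
        amb = list(conv)
        amb[toy_spec.cpg_positions[0]] = "G"
        reads = [
            ("r1", "AAAA" + conv),                  # pass
            ("r2", "CCCC" + "".join(meth)),         # pass
            ("r3", "GGGG" + conv),                  # unassigned
            ("r4", "AAAA" + "".join(bad_ctrl)),     # control fail
            ("r5", "AAAA" + "".join(amb)),          # ambiguous CpG
            ("r6", "AAAA" + conv[: len(conv) // 2]),  # too short
        ]
        calls, ledger, per_sample = process_reads(reads, spec, toy_ref)
        d = ledger.as_dict()
        assert d["total"] == 6 and d["passed"] == 2
        assert d["unassigned_barcode"] == 1
        assert d["failed_conversion_control"] == 1
        assert d["ambiguous_cpg"] == 1
        assert d["low_alignment_score"] == 1
        # reads mirror the fully-methylated converted reference
        assert set(calls["pattern"]) == {"M" * toy_spec.n_cpg}

    def test_batch_matches_single_read_path(self, toy_spec, toy_ref):
        """The vectorized engine and the reference single-read path call
        identical patterns on noisy substitution-only reads."""
        spec = self._spec(toy_spec)
        rng = np.random.default_rng(5)
        conv = toy_ref.converted_seq
        reads = []
        expected = {}
        for i in range(200):
            read = list(conv)
            for p in toy_spec.cpg_positions:  # random epiallele
                read[p] = "C" if rng.random() < 0.5 else "T"
            for _ in range(rng.integers(0, 3)):  # up to 2 substitutions
                j = int(rng.integers(len(read)))
                read[j] = "ACGT"[rng.integers(4)]
            seq = "".join(read)
            reads.append((f"r{i}", "AAAA" + seq))
            aln = align_read(seq, toy_ref)
            if (apply_coverage_filter(aln, toy_spec)
                    and check_conversion_controls(aln, toy_spec)):
                call = genotype_cpgs(aln, toy_spec)
                if call.pattern:
                    expected[f"r{i}"] = call.pattern
        calls, ledger, _ = process_reads(reads, spec, toy_ref)
        got = dict(zip(calls["read_id"], calls["pattern"]))
        assert got == expected

    def test_determinism(self, toy_spec, toy_ref):
        spec = self._spec(toy_spec)
        rng = np.random.default_rng(9)
        reads = [("r%d" % i,
                  "AAAA" + "".join(rng.choice(list("ACGT"),
                                              len(toy_ref.converted_seq))))
                 for i in range(100)]
        c1, l1, _ = process_reads(list(reads), spec, toy_ref)
        c2, l2, _ = process_reads(list(reads), spec, toy_ref)
        assert c1.equals(c2) and l1.as_dict() == l2.as_dict()


class TestFastqIO:
    def test_roundtrip(self, tmp_path):
        recs = [("a", "ACGT", "IIII"), ("b", "GGTT", "IIII")]
        p = tmp_path / "x.fastq"
        assert write_fastq(p, recs) == 2
        assert list(read_fastq(p)) == [("a", "ACGT"), ("b", "GGTT")]

    def test_gzip_roundtrip(self, tmp_path):
        p = tmp_path / "x.fastq.gz"
        write_fastq(p, [("a", "ACGT", "IIII")])
        assert list(read_fastq(p)) == [("a", "ACGT")]

    def test_corrupt_record_names_index(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@a\nACGT\n+\nIIII\nnot-a-header\nACGT\n+\nIIII\n")
        with pytest.raises(ValueError, match="index 1"):
            list(read_fastq(p))
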