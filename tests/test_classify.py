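"""Read mapping, SAM import, junction classification, orientation summary."""

import numpy as np
import pytest

from sscswitch import (
    ClassifyParams,
    ReferenceIndex,
    SimConfig,
    classify_junction_read,
    classify_reads,
    flip_ssc,
    import_alignments,
    map_read,
    simulate_genome,
    simulate_molecules,
    simulate_reads,
    summarize_orientation,
)


@pytest.fixture(scope="module")
def haplotypes():
    cfg = SimConfig(seed=77)
    genome, structure = simulate_genome(cfg)
    return genome, flip_ssc(genome, structure), structure


class TestMapRead:
    def test_exact_substring_single_block(self, haplotypes):
        ref, _, _ = haplotypes
        read = ref.seq[4000:5000]
        aln = map_read(read, ref, "r1")
        assert aln.aligned_read_fraction == 1.0
        assert aln.identity == 1.0
        assert len(aln.blocks) == 1
        assert aln.blocks[0] == ((0, 1000), (4000, 5000))

    def test_origin_crossing_read_stays_monotone(self, haplotypes):
        ref, _, _ = haplotypes
        read = ref.seq[-500:] + ref.seq[:500]
        aln = map_read(read, ref, "wrap")
        assert aln.aligned_read_fraction == 1.0
        assert len(aln.blocks) == 1

    def test_reverse_strand_read(self, haplotypes):
        ref, _, _ = haplotypes
        comp = str.maketrans("ACGT", "TGCA")
        read = ref.seq[2000:3500].translate(comp)[::-1]
        aln = map_read(read, ref, "rc")
        assert aln.strand == "-"
        assert aln.aligned_read_fraction == 1.0

    def test_junction_read_breaks_on_wrong_haplotype(self, haplotypes):
        """A read across IR1-ssc maps to the F haplotype only up to the junction."""
        ref_f, ref_r, structure = haplotypes
        s = structure.ir1[0]
        read = ref_r.seq[s - 400 : structure.ir1[1] + 400]  # LSC-IR1-ssc span
        aln_f = map_read(read, ref_f, "jr")
        aln_r = map_read(read, ref_r, "jr")
        assert aln_r.aligned_read_fraction == 1.0
        # on F only one side of the junction can map (either half, either
        # strand — both halves are 2400 bp), so the read fraction caps well
        # below the 90% criterion
        assert aln_f.aligned_read_fraction < 0.9
        assert classify_junction_read(aln_f, aln_r, structure).label == "reverse"

    def test_substitution_noise_identity(self, haplotypes):
        ref, _, _ = haplotypes
        rng = np.random.default_rng(13)
        frag = list(ref.seq[1000:3000])
        pos = rng.choice(2000, size=40, replace=False)  # 2% substitutions
        for p in pos:
            frag[p] = "ACGT"[(("ACGT".index(frag[p])) + 1) % 4]
        aln = map_read("".join(frag), ref, "noisy")
        assert aln.aligned_read_fraction > 0.95
        assert aln.identity >= 0.97

    def test_no_anchors_gives_empty_alignment(self, haplotypes):
        ref, _, _ = haplotypes
        aln = map_read("T" * 400, ref, "junk")
        assert aln.is_empty and aln.aligned_read_fraction == 0.0

    def test_deterministic(self, haplotypes):
        ref, _, _ = haplotypes
        read = ref.seq[6000:8500]
        assert map_read(read, ref, "d") == map_read(read, ref, "d")


SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:F\tLN:13200\n@SQ\tSN:R\tLN:13200\n"


def _write_sam(tmp_path, body, name="aln.sam"):
    p = tmp_path / name
    p.write_text(SAM_HEADER + body)
    return str(p)


class TestImportAlignments:
    def test_single_primary_record(self, tmp_path):
        body = "r1\t0\tF\t101\t60\t500M\t*\t0\t0\t" + "A" * 500 + "\t*\n"
        alns = import_alignments(_write_sam(tmp_path, body))
        assert len(alns) == 1
        a = alns[0]
        assert a.blocks == (((0, 500), (100, 600)),)
        assert a.aligned_read_fraction == 1.0

    def test_supplementary_merged(self, tmp_path):
        body = (
            "r1\t0\tF\t101\t60\t300M200S\t*\t0\t0\t" + "A" * 500 + "\t*\n"
            "r1\t2048\tF\t1001\t60\t300H200M\t*\t0\t0\t" + "A" * 200 + "\t*\n"
        )
        alns = import_alignments(_write_sam(tmp_path, body))
        assert len(alns) == 1
        a = alns[0]
        assert a.aligned_read_bases == 500
        assert a.aligned_read_fraction == 1.0
        assert len(a.blocks) == 2

    def test_clipping_reduces_aligned_fraction(self, tmp_path):
        body = "r1\t0\tF\t101\t60\t100S300M100S\t*\t0\t0\t" + "A" * 500 + "\t*\n"
        alns = import_alignments(_write_sam(tmp_path, body))
        assert alns[0].aligned_read_fraction == pytest.approx(300 / 500)

    def test_unknown_reference_dropped(self, tmp_path, caplog):
        body = (
            "r1\t0\tF\t101\t60\t100M\t*\t0\t0\t" + "A" * 100 + "\t*\n"
            "r2\t0\tR\t101\t60\t100M\t*\t0\t0\t" + "A" * 100 + "\t*\n"
        )
        alns = import_alignments(_write_sam(tmp_path, body), ref_names={"F"})
        assert [a.read_id for a in alns] == ["r1"]

    def test_indel_cigar_block_structure(self, tmp_path):
        body = "r1\t0\tF\t101\t60\t100M5D100M3I100M\t*\t0\t0\t" + "A" * 303 + "\t*\n"
        a = import_alignments(_write_sam(tmp_path, body))[0]
        assert a.aligned_read_bases == 300
        assert len(a.blocks) == 3


class TestClassifyJunctionRead:
    def _read_call(self, haplotypes, read, params=None):
        ref_f, ref_r, structure = haplotypes
        aln_f = map_read(read, ref_f, "q")
        aln_r = map_read(read, ref_r, "q")
        return classify_junction_read(aln_f, aln_r, structure, params)

    def test_spanning_read_forward(self, haplotypes):
        ref_f, _, st_ = haplotypes
        read = ref_f.seq[st_.ir1[0] - 300 : st_.ir1[1] + 300]
        assert self._read_call(haplotypes, read).label == "forward"

    def test_spanning_read_reverse(self, haplotypes):
        _, ref_r, st_ = haplotypes
        read = ref_r.seq[st_.ir1[0] - 300 : st_.ir1[1] + 300]
        assert self._read_call(haplotypes, read).label == "reverse"

    def test_short_overhang_rejected(self, haplotypes):
        ref_f, _, st_ = haplotypes
        read = ref_f.seq[st_.ir1[0] - 300 : st_.ir1[1] + 150]
        call = self._read_call(haplotypes, read)
        assert call.label == "non_junction"
        assert call.right_overhang < 200

    def test_read_inside_ir_rejected(self, haplotypes):
        ref_f, _, st_ = haplotypes
        read = ref_f.seq[st_.ir1[0] + 100 : st_.ir1[1] - 100]
        call = self._read_call(haplotypes, read)
        assert call.label == "non_junction"
        assert call.left_overhang == 0 and call.right_overhang == 0

    def test_read_length_prefilter(self, haplotypes):
        ref_f, _, st_ = haplotypes
        read = ref_f.seq[st_.ir1[0] - 300 : st_.ir1[1] + 300]
        call = self._read_call(haplotypes, read, ClassifyParams(min_read_len=20_000))
        assert call.label == "non_junction"

    def test_mismatched_read_ids_rejected(self, haplotypes):
        ref_f, ref_r, st_ = haplotypes
        a = map_read(ref_f.seq[:1000], ref_f, "x")
        b = map_read(ref_f.seq[:1000], ref_r, "y")
        with pytest.raises(ValueError):
            classify_junction_read(a, b, st_)


@pytest.fixture(scope="module")
def simulated_calls():
    cfg = SimConfig(n_reads=400, n_molecules=150, seed=21)
    genome, structure = simulate_genome(cfg)
    molecules = simulate_molecules(genome, structure, cfg)
    reads = simulate_reads(molecules, cfg)
    ref_r = flip_ssc(genome, structure)
    calls = classify_reads(
        [(r.read_id, r.seq) for r in reads], genome, ref_r, structure
    )
    provenance = {r.read_id: r.orientation for r in reads}
    return cfg, genome, ref_r, structure, reads, calls, provenance


class TestPipelineProperties:
    def test_error_free_classification_is_exact(self, simulated_calls):
        *_, calls, provenance = simulated_calls
        classified = [c for c in calls if c.label in ("forward", "reverse")]
        assert classified, "no junction reads simulated"
        for c in classified:
            assert (c.label == "forward") == (provenance[c.read_id] == "F")
        assert sum(c.label == "ambiguous" for c in calls) == 0

    def test_raising_overhang_threshold_is_monotone(self, simulated_calls):
        _, genome, ref_r, structure, reads, _, _ = simulated_calls
        pairs = [(r.read_id, r.seq) for r in reads]
        counts = []
        for overhang in (100, 200, 400, 800):
            calls = classify_reads(
                pairs, genome, ref_r, structure,
                ClassifyParams(min_overhang=overhang),
            )
            rep = summarize_orientation(calls)
            counts.append(rep.n_classified)
        assert counts == sorted(counts, reverse=True)


class TestSummarize:
    def test_published_count_example(self):
        rep = summarize_orientation(counts=(82, 99))
        assert rep.prop_forward == pytest.approx(82 / 181)
        assert round(rep.prop_forward, 2) == 0.45
        assert round(rep.prop_reverse, 2) == 0.55
        assert rep.ratio_printed == 0.82
        assert rep.ratio == pytest.approx(82 / 99)
        assert rep.ci_low < 82 / 181 < rep.ci_high

    def test_symmetric_counts(self):
        rep = summarize_orientation(counts=(50, 50))
        assert rep.ratio_printed == 1.0
        assert rep.ci_low < 0.5 < rep.ci_high
        assert rep.ci_low + rep.ci_high == pytest.approx(1.0, abs=1e-6)

    def test_empty_counts_are_undefined_not_fatal(self):
        rep = summarize_orientation(counts=(0, 0))
        assert rep.prop_forward is None and rep.ratio is None
        assert rep.n_classified == 0

    def test_one_sided_counts(self):
        rep = summarize_orientation(counts=(10, 0))
        assert rep.prop_forward == 1.0
        assert rep.ratio is None
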