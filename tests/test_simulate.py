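import numpy as np
import pytest
from Bio.Seq import reverse_complement

from karyograph import simulate
from karyograph.simulate import (
    SyntheticTruth,
    emit_hic_links,
    emit_read_alignments,
    emit_truth_alignments,
    fragment_layer,
    inject_chimeras,
    sample_reads,
    simulate_genome,
)


class TestSimulateGenome:
    def test_requested_lengths(self):
        truth = simulate_genome(2, [1_000_000, 2_000_000], seed=0)
        assert len(truth.chromosomes["chr1"]) == 1_000_000
        assert len(truth.chromosomes["chr2"]) == 2_000_000

    def test_deterministic_per_seed(self):
        a = simulate_genome(2, [100_000, 50_000], seed=9)
        b = simulate_genome(2, [100_000, 50_000], seed=9)
        c = simulate_genome(2, [100_000, 50_000], seed=10)
        assert a.chromosomes == b.chromosomes
        assert a.chromosomes != c.chromosomes

    def test_telomere_arrays_at_ends(self):
        truth = simulate_genome(1, [200_000], telomere_motif="TTAGGC",
                                telomere_copies=100, seed=1)
        seq = truth.chromosomes["chr1"]
        assert seq.startswith("TTAGGC" * 100)
        assert seq.endswith("TTAGGC" * 100)

    def test_repeat_copy_divergence(self):
        """Two copies at divergence d differ at ~2d(1 - 2d/3)-ish of sites;
        at d=0.05 pairwise identity lands near 0.90 within sampling error."""
        spec = {"length": 5_000, "copies": 20, "divergence": 0.05}
        truth = simulate_genome(2, [500_000, 400_000], repeat_spec=spec, seed=2)
        assert len(truth.repeats) == 20
        copies = [
            truth.chromosomes[c][s:e] for c, s, e, _ in truth.repeats
        ]
        rng = np.random.default_rng(0)
        diffs = []
        for _ in range(30):
            i, j = rng.choice(len(copies), size=2, replace=False)
            a, b = copies[i], copies[j]
            diffs.append(sum(x != y for x, y in zip(a, b)) / len(a))
        mean_div = float(np.mean(diffs))
        # expected pairwise difference: 2d minus coincident-site corrections
        assert 0.06 <= mean_div <= 0.13
        assert 1 - mean_div == pytest.approx(0.90, abs=0.035)

    def test_repeat_longer_than_chromosome_rejected(self):
        with pytest.raises(ValueError, match="repeat"):
            simulate_genome(
                1, [50_000],
                repeat_spec={"length": 60_000, "copies": 1, "divergence": 0},
                telomere_copies=10, seed=0,
            )


class TestFragmentLayer:
    def test_giant_n50_single_contig_per_chromosome(self):
        truth = simulate_genome(2, [300_000, 200_000], seed=3)
        contigs = fragment_layer(truth, "A", n50_target=10_000_000, seed=4)
        assert len(contigs) == 2

    def test_total_bases_at_least_genome(self):
        truth = simulate_genome(2, [900_000, 600_000], seed=5)
        fragment_layer(truth, "A", 200_000, overlap=20_000, seed=6)
        assert sum(truth.layer_lengths("A").values()) >= truth.genome_size()

    def test_seeds_give_distinct_breakpoints(self):
        truth = simulate_genome(1, [900_000], seed=5)
        a = fragment_layer(truth, "A", 200_000, seed=6)
        b = fragment_layer(truth, "B", 200_000, seed=7)
        ends_a = sorted(s.end for segs in a.values() for s in segs)
        ends_b = sorted(s.end for segs in b.values() for s in segs)
        assert ends_a != ends_b

    def test_contig_sequences_reconstruct(self):
        truth = simulate_genome(1, [500_000], seed=8)
        fragment_layer(truth, "A", 150_000, seed=9, rc_prob=0.5)
        for name, (seg,) in truth.layers["A"].items():
            seq = truth.contig_sequence("A", name)
            ref = truth.chromosomes[seg.chrom][seg.start:seg.end]
            assert seq == (reverse_complement(ref) if seg.strand == "-" else ref)


class TestInjectChimeras:
    def _fragmented(self):
        truth = simulate_genome(2, [800_000, 600_000], seed=10)
        fragment_layer(truth, "A", 250_000, seed=11)
        return truth

    def test_empty_plan_noop(self):
        truth = self._fragmented()
        before = dict(truth.layers["A"])
        inject_chimeras(truth, "A", [])
        assert truth.layers["A"] == before
        assert truth.chimera_junctions == []

    def test_junction_recorded_and_sequence_spliced(self):
        truth = self._fragmented()
        pos_a = simulate._mid_fragment_position(truth, "A", "chr1")
        pos_b = simulate._mid_fragment_position(truth, "A", "chr2")
        inject_chimeras(truth, "A", [("chr1", pos_a, "chr2", pos_b)])
        assert len(truth.chimera_junctions) == 1
        layer, contig, junction, donors = truth.chimera_junctions[0]
        assert donors == ("chr1", "chr2")
        seq = truth.contig_sequence("A", contig)
        assert seq[:junction] == truth.chromosomes["chr1"][pos_a - junction:pos_a]
        assert seq[junction:junction + 1_000] == truth.chromosomes["chr2"][pos_b:pos_b + 1_000]

    def test_absent_fragment_rejected(self):
        truth = self._fragmented()
        with pytest.raises(KeyError):
            inject_chimeras(truth, "A", [("chr9", 100, "chr1", 300_000)])


class TestSampleReads:
    def test_coverage_accounting(self):
        truth = simulate_genome(2, [2_000_000, 1_000_000], seed=12)
        sample_reads(truth, coverage=10, seed=13)
        total = sum(len(s) for s in truth.reads.values())
        assert total == pytest.approx(10 * truth.genome_size(), rel=0.05)

    def test_error_free_reads_are_substrings(self):
        truth = simulate_genome(1, [300_000], seed=14)
        sample_reads(truth, coverage=2, error_rate=0.0, seed=15)
        for rid, seq in list(truth.reads.items())[:50]:
            seg = truth.read_origins[rid]
            ref = truth.chromosomes[seg.chrom][seg.start:seg.end]
            assert seq == (reverse_complement(ref) if seg.strand == "-" else ref)

    def test_seed_reproducibility(self):
        t1 = simulate_genome(1, [300_000], seed=14)
        sample_reads(t1, coverage=2, seed=15)
        t2 = simulate_genome(1, [300_000], seed=14)
        sample_reads(t2, coverage=2, seed=15)
        assert t1.reads == t2.reads


class TestEmitTruthAlignments:
    def test_identical_layers_only_mergeable_geometry(self):
        from karyograph.alignio import classify_merge

        truth = simulate_genome(1, [900_000], seed=16)
        fragment_layer(truth, "A", 250_000, seed=17)
        truth.layers["B"] = {
            n.replace("A_", "B_", 1): segs for n, segs in truth.layers["A"].items()
        }
        alns = emit_truth_alignments(truth, [("A", "B")])[("A", "B")]
        assert alns
        for r in alns:
            assert classify_merge(r).label in ("contained", "containing", "dovetail")

    def test_chimera_induces_conflict_at_junction(self):
        from karyograph.alignio import classify_merge

        truth = simulate_genome(2, [900_000, 700_000], seed=18)
        fragment_layer(truth, "A", 250_000, seed=19)
        fragment_layer(truth, "B", 300_000, seed=20)
        pos_a = simulate._mid_fragment_position(truth, "A", "chr1")
        pos_b = simulate._mid_fragment_position(truth, "A", "chr2")
        inject_chimeras(truth, "A", [("chr1", pos_a, "chr2", pos_b)])
        layer, contig, junction, _ = truth.chimera_junctions[0]
        alns = emit_truth_alignments(truth, [("B", "A")])[("B", "A")]
        conflicts = [
            classify_merge(r)
            for r in alns
            if r.target_name == contig and classify_merge(r).label == "internal_conflict"
        ]
        assert conflicts
        for mc in conflicts:
            assert any(abs(bp - junction) <= 1 for bp in mc.conflict_breakpoints)

    def test_contained_read_single_record(self):
        truth = simulate_genome(1, [600_000], seed=21)
        fragment_layer(truth, "A", 10_000_000, seed=22)  # one contig
        sample_reads(truth, coverage=0.2, seed=23)
        alns = emit_read_alignments(truth, "A")
        per_read = {}
        for r in alns:
            per_read[r.query_name] = per_read.get(r.query_name, 0) + 1
        assert per_read and all(v == 1 for v in per_read.values())

    def test_alignment_coordinates_reproduce_sequence(self, fx):
        """Emitted records are mutually consistent with the truth sequences:
        the aligned substrings are identical (identity 1 fixtures)."""
        truth = fx.truth
        (q, t), recs = next(iter(fx.reciprocal_alignments.items()))
        qf = truth.layer_fasta(q)
        tf = truth.layer_fasta(t)
        for r in recs[:25]:
            qs = qf[r.query_name][r.query_start:r.query_end]
            ts = tf[r.target_name][r.target_start:r.target_end]
            if r.strand == "-":
                ts = reverse_complement(ts)
            assert qs == ts


class TestEmitHicLinks:
    def test_zero_trans_rate_all_cis(self):
        truth = simulate_genome(3, [500_000, 400_000, 300_000], seed=24)
        fragment_layer(truth, "A", 120_000, seed=25)
        links = emit_hic_links(truth, "A", cis_rate=1.0, trans_rate=0.0,
                               n_pairs=500, seed=26)
        chrom_of = {c: segs[0].chrom for c, segs in truth.layers["A"].items()}
        assert links
        for a, b, ev, count in links:
            assert ev == "hic" and count >= 1
            assert chrom_of[a] == chrom_of[b]

    def test_cis_fraction_near_expected(self):
        truth = simulate_genome(3, [500_000, 400_000, 300_000], seed=27)
        fragment_layer(truth, "A", 120_000, seed=28)
        links = emit_hic_links(truth, "A", cis_rate=0.7, trans_rate=0.3,
                               n_pairs=4_000, seed=29)
        chrom_of = {c: segs[0].chrom for c, segs in truth.layers["A"].items()}
        cis = sum(c for a, b, _, c in links if chrom_of[a] == chrom_of[b])
        total = sum(c for *_, c in links)
        # binomial check at ~3 sigma; note same-contig cis pairs are not
        # emitted as links, which biases the observed fraction downward
        assert cis / total == pytest.approx(0.7, abs=0.12)

    def test_seed_reproducibility(self):
        truth = simulate_genome(2, [400_000, 300_000], seed=30)
        fragment_layer(truth, "A", 120_000, seed=31)
        l1 = emit_hic_links(truth, "A", n_pairs=300, seed=32)
        l2 = emit_hic_links(truth, "A", n_pairs=300, seed=32)
        assert l1 == l2


class TestTruthSerialization:
    def test_roundtrip(self, tmp_path):
        truth = simulate_genome(2, [400_000, 300_000], seed=33)
        fragment_layer(truth, "A", 150_000, seed=34)
        pos_a = simulate._mid_fragment_position(truth, "A", "chr1")
        pos_b = simulate._mid_fragment_position(truth, "A", "chr2")
        inject_chimeras(truth, "A", [("chr1", pos_a, "chr2", pos_b)])
        sample_reads(truth, coverage=0.5, seed=35)
        truth.to_dir(tmp_path / "truth")
        back = SyntheticTruth.from_dir(tmp_path / "truth")
        assert back.chromosomes == truth.chromosomes
        assert back.layers == truth.layers
        assert back.chimera_junctions == truth.chimera_junctions
        assert back.reads == truth.reads
        assert back.seed == truth.seed
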