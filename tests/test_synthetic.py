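import numpy as np
import pytest
from scipy.stats import chisquare

from virosift import seqio, synthetic
from virosift.synthetic import SignatureModel, default_models, simulate_contigs, simulate_reads


class TestSignatureModel:
    def test_defaults_are_valid(self):
        for model in default_models().values():
            assert abs(sum(model.size_pmf.values()) - 1.0) < 1e-9
            assert all(15 <= s <= 35 for s in model.size_pmf)
            assert 0.0 <= model.positive_strand_fraction <= 1.0

    def test_rejects_bad_pmf(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SignatureModel("x", {21: 0.5}, 0.5)
        with pytest.raises(ValueError, match="keys"):
            SignatureModel("x", {40: 1.0}, 0.5)
        with pytest.raises(ValueError, match="strand_fraction"):
            SignatureModel("x", {21: 1.0}, 1.5)


class TestSimulateContigs:
    def test_empty(self):
        contigs, truth = simulate_contigs({"sirna": 0, "pirna": 0}, seed=1)
        assert contigs == [] and truth == []

    def test_determinism(self, tmp_path):
        out = []
        for _ in range(2):
            contigs, truth = simulate_contigs({"sirna": 3}, seed=5)
            path = tmp_path / "c.fasta"
            seqio.write_fasta(path, contigs)
            out.append(path.read_bytes())
        assert out[0] == out[1]

    def test_counts_per_class(self):
        contigs, truth = simulate_contigs({"sirna": 20, "pirna": 20, "degradation": 20}, seed=2)
        assert len(contigs) == 60
        per_class = {}
        for t in truth:
            per_class[t.true_class] = per_class.get(t.true_class, 0) + 1
        assert per_class == {"sirna": 20, "pirna": 20, "degradation": 20}

    def test_every_contig_has_one_truth_record(self):
        contigs, truth = simulate_contigs({"sirna": 5, "degradation": 3}, seed=3)
        assert sorted(c.id for c in contigs) == sorted(t.contig_id for t in truth)

    def test_lengths_within_range(self):
        contigs, _ = simulate_contigs({"sirna": 30}, length_range=(501, 600), seed=4)
        assert all(501 <= c.length <= 600 for c in contigs)

    @pytest.mark.parametrize(
        "kwargs", [{"length_range": (100, 600)}, {"length_range": (600, 500)}, {"gc": 0.0}, {"gc": 1.2}]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            simulate_contigs({"sirna": 1}, seed=1, **kwargs)

    def test_gc_content_tracks_parameter(self):
        contigs, _ = simulate_contigs({"sirna": 5}, length_range=(2000, 3000), gc=0.7, seed=6)
        seq = "".join(c.sequence for c in contigs)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.7) < 0.02


class TestSimulateReads:
    def test_degenerate_pmf_gives_single_length(self):
        contigs, truth = simulate_contigs({"sirna": 2}, seed=1)
        model = SignatureModel("sirna", {21: 1.0}, 0.5, reads_per_contig=500)
        reads, aln = simulate_reads(contigs, truth, {"sirna": model}, seed=2)
        assert all(len(r.sequence) == 21 for r in reads)
        assert all(a.read_length == 21 for a in aln)

    def test_strand_fraction_boundary(self):
        contigs, truth = simulate_contigs({"sirna": 2}, seed=1)
        model = SignatureModel("sirna", {21: 1.0}, 1.0, reads_per_contig=300)
        _, aln = simulate_reads(contigs, truth, {"sirna": model}, seed=2)
        assert all(a.strand == "+" for a in aln)

    def test_read_sequence_matches_contig_substring(self):
        contigs, truth = simulate_contigs({"pirna": 2}, seed=3)
        models = default_models(reads_per_contig=200)
        reads, aln = simulate_reads(contigs, truth, models, seed=4)
        by_id = {c.id: c for c in contigs}
        read_seq = {r.id: r.sequence for r in reads}
        for a in aln:
            sub = by_id[a.contig_id].sequence[a.start : a.start + a.read_length]
            expected = sub if a.strand == "+" else seqio.reverse_complement(sub)
            assert read_seq[a.read_id] == expected

    def test_missing_model_rejected(self):
        contigs, truth = simulate_contigs({"sirna": 1}, seed=1)
        with pytest.raises(ValueError, match="no signature model"):
            simulate_reads(contigs, truth, {"pirna": default_models()["pirna"]}, seed=1)

    def test_size_histogram_goodness_of_fit(self):
        # sampler distribution check: n=10000 draws vs the pirna pmf, alpha=0.01
        contigs, truth = simulate_contigs({"pirna": 1}, length_range=(2000, 2000), seed=5)
        model = SignatureModel("pirna", default_models()["pirna"].size_pmf, 0.1, reads_per_contig=10000)
        _, aln = simulate_reads(contigs, truth, {"pirna": model}, seed=6)
        sizes, probs = model.sizes_and_probs()
        observed = np.array([sum(a.read_length == s for a in aln) for s in sizes])
        _, p = chisquare(observed, probs * len(aln))
        assert p > 0.01

    def test_strand_fraction_converges(self):
        contigs, truth = simulate_contigs({"pirna": 1}, seed=7)
        model = SignatureModel("pirna", {25: 1.0}, 0.3, reads_per_contig=5000)
        _, aln = simulate_reads(contigs, truth, {"pirna": model}, seed=8)
        frac = sum(a.strand == "+" for a in aln) / len(aln)
        n, p = len(aln), 0.3
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_determinism(self):
        contigs, truth = simulate_contigs({"sirna": 2}, seed=9)
        models = default_models(reads_per_contig=100)
        first = simulate_reads(contigs, truth, models, seed=10)
        second = simulate_reads(contigs, truth, models, seed=10)
        assert first == second

    def test_error_rate_marks_mismatches(self):
        contigs, truth = simulate_contigs({"sirna": 1}, seed=11)
        models = default_models(reads_per_contig=2000)
        _, aln = simulate_reads(contigs, truth, models, seed=12, error_rate=0.02)
        total_mm = sum(a.mismatches for a in aln)
        total_bases = sum(a.read_length for a in aln)
        assert 0.01 < total_mm / total_bases < 0.04


class TestWriteFixture:
    def test_round_trip_counts(self, tmp_path, small_fixture):
        contigs, truth, reads, alignments = small_fixture
        paths = synthetic.write_fixture(tmp_path / "fx", contigs, reads, alignments, truth)
        assert len(seqio.read_fasta(paths["contigs"])) == len(contigs)
        assert len(seqio.read_fastq(paths["reads"])) == len(reads)
        assert len(seqio.read_alignments(paths["alignments_tsv"])) == len(alignments)
        assert len(synthetic.read_truth_table(paths["truth"])) == len(truth)

    def test_sam_strand_flags_agree_with_truth(self, tmp_path, small_fixture):
        contigs, truth, reads, alignments = small_fixture
        paths = synthetic.write_fixture(tmp_path / "fx", contigs, reads, alignments, truth)
        from_sam = seqio.read_alignments(paths["alignments_sam"], contigs=contigs)
        strand_truth = {a.read_id: a.strand for a in alignments}
        assert len(from_sam) == len(alignments)
        for a in from_sam:
            assert a.strand == strand_truth[a.read_id]

    def test_empty_simulation_writes_valid_files(self, tmp_path):
        paths = synthetic.write_fixture(tmp_path / "fx", [], [], [], [])
        assert seqio.read_fasta(paths["contigs"]) == []
        assert seqio.read_alignments(paths["alignments_tsv"]) == []
        assert synthetic.read_truth_table(paths["truth"]) == []
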