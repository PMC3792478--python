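import dataclasses

import pytest
from helpers import random_sequence

from smdscan import io_formats as io
from smdscan import junction_detect as jd
from smdscan import synthetic_data as sd
from smdscan.pipeline import call_junctions


def aln(read_id, pos, cigar, chrom="chr1"):
    return io.AlignmentRecord(read_id, chrom, pos, cigar)


@pytest.fixture()
def flat_genome(rng):
    return io.GenomeSequence({"chr1": random_sequence(rng, 2000)})


class TestExtractJunctions:
    def test_skip_coordinate_arithmetic(self, flat_genome):
        reads = [aln("r1", 101, [("M", 20), ("N", 100), ("M", 20)])]
        (j,) = jd.extract_junctions(reads, flat_genome)
        assert (j.start, j.end, j.support) == (121, 220, 1)

    def test_same_intron_aggregates_support(self, flat_genome):
        reads = [
            aln("r1", 101, [("M", 20), ("N", 100), ("M", 20)]),
            aln("r2", 91, [("M", 30), ("N", 100), ("M", 10)]),
        ]
        (j,) = jd.extract_junctions(reads, flat_genome)
        assert j.support == 2

    def test_generator_truth_exact_recovery(self, default_config):
        """Noise-free simulated reads recover the planted intron set with
        sensitivity and precision 1.0 at the requested supports."""
        cfg = dataclasses.replace(default_config, noise_free=True)
        genome, genes, truth = sd.generate_genome(cfg)
        reads = sd.simulate_spliced_alignments(cfg, truth, genes)["wt"]
        junctions = jd.extract_junctions(reads, genome)
        got = {(j.start, j.end): j.support for j in junctions}
        expected = {}
        for t in truth.genes.values():
            if t.intron_g is None:
                continue
            depth = (
                cfg.annotated_junction_depth if t.intronic
                else cfg.smd_junction_depth_wt
            )
            expected[t.intron_g] = int(round(depth))
        assert got == expected


class TestFilterCanonical:
    def make_world(self, intron_seq_ends, strand="+"):
        """One 600-nt gene with a 100-nt intron with chosen terminal bases."""
        rng_seq = list(random_sequence(__import__("numpy").random.default_rng(3), 600))
        start, end = 201, 300
        (d1, d2), (a1, a2) = intron_seq_ends
        if strand == "+":
            rng_seq[start - 1], rng_seq[start] = d1, d2
            rng_seq[end - 2], rng_seq[end - 1] = a1, a2
        else:
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            rng_seq[end - 1], rng_seq[end - 2] = comp[d1], comp[d2]
            rng_seq[start], rng_seq[start - 1] = comp[a1], comp[a2]
        genome = io.GenomeSequence({"chr1": "".join(rng_seq)})
        genes = {"g1": io.GeneModel("g1", "chr1", strand, 1, 600, 1, 600)}
        reads = [
            aln(f"r{i}", 181, [("M", 20), ("N", 100), ("M", 20)]) for i in range(3)
        ]
        return genome, genes, jd.extract_junctions(reads, genome)

    def test_gt_ag_kept(self):
        genome, genes, junctions = self.make_world((("G", "T"), ("A", "G")))
        kept = jd.filter_canonical(junctions, genome, genes, min_support=2)
        assert len(kept) == 1 and kept[0].canonical

    def test_gc_ag_dropped(self):
        genome, genes, junctions = self.make_world((("G", "C"), ("A", "G")))
        assert jd.filter_canonical(junctions, genome, genes, 2) == []

    def test_minus_strand_orientation(self):
        genome, genes, junctions = self.make_world((("G", "T"), ("A", "G")), strand="-")
        kept = jd.filter_canonical(junctions, genome, genes, 2)
        assert len(kept) == 1
        assert (kept[0].donor, kept[0].acceptor) == ("GT", "AG")

    def test_min_support_threshold(self):
        genome, genes, junctions = self.make_world((("G", "T"), ("A", "G")))
        low = [dataclasses.replace(junctions[0], support=1)]
        assert jd.filter_canonical(low, genome, genes, min_support=2) == []

    def test_support_never_increases(self):
        genome, genes, junctions = self.make_world((("G", "T"), ("A", "G")))
        kept = jd.filter_canonical(junctions, genome, genes, 2)
        assert all(k.support == j.support for k, j in zip(kept, junctions))


class TestClassifyJunctions:
    def test_statuses_on_generator_output(self, default_config):
        cfg = dataclasses.replace(default_config, noise_free=True)
        genome, genes, truth = sd.generate_genome(cfg)
        reads = sd.simulate_spliced_alignments(cfg, truth, genes)["rrp6"]
        raw = jd.extract_junctions(reads, genome)
        kept = jd.filter_canonical(raw, genome, genes, 2)
        classified, stats = jd.classify_junctions(kept, genes)
        statuses = {j.status for j in classified}
        assert statuses <= {"annotated", "novel_in_intronless"}
        annotated_hosts = {j.host_gene for j in classified if j.status == "annotated"}
        novel_hosts = {j.host_gene for j in classified if j.status == "novel_in_intronless"}
        assert annotated_hosts == truth.intronic_genes
        assert novel_hosts == truth.smd_genes
        # 10 of 80 intronless genes carry spliced reads -> 12.5%
        assert stats["pct_intronless_with_canonical_junction"] == pytest.approx(12.5)
        assert stats["pct_intronic_with_annotated_junction"] == pytest.approx(100.0)

    def test_statuses_are_exhaustive_and_exclusive(self, default_config):
        cfg = dataclasses.replace(default_config, noise_free=True)
        genome, genes, truth = sd.generate_genome(cfg)
        reads = sd.simulate_spliced_alignments(cfg, truth, genes)["wt"]
        raw = jd.extract_junctions(reads, genome)
        kept = jd.filter_canonical(raw, genome, genes, 1)
        classified, _ = jd.classify_junctions(kept, genes)
        for j in classified:
            assert j.status in {
                "annotated", "novel_in_intronic", "novel_in_intronless", "intergenic"
            }


class TestBpWithinIntron:
    def test_planted_bp_distance(self, default_config):
        cfg = dataclasses.replace(default_config, noise_free=True)
        genome, genes, truth = sd.generate_genome(cfg)
        reads = sd.simulate_spliced_alignments(cfg, truth, genes)["rrp6"]
        kept = jd.filter_canonical(
            jd.extract_junctions(reads, genome), genome, genes, 2
        )
        checked = 0
        for j in kept:
            flagged = jd.bp_within_intron(j, genome, genes)
            t = truth.genes[j.host_gene]
            assert flagged.bp_in_intron
            assert flagged.bp_to_acceptor == t.acceptor - t.bp
            checked += 1
        assert checked > 0

    def test_intron_without_bp(self, flat_genome):
        # force a GT..AG intron with no BP literal inside
        seq = list(flat_genome.chromosomes["chr1"])
        s = "".join(seq)
        s = s.replace("ACTAAC", "ACCAAC")
        seq = list(s)
        seq[200], seq[201] = "G", "T"
        seq[298], seq[299] = "A", "G"
        genome = io.GenomeSequence({"chr1": "".join(seq)})
        genes = {"g1": io.GeneModel("g1", "chr1", "+", 1, 600, 1, 600)}
        reads = [aln(f"r{i}", 181, [("M", 20), ("N", 100), ("M", 20)]) for i in range(2)]
        (j,) = jd.filter_canonical(jd.extract_junctions(reads, genome), genome, genes, 2)
        flagged = jd.bp_within_intron(j, genome, genes)
        assert not flagged.bp_in_intron and flagged.bp_to_acceptor is None

    def test_bp_just_outside_intron_not_counted(self):
        # BP literal ends 1 nt upstream of the intron start
        base = list("C" * 600)
        base[193:200] = "ACTAACA"  # positions 194..200, intron starts at 201
        base[200], base[201] = "G", "T"
        base[298], base[299] = "A", "G"
        genome = io.GenomeSequence({"chr1": "".join(base)})
        genes = {"g1": io.GeneModel("g1", "chr1", "+", 1, 600, 1, 600)}
        reads = [aln(f"r{i}", 181, [("M", 20), ("N", 100), ("M", 20)]) for i in range(2)]
        (j,) = jd.filter_canonical(jd.extract_junctions(reads, genome), genome, genes, 2)
        assert (j.start, j.end) == (201, 300)
        assert not jd.bp_within_intron(j, genome, genes).bp_in_intron


class TestRrp6Contrast:
    def test_stabilized_condition_finds_more_intronless_junctions(self, toy_world, default_config):
        genome, genes, truth = toy_world
        alignments = sd.simulate_spliced_alignments(default_config, truth, genes)
        fractions = {}
        for cond in ("wt", "rrp6"):
            _, stats = call_junctions(alignments[cond], genome, genes)
            fractions[cond] = stats["pct_intronless_with_canonical_junction"]
        assert fractions["rrp6"] > fractions["wt"]
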