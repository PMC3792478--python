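import numpy as np
import pytest
from helpers import (
    brute_force_nearest_ag,
    codon_walk_translate,
    make_spliced_gene,
    random_sequence,
)

from smdscan import io_formats as io
from smdscan import motif_scan as ms
from smdscan import splice_model as sp


@pytest.fixture()
def bdf2_profile(bdf2):
    transcript, gene, truth, genome = bdf2
    _, coords = io.transcript_sequence(genome, gene)
    return transcript, ms.call_splice_signals(gene, transcript, coords)


class TestPairBpToAcceptors:
    def test_distal_bp_pairs_at_twelve_nt(self, bdf2_profile):
        _, profile = bdf2_profile
        pairings = {p.bp: p for p in sp.pair_bp_to_acceptors(profile)}
        assert pairings[1660].acceptor == 1672
        assert pairings[1660].spacing == 12
        assert pairings[1660].feasible_two_step

    def test_proximal_bp_is_far_from_any_acceptor(self, bdf2_profile):
        _, profile = bdf2_profile
        pairings = {p.bp: p for p in sp.pair_bp_to_acceptors(profile)}
        assert pairings[254].acceptor == 1672
        assert pairings[254].spacing > 1400
        assert not pairings[254].feasible_two_step

    def test_spacing_one_boundary(self):
        # pairing arithmetic at the closest possible AG (one nt downstream)
        profile = ms.SpliceSignalProfile(
            gene_id="g",
            five_ss=[],
            bp=[ms.MotifHit("g", "bp", 10, 7, "ACTAACA")],
            acceptors=[11],
            sm=[],
            ordered_pairs=[],
        )
        (pairing,) = sp.pair_bp_to_acceptors(profile)
        assert pairing.spacing == 1 and pairing.feasible_two_step

    def test_no_downstream_ag(self):
        seq = "GTATGT" + "C" * 20 + "ACTAACT" + "C" * 10
        gene = io.GeneModel("g", "c", "+", 1, len(seq), 1, len(seq))
        profile = ms.call_splice_signals(gene, seq)
        (pairing,) = sp.pair_bp_to_acceptors(profile)
        assert pairing.acceptor is None and not pairing.feasible_two_step

    def test_bad_d_max(self, bdf2_profile):
        with pytest.raises(ValueError):
            sp.pair_bp_to_acceptors(bdf2_profile[1], d_max=0)

    def test_matches_nearest_ag_oracle_on_random_transcripts(self, rng):
        for _ in range(100):
            seq = random_sequence(rng, 600)
            gene = io.GeneModel("g", "c", "+", 1, 600, 1, 600)
            profile = ms.call_splice_signals(gene, seq, min_5ss_bp_spacing=1)
            for pairing in sp.pair_bp_to_acceptors(profile):
                assert pairing.acceptor == brute_force_nearest_ag(seq, pairing.bp)


class TestClassifyEvent:
    def test_bdf2_two_events_from_one_donor(self, bdf2_profile):
        _, profile = bdf2_profile
        events = sp.events_for_profile(profile)
        assert len(events) == 2
        by_bp = {e.pairing.bp: e.event_class for e in events}
        assert by_bp == {254: "cleavage_only", 1660: "two_step"}

    def test_two_step_intron_interval(self, bdf2_profile):
        _, profile = bdf2_profile
        events = {e.pairing.bp: e for e in sp.events_for_profile(profile)}
        assert events[1660].intron == (33, 1673)  # donor start .. G of the AG
        assert events[254].intron is None

    def test_absent_acceptor_is_cleavage_only(self):
        pairing = sp.BPPairing("g", 100, None, None, False)
        event = sp.classify_event(50, pairing)
        assert event.event_class == "cleavage_only"

    def test_donor_downstream_of_bp_rejected(self):
        pairing = sp.BPPairing("g", 100, 130, 30, True)
        with pytest.raises(ValueError):
            sp.classify_event(150, pairing)

    def test_monotone_in_d_max(self, bdf2_profile):
        # increasing d_max never converts two_step -> cleavage_only
        _, profile = bdf2_profile
        previous_two_step: set[int] = set()
        for d_max in (5, 12, 100, 2000):
            events = sp.events_for_profile(profile, d_max=d_max)
            now = {e.pairing.bp for e in events if e.event_class == "two_step"}
            assert previous_two_step <= now
            previous_two_step = now


class TestAcceptorReselection:
    def test_bdf2_alternative_acceptor(self, bdf2_profile):
        transcript, profile = bdf2_profile
        pairing = {p.bp: p for p in sp.pair_bp_to_acceptors(profile)}[1660]
        mutated = sp.select_acceptor_after_mutation(transcript, pairing, {1673: "A"})
        assert mutated.acceptor == 1702
        assert mutated.spacing == 42
        assert mutated.feasible_two_step  # 42 nt is within the default d_max

    def test_empty_edit_is_identity(self, bdf2_profile):
        transcript, profile = bdf2_profile
        for pairing in sp.pair_bp_to_acceptors(profile):
            assert sp.select_acceptor_after_mutation(transcript, pairing, {}) == pairing

    def test_destroying_all_downstream_ags(self, bdf2_profile):
        transcript, profile = bdf2_profile
        pairing = {p.bp: p for p in sp.pair_bp_to_acceptors(profile)}[1660]
        mutated = sp.select_acceptor_after_mutation(
            transcript, pairing, {1673: "A", 1703: "A"}
        )
        assert mutated.acceptor is None and not mutated.feasible_two_step

    def test_edit_at_non_ag_position_is_noop(self, bdf2_profile):
        transcript, profile = bdf2_profile
        pairing = {p.bp: p for p in sp.pair_bp_to_acceptors(profile)}[1660]
        assert sp.select_acceptor_after_mutation(transcript, pairing, {5: "C"}) == pairing

    def test_edit_outside_transcript_rejected(self, bdf2_profile):
        transcript, profile = bdf2_profile
        pairing = sp.pair_bp_to_acceptors(profile)[0]
        with pytest.raises(ValueError):
            sp.select_acceptor_after_mutation(transcript, pairing, {10_000: "A"})


def make_event(gene_id, intron):
    donor, end = intron
    pairing = sp.BPPairing(gene_id, end - 20, end - 1, 19, True)
    return sp.SpliceEvent(gene_id, donor, pairing, "two_step", intron)


class TestFrameEffect:
    def test_in_frame_deletion(self, rng):
        gene, transcript, intron = make_spliced_gene(rng, intron_length=90)
        event = make_event(gene.gene_id, intron)
        assert sp.classify_frame_effect(event, gene, transcript) is (
            sp.FrameEffect.IN_FRAME_DELETION
        )

    def test_frameshift(self, rng):
        gene, transcript, intron = make_spliced_gene(rng, intron_length=91)
        event = make_event(gene.gene_id, intron)
        assert sp.classify_frame_effect(event, gene, transcript) is (
            sp.FrameEffect.FRAMESHIFT
        )

    @pytest.mark.parametrize(
        "location,expected",
        [("utr5", sp.FrameEffect.UTR5_INTRON), ("utr3", sp.FrameEffect.UTR3_INTRON)],
    )
    def test_utr_introns(self, rng, location, expected):
        gene, transcript, intron = make_spliced_gene(rng, 90, location=location)
        event = make_event(gene.gene_id, intron)
        assert sp.classify_frame_effect(event, gene, transcript) is expected

    def test_ptc_introduced_by_exon_junction(self):
        # splicing joins ...GGT TA | intron | A GGG... into a TAA stop codon
        utr5 = "C" * 30
        cds_after = "A" + "GGGAAA" * 20 + "TAA"
        intron96 = "GTATGT" + "C" * 68 + "ACTAACA" + "C" * 13 + "AG"
        transcript = utr5 + "ATGGGTTA" + intron96 + cds_after + "C" * 30
        gene = io.GeneModel(
            "g", "c", "+", 1, len(transcript),
            cds_start=31, cds_end=30 + 8 + 96 + len(cds_after),
        )
        event = make_event("g", (39, 39 + 96 - 1))
        assert sp.classify_frame_effect(event, gene, transcript) is (
            sp.FrameEffect.PTC_INTRODUCED
        )

    def test_cleavage_only_event_rejected(self, rng):
        gene, transcript, _ = make_spliced_gene(rng, 90)
        pairing = sp.BPPairing("g", 100, None, None, False)
        event = sp.SpliceEvent("g", 50, pairing, "cleavage_only", None)
        with pytest.raises(ValueError):
            sp.classify_frame_effect(event, gene, transcript)

    def test_agrees_with_codon_walker_on_random_events(self):
        """Classification vs an independent codon-walk oracle, 200 events."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            length = int(rng.integers(60, 121))
            location = str(rng.choice(["cds", "utr5", "utr3"]))
            gene, transcript, intron = make_spliced_gene(rng, length, location)
            event = make_event(gene.gene_id, intron)
            got = sp.classify_frame_effect(event, gene, transcript)
            s, e = intron
            if e < gene.cds_start:
                expected = sp.FrameEffect.UTR5_INTRON
            elif s > gene.cds_end:
                expected = sp.FrameEffect.UTR3_INTRON
            elif length % 3:
                expected = sp.FrameEffect.FRAMESHIFT
            else:
                spliced = transcript[: s - 1] + transcript[e:]
                cds = spliced[gene.cds_start - 1 : gene.cds_end - length]
                protein = codon_walk_translate(cds)
                expected = (
                    sp.FrameEffect.PTC_INTRODUCED
                    if "*" in protein[:-1]
                    else sp.FrameEffect.IN_FRAME_DELETION
                )
            assert got is expected
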