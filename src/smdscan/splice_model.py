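"""Branch-point/acceptor pairing and splice-event classification.

A profiled transcript can support two kinds of spliceosomal events:

* a **two-step** event — both transesterifications complete, the intron is
  excised and donor joined to acceptor — feasible only when an AG acceptor
  lies within ``d_max`` nt downstream of the branch point; and
* a **cleavage-only** event — the first step (branch-point attack on the
  donor) occurs but the distance to the nearest AG is too large for exon
  ligation, releasing a free 5' exon and a lariat intermediate, both
  substrates for nuclear RNA surveillance.

Spacing is ``acceptor_start - bp_start`` in transcript coordinates with both
coordinates at the first base of their motif/dinucleotide; the coordinates
reported for real-gene fixtures reproduce the printed BP-to-3'ss spacings
under this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

from Bio.Seq import Seq

from .io_formats import GeneModel
from .motif_scan import MotifHit, SpliceSignalProfile, find_ag_positions

DEFAULT_D_MAX = 100


class FrameEffect(str, Enum):
    IN_FRAME_DELETION = "in_frame_deletion"
    FRAMESHIFT = "frameshift"
    PTC_INTRODUCED = "ptc_introduced"
    UTR5_INTRON = "utr5_intron"
    UTR3_INTRON = "utr3_intron"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class BPPairing:
    """A branch point paired with its nearest downstream AG acceptor."""

    gene_id: str
    bp: int  # transcript index of BP motif start
    acceptor: int | None  # transcript index of AG start, or None
    spacing: int | None  # acceptor - bp, nt
    feasible_two_step: bool

    def __post_init__(self) -> None:
        if self.acceptor is not None and self.spacing is not None and self.spacing <= 0:
            raise ValueError("acceptor must be downstream of the branch point")
        if self.feasible_two_step and self.acceptor is None:
            raise ValueError("two-step feasibility requires an acceptor")


@dataclass(frozen=True)
class SpliceEvent:
    """A (donor, BP, acceptor?) triple classified as cleavage-only or two-step."""

    gene_id: str
    donor: int  # transcript index of 5'ss motif start
    pairing: BPPairing
    event_class: str  # "cleavage_only" | "two_step"
    intron: tuple[int, int] | None  # transcript interval, donor..acceptor AG end
    frame_effect: FrameEffect = FrameEffect.NOT_APPLICABLE

    @property
    def intron_length(self) -> int | None:
        if self.intron is None:
            return None
        return self.intron[1] - self.intron[0] + 1


def pair_bp_to_acceptors(
    profile: SpliceSignalProfile, d_max: int = DEFAULT_D_MAX
) -> list[BPPairing]:
    """Pair every BP hit with the nearest downstream AG.

    Feasibility of the second splicing step is a pure distance criterion:
    spacing <= ``d_max``. A BP with no downstream AG is returned with an
    absent acceptor.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    pairings = []
    for bp_hit in profile.bp:
        downstream = [a for a in profile.acceptors if a > bp_hit.position]
        if downstream:
            acceptor = min(downstream)
            spacing = acceptor - bp_hit.position
            pairings.append(
                BPPairing(
                    profile.gene_id, bp_hit.position, acceptor, spacing,
                    feasible_two_step=spacing <= d_max,
                )
            )
        else:
            pairings.append(
                BPPairing(profile.gene_id, bp_hit.position, None, None, False)
            )
    return pairings


def classify_event(
    donor: MotifHit | int, pairing: BPPairing, d_max: int = DEFAULT_D_MAX
) -> SpliceEvent:
    """Classify a (donor, pairing) as two-step or cleavage-only.

    Two-step iff the pairing's acceptor is within ``d_max``; the intron then
    spans from the first base of the donor motif through the G of the
    acceptor AG.
    """
    donor_pos = donor.position if isinstance(donor, MotifHit) else donor
    if donor_pos >= pairing.bp:
        raise ValueError("donor must lie upstream of the branch point")
    feasible = (
        pairing.acceptor is not None
        and pairing.spacing is not None
        and pairing.spacing <= d_max
    )
    if feasible:
        intron = (donor_pos, pairing.acceptor + 1)  # through the G of AG
        return SpliceEvent(pairing.gene_id, donor_pos, pairing, "two_step", intron)
    return SpliceEvent(pairing.gene_id, donor_pos, pairing, "cleavage_only", None)


def select_acceptor_after_mutation(
    transcript: str,
    pairing: BPPairing,
    mutations: dict[int, str],
    d_max: int = DEFAULT_D_MAX,
) -> BPPairing:
    """Re-run nearest-AG acceptor selection after point mutations.

    ``mutations`` maps 1-based transcript indices to replacement bases (the
    edit is applied before re-scanning). Mirrors cryptic-acceptor usage:
    destroying the proximal AG shifts splicing to the next AG downstream.
    """
    seq = list(transcript)
    for pos, base in mutations.items():
        if not 1 <= pos <= len(seq):
            raise ValueError(f"mutation position {pos} outside transcript")
        seq[pos - 1] = base.upper().replace("U", "T")
    edited = "".join(seq)
    downstream = [p for p in find_ag_positions(edited) if p > pairing.bp]
    if downstream:
        acceptor = min(downstream)
        spacing = acceptor - pairing.bp
        return replace(
            pairing,
            acceptor=acceptor,
            spacing=spacing,
            feasible_two_step=spacing <= d_max,
        )
    return replace(pairing, acceptor=None, spacing=None, feasible_two_step=False)


def splice_transcript(transcript: str, intron: tuple[int, int]) -> str:
    """Remove a transcript-coordinate closed interval (the excised intron)."""
    s, e = intron
    return transcript[: s - 1] + transcript[e:]


def classify_frame_effect(
    event: SpliceEvent, gene: GeneModel, transcript: str
) -> FrameEffect:
    """Consequence of a two-step splice for the reading frame.

    UTR introns leave the ORF untouched; a CDS intron whose length is not a
    multiple of three shifts the frame; an in-frame deletion is benign only
    if the joined exons do not create a premature stop codon upstream of the
    original stop.
    """
    if event.event_class != "two_step" or event.intron is None:
        raise ValueError("frame effect is defined for two-step events only")
    s, e = event.intron
    if e < gene.cds_start:
        return FrameEffect.UTR5_INTRON
    if s > gene.cds_end:
        return FrameEffect.UTR3_INTRON
    length = e - s + 1
    if length % 3 != 0:
        return FrameEffect.FRAMESHIFT
    spliced = splice_transcript(transcript, event.intron)
    cds = spliced[gene.cds_start - 1 : gene.cds_end - length]
    n_codons = len(cds) // 3
    protein = str(Seq(cds[: n_codons * 3]).translate())
    if "*" in protein[:-1]:
        return FrameEffect.PTC_INTRODUCED
    return FrameEffect.IN_FRAME_DELETION


def events_for_profile(
    profile: SpliceSignalProfile,
    d_max: int = DEFAULT_D_MAX,
) -> list[SpliceEvent]:
    """All classified events from a profile's ordered (donor, BP) pairs.

    One event per (donor, BP) ordered pair, using each BP's nearest-AG
    pairing. The same donor can therefore drive both a cleavage-only and a
    two-step event via alternative branch points.
    """
    pairings = {p.bp: p for p in pair_bp_to_acceptors(profile, d_max)}
    events = []
    for donor, bp_hit in profile.ordered_pairs:
        events.append(classify_event(donor, pairings[bp_hit.position], d_max))
    return events
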