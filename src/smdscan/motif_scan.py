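"""Degenerate splice-signal consensus motifs and per-gene signal profiling.

The three consensus elements screened for are the yeast 5' splice site
(donor) GTA[TCA]GT, the branch point ACTAAC[GAT] (the branch adenosine sits
in the invariant core), and the single-stranded Sm-protein binding element
[AG]A-T(4..6)-G-[AG]. Motifs are written in DNA alphabet; RNA input is
normalised at ingest (see :mod:`smdscan.io_formats`).

Hit coordinates are 1-based transcript indices of the first matched base.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import CoordinateMap, GeneModel, GenomeSequence, transcript_sequence

# Element kinds: ("fixed", base) | ("choice", bases) | ("run", base, min, max)
Element = tuple


@dataclass(frozen=True)
class ConsensusMotif:
    """A degenerate pattern of fixed bases, choice sets and homopolymer runs."""

    name: str
    elements: tuple[Element, ...]

    def __post_init__(self) -> None:
        for el in self.elements:
            if el[0] == "run":
                _, base, lo, hi = el
                if lo < 1 or lo > hi:
                    raise ValueError(f"{self.name}: invalid run bounds ({lo},{hi})")
            elif el[0] not in ("fixed", "choice"):
                raise ValueError(f"{self.name}: unknown element kind {el[0]!r}")
        if self.min_length < 1:
            raise ValueError(f"{self.name}: empty motif")

    @property
    def min_length(self) -> int:
        return sum(el[2] if el[0] == "run" else 1 for el in self.elements)

    @property
    def max_length(self) -> int:
        return sum(el[3] if el[0] == "run" else 1 for el in self.elements)

    def regex(self) -> re.Pattern:
        parts = []
        for el in self.elements:
            if el[0] == "fixed":
                parts.append(el[1])
            elif el[0] == "choice":
                parts.append(f"[{el[1]}]")
            else:
                _, base, lo, hi = el
                parts.append(f"{base}{{{lo},{hi}}}")
        # lookahead with a capture group reports every start position once,
        # with the greedy (longest) valid match at that start
        return re.compile(f"(?=({''.join(parts)}))")


def _norm(s: str) -> str:
    return s.upper().replace("U", "T")


FIVE_PRIME_SS = ConsensusMotif(
    "5ss",
    (("fixed", "G"), ("fixed", "T"), ("fixed", "A"),
     ("choice", "TCA"), ("fixed", "G"), ("fixed", "T")),
)
BRANCH_POINT = ConsensusMotif(
    "bp",
    (("fixed", "A"), ("fixed", "C"), ("fixed", "T"),
     ("fixed", "A"), ("fixed", "A"), ("fixed", "C"), ("choice", "GAT")),
)
SM_SITE = ConsensusMotif(
    "sm",
    (("choice", "AG"), ("fixed", "A"), ("run", "T", 4, 6),
     ("fixed", "G"), ("choice", "AG")),
)


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif: str
    position: int  # 1-based transcript index of first matched base
    length: int
    matched: str

    @property
    def end(self) -> int:
        """Transcript index of the last matched base."""
        return self.position + self.length - 1


@dataclass
class SpliceSignalProfile:
    """Per-gene record of donor/BP/acceptor/Sm hits and their ordering."""

    gene_id: str
    five_ss: list[MotifHit]
    bp: list[MotifHit]
    acceptors: list[int]  # transcript indices of AG dinucleotide starts
    sm: list[MotifHit]
    ordered_pairs: list[tuple[MotifHit, MotifHit]]  # (donor, bp)
    sm_near_5ss: bool = False
    coords: CoordinateMap | None = None

    @property
    def signals_in_correct_order(self) -> bool:
        return bool(self.ordered_pairs)


def expand_consensus(motif: ConsensusMotif) -> set[str]:
    """All literal DNA strings the motif matches."""
    per_element: list[list[str]] = []
    for el in motif.elements:
        if el[0] == "fixed":
            per_element.append([el[1]])
        elif el[0] == "choice":
            per_element.append(list(el[1]))
        else:
            _, base, lo, hi = el
            per_element.append([base * k for k in range(lo, hi + 1)])
    return {"".join(parts) for parts in itertools.product(*per_element)}


def scan_sequence(
    seq: str, motif: ConsensusMotif, gene_id: str = ""
) -> list[MotifHit]:
    """All motif matches in ``seq``; one hit per start, longest match kept.

    N bases never match. Positions are 1-based along ``seq``.
    """
    seq = _norm(seq)
    hits = []
    for m in motif.regex().finditer(seq):
        lit = m.group(1)
        hits.append(MotifHit(gene_id, motif.name, m.start() + 1, len(lit), lit))
    return hits


def find_ag_positions(seq: str) -> list[int]:
    """1-based start positions of every AG dinucleotide in ``seq``."""
    seq = _norm(seq)
    return [m.start() + 1 for m in re.finditer("(?=AG)", seq)]


def call_splice_signals(
    gene: GeneModel,
    transcript: str,
    coords: CoordinateMap | None = None,
    min_5ss_bp_spacing: int = 20,
) -> SpliceSignalProfile:
    """Profile donor/BP/acceptor/Sm signals on one transcript.

    ``ordered_pairs`` holds every (donor, BP) pair with the BP starting at
    least ``min_5ss_bp_spacing`` nt downstream of the donor start — the
    "signals in the correct order" criterion. Acceptors are bare AG
    dinucleotide starts downstream of at least one BP.
    """
    five = scan_sequence(transcript, FIVE_PRIME_SS, gene.gene_id)
    bp = scan_sequence(transcript, BRANCH_POINT, gene.gene_id)
    sm = scan_sequence(transcript, SM_SITE, gene.gene_id)
    ag = find_ag_positions(transcript)
    min_bp = min((h.position for h in bp), default=None)
    acceptors = [p for p in ag if min_bp is not None and p > min_bp]
    pairs = [
        (d, b)
        for d in five
        for b in bp
        if b.position - d.position >= min_5ss_bp_spacing
    ]
    return SpliceSignalProfile(
        gene_id=gene.gene_id,
        five_ss=five,
        bp=bp,
        acceptors=acceptors,
        sm=sm,
        ordered_pairs=pairs,
        coords=coords,
    )


def sm_sites_near_5ss(
    profile: SpliceSignalProfile, window: int = 50
) -> SpliceSignalProfile:
    """Flag the profile if an Sm site ends within ``window`` nt upstream of a donor."""
    if window <= 0:
        raise ValueError("window must be positive")
    flag = any(
        d.position - window <= s.end <= d.position - 1
        for d in profile.five_ss
        for s in profile.sm
    )
    profile.sm_near_5ss = flag
    return profile


def screen_gene_set(
    genes: dict[str, GeneModel],
    genome: GenomeSequence,
    min_5ss_bp_spacing: int = 20,
    sm_window: int = 50,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Scan every gene; per-gene signal table plus funnel counts.

    Funnel counts mirror the intronless-gene screen: how many intronless
    genes exist, how many carry donor+BP in the correct order, and how many
    of those additionally have an Sm site within ``sm_window`` nt upstream
    of a donor.
    """
    rows = []
    for gid in sorted(genes):
        gene = genes[gid]
        transcript, coords = transcript_sequence(genome, gene)
        profile = call_splice_signals(gene, transcript, coords, min_5ss_bp_spacing)
        if profile.five_ss:
            sm_sites_near_5ss(profile, sm_window)
        rows.append(
            {
                "gene_id": gid,
                "intron_status": gene.intron_status,
                "n_5ss": len(profile.five_ss),
                "n_bp": len(profile.bp),
                "signals_in_order": profile.signals_in_correct_order,
                "sm_near_5ss": profile.sm_near_5ss,
            }
        )
    table = pd.DataFrame(rows).set_index("gene_id")
    intronless = table[table.intron_status == "intronless"]
    funnel = {
        "n_genes": len(table),
        "n_intronless": len(intronless),
        "n_intronless_signals_in_order": int(intronless.signals_in_order.sum()),
        "n_intronless_sm_near_5ss": int(
            (intronless.signals_in_order & intronless.sm_near_5ss).sum()
        ),
    }
    return table, funnel
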