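"""Shared test utilities, including the brute-force oracles."""

import numpy as np

from smdscan import io_formats as io
from smdscan.motif_scan import ConsensusMotif, expand_consensus

STOP_FREE_CODONS = [
    c
    for c in (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT")
    if c not in ("TAA", "TAG", "TGA")
]


def random_sequence(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))


def brute_force_scan(seq: str, motif: ConsensusMotif):
    """Try every expansion literal at every offset; longest match per start.

    Independent of the scanner: no regex, plain slice comparison against the
    enumerated literal set.
    """
    literals = expand_consensus(motif)
    by_length = {}
    for lit in literals:
        by_length.setdefault(len(lit), set()).add(lit)
    lengths = sorted(by_length, reverse=True)  # longest first
    hits = []
    for i in range(len(seq)):
        for L in lengths:
            if seq[i : i + L] in by_length[L]:
                hits.append((i + 1, L))
                break
    return hits


def brute_force_nearest_ag(seq: str, bp_start: int):
    """Scan every position downstream of ``bp_start`` for AG; take minimum."""
    for i in range(bp_start, len(seq)):  # i is 0-based; bp_start is 1-based
        if seq[i : i + 2] == "AG":
            return i + 1
    return None


def codon_walk_translate(cds: str):
    """Minimal independent codon walker (no Biopython)."""
    table = {}
    bases = "TCAG"
    amino = (
        "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    )
    k = 0
    for a in bases:
        for b in bases:
            for c in bases:
                table[a + b + c] = amino[k]
                k += 1
    return "".join(
        table[cds[i : i + 3]] for i in range(0, len(cds) - len(cds) % 3, 3)
    )


def make_spliced_gene(rng, intron_length=90, location="cds", n_codons=120):
    """A gene with a stop-free CDS and one planted cryptic intron.

    Returns (gene, transcript, intron_interval) with the intron interval in
    1-based transcript coordinates (donor start .. G of the acceptor AG).
    """
    utr5, utr3 = 150, 150
    cds = "".join(rng.choice(STOP_FREE_CODONS, size=n_codons)) + "TAA"
    utr5_seq = random_sequence(rng, utr5)
    utr3_seq = random_sequence(rng, utr3)
    body = utr5_seq + cds + utr3_seq

    intron = list(random_sequence(rng, intron_length))
    intron[:6] = "GTATGT"
    intron[-2:] = "AG"
    bp_off = intron_length - 2 - 20  # BP motif 20 nt upstream of the AG start
    intron[bp_off : bp_off + 7] = "ACTAACA"
    intron = "".join(intron)

    if location == "cds":
        insert_at = utr5 + 3 * (n_codons // 2)  # 0-based, codon boundary
    elif location == "utr5":
        insert_at = 30
    else:  # utr3
        insert_at = utr5 + len(cds) + 30
    transcript = body[:insert_at] + intron + body[insert_at:]
    gene = io.GeneModel(
        "gtest", "chrT", "+", 1, len(transcript),
        cds_start=utr5 + 1, cds_end=utr5 + len(cds) + intron_length
        if location != "utr5" else utr5 + len(cds),
        introns=[],
    )
    # CDS interval in the unspliced transcript: shifted by the intron when
    # the intron precedes (part of) it
    if location == "utr5":
        gene = io.GeneModel(
            "gtest", "chrT", "+", 1, len(transcript),
            cds_start=utr5 + intron_length + 1,
            cds_end=utr5 + intron_length + len(cds),
        )
    elif location == "utr3":
        gene = io.GeneModel(
            "gtest", "chrT", "+", 1, len(transcript),
            cds_start=utr5 + 1, cds_end=utr5 + len(cds),
        )
    intron_interval = (insert_at + 1, insert_at + intron_length)
    return gene, transcript, intron_interval
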