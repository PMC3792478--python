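"""Canonical GT/AG splice-junction calling from gapped alignments.

Junctions are read off skip ("N") operations of already-aligned reads, so
this module never aligns anything itself. A junction is canonical when its
intron starts with GT and ends with AG on the sense strand of its host
gene. Novel canonical junctions inside annotated-intronless genes are the
RNA-seq evidence for unannotated splicing of those transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd
from Bio.Seq import reverse_complement

from .io_formats import AlignmentRecord, FormatError, GeneModel, GenomeSequence
from .motif_scan import BRANCH_POINT, scan_sequence

DEFAULT_MIN_SUPPORT = 2


@dataclass(frozen=True)
class JunctionRecord:
    chrom: str
    start: int  # first skipped base, 1-based closed
    end: int  # last skipped base
    strand: str | None
    support: int
    donor: str  # sense-strand dinucleotide at the intron 5' end
    acceptor: str  # sense-strand dinucleotide at the intron 3' end
    canonical: bool
    host_gene: str | None = None
    status: str = "unclassified"
    bp_in_intron: bool = False
    bp_to_acceptor: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def extract_junctions(
    alignments: list[AlignmentRecord], genome: GenomeSequence
) -> list[JunctionRecord]:
    """One junction per distinct skipped interval; support = distinct reads.

    Dinucleotides are recorded from the plus strand here and re-oriented
    when a host gene (and hence a strand) is assigned.
    """
    support: dict[tuple[str, int, int], set[str]] = {}
    for aln in alignments:
        pos = aln.pos
        for op, length in aln.cigar:
            if op == "N":
                intron = (aln.chrom, pos, pos + length - 1)
                support.setdefault(intron, set()).add(aln.read_id)
            pos += length
        if pos - aln.pos != aln.reference_span:
            raise FormatError(f"{aln.read_id}: inconsistent operation lengths")
    junctions = []
    for (chrom, start, end), reads in sorted(support.items()):
        if chrom not in genome:
            raise FormatError(f"junction on unknown chromosome {chrom!r}")
        donor = genome.fetch(chrom, start, start + 1)
        acceptor = genome.fetch(chrom, end - 1, end)
        junctions.append(
            JunctionRecord(
                chrom=chrom, start=start, end=end, strand=None,
                support=len(reads), donor=donor, acceptor=acceptor,
                canonical=False,
            )
        )
    return junctions


def _orient(junction: JunctionRecord, strand: str) -> tuple[str, str, bool]:
    """Sense-strand donor/acceptor dinucleotides and the canonical flag."""
    if strand == "+":
        donor, acceptor = junction.donor, junction.acceptor
    else:
        donor = reverse_complement(junction.acceptor)
        acceptor = reverse_complement(junction.donor)
    return donor, acceptor, (donor == "GT" and acceptor == "AG")


def assign_host_genes(
    junctions: list[JunctionRecord], annotation: dict[str, GeneModel]
) -> list[JunctionRecord]:
    """Resolve host gene, strand and sense-strand canonical flag.

    A junction contained in two genes goes to the one whose strand makes it
    canonical; if both or neither qualify it stays intergenic. Deterministic:
    candidate genes are considered in gene-id order.
    """
    out = []
    for j in junctions:
        hosts = [
            g for g in sorted(annotation)
            if annotation[g].contains(j.chrom, j.start, j.end)
        ]
        chosen: GeneModel | None = None
        if len(hosts) == 1:
            chosen = annotation[hosts[0]]
        elif len(hosts) > 1:
            canonical_hosts = [
                g for g in hosts if _orient(j, annotation[g].strand)[2]
            ]
            if len(canonical_hosts) == 1:
                chosen = annotation[canonical_hosts[0]]
        if chosen is None:
            out.append(replace(j, status="intergenic"))
            continue
        donor, acceptor, canonical = _orient(j, chosen.strand)
        out.append(
            replace(
                j, strand=chosen.strand, donor=donor, acceptor=acceptor,
                canonical=canonical, host_gene=chosen.gene_id,
            )
        )
    return out


def filter_canonical(
    junctions: list[JunctionRecord],
    genome: GenomeSequence,
    annotation: dict[str, GeneModel],
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[JunctionRecord]:
    """Keep sense-strand GT..AG junctions with at least ``min_support`` reads."""
    assigned = assign_host_genes(junctions, annotation)
    return [j for j in assigned if j.canonical and j.support >= min_support]


def classify_junctions(
    junctions: list[JunctionRecord], annotation: dict[str, GeneModel]
) -> tuple[list[JunctionRecord], dict[str, float]]:
    """Assign annotated/novel status and per-class gene statistics.

    Statistics: fraction (%) of intronic genes with at least one junction
    exactly matching an annotated intron, and fraction (%) of intronless
    genes with at least one canonical junction.
    """
    classified = []
    intronic_hit: set[str] = set()
    intronless_hit: set[str] = set()
    for j in junctions:
        if j.host_gene is None:
            classified.append(replace(j, status="intergenic"))
            continue
        gene = annotation[j.host_gene]
        if (j.start, j.end) in gene.introns:
            status = "annotated"
            intronic_hit.add(gene.gene_id)
        elif gene.intron_status == "intronic":
            status = "novel_in_intronic"
        else:
            status = "novel_in_intronless"
            if j.canonical:
                intronless_hit.add(gene.gene_id)
        classified.append(replace(j, status=status))
    n_intronic = sum(1 for g in annotation.values() if g.intron_status == "intronic")
    n_intronless = len(annotation) - n_intronic
    stats = {
        "pct_intronic_with_annotated_junction": (
            100.0 * len(intronic_hit) / n_intronic if n_intronic else 0.0
        ),
        "pct_intronless_with_canonical_junction": (
            100.0 * len(intronless_hit) / n_intronless if n_intronless else 0.0
        ),
    }
    return classified, stats


def bp_within_intron(
    junction: JunctionRecord,
    genome: GenomeSequence,
    annotation: dict[str, GeneModel],
) -> JunctionRecord:
    """Flag a junction whose intron contains a branch-point consensus.

    The intron sequence is taken on the sense strand of the host gene;
    ``bp_to_acceptor`` is the distance (nt) from the BP motif start to the
    first base of the acceptor AG, using the BP nearest the acceptor.
    """
    if junction.host_gene is None:
        raise ValueError("junction has no host gene")
    gene = annotation[junction.host_gene]
    raw = genome.fetch(junction.chrom, junction.start, junction.end)
    intron_seq = raw if gene.strand == "+" else reverse_complement(raw)
    hits = scan_sequence(intron_seq, BRANCH_POINT)
    if not hits:
        return replace(junction, bp_in_intron=False, bp_to_acceptor=None)
    acceptor_start = len(intron_seq) - 1  # 1-based index of the A of the AG
    distance = acceptor_start - hits[-1].position
    return replace(junction, bp_in_intron=True, bp_to_acceptor=distance)


def junction_table(junctions: list[JunctionRecord]) -> pd.DataFrame:
    rows = [
        {
            "chrom": j.chrom, "start": j.start, "end": j.end,
            "strand": j.strand or ".", "support": j.support,
            "donor": j.donor, "acceptor": j.acceptor,
            "canonical": j.canonical, "host_gene": j.host_gene or ".",
            "status": j.status, "bp_in_intron": j.bp_in_intron,
            "bp_to_acceptor": j.bp_to_acceptor,
        }
        for j in junctions
    ]
    return pd.DataFrame(rows)
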