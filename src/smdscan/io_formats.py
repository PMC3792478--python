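"""Readers/writers for the external formats the pipeline touches.

Coordinate conventions, enforced here and relied on everywhere else:

* Genomic coordinates are 1-based, closed intervals (the GFF3 dialect).
* BED output converts to 0-based, half-open on the way out.
* Transcript coordinates are 1-based indices along the sense strand of the
  gene body; :class:`CoordinateMap` converts transcript index <-> genomic
  position bijectively, and to the ATG-relative convention (+1 = first base
  of the start codon, no position zero) used in reports.
* All sequence is stored as uppercase DNA; RNA input (U) is mapped to T at
  ingest so a single alphabet is used internally.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import reverse_complement

VALID_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeSequence:
    """Mapping from chromosome name to an uppercase A/C/G/T/N string."""

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if not name:
                raise FormatError("empty chromosome name")
            bad = set(seq) - VALID_ALPHABET
            if bad:
                raise FormatError(
                    f"non-nucleotide characters {sorted(bad)} in {name!r}"
                )

    def __getitem__(self, chrom: str) -> str:
        return self.chromosomes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of the 1-based closed interval [start, end]."""
        if start < 1 or end > len(self.chromosomes[chrom]) or start > end:
            raise ValueError(f"interval [{start},{end}] out of bounds on {chrom}")
        return self.chromosomes[chrom][start - 1 : end]


@dataclass
class GeneModel:
    """A gene with genomic extent, CDS (in transcript coordinates) and introns.

    ``cds_start``/``cds_end`` are 1-based indices into the spliced-equal-
    unspliced gene-body sequence on the sense strand; ``cds_start`` is the
    first base of the start codon. ``introns`` are annotated introns as
    1-based closed genomic intervals.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds_start: int
    cds_end: int
    introns: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise FormatError(f"{self.gene_id}: bad gene interval")
        if self.cds_start < 1 or self.cds_end < self.cds_start:
            raise FormatError(f"{self.gene_id}: bad CDS interval")
        if self.cds_end > self.length:
            raise FormatError(f"{self.gene_id}: CDS extends beyond gene length")
        for s, e in self.introns:
            if s < self.start or e > self.end or s > e:
                raise FormatError(f"{self.gene_id}: intron [{s},{e}] outside gene")
        ordered = sorted(self.introns)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise FormatError(f"{self.gene_id}: overlapping introns")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def intron_status(self) -> str:
        return "intronic" if self.introns else "intronless"

    def contains(self, chrom: str, start: int, end: int) -> bool:
        return chrom == self.chrom and start >= self.start and end <= self.end


@dataclass
class CountsTable:
    """Rectangular table of non-negative integer read counts.

    ``counts`` is indexed by gene_id with one column per sample;
    ``conditions`` optionally labels each sample with a condition.
    """

    counts: pd.DataFrame
    conditions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise FormatError("duplicate gene ids in counts table")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative counts")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class AlignmentRecord:
    """A gapped alignment reduced to match/skip operations.

    ``pos`` is the 1-based leftmost genomic position; ``cigar`` is an ordered
    list of (op, length) with op in {"M", "N"}. Skip ("N") operations are the
    introns junction extraction works from.
    """

    read_id: str
    chrom: str
    pos: int
    cigar: list[tuple[str, int]]

    def __post_init__(self) -> None:
        if not self.cigar:
            raise FormatError(f"{self.read_id}: empty CIGAR")
        if any(length <= 0 for _, length in self.cigar):
            raise FormatError(f"{self.read_id}: non-positive operation length")
        if any(op not in ("M", "N") for op, _ in self.cigar):
            raise FormatError(f"{self.read_id}: unsupported CIGAR operation")
        if "M" not in (op for op, _ in self.cigar):
            raise FormatError(f"{self.read_id}: no match operation")
        if self.cigar[0][0] == "N" or self.cigar[-1][0] == "N":
            raise FormatError(f"{self.read_id}: skip at alignment edge")

    @property
    def reference_span(self) -> int:
        return sum(length for _, length in self.cigar)


class CoordinateMap:
    """Bijective transcript-index <-> genomic map for one gene body.

    Transcript index ``i`` runs 1..gene length along the sense strand (minus-
    strand genes read right to left on the genome). ATG-relative coordinates
    follow the +1 = first base of the start codon convention with no zero.
    """

    def __init__(self, gene: GeneModel) -> None:
        self.gene = gene

    def index_to_genomic(self, i: int) -> int:
        g = self.gene
        if not 1 <= i <= g.length:
            raise ValueError(f"transcript index {i} outside 1..{g.length}")
        return g.start + i - 1 if g.strand == "+" else g.end - i + 1

    def genomic_to_index(self, pos: int) -> int:
        g = self.gene
        if not g.start <= pos <= g.end:
            raise ValueError(f"genomic position {pos} outside gene {g.gene_id}")
        return pos - g.start + 1 if g.strand == "+" else g.end - pos + 1

    def index_to_atg(self, i: int) -> int:
        c = self.gene.cds_start
        return i - c + 1 if i >= c else i - c

    def atg_to_index(self, t: int) -> int:
        if t == 0:
            raise ValueError("ATG-relative coordinate 0 does not exist")
        c = self.gene.cds_start
        return t + c - 1 if t > 0 else t + c

    def genomic_to_atg(self, pos: int) -> int:
        return self.index_to_atg(self.genomic_to_index(pos))

    def atg_to_genomic(self, t: int) -> int:
        return self.index_to_genomic(self.atg_to_index(t))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> GenomeSequence:
    """Read a genome FASTA; uppercase, map U->T, reject duplicate headers."""
    chroms: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in chroms:
            raise FormatError(f"duplicate FASTA record {record.id!r}")
        seq = str(record.seq).upper().replace("U", "T")
        bad = set(seq) - VALID_ALPHABET
        if bad:
            raise FormatError(
                f"non-nucleotide characters {sorted(bad)} in record {record.id!r}"
            )
        chroms[record.id] = seq
    if not chroms:
        raise FormatError(f"no FASTA records in {path}")
    return GenomeSequence(chroms)


def read_gff3(path: str | os.PathLike) -> dict[str, GeneModel]:
    """Read gene/mRNA/CDS/intron features into GeneModels keyed by gene id.

    A gene is ``intronic`` iff it has at least one intron feature. Child
    features falling outside their gene's span raise :class:`FormatError`.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="error",
        keep_order=True,
    )
    genes: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        gene_id = gene.id
        cds_intervals: list[tuple[int, int]] = []
        introns: list[tuple[int, int]] = []
        for child in db.children(gene, featuretype=("mRNA", "CDS", "intron")):
            if child.start < gene.start or child.end > gene.end:
                raise FormatError(
                    f"{child.featuretype} {child.id} outside gene {gene_id}"
                )
            if child.featuretype == "CDS":
                cds_intervals.append((child.start, child.end))
            elif child.featuretype == "intron":
                introns.append((child.start, child.end))
        if not cds_intervals:
            raise FormatError(f"gene {gene_id} has no CDS feature")
        cds_g_start = min(s for s, _ in cds_intervals)
        cds_g_end = max(e for _, e in cds_intervals)
        if gene.strand == "+":
            cds_start = cds_g_start - gene.start + 1
            cds_end = cds_g_end - gene.start + 1
        else:
            cds_start = gene.end - cds_g_end + 1
            cds_end = gene.end - cds_g_start + 1
        genes[gene_id] = GeneModel(
            gene_id=gene_id,
            chrom=gene.seqid,
            strand=gene.strand,
            start=gene.start,
            end=gene.end,
            cds_start=cds_start,
            cds_end=cds_end,
            introns=sorted(introns),
        )
    return genes


def transcript_sequence(
    genome: GenomeSequence, gene: GeneModel
) -> tuple[str, CoordinateMap]:
    """Sense-strand gene-body sequence plus its coordinate map.

    Minus-strand genes are reverse-complemented so every downstream scan
    operates on the transcript (sense) strand only.
    """
    if gene.chrom not in genome:
        raise ValueError(f"chromosome {gene.chrom!r} not in genome")
    raw = genome.fetch(gene.chrom, gene.start, gene.end)
    seq = raw if gene.strand == "+" else reverse_complement(raw)
    if gene.cds_start > len(seq):
        raise ValueError(f"{gene.gene_id}: CDS start beyond gene length")
    return seq, CoordinateMap(gene)


def read_counts_tsv(
    path: str | os.PathLike, conditions: dict[str, str] | None = None
) -> CountsTable:
    """Read a counts TSV (gene_id column + one integer column per sample)."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if not all(pd.api.types.is_integer_dtype(df[c]) for c in df.columns):
        raise FormatError("counts columns must be integers")
    return CountsTable(df, conditions or {})


def write_counts_tsv(table: CountsTable, path: str | os.PathLike) -> None:
    table.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_sam(path: str | os.PathLike) -> list[AlignmentRecord]:
    """Read a SAM-subset file (M/N CIGAR operations only) via pysam."""
    op_names = {0: "M", 3: "N"}
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            cigar: list[tuple[str, int]] = []
            for code, length in aln.cigartuples:
                if code not in op_names:
                    raise FormatError(
                        f"{aln.query_name}: unsupported CIGAR op code {code}"
                    )
                cigar.append((op_names[code], length))
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    pos=aln.reference_start + 1,
                    cigar=cigar,
                )
            )
    return records


def write_sam(
    records: list[AlignmentRecord],
    genome: GenomeSequence,
    path: str | os.PathLike,
) -> None:
    """Write AlignmentRecords as minimal text SAM with an @SQ header."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, seq in genome.chromosomes.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for rec in records:
            cigar = "".join(f"{length}{op}" for op, length in rec.cigar)
            read_len = sum(length for op, length in rec.cigar if op == "M")
            fh.write(
                f"{rec.read_id}\t0\t{rec.chrom}\t{rec.pos}\t255\t{cigar}\t*\t0\t0\t"
                f"{'N' * read_len}\t*\n"
            )


def write_junction_bed(junctions, path: str | os.PathLike) -> None:
    """Write junctions as BED6 (0-based half-open), sorted deterministically.

    Score column is read support; name is ``hostGene|status`` (``.`` for a
    junction with no host gene).
    """
    rows = []
    for j in junctions:
        host = j.host_gene if j.host_gene is not None else "."
        strand = j.strand if j.strand is not None else "."
        rows.append((j.chrom, j.start - 1, j.end, f"{host}|{j.status}", j.support, strand))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_genome_fasta(genome: GenomeSequence, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name in genome.chromosomes:
            fh.write(f">{name}\n")
            seq = genome.chromosomes[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_gff3(genes: dict[str, GeneModel], path: str | os.PathLike) -> None:
    """Write GeneModels as GFF3 gene/mRNA/CDS/intron features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(genes):
            g = genes[gid]
            # CDS back to genomic coordinates
            if g.strand == "+":
                cgs = g.start + g.cds_start - 1
                cge = g.start + g.cds_end - 1
            else:
                cge = g.end - g.cds_start + 1
                cgs = g.end - g.cds_end + 1
            lines = [
                (g.chrom, "smdscan", "gene", g.start, g.end, g.strand, f"ID={gid}"),
                (g.chrom, "smdscan", "mRNA", g.start, g.end, g.strand,
                 f"ID={gid}.t1;Parent={gid}"),
                (g.chrom, "smdscan", "CDS", cgs, cge, g.strand,
                 f"ID={gid}.cds;Parent={gid}.t1"),
            ]
            for k, (s, e) in enumerate(g.introns, 1):
                lines.append(
                    (g.chrom, "smdscan", "intron", s, e, g.strand,
                     f"ID={gid}.i{k};Parent={gid}.t1")
                )
            for chrom, src, ftype, s, e, strand, attrs in lines:
                fh.write(f"{chrom}\t{src}\t{ftype}\t{s}\t{e}\t.\t{strand}\t.\t{attrs}\n")
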