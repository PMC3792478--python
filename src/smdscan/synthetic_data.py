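"""Seeded generators for toy genomes, counts and alignments with planted truth.

The generator emulates the statistical structure of the study's data so the
whole screen can be exercised without any download:

* a toy genome in which a configurable fraction of genes carry one
  annotated GT..AG intron (with an internal branch point) and a disjoint
  fraction of the intronless genes are planted SMD targets — a cryptic
  intron whose donor, branch point and acceptor are real motif literals,
  plus an Sm site just upstream of the donor;
* IP/mock count libraries in which Sm-bound genes (SMD targets and
  intron-containing genes) are enriched by a factor epsilon;
* wild-type vs splicing-mutant libraries in which SMD targets rise
  rho-fold; and
* per-condition gapped alignments whose junction-spanning reads over SMD
  introns are amplified in the exosome-mutant-like condition.

Backgrounds are rejection-sampled so that no unplanted donor/BP/Sm literal
survives anywhere in a gene body, making planted-truth recovery tests
exact. Every output is a pure function of the config (including its seed).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AlignmentRecord, CountsTable, GeneModel, GenomeSequence
from .motif_scan import BRANCH_POINT, FIVE_PRIME_SS, SM_SITE, expand_consensus

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 1
    n_genes: int = 100
    intronic_fraction: float = 0.2
    smd_fraction: float = 0.1
    gene_length_range: tuple[int, int] = (900, 1400)
    gc_content: float = 0.5
    minus_strand_fraction: float = 0.3
    depth: float = 500.0
    dispersion: float = 0.02
    ip_enrichment: float = 8.0  # epsilon: Sm-bound gene IP multiplier
    mutant_fold_up: float = 4.0  # rho: SMD gene level in the splicing mutant
    rrp6_stabilization: float = 3.0  # spliced-product junction-read multiplier
    replicates: int = 2  # per wt/mutant condition
    ip_replicates: int = 2
    utr_length_range: tuple[int, int] = (60, 120)
    intron_length_range: tuple[int, int] = (60, 120)
    unspliced_reads_per_gene: int = 5
    annotated_junction_depth: float = 8.0
    smd_junction_depth_wt: float = 1.2
    prp40_junction_retention: float = 0.3
    read_anchor: int = 20
    intergenic_gap: int = 100
    noise_free: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.intronic_fraction <= 1 or not 0 <= self.smd_fraction <= 1:
            raise ValueError("fractions must be in [0,1]")
        if self.intronic_fraction + self.smd_fraction > 1:
            raise ValueError("intronic and SMD fractions overlap")
        if self.ip_enrichment < 1 or self.mutant_fold_up < 1:
            raise ValueError("enrichment factors must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass
class GeneTruth:
    gene_id: str
    strand: str
    intronic: bool
    smd_target: bool
    sm_bound: bool
    five_ss: int | None = None  # transcript index of donor motif start
    bp: int | None = None  # transcript index of BP motif start
    acceptor: int | None = None  # transcript index of the acceptor AG start
    sm_site: tuple[int, int] | None = None  # transcript interval
    intron_t: tuple[int, int] | None = None  # transcript interval
    intron_g: tuple[int, int] | None = None  # genomic interval
    base_mean: float = 0.0


@dataclass
class PlantedTruth:
    genes: dict[str, GeneTruth] = field(default_factory=dict)

    @property
    def smd_genes(self) -> set[str]:
        return {g for g, t in self.genes.items() if t.smd_target}

    @property
    def intronic_genes(self) -> set[str]:
        return {g for g, t in self.genes.items() if t.intronic}

    @property
    def intronless_genes(self) -> set[str]:
        return {g for g, t in self.genes.items() if not t.intronic}

    @property
    def sm_bound_genes(self) -> set[str]:
        return {g for g, t in self.genes.items() if t.sm_bound}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gid in sorted(self.genes):
            t = self.genes[gid]
            rows.append(
                {"gene_id": gid, "strand": t.strand, "intronic": t.intronic,
                 "smd_target": t.smd_target, "sm_bound": t.sm_bound,
                 "five_ss": t.five_ss, "bp": t.bp, "acceptor": t.acceptor,
                 "base_mean": t.base_mean}
            )
        return pd.DataFrame(rows).set_index("gene_id")


class GenerationError(RuntimeError):
    pass


def forbidden_literals() -> set[str]:
    """Every literal of the three screened motifs (kept out of backgrounds)."""
    return (
        expand_consensus(FIVE_PRIME_SS)
        | expand_consensus(BRANCH_POINT)
        | expand_consensus(SM_SITE)
    )


_FORBIDDEN_RE = re.compile(
    "(?=(" + "|".join(sorted(forbidden_literals(), key=len, reverse=True)) + "))"
)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(BASES, size=n, p=p))


def _clean_background(
    seq: list[str],
    protected: set[int],
    ag_free_windows: list[tuple[int, int]],
    rng: np.random.Generator,
    gc: float,
    max_iter: int = 500,
) -> None:
    """Redraw background bases until no unplanted motif literal remains.

    ``protected`` holds 0-based indices of planted bases, never redrawn.
    ``ag_free_windows`` are 0-based closed intervals that must contain no AG
    whose bases are both unprotected (keeps nearest-AG truths exact).
    """
    for _ in range(max_iter):
        s = "".join(seq)
        dirty: set[int] = set()
        for m in _FORBIDDEN_RE.finditer(s):
            span = range(m.start(), m.start() + len(m.group(1)))
            free = [i for i in span if i not in protected]
            if free:  # unplanted (or partially unplanted) occurrence
                dirty.update(free)
        for lo, hi in ag_free_windows:
            for m in re.finditer("(?=AG)", s[lo : hi + 1]):
                i = lo + m.start()
                free = [j for j in (i, i + 1) if j not in protected]
                if free:
                    dirty.update(free)
        if not dirty:
            return
        redraw = _random_bases(rng, len(dirty), gc)
        for i, base in zip(sorted(dirty), redraw):
            seq[i] = base
    raise GenerationError("background cleaning did not converge; shorten genes")


def _plant(seq: list[str], start0: int, literal: str, protected: set[int]) -> None:
    for k, base in enumerate(literal):
        seq[start0 + k] = base
        protected.add(start0 + k)


def _build_gene_sequence(
    rng: np.random.Generator, cfg: GeneratorConfig, kind: str
) -> tuple[str, dict]:
    """Sense-strand gene body with planted features.

    ``kind``: "plain" (no signals), "smd" (cryptic intron + Sm site) or
    "intronic" (annotated intron). Returns (sequence, feature dict with
    1-based transcript coordinates).
    """
    utr5 = int(rng.integers(*cfg.utr_length_range, endpoint=True))
    utr3 = int(rng.integers(*cfg.utr_length_range, endpoint=True))
    length = int(rng.integers(*cfg.gene_length_range, endpoint=True))
    cds_len = length - utr5 - utr3
    seq = _random_bases(rng, length, cfg.gc_content)
    protected: set[int] = set()
    ag_windows: list[tuple[int, int]] = []
    feats: dict = {"cds_start": utr5 + 1, "cds_end": utr5 + cds_len}
    if kind in ("smd", "intronic"):
        anchor = cfg.read_anchor + 10
        il = int(rng.integers(*cfg.intron_length_range, endpoint=True))
        # intron fully inside the CDS with exonic anchors on both sides
        lo = utr5 + anchor
        hi = utr5 + cds_len - anchor - il
        if hi <= lo:
            raise GenerationError("gene too short for the requested intron")
        i_start = int(rng.integers(lo, hi, endpoint=True))  # 0-based donor start
        i_end = i_start + il - 1
        bp_dist = int(rng.integers(15, min(40, il - 26), endpoint=True))
        acc0 = i_end - 1  # 0-based index of the acceptor A
        bp0 = acc0 - bp_dist
        bp_literal = "ACTAAC" + str(rng.choice(list("GAT")))
        _plant(seq, i_start, "GTATGT", protected)
        _plant(seq, bp0, bp_literal, protected)
        _plant(seq, acc0, "AG", protected)
        ag_windows.append((bp0 + 6, acc0 - 1))
        feats.update(
            five_ss=i_start + 1,
            bp=bp0 + 1,
            acceptor=acc0 + 1,
            intron_t=(i_start + 1, i_end + 1),
        )
        if kind == "smd":
            run_len = int(rng.integers(4, 6, endpoint=True))
            sm_literal = (
                str(rng.choice(list("AG"))) + "A" + "T" * run_len
                + "G" + str(rng.choice(list("AG")))
            )
            sm_end0 = i_start - int(rng.integers(5, 45, endpoint=True))
            sm_start0 = sm_end0 - len(sm_literal) + 1
            if sm_start0 < 0:
                raise GenerationError("no room for the Sm site")
            _plant(seq, sm_start0, sm_literal, protected)
            feats["sm_site"] = (sm_start0 + 1, sm_end0 + 1)
    _clean_background(seq, protected, ag_windows, rng, cfg.gc_content)
    return "".join(seq), feats


def generate_genome(
    config: GeneratorConfig,
) -> tuple[GenomeSequence, dict[str, GeneModel], PlantedTruth]:
    """Toy single-chromosome genome with planted gene structure.

    Deterministic given the config. Intronic genes carry one annotated
    GT..AG intron with an internal BP; SMD genes are annotated intronless
    but carry the full cryptic signal set; remaining genes are signal-free.
    """
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_genes
    n_intronic = round(n * config.intronic_fraction)
    n_smd = round(n * config.smd_fraction)
    order = rng.permutation(n)
    intronic_idx = set(order[:n_intronic].tolist())
    smd_idx = set(order[n_intronic : n_intronic + n_smd].tolist())

    chrom_parts: list[str] = []
    cursor = 1
    genes: dict[str, GeneModel] = {}
    truth = PlantedTruth()
    for i in range(n):
        gid = f"g{i + 1:04d}"
        kind = "intronic" if i in intronic_idx else "smd" if i in smd_idx else "plain"
        body, feats = _build_gene_sequence(rng, config, kind)
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        spacer = "".join(_random_bases(rng, config.intergenic_gap, config.gc_content))
        chrom_parts.append(spacer)
        cursor += config.intergenic_gap
        g_start = cursor
        g_end = cursor + len(body) - 1
        inserted = body if strand == "+" else _revcomp(body)
        chrom_parts.append(inserted)
        cursor = g_end + 1

        intron_g = None
        introns: list[tuple[int, int]] = []
        if "intron_t" in feats:
            ts, te = feats["intron_t"]
            if strand == "+":
                intron_g = (g_start + ts - 1, g_start + te - 1)
            else:
                intron_g = (g_end - te + 1, g_end - ts + 1)
            if kind == "intronic":
                introns = [intron_g]
        genes[gid] = GeneModel(
            gene_id=gid, chrom="chrS", strand=strand, start=g_start, end=g_end,
            cds_start=feats["cds_start"], cds_end=feats["cds_end"], introns=introns,
        )
        truth.genes[gid] = GeneTruth(
            gene_id=gid, strand=strand,
            intronic=(kind == "intronic"),
            smd_target=(kind == "smd"),
            sm_bound=(kind in ("intronic", "smd")),
            five_ss=feats.get("five_ss"),
            bp=feats.get("bp"),
            acceptor=feats.get("acceptor"),
            sm_site=feats.get("sm_site"),
            intron_t=feats.get("intron_t"),
            intron_g=intron_g,
        )
    chrom_parts.append("".join(_random_bases(rng, config.intergenic_gap, config.gc_content)))
    genome = GenomeSequence({"chrS": "".join(chrom_parts)})
    return genome, genes, truth


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------------------
# BDF2-like deterministic fixture
# ---------------------------------------------------------------------------

BDF2_5SS = 33  # fixture choice: the printed record gives no donor coordinate
BDF2_BP_PROXIMAL = 254
BDF2_BP_DISTAL = 1660
BDF2_ACCEPTOR = 1672
BDF2_ALT_ACCEPTOR = 1702
BDF2_LENGTH = 1800


def bdf2_like_fixture() -> tuple[str, GeneModel, dict]:
    """Deterministic transcript reproducing the BDF2 splice-site geometry.

    Signals sit at the printed coordinates (+1 = A of the ATG): donor at
    +33 (a documented fixture choice), branch points at +254 and +1660,
    acceptor AG at +1672 and the alternative acceptor AG at +1702. The
    background is pyrimidine-only, so the planted literals are the only
    motif matches and the two planted AGs are the only AG dinucleotides —
    in particular there is no AG between the proximal BP and +1672.
    """
    rng = np.random.default_rng(20130815)
    seq = list(rng.choice(np.array(list("CT")), size=BDF2_LENGTH))
    for pos, literal in (
        (BDF2_5SS, "GTATGT"),
        (BDF2_BP_PROXIMAL, "ACTAACA"),
        (BDF2_BP_DISTAL, "ACTAACT"),
        (BDF2_ACCEPTOR, "AG"),
        (BDF2_ALT_ACCEPTOR, "AG"),
    ):
        for k, base in enumerate(literal):
            seq[pos - 1 + k] = base
    transcript = "".join(seq)
    gene = GeneModel(
        gene_id="BDF2_like", chrom="chrBDF2", strand="+",
        start=1, end=BDF2_LENGTH, cds_start=1, cds_end=BDF2_LENGTH,
    )
    truth = {
        "five_ss": BDF2_5SS,
        "bp": [BDF2_BP_PROXIMAL, BDF2_BP_DISTAL],
        "acceptors": [BDF2_ACCEPTOR, BDF2_ALT_ACCEPTOR],
    }
    return transcript, gene, truth


# ---------------------------------------------------------------------------
# Count and alignment simulators
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def sample_conditions(config: GeneratorConfig) -> dict[str, str]:
    """Sample name -> condition label for the simulated library design."""
    cond: dict[str, str] = {}
    for i in range(1, config.ip_replicates + 1):
        cond[f"ip_{i}"] = "ip"
    cond["mock"] = "mock"
    for label in ("wt", "prp40", "rrp6"):
        for i in range(1, config.replicates + 1):
            cond[f"{label}_{i}"] = label
    return cond


def simulate_counts(config: GeneratorConfig, truth: PlantedTruth) -> CountsTable:
    """Negative-binomial count libraries with the planted IP / mutant structure.

    Gene base means are log-normal around the configured depth. Sm-bound
    genes are multiplied by epsilon in IP samples; SMD targets by rho in the
    splicing-mutant samples.
    """
    rng = np.random.default_rng([config.seed, 1])
    gene_ids = sorted(truth.genes)
    n = len(gene_ids)
    base = config.depth * np.exp(rng.normal(-0.125, 0.5, size=n))
    for gid, mu in zip(gene_ids, base):
        truth.genes[gid].base_mean = float(mu)
    bound = np.array([truth.genes[g].sm_bound for g in gene_ids])
    smd = np.array([truth.genes[g].smd_target for g in gene_ids])
    conditions = sample_conditions(config)
    data = {}
    for sample, cond in conditions.items():
        mean = base.copy()
        if cond == "ip":
            mean = mean * np.where(bound, config.ip_enrichment, 1.0)
        elif cond == "prp40":
            mean = mean * np.where(smd, config.mutant_fold_up, 1.0)
        data[sample] = _nb_draw(rng, mean, config.dispersion)
    df = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    return CountsTable(df, conditions)


def simulate_spliced_alignments(
    config: GeneratorConfig,
    truth: PlantedTruth,
    genes: dict[str, GeneModel],
) -> dict[str, list[AlignmentRecord]]:
    """Per-condition gapped alignments over the toy genome.

    Every gene gets unspliced (single-match) reads. Annotated introns get
    junction reads in all conditions (reduced by the retention factor in the
    splicing mutant); planted SMD introns get junction reads whose depth is
    multiplied by the stabilization factor in the exosome-mutant-like
    condition. In ``noise_free`` mode junction counts equal their rounded
    expectations instead of Poisson draws.
    """
    rng = np.random.default_rng([config.seed, 2])
    a = config.read_anchor
    out: dict[str, list[AlignmentRecord]] = {}
    for cond in ("wt", "prp40", "rrp6"):
        reads: list[AlignmentRecord] = []
        for gid in sorted(genes):
            gene = genes[gid]
            t = truth.genes[gid]
            for i in range(config.unspliced_reads_per_gene):
                pos = int(rng.integers(gene.start, gene.end - 2 * a + 1, endpoint=True))
                reads.append(
                    AlignmentRecord(f"{cond}:{gid}:u{i}", gene.chrom, pos, [("M", 2 * a)])
                )
            if t.intron_g is None:
                continue
            if t.intronic:
                lam = config.annotated_junction_depth
                if cond == "prp40":
                    lam *= config.prp40_junction_retention
            else:  # planted SMD intron
                lam = config.smd_junction_depth_wt
                if cond == "prp40":
                    lam *= config.prp40_junction_retention
                elif cond == "rrp6":
                    lam *= config.rrp6_stabilization
            n_junc = int(round(lam)) if config.noise_free else int(rng.poisson(lam))
            gs, ge = t.intron_g
            il = ge - gs + 1
            for i in range(n_junc):
                reads.append(
                    AlignmentRecord(
                        f"{cond}:{gid}:j{i}", gene.chrom, gs - a,
                        [("M", a), ("N", il), ("M", a)],
                    )
                )
        out[cond] = reads
    return out
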