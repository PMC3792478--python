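# Methods

## Coordinate conventions

Genomic coordinates are 1-based closed (GFF3 dialect) throughout; BED output
converts to 0-based half-open. Transcript positions are 1-based indices
along the sense strand of the gene body; minus-strand genes are
reverse-complemented at ingest so every scan is a sense-strand operation.
Reports can convert to the ATG-relative convention (+1 = first base of the
start codon, no position zero) via `CoordinateMap`. All motif coordinates
refer to the **first base of the match**. The literature never states
whether printed branch-point coordinates denote the motif start or the
branch adenosine; the motif-start convention is used because it reproduces
the published 12-nt BP-to-3′ss spacing of the BDF2 locus exactly
(1672 − 1660 = 12), and it is applied uniformly. RNA alphabet (U) is mapped
to T at ingest; N never matches any motif element (conservative on masked
sequence).

## Motif scanning

Degenerate consensi are modelled as sequences of fixed bases, choice sets
and bounded homopolymer runs, compiled to an overlapping-match regular
expression (`(?=(...))`). Each start position is reported once with the
longest valid match (relevant only for the Sm site's U₄₋₆ run). This choice
makes site counts well defined: overlapping run extensions are never double
counted. Acceptors are bare AG dinucleotides — the junction criterion in
the field is GU/AG, and yeast 3′ss have little consensus beyond the AG —
so no extended 3′ss model is imposed.

"Signals in correct order" requires a branch point starting at least
`min_5ss_bp_spacing` nt (default 20, configurable) downstream of a donor
start. No minimum is stated in the literature; the shortest natural yeast
donor-to-BP spacings motivate a small positive floor, and the funnel count
is monotone non-increasing in this parameter (property-tested). The Sm
proximity rule flags an Sm site whose last base falls within the 50 nt
immediately upstream of a donor start (window boundary inclusive).

## Splice-event model

Each branch point is paired with the **nearest downstream AG** (the
observed +1672 → +1702 shift after acceptor mutation is nearest-next
behaviour). Spacing is acceptor start minus BP start. A pairing supports
two-step splicing iff spacing ≤ `d_max`; default 100 nt — 12 nt works in
vivo, >1400 nt does not, and typical yeast BP-to-3′ss distances are tens of
nt, so 100 is a permissive upper bound. Increasing `d_max` never converts a
two-step event to cleavage-only (tested). The two-step intron spans the
donor motif start through the G of the acceptor AG.

Frame consequences of a two-step event: introns entirely in the 5′ or 3′
UTR leave the ORF intact; CDS introns whose length is not a multiple of 3
are frameshifts; in-frame deletions are checked for a new stop codon by
translating the spliced CDS (Biopython) against the original stop — an
independent codon-walker oracle backs this in the tests. Introns straddling
a CDS boundary are treated as CDS introns; the generator never plants such
events.

## Enrichment and normalization

The original ranking metric for IP enrichment is unstated; the package uses
log₂((CPM_IP + p)/(CPM_control + p)) with p = 1 count-per-million. Working
on the CPM scale before adding the pseudocount makes the score exactly
invariant to library scaling and antisymmetric under swapping IP and
control; ties at the top-K boundary break lexicographically by gene id so
runs are bit-reproducible. K defaults to 500 (the screen's published cut);
for 100-gene simulations the analysis uses K = 40 — comfortably above the
30 truly bound genes, mirroring the generous published cut relative to its
~6000-gene universe.

Count normalization is median-of-ratios: a gene-wise geometric-mean
reference over all-zero-free genes, sample factors as the linear-space
median of count/reference ratios (this matches DESeq2; cross-checked
against `pydeseq2.preprocessing.deseq2_norm` in the tests). Size factors
are only defined up to a common scale, so normalized counts are anchored
to a dimensionless per-million scale (mean per-sample normalized total =
10⁶) before the fold-change pseudocount is added; fold changes are then
degree-zero in the input counts and condition-wise library scaling cancels
exactly. The screen filters on fold change alone (≥ θ, default 3), with no
significance test — mirroring the original design, which reported a fold
threshold only.

## Junction calling

Junctions are extracted from skip (N) operations of provided gapped
alignments; alignment itself is out of scope. Support counts distinct read
ids. Canonical means GT..AG on the host gene's sense strand;
`min_support` defaults to 2 because unreplicated junction reads are
indistinguishable from alignment noise. A junction contained in two genes
is assigned to the one whose strand makes it canonical; if both or neither
qualify it is reported as intergenic (deterministic, gene-id order). The
BP-within-intron check scans the intron's sense sequence for the BP
consensus and reports the distance from the BP nearest the acceptor to the
acceptor AG start.

## Candidate tiers

Tier A = reproducibly Sm-enriched ∧ signals in order ∧ ≥θ-fold up. Junction
evidence deliberately does **not** gate tier A: a genuine SMD target whose
spliced products are destroyed rapidly can leave no junction reads at all.
Tier B = not A, but canonical junction + BP within the intron. Genes
missing from an evidence table keep a null field rather than being dropped,
for auditability. The summary statistic is the percentage of intronless
genes in tiers A∪B.

## Synthetic data

The generator emulates the statistical structure of the original libraries
so the full screen runs without any download. Defaults define the study
conditions: 100 genes (lengths 900–1400 nt, UTRs 60–120 nt, uniform base
composition, ~30% minus-strand), 20% intronic, 10% planted SMD targets
(disjoint, intronless); NB counts with depth 500 (log-normal gene base
means) and gene-wise dispersion 0.02 — typical for high-count yeast bulk
RNA-seq replicates; two replicates per condition (the original replicate
structure is unstated); IP enrichment ε = 8 on Sm-bound genes (SMD ∪
intronic); mutant fold-up ρ = 4 on SMD targets; junction-read depths of 8
(annotated introns), 1.2 (SMD introns, wild type), ×0.3 retention in the
splicing mutant and ×3 stabilization in the exosome mutant.

Backgrounds are **rejection-sampled**: any unplanted donor/BP/Sm literal
anywhere in a gene body, or stray AG between a planted BP and its acceptor,
is redrawn. This guarantees planted-truth recovery tests are exact rather
than tolerance-based. The calibration tests that state dispersion 0.05 use
that value explicitly. Note that a *single* gene's fold-change estimate at
depth 500 with dispersion 0.05 and two replicates has a log-scale standard
deviation of ≈0.23, so per-gene estimates land in [2.5, 3.6] only ~60% of
the time; calibration is therefore assessed on the mean fold change across
the planted gene set, whose sampling error is √10 smaller.

What the generator does **not** model: read errors, positional coverage
bias, multi-mapping, gene-length effects on counts, lariat reads,
non-canonical junctions, overlapping genes. Passing recovery tests
demonstrate correctness of the pipeline's logic under the assumed
statistical structure, not performance on real libraries — in particular
the real screen's genome-wide counts depend on the annotation release and
sequencing depth and are not reproduced here.

## Fixture

The BDF2-like fixture is a deterministic 1800-nt transcript with the donor
at +33 (the published record prints no donor coordinate; any clean upstream
position serves, and the choice is recorded in the fixture truth), branch
points at +254 and +1660, acceptors at +1672 and +1702. The background is
pyrimidine-only, so the planted elements are provably the only motif and AG
occurrences; in particular no AG intervenes between +254 and +1672, making
the proximal branch point's nearest-acceptor spacing 1418 nt.

## Problem sizes

Test and acceptance runs use 100-gene genomes, 20-seed recovery screens,
1000×1-kb oracle comparisons, 2×10⁶-position background-rate estimates and
100-seed calibration loops; the whole suite completes in well under a
minute on one CPU.
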