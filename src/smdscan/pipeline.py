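"""End-to-end composition of the SMD screen on in-memory objects.

Thin glue over the module-level operations: signal profiling, the Sm-IP
funnel, the fold-change filter, junction calling, and tiered candidate
integration. The CLI subcommands and the simulation-recovery tests both go
through :func:`run_screen` so they exercise the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import differential, junction_detect, motif_scan
from .candidate_call import SMDCandidate, integrate_evidence, summarize
from .io_formats import AlignmentRecord, CountsTable, GeneModel, GenomeSequence
from .ip_enrichment import FunnelReport, build_funnel
from .junction_detect import JunctionRecord


@dataclass
class ScreenParams:
    ip_samples: tuple[str, str] = ("ip_1", "ip_2")
    control_sample: str = "mock"
    k: int = 40
    wt_samples: tuple[str, ...] = ("wt_1", "wt_2")
    mut_samples: tuple[str, ...] = ("prp40_1", "prp40_2")
    theta: float = 3.0
    min_5ss_bp_spacing: int = 20
    sm_window: int = 50
    d_max: int = 100
    min_support: int = 2


@dataclass
class ScreenResult:
    signal_table: pd.DataFrame
    signal_funnel: dict[str, int]
    funnel: FunnelReport
    up_set: set[str]
    junctions: list[JunctionRecord]
    junction_stats: dict[str, float]
    candidates: list[SMDCandidate]
    summary: dict[str, float] = field(default_factory=dict)


def call_junctions(
    alignments: list[AlignmentRecord],
    genome: GenomeSequence,
    genes: dict[str, GeneModel],
    min_support: int = 2,
) -> tuple[list[JunctionRecord], dict[str, float]]:
    """Extract, canonical-filter, classify and BP-flag junctions."""
    raw = junction_detect.extract_junctions(alignments, genome)
    kept = junction_detect.filter_canonical(raw, genome, genes, min_support)
    classified, stats = junction_detect.classify_junctions(kept, genes)
    flagged = [
        junction_detect.bp_within_intron(j, genome, genes)
        if j.host_gene is not None else j
        for j in classified
    ]
    return flagged, stats


def run_screen(
    genome: GenomeSequence,
    genes: dict[str, GeneModel],
    counts: CountsTable,
    alignments: list[AlignmentRecord],
    params: ScreenParams | None = None,
) -> ScreenResult:
    params = params or ScreenParams()
    signal_table, signal_funnel = motif_scan.screen_gene_set(
        genes, genome, params.min_5ss_bp_spacing, params.sm_window
    )
    funnel = build_funnel(
        counts, genes, signal_table, params.ip_samples,
        params.control_sample, params.k,
    )
    records = differential.fold_changes(
        counts, list(params.wt_samples), list(params.mut_samples),
        theta=params.theta,
    )
    up_set = differential.threshold_up(records, params.theta, genes, "intronless")
    junctions, junction_stats = call_junctions(
        alignments, genome, genes, params.min_support
    )
    fc = {r.gene_id: r.fold_change for r in records}
    candidates = integrate_evidence(funnel, signal_table, up_set, junctions, fc)
    result = ScreenResult(
        signal_table=signal_table,
        signal_funnel=signal_funnel,
        funnel=funnel,
        up_set=up_set,
        junctions=junctions,
        junction_stats=junction_stats,
        candidates=candidates,
    )
    result.summary = summarize(candidates, genes)
    return result
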