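"""Sm-IP enrichment ranking and the replicate-intersection funnel.

Models the RIP-seq arm of the screen: transcripts co-precipitating with the
Sm ring are ranked per replicate by a library-scaled IP/control log-ratio,
the top-K sets of two replicates are intersected, and the reproducibly
bound set is partitioned by intron status and crossed with the
splice-signal table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CountsTable, GeneModel

DEFAULT_K = 500
DEFAULT_PSEUDOCOUNT = 1.0  # counts per million


@dataclass(frozen=True)
class EnrichmentRecord:
    gene_id: str
    ip_count: int
    control_count: int
    score: float  # log2 (CPM_ip + p) / (CPM_control + p)
    rank: int  # 1 = most enriched


@dataclass
class FunnelReport:
    """Top-K intersection of two IP replicates plus downstream partitions."""

    k: int
    top_a: set[str]
    top_b: set[str]
    common: set[str] = field(init=False)
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.common = self.top_a & self.top_b
        self.counts.setdefault("common", len(self.common))


def enrichment_scores(
    counts: CountsTable,
    ip_sample: str,
    control_sample: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[EnrichmentRecord]:
    """Rank genes by pseudocounted, library-scaled log2 IP/control ratio.

    Counts are scaled to counts-per-million before the pseudocount is added,
    so the score is exactly invariant to uniform library scaling and
    antisymmetric under swapping IP and control. Ties rank by gene id.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    for sample in (ip_sample, control_sample):
        if sample not in counts.counts.columns:
            raise KeyError(f"sample {sample!r} not in counts table")
    ip = counts.counts[ip_sample].to_numpy(dtype=float)
    ctl = counts.counts[control_sample].to_numpy(dtype=float)
    cpm_ip = ip / ip.sum() * 1e6
    cpm_ctl = ctl / ctl.sum() * 1e6
    score = np.log2((cpm_ip + pseudocount) / (cpm_ctl + pseudocount))
    df = pd.DataFrame(
        {"gene_id": counts.gene_ids, "ip": ip.astype(int), "ctl": ctl.astype(int),
         "score": score}
    ).sort_values(["score", "gene_id"], ascending=[False, True], kind="mergesort")
    return [
        EnrichmentRecord(row.gene_id, row.ip, row.ctl, row.score, rank)
        for rank, row in enumerate(df.itertuples(index=False), start=1)
    ]


def topk_intersection(
    rep_a: list[EnrichmentRecord], rep_b: list[EnrichmentRecord], k: int = DEFAULT_K
) -> FunnelReport:
    """Intersect the top-K gene sets of two ranked replicates."""
    if k <= 0:
        raise ValueError("K must be positive")
    if k > len(rep_a) or k > len(rep_b):
        raise ValueError("K exceeds the number of ranked genes")
    top_a = {r.gene_id for r in rep_a if r.rank <= k}
    top_b = {r.gene_id for r in rep_b if r.rank <= k}
    return FunnelReport(k=k, top_a=top_a, top_b=top_b)


def partition_by_intron_status(
    gene_set: set[str], annotation: dict[str, GeneModel]
) -> tuple[set[str], set[str]]:
    """Split a gene set into (intronic, intronless) by annotation."""
    unknown = gene_set - annotation.keys()
    if unknown:
        raise KeyError(f"genes not in annotation: {sorted(unknown)}")
    intronic = {g for g in gene_set if annotation[g].intron_status == "intronic"}
    return intronic, gene_set - intronic


def cross_with_signals(
    intronless_set: set[str], signal_table: pd.DataFrame
) -> dict[str, int]:
    """Count enriched intronless genes with ordered splice signals / Sm sites."""
    missing = intronless_set - set(signal_table.index)
    if missing:
        raise KeyError(f"genes missing from signal table: {sorted(missing)}")
    sub = signal_table.loc[sorted(intronless_set)]
    with_signals = sub[sub.signals_in_order]
    return {
        "intronless_in_common": len(intronless_set),
        "with_signals_in_order": int(sub.signals_in_order.sum()),
        "with_sm_near_5ss": int(with_signals.sm_near_5ss.sum()),
    }


def build_funnel(
    counts: CountsTable,
    annotation: dict[str, GeneModel],
    signal_table: pd.DataFrame,
    ip_samples: tuple[str, str],
    control_sample: str,
    k: int = DEFAULT_K,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> FunnelReport:
    """Full funnel: rank both replicates, intersect, partition, cross."""
    rep_a = enrichment_scores(counts, ip_samples[0], control_sample, pseudocount)
    rep_b = enrichment_scores(counts, ip_samples[1], control_sample, pseudocount)
    report = topk_intersection(rep_a, rep_b, k)
    intronic, intronless = partition_by_intron_status(report.common, annotation)
    report.counts["intronic_in_common"] = len(intronic)
    report.counts["intronless_in_common"] = len(intronless)
    report.counts.update(cross_with_signals(intronless, signal_table))
    return report
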