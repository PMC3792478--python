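"""Evidence integration into tiered SMD candidates.

Tier A is the three-way rule that produced the screen's strongest
candidates: reproducible Sm co-precipitation, donor+BP splice signals in
the correct order, and at least a ``theta``-fold rise in the
splicing-mutant library. Junction evidence does not gate tier A (a target
whose spliced products are degraded too fast may leave no junction reads);
instead, genes missing tier A but carrying a canonical junction with a
branch-point consensus inside the inferred intron form tier B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_formats import GeneModel
from .ip_enrichment import FunnelReport
from .junction_detect import JunctionRecord


@dataclass(frozen=True)
class EvidenceVector:
    sm_enriched: bool = False
    signals_in_order: bool = False
    fold_up: bool = False
    junction_support: bool = False
    bp_in_intron: bool = False


@dataclass
class SMDCandidate:
    gene_id: str
    evidence: EvidenceVector
    tier: str = field(init=False)
    fold_change: float | None = None
    rank: int | None = None
    junction_reads: int | None = None
    bp_to_acceptor: int | None = None

    def __post_init__(self) -> None:
        self.tier = assign_tier(self.evidence)


def assign_tier(ev: EvidenceVector) -> str:
    """Pure tier rule over the evidence vector."""
    if ev.sm_enriched and ev.signals_in_order and ev.fold_up:
        return "A"
    if ev.junction_support and ev.bp_in_intron:
        return "B"
    return "none"


def integrate_evidence(
    funnel: FunnelReport,
    signal_table: pd.DataFrame,
    up_set: set[str],
    junctions: list[JunctionRecord],
    fold_changes: dict[str, float] | None = None,
) -> list[SMDCandidate]:
    """One candidate per gene in the signal table's universe.

    The signal table defines the gene universe; funnel/up-set genes outside
    it are orphans and raise. Sorted by (tier, descending fold change,
    gene id).
    """
    universe = set(signal_table.index)
    orphans = (funnel.common | up_set) - universe
    if orphans:
        raise ValueError(f"gene ids outside the annotation universe: {sorted(orphans)}")
    junc_by_gene: dict[str, JunctionRecord] = {}
    for j in junctions:
        if j.host_gene is None or not j.canonical:
            continue
        best = junc_by_gene.get(j.host_gene)
        if best is None or j.support > best.support:
            junc_by_gene[j.host_gene] = j
    candidates = []
    for gid in signal_table.index:
        j = junc_by_gene.get(gid)
        ev = EvidenceVector(
            sm_enriched=gid in funnel.common,
            signals_in_order=bool(signal_table.loc[gid, "signals_in_order"]),
            fold_up=gid in up_set,
            junction_support=j is not None,
            bp_in_intron=bool(j.bp_in_intron) if j is not None else False,
        )
        candidates.append(
            SMDCandidate(
                gene_id=gid,
                evidence=ev,
                fold_change=(fold_changes or {}).get(gid),
                junction_reads=j.support if j is not None else None,
                bp_to_acceptor=j.bp_to_acceptor if j is not None else None,
            )
        )
    tier_order = {"A": 0, "B": 1, "none": 2}
    candidates.sort(
        key=lambda c: (
            tier_order[c.tier],
            -(c.fold_change if c.fold_change is not None else float("-inf")),
            c.gene_id,
        )
    )
    return candidates


def summarize(
    candidates: list[SMDCandidate], annotation: dict[str, GeneModel]
) -> dict[str, float]:
    """Tier counts and the headline statistic: % of intronless genes with
    any SMD evidence (tier A or B)."""
    n_intronless = sum(
        1 for g in annotation.values() if g.intron_status == "intronless"
    )
    tiers = {"A": 0, "B": 0, "none": 0}
    evident_intronless = 0
    for c in candidates:
        tiers[c.tier] += 1
        if c.tier != "none" and annotation[c.gene_id].intron_status == "intronless":
            evident_intronless += 1
    pct = 100.0 * evident_intronless / n_intronless if n_intronless else 0.0
    return {
        "tier_A": tiers["A"],
        "tier_B": tiers["B"],
        "tier_none": tiers["none"],
        "n_intronless": n_intronless,
        "pct_intronless_with_evidence": pct,
    }


def candidate_table(candidates: list[SMDCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id, "tier": c.tier,
                "sm_enriched": c.evidence.sm_enriched,
                "signals_in_order": c.evidence.signals_in_order,
                "fold_up": c.evidence.fold_up,
                "junction_support": c.evidence.junction_support,
                "bp_in_intron": c.evidence.bp_in_intron,
                "fold_change": c.fold_change,
                "junction_reads": c.junction_reads,
                "bp_to_acceptor": c.bp_to_acceptor,
            }
            for c in candidates
        ]
    ).set_index("gene_id")
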