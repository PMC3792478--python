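"""Library normalization and the fold-change filter for mutant contrasts.

Normalization is median-of-ratios: each sample's size factor is the median,
over genes with no zero count, of that sample's count divided by the
gene's geometric mean across samples. Fold changes compare mean normalized
counts between conditions with a pseudocount; the screen keeps intronless
genes whose splicing-mutant level rises at least ``theta``-fold (default 3).
No significance test is applied — the screen is a pure fold filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CountsTable, GeneModel

DEFAULT_THETA = 3.0
DEFAULT_PSEUDOCOUNT = 1.0


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class DifferentialRecord:
    gene_id: str
    mean_wt: float  # normalized mean (per-million scale), wild-type condition
    mean_mut: float  # normalized mean (per-million scale), mutant condition
    fold_change: float  # pseudocounted mutant / wild-type
    up: bool


def size_factors(counts: CountsTable, samples: list[str] | None = None) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Genes with any zero count are excluded from the median; at least one
    all-nonzero gene is required.
    """
    df = counts.counts[samples] if samples is not None else counts.counts
    if df.shape[1] < 2:
        raise NormalizationError("need at least two samples")
    mat = df.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise NormalizationError("no gene with nonzero counts in every sample")
    sub = mat[nonzero]
    geomean = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / geomean[:, None], axis=0)
    return pd.Series(factors, index=df.columns, name="size_factor")


def normalized_counts(
    counts: CountsTable, samples: list[str] | None = None
) -> pd.DataFrame:
    """Factor-corrected counts on a per-million scale.

    After dividing by size factors the matrix is rescaled so the mean
    per-sample total is one million. Size factors (hence normalized counts)
    are only defined up to a common scale; anchoring to this dimensionless
    scale makes every downstream ratio statistic exactly invariant to
    condition-wise library scaling even with a pseudocount.
    """
    df = counts.counts[samples] if samples is not None else counts.counts
    norm = df / size_factors(counts, samples)
    grand = norm.to_numpy().sum() / norm.shape[1]
    return norm / grand * 1e6


def fold_changes(
    counts: CountsTable,
    wt_samples: list[str],
    mut_samples: list[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    theta: float = DEFAULT_THETA,
) -> list[DifferentialRecord]:
    """Per-gene mutant/wild-type fold change on normalized means.

    fc = (mean_norm_mut + p) / (mean_norm_wt + p); ``up`` flags fc >= theta.
    """
    if not wt_samples or not mut_samples:
        raise ValueError("both conditions need at least one sample")
    if theta <= 0:
        raise ValueError("theta must be positive")
    norm = normalized_counts(counts, list(wt_samples) + list(mut_samples))
    mean_wt = norm[wt_samples].mean(axis=1)
    mean_mut = norm[mut_samples].mean(axis=1)
    fc = (mean_mut + pseudocount) / (mean_wt + pseudocount)
    return [
        DifferentialRecord(g, float(mean_wt[g]), float(mean_mut[g]), float(fc[g]),
                           bool(fc[g] >= theta))
        for g in counts.gene_ids
    ]


def threshold_up(
    records: list[DifferentialRecord],
    theta: float = DEFAULT_THETA,
    annotation: dict[str, GeneModel] | None = None,
    restrict_to: str | None = "intronless",
) -> set[str]:
    """Genes with fold change >= theta, optionally restricted by intron status.

    Monotone in theta: a stricter threshold yields a subset.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    up = {r.gene_id for r in records if r.fold_change >= theta}
    if restrict_to is not None and annotation is not None:
        up = {g for g in up if annotation[g].intron_status == restrict_to}
    return up


def differential_table(records: list[DifferentialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene_id": r.gene_id, "mean_wt": r.mean_wt, "mean_mut": r.mean_mut,
             "fold_change": r.fold_change, "up": r.up}
            for r in records
        ]
    ).set_index("gene_id")
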