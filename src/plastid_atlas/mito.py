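"""Organelle co-regulation: mean Pearson correlation of each plastid
transporter with a panel of mitochondria-encoded genes.

Correlations are computed across condition-group values (by default the
per-group means of the expression matrix, e.g. 17 light:dark acclimation
processing groups) using pairwise-complete observations. For each
transporter the arithmetic mean of its pairwise correlations with the panel
is reported overall and split by mitochondrial gene function (organelle
biogenesis vs respiratory complexes); transporters whose means exceed the
crosstalk cut on BOTH functional axes are flagged as putative
plastid-mitochondria crosstalk candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core_io import ExpressionMatrix, ThresholdConfig

MITO_FUNCTION_CLASSES = ("biogenesis", "respiratory_complex")


@dataclass(frozen=True)
class MitoGene:
    """One mitochondria-encoded panel gene with its function class."""

    gene_id: str
    function_class: str

    def __post_init__(self) -> None:
        if self.function_class not in MITO_FUNCTION_CLASSES:
            raise ValueError(
                f"function_class must be one of {MITO_FUNCTION_CLASSES}, "
                f"got {self.function_class!r}"
            )


@dataclass(frozen=True)
class MitoCorrelationResult:
    transporter_id: str
    mean_r_overall: float | None
    mean_r_biogenesis: float | None
    mean_r_respiratory: float | None
    n_mito_genes_used: int


def condition_correlation(
    x: np.ndarray, y: np.ndarray, min_points: int = 3
) -> float | None:
    """Pearson r over pairwise-complete observations.

    Returns None (undefined) with fewer than ``min_points`` shared
    non-missing values or when either vector has zero variance on the shared
    support. Never silently imputes missing values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < min_points:
        return None
    xs, ys = x[mask], y[mask]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return None
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(xs, ys)[0, 1]
    if not np.isfinite(r):  # variance underflow on near-constant input
        return None
    return float(np.clip(r, -1.0, 1.0))


def _condition_values(expr: ExpressionMatrix, cfg: ThresholdConfig) -> ExpressionMatrix:
    if cfg.group_reduce == "mean" and expr.sample_groups:
        return expr.group_means()
    return expr


def mean_mito_correlation(
    transporter_id: str,
    expr: ExpressionMatrix,
    panel: Sequence[MitoGene],
    cfg: ThresholdConfig,
) -> MitoCorrelationResult:
    """Average the transporter's pairwise r over the mitochondrial panel.

    Panel genes absent from the matrix, and pairs with undefined
    correlations, are excluded from every mean; ``n_mito_genes_used`` counts
    the pairs that did contribute. Means are None when no pair contributed.
    """
    if transporter_id not in expr:
        raise KeyError(f"transporter {transporter_id!r} not in expression matrix")
    if not panel:
        raise ValueError("mitochondrial panel is empty")
    values = _condition_values(expr, cfg)
    if cfg.log2_expression:
        values = ExpressionMatrix(
            values.genes,
            values.samples,
            np.log2(values.values),
            values.sample_groups,
        )
    x = values.row(transporter_id)
    by_class: dict[str, list[float]] = {c: [] for c in MITO_FUNCTION_CLASSES}
    for gene in panel:
        if gene.gene_id not in values:
            continue
        r = condition_correlation(x, values.row(gene.gene_id))
        if r is not None:
            by_class[gene.function_class].append(r)

    def mean(rs: list[float]) -> float | None:
        return float(np.mean(rs)) if rs else None

    all_rs = by_class["biogenesis"] + by_class["respiratory_complex"]
    return MitoCorrelationResult(
        transporter_id=transporter_id,
        mean_r_overall=mean(all_rs),
        mean_r_biogenesis=mean(by_class["biogenesis"]),
        mean_r_respiratory=mean(by_class["respiratory_complex"]),
        n_mito_genes_used=len(all_rs),
    )


def crosstalk_candidates(
    results: Sequence[MitoCorrelationResult], cfg: ThresholdConfig
) -> tuple[set[str], set[str]]:
    """Split transporters into positively and negatively coupled candidates.

    Positive: mean r above the cut on both the biogenesis and the
    respiratory axis; negative: below minus the cut on both. The two sets
    are disjoint by construction.
    """
    cut = cfg.crosstalk_cut
    positive, negative = set(), set()
    for res in results:
        b, r = res.mean_r_biogenesis, res.mean_r_respiratory
        if b is None or r is None:
            continue
        if b > cut and r > cut:
            positive.add(res.transporter_id)
        elif b < -cut and r < -cut:
            negative.add(res.transporter_id)
    return positive, negative
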