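"""Seven-condition composite evidence score for transporter-gene linkage.

For each (transporter, candidate gene) pair seven independent indicators are
summed into a 0-7 score: (i) shared co-expression (WGCNA) module; (ii)-(iv)
Pearson correlation strictly above the threshold in RNA-seq, microarray and
cross-species-homolog microarray data; (v) plastid targeting of the
candidate gene; (vi) shared inferred evolutionary origin point; (vii) shared
pattern of inferred loss. Genes scoring at least the association cut
(default 3) are deemed associated; pathways recruiting more than three
associated genes (default >= 4) are linked; linked pathways collapse onto
five functional categories for Venn-style profiling.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core_io import ThresholdConfig

#: the five functional categories of the pathway map
FIVE_CATEGORIES = (
    "photosynthesis-related",
    "amino-acid-related",
    "biogenesis-related",
    "carbon-related",
    "lipid-related",
)


@dataclass(frozen=True)
class EvidenceBundle:
    """The seven condition inputs for one (transporter, gene) pair.

    Correlation fields are ``None`` when undefined (gene absent from the
    dataset, fewer than 3 shared observations, or zero variance); undefined
    correlations contribute 0 to the score.
    """

    transporter_id: str
    gene_id: str
    same_wgcna_module: bool = False
    r_rnaseq: float | None = None
    r_microarray: float | None = None
    r_tp_homolog_microarray: float | None = None
    plastid_targeted: bool = False
    same_origin: bool = False
    same_loss_pattern: bool = False

    def __post_init__(self) -> None:
        for name in ("r_rnaseq", "r_microarray", "r_tp_homolog_microarray"):
            r = getattr(self, name)
            if r is not None and not (-1.0 <= r <= 1.0 + 1e-12):
                raise ValueError(f"{name}={r} outside [-1, 1]")


@dataclass(frozen=True)
class EvolutionAnnotation:
    """Inferred origin point and loss pattern of one gene.

    ``origin_ancestor`` names the earliest common ancestor (of the query
    lineage's photosynthetic relatives) in which homologues are detected;
    ``loss_clades`` the monophyletic descendant clades where the gene was
    lost.
    """

    gene_id: str
    origin_ancestor: str
    loss_clades: frozenset[str] = frozenset()


@dataclass
class PathwayMap:
    """gene -> pathways and pathway -> one of the five categories."""

    gene_pathways: dict[str, set[str]]
    pathway_category: dict[str, str]

    def __post_init__(self) -> None:
        bad = {c for c in self.pathway_category.values() if c not in FIVE_CATEGORIES}
        if bad:
            raise ValueError(f"unknown pathway categories: {sorted(bad)}")

    def genes_in(self, pathway: str) -> set[str]:
        return {g for g, ps in self.gene_pathways.items() if pathway in ps}

    @property
    def pathways(self) -> set[str]:
        return set(self.pathway_category)


def composite_score(bundle: EvidenceBundle, cfg: ThresholdConfig) -> int:
    """Sum of the seven indicators, each worth +1.

    Correlations count only when strictly greater than ``cfg.corr_threshold``
    (an r of exactly 0.5 scores 0); undefined correlations score 0.
    """

    def corr_hit(r: float | None) -> bool:
        return r is not None and r > cfg.corr_threshold

    return (
        int(bundle.same_wgcna_module)
        + int(corr_hit(bundle.r_rnaseq))
        + int(corr_hit(bundle.r_microarray))
        + int(corr_hit(bundle.r_tp_homolog_microarray))
        + int(bundle.plastid_targeted)
        + int(bundle.same_origin)
        + int(bundle.same_loss_pattern)
    )


def tp_homolog_correlation(
    transporter_id: str,
    gene_id: str,
    rbh_map: Mapping[str, str],
    homolog_expr,
) -> float | None:
    """Cross-species correlation condition: Pearson r between the mapped
    homologues of the transporter and the candidate gene in the other
    species' expression matrix.

    Undefined (None, scoring 0) when either gene lacks an RBH-mapped
    homologue or a homologue is absent from the matrix.
    """
    from .mito import condition_correlation  # local import: avoid cycle

    ht, hg = rbh_map.get(transporter_id), rbh_map.get(gene_id)
    if ht is None or hg is None or ht not in homolog_expr or hg not in homolog_expr:
        return None
    return condition_correlation(homolog_expr.row(ht), homolog_expr.row(hg))


def same_loss(
    a: EvolutionAnnotation, b: EvolutionAnnotation, cfg: ThresholdConfig
) -> bool:
    """Loss-pattern agreement: set equality by default, subset when
    configured."""
    if cfg.loss_match_mode == "equal":
        return a.loss_clades == b.loss_clades
    return a.loss_clades <= b.loss_clades or b.loss_clades <= a.loss_clades


def associated_genes(
    transporter_id: str,
    bundles: Sequence[EvidenceBundle],
    cfg: ThresholdConfig,
) -> set[str]:
    """Genes whose composite score reaches ``cfg.assoc_min_score``
    (inclusive: a score of exactly 3 associates under the default)."""
    wrong = {b.transporter_id for b in bundles} - {transporter_id}
    if wrong:
        raise ValueError(f"bundles reference other transporters: {sorted(wrong)}")
    return {
        b.gene_id for b in bundles if composite_score(b, cfg) >= cfg.assoc_min_score
    }


def pathway_links(
    transporter_id: str,
    associated: set[str],
    pmap: PathwayMap,
    cfg: ThresholdConfig,
) -> set[str]:
    """Pathways recruiting at least ``cfg.pathway_min_genes`` associated
    genes (default 4, the strict reading of 'more than three')."""
    linked = set()
    for pathway in pmap.pathways:
        if len(pmap.genes_in(pathway) & associated) >= cfg.pathway_min_genes:
            linked.add(pathway)
    return linked


def category_profile(
    transporter_id: str, linked_pathways: set[str], pmap: PathwayMap
) -> frozenset[str]:
    """Collapse linked pathways onto their five-category subset."""
    missing = linked_pathways - pmap.pathways
    if missing:
        raise ValueError(f"pathways without a category: {sorted(missing)}")
    return frozenset(pmap.pathway_category[p] for p in linked_pathways)


def venn_counts(
    profiles: Mapping[str, frozenset[str]]
) -> dict[frozenset[str], int]:
    """Venn-region counts over per-transporter category subsets.

    Keys are non-empty category subsets; values count transporters with
    exactly that subset, so the counts sum to the number of transporters
    with at least one category.
    """
    counts: Counter = Counter()
    for subset in profiles.values():
        if subset:
            counts[frozenset(subset)] += 1
    return dict(counts)
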