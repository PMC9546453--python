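"""Pairwise homology search, best-hit / reciprocal-best-hit orthology,
consensus targeting and transporter selection.

The search contract allows two interchangeable backends: the internal
local-alignment scorer (:mod:`plastid_atlas.align`) or ingestion of a
precomputed 12-column hit table; both yield the same
:class:`HomologyHit` semantics and pass through the same e-value/identity
filters.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import align
from .core_io import (
    PREDICTOR_TOOLS,
    ProteinRecord,
    TargetingPrediction,
    ThresholdConfig,
)

logger = logging.getLogger("plastid_atlas.homology")


@dataclass(frozen=True)
class HomologyHit:
    """One above-threshold pairwise hit (outfmt-6 dialect fields)."""

    query_id: str
    subject_id: str
    identity_pct: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not self.query_id or not self.subject_id:
            raise ValueError("query_id and subject_id must be non-empty")
        if self.identity_pct > 100.0 or self.identity_pct < 0.0:
            raise ValueError(f"identity_pct {self.identity_pct} outside [0, 100]")
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue}")


@dataclass(frozen=True)
class RbhPair:
    """A reciprocal best hit: each member is the other's best hit."""

    id_a: str
    id_b: str
    forward_hit: HomologyHit
    reverse_hit: HomologyHit


@dataclass(frozen=True)
class CompartmentProfile:
    """Consensus subcellular localization call for one gene."""

    gene_id: str
    plastid: bool
    mitochondrion: bool
    other_labels: frozenset[str] = frozenset()
    category_code: str = "U"

    @property
    def dual_targeted(self) -> bool:
        return self.plastid and self.mitochondrion


def pairwise_homology_search(
    queries: Sequence[ProteinRecord],
    subjects: Sequence[ProteinRecord],
    cfg: ThresholdConfig,
) -> list[HomologyHit]:
    """All-vs-all local-alignment search with BLAST-like filtering.

    Every returned hit satisfies ``evalue <= cfg.max_evalue`` and
    ``identity_pct >= cfg.min_identity_pct``. The effective search space for
    the e-value is (sum of query lengths) x (sum of subject lengths), fixed
    for the whole search, so results are deterministic for fixed inputs.
    Hits are ordered by query id, then descending bitscore, then subject id.
    """
    if not queries or not subjects:
        raise ValueError("queries and subjects must be non-empty")
    for rec in queries:
        if not rec.sequence:
            raise ValueError(f"empty query sequence {rec.gene_id!r}")
    search_space = float(sum(len(q.sequence) for q in queries)) * float(
        sum(len(s.sequence) for s in subjects)
    )
    hits: list[HomologyHit] = []
    for q in queries:
        for s in subjects:
            aln = align.smith_waterman(q.sequence, s.sequence)
            if aln.score == 0:
                continue
            ev = align.evalue(aln.score, search_space)
            if ev > cfg.max_evalue or aln.identity_pct < cfg.min_identity_pct:
                continue
            hits.append(
                HomologyHit(
                    query_id=q.gene_id,
                    subject_id=s.gene_id,
                    identity_pct=aln.identity_pct,
                    aln_length=aln.n_columns,
                    mismatches=aln.n_mismatches,
                    gap_opens=aln.n_gap_opens,
                    q_start=aln.q_start,
                    q_end=aln.q_end,
                    s_start=aln.s_start,
                    s_end=aln.s_end,
                    evalue=ev,
                    bitscore=align.bit_score(aln.score),
                )
            )
    hits.sort(key=lambda h: (h.query_id, -h.bitscore, h.evalue, h.subject_id))
    return hits


def best_hit(hits_for_one_query: Sequence[HomologyHit]) -> HomologyHit | None:
    """Best-hit semantics: maximal bitscore, ties by lower e-value then
    lexicographically smallest subject id. Empty input yields None."""
    if not hits_for_one_query:
        return None
    queries = {h.query_id for h in hits_for_one_query}
    if len(queries) != 1:
        raise ValueError(f"hits span multiple queries: {sorted(queries)}")
    return min(hits_for_one_query, key=lambda h: (-h.bitscore, h.evalue, h.subject_id))


def _best_by_query(hits: Iterable[HomologyHit]) -> dict[str, HomologyHit]:
    grouped: dict[str, list[HomologyHit]] = defaultdict(list)
    for h in hits:
        grouped[h.query_id].append(h)
    return {q: best_hit(hs) for q, hs in grouped.items()}


def reciprocal_best_hits(
    hits_ab: Sequence[HomologyHit],
    hits_ba: Sequence[HomologyHit],
    cfg: ThresholdConfig,
) -> list[RbhPair]:
    """Reciprocal best hits between two directed above-threshold searches.

    (a, b) is a pair iff a's best hit in B is b and b's best hit in A is a.
    Hits failing the configured thresholds are ignored. Output sorted by
    ``id_a``.
    """

    def passes(h: HomologyHit) -> bool:
        return h.evalue <= cfg.max_evalue and h.identity_pct >= cfg.min_identity_pct

    fwd = _best_by_query(h for h in hits_ab if passes(h))
    rev = _best_by_query(h for h in hits_ba if passes(h))
    pairs = []
    for a, fh in fwd.items():
        rh = rev.get(fh.subject_id)
        if rh is not None and rh.subject_id == a:
            pairs.append(RbhPair(id_a=a, id_b=fh.subject_id, forward_hit=fh, reverse_hit=rh))
    pairs.sort(key=lambda p: p.id_a)
    return pairs


def one_to_many_table(hits_ab: Sequence[HomologyHit]) -> dict[str, list[str]]:
    """All above-threshold subjects per query (one-to-many companion table);
    the RBH pairing itself stays strictly one-to-one."""
    table: dict[str, list[str]] = defaultdict(list)
    for h in sorted(hits_ab, key=lambda h: (h.query_id, -h.bitscore, h.subject_id)):
        if h.subject_id not in table[h.query_id]:
            table[h.query_id].append(h.subject_id)
    return dict(table)


#: label sets the consensus rule recognises as membrane/secretory evidence
_PM_ER_LABELS = frozenset({"secretory/ER", "plasma-membrane"})

#: plant-convention category codes keyed by compartment label
_PLANT_CODES = {
    "plastid": "C",
    "mitochondrion": "M",
    "vacuole": "V",
    "golgi": "G",
    "plasma-membrane": "PM",
}


def consensus_targeting(
    preds: Sequence[TargetingPrediction],
    cfg: ThresholdConfig,
    convention: str = "query",
) -> CompartmentProfile:
    """Consensus localization from the four predictors' labels.

    Plastid iff ASAFind or HECTAR predicts plastid. Mitochondrion iff HECTAR
    predicts mitochondrion or the MitoFates presequence probability reaches
    the configured cut (default 0.35). WolfPSort acts only as a fallback
    label when the three primary tools give nothing. Genes with no evidence
    are category U (unknown/undefined).
    """
    if not preds:
        return CompartmentProfile(gene_id="", plastid=False, mitochondrion=False)
    genes = {p.gene_id for p in preds}
    if len(genes) != 1:
        raise ValueError(f"predictions span multiple genes: {sorted(genes)}")
    gene_id = preds[0].gene_id
    by_tool: dict[str, TargetingPrediction] = {}
    for p in preds:
        if p.tool in by_tool:
            raise ValueError(f"duplicate prediction for ({gene_id}, {p.tool})")
        by_tool[p.tool] = p

    plastid = any(
        by_tool[t].label == "plastid" for t in ("ASAFind", "HECTAR") if t in by_tool
    )
    mito = ("HECTAR" in by_tool and by_tool["HECTAR"].label == "mitochondrion") or (
        "MitoFates" in by_tool and by_tool["MitoFates"].score >= cfg.mitofates_cut
    )
    primary_labels = {
        by_tool[t].label
        for t in ("ASAFind", "HECTAR", "MitoFates")
        if t in by_tool and by_tool[t].label not in ("none", "other")
    }
    other = frozenset(primary_labels - {"plastid", "mitochondrion"})
    if not plastid and not mito and not other and "WolfPSort" in by_tool:
        wl = by_tool["WolfPSort"].label
        if wl not in ("none", "other"):
            other = frozenset({wl})

    code = _category_code(plastid, mito, other, convention)
    return CompartmentProfile(
        gene_id=gene_id,
        plastid=plastid,
        mitochondrion=mito,
        other_labels=other,
        category_code=code,
    )


def _category_code(
    plastid: bool, mito: bool, other: frozenset[str], convention: str
) -> str:
    if convention == "query":
        if plastid and mito:
            return "P+M"
        if plastid:
            return "P"
        if mito:
            return "M"
        if other & _PM_ER_LABELS:
            return "PM/ER"
        if "nucleus" in other:
            return "N"
        return "U"
    if convention == "plant":
        if plastid:
            return "C"
        if mito:
            return "M"
        for label in sorted(other):
            if label in _PLANT_CODES:
                return _PLANT_CODES[label]
        return "*"
    raise ValueError(f"unknown convention {convention!r}")


def select_plastid_transporters(
    proteome: Sequence[ProteinRecord],
    preds: Sequence[TargetingPrediction],
    transport_terms: Iterable[str],
    cfg: ThresholdConfig,
) -> set[str]:
    """Genes with >= 1 transport-associated functional term AND a consensus
    plastid targeting call. Output independent of input ordering."""
    terms = set(transport_terms)
    if not terms:
        raise ValueError("transport-term list must be non-empty")
    by_gene: dict[str, list[TargetingPrediction]] = defaultdict(list)
    for p in preds:
        by_gene[p.gene_id].append(p)
    selected = set()
    for rec in proteome:
        if not (rec.functional_terms & terms):
            continue
        profile = consensus_targeting(by_gene.get(rec.gene_id, []), cfg)
        if profile.plastid:
            selected.add(rec.gene_id)
    return selected


def cross_species_localization_table(
    homolog_map: Mapping[str, Sequence[str]],
    subject_profiles: Mapping[str, CompartmentProfile],
) -> dict[str, Counter]:
    """Per-query multiset of homolog localization categories.

    Queries whose homologs span several categories surface as multi-entry
    counters ("multiple localisations"); subjects without a profile count
    as U.
    """
    table: dict[str, Counter] = {}
    for query in sorted(homolog_map):
        counts: Counter = Counter()
        for subject in homolog_map[query]:
            profile = subject_profiles.get(subject)
            counts[profile.category_code if profile else "U"] += 1
        table[query] = counts
    return table
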