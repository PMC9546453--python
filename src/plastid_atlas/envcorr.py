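"""Environmental meta-omics stage.

Meta-gene homologues of each transporter family (emulating Ocean Gene Atlas
BLAST exports) are filtered in two stages — best hit among labelled cultured
references must be a diatom plastid-targeted sequence AND best hit in the
query proteome must be the queried gene — then restricted to the diatom
plastid clade of a neighbour-joining guide tree. Retained meta-gene
abundances are summed per sampling station for each depth-layer x
size-fraction combination; for every environmental parameter the
meta-transcriptome (MetaT) and meta-genome (MetaG) station sums are
correlated with the parameter, the MetaT correlation is tested with a
two-tailed t-test, and the comparison of R² values signs the result
(positive when the transcriptome tracks the parameter more tightly than the
gene pool). Significant signed calls are aggregated over the ten
combinations, and a merged primary-production panel yields a single
flag per family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import sqrt
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.tree import nj

from . import align
from .core_io import (
    DEFAULT_PRIMARY_PRODUCTION_PARAMS,
    FormatError,
    ProteinRecord,
    ThresholdConfig,
)

logger = logging.getLogger("plastid_atlas.envcorr")

DEPTH_LAYERS = ("SRF", "DCM")


@dataclass(frozen=True)
class ReferenceSeq:
    """A cultured reference sequence with lineage and targeting labels."""

    record: ProteinRecord
    lineage: str  # e.g. diatom, haptophyte, cryptomonad, other_ochrophyte
    plastid_targeted: bool

    @property
    def gene_id(self) -> str:
        return self.record.gene_id

    @property
    def is_diatom_plastid(self) -> bool:
        return self.lineage == "diatom" and self.plastid_targeted


@dataclass(frozen=True)
class StationRecord:
    """Environmental covariates of one station / depth / size sample."""

    station_id: str
    depth_layer: str
    size_fraction: str
    env: tuple[tuple[str, float], ...]

    def env_value(self, parameter: str) -> float | None:
        for k, v in self.env:
            if k == parameter:
                return None if np.isnan(v) else v
        return None


@dataclass(frozen=True)
class AbundanceRecord:
    """MetaT/MetaG relative abundance of one meta-gene at one station."""

    family_id: str
    meta_gene_id: str
    station_id: str
    depth_layer: str
    size_fraction: str
    metaT: float
    metaG: float | None

    def __post_init__(self) -> None:
        if self.metaT < 0 or (self.metaG is not None and self.metaG < 0):
            raise ValueError("relative abundances must be non-negative")


@dataclass(frozen=True)
class EnvCorrelation:
    """Signed MetaT-vs-MetaG correlation call for one family x parameter x
    combo."""

    family_id: str
    parameter: str
    combo: tuple[str, str]
    r_T: float | None
    r_G: float | None
    n: int
    p: float | None
    sign: int
    significant: bool


@dataclass(frozen=True)
class AggregateCell:
    """Signed count of significant combos for one family x parameter."""

    family_id: str
    parameter: str
    n_sig_pos: int
    n_sig_neg: int
    strong_positive: bool
    strong_negative: bool

    @property
    def signed_score(self) -> int:
        return self.n_sig_pos - self.n_sig_neg


# ---------------------------------------------------------------------------
# homologue filtering and clade extraction
# ---------------------------------------------------------------------------


def _best_hit_id(
    seq: str, candidates: Sequence[ProteinRecord], search_space: float, cfg: ThresholdConfig
) -> str | None:
    """Highest-scoring above-threshold candidate (ties: smallest id)."""
    best: tuple[float, str] | None = None
    for cand in candidates:
        aln = align.smith_waterman(seq, cand.sequence)
        if aln.score == 0:
            continue
        if align.evalue(aln.score, search_space) > cfg.max_evalue:
            continue
        key = (-aln.score, cand.gene_id)
        if best is None or key < best:
            best = key
    return best[1] if best else None


def filter_meta_homologues(
    meta_seqs: Sequence[ProteinRecord],
    reference_set: Sequence[ReferenceSeq],
    query_proteome: Sequence[ProteinRecord],
    query_gene_id: str,
    cfg: ThresholdConfig,
) -> set[str]:
    """Two-stage best-hit filter with intersection semantics.

    A meta sequence survives iff (a) its best hit among the cultured
    references is a diatom plastid-targeted sequence and (b) its best hit in
    the query proteome is the queried gene itself.
    """
    if not reference_set:
        raise ValueError("reference set must be non-empty")
    ref_records = [r.record for r in reference_set]
    ref_by_id = {r.gene_id: r for r in reference_set}
    meta_len = float(sum(len(m.sequence) for m in meta_seqs))
    ref_space = meta_len * sum(len(r.sequence) for r in ref_records)
    prot_space = meta_len * sum(len(p.sequence) for p in query_proteome)
    retained = set()
    for m in meta_seqs:
        ref_best = _best_hit_id(m.sequence, ref_records, ref_space, cfg)
        if ref_best is None or not ref_by_id[ref_best].is_diatom_plastid:
            continue
        prot_best = _best_hit_id(m.sequence, query_proteome, prot_space, cfg)
        if prot_best == query_gene_id:
            retained.add(m.gene_id)
    return retained


def pairwise_distance(a: str, b: str) -> float | None:
    """Alignment dissimilarity: 1 - fractional identity of the local
    alignment; None when the sequences share no positive-scoring overlap."""
    aln = align.smith_waterman(a, b)
    if aln.n_columns == 0:
        return None
    return 1.0 - aln.n_identical / aln.n_columns


def _coverage(query_seq: str, seq: str) -> float:
    aln = align.smith_waterman(query_seq, seq)
    if aln.n_columns == 0:
        return 0.0
    return (aln.q_end - aln.q_start + 1) / len(query_seq)


def clade_extract(
    retained_meta: Sequence[ProteinRecord],
    reference_set: Sequence[ReferenceSeq],
    query_seq: str,
    min_coverage: float = 0.5,
) -> set[str]:
    """Restrict retained meta-genes to the diatom-plastid clade of an NJ
    guide tree.

    Sequences covering less than ``min_coverage`` of the query sequence are
    dropped (emulating removal of poorly aligned sequences), as are
    sequences with undefined pairwise distances. A neighbour-joining tree is
    built from 1 - fractional-identity distances; the smallest bipartition
    side holding every diatom plastid-targeted reference and no other
    cultured reference defines the clade. When no such clade exists the
    filter-stage set is returned unchanged with a warning.
    """
    meta_ids = {m.gene_id for m in retained_meta}
    seqs: dict[str, str] = {}
    for ref in reference_set:
        seqs[ref.gene_id] = ref.record.sequence
    for m in retained_meta:
        seqs[m.gene_id] = m.sequence

    kept = {}
    for name, seq in seqs.items():
        if _coverage(query_seq, seq) >= min_coverage:
            kept[name] = seq
        else:
            logger.warning("dropping %s: <%.0f%% overlap with query", name, 100 * min_coverage)

    names = sorted(kept)
    if len(names) < 4:
        logger.warning("fewer than 4 alignable sequences; skipping clade extraction")
        return meta_ids

    dist = {}
    undefined: dict[str, int] = {n: 0 for n in names}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = pairwise_distance(kept[a], kept[b])
            dist[(a, b)] = d
            if d is None:
                undefined[a] += 1
                undefined[b] += 1
    # drop sequences involved in undefined distances, worst offender first
    while max(undefined.values(), default=0) > 0:
        worst = max(sorted(undefined), key=lambda n: undefined[n])
        logger.warning("dropping %s: undefined pairwise distances", worst)
        for (a, b), d in list(dist.items()):
            if worst in (a, b):
                if d is None:
                    other = b if a == worst else a
                    undefined[other] -= 1
                del dist[(a, b)]
        del undefined[worst]
        names.remove(worst)
    if len(names) < 4:
        logger.warning("fewer than 4 sequences after distance pruning; skipping clade extraction")
        return meta_ids

    mat = np.zeros((len(names), len(names)))
    idx = {n: i for i, n in enumerate(names)}
    for (a, b), d in dist.items():
        mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = d
    tree = nj(DistanceMatrix(mat, names))

    diatom_refs = {
        r.gene_id for r in reference_set if r.is_diatom_plastid and r.gene_id in idx
    }
    other_refs = {
        r.gene_id for r in reference_set if not r.is_diatom_plastid and r.gene_id in idx
    }
    if not diatom_refs:
        logger.warning("no diatom plastid reference in the tree; keeping filter-stage set")
        return meta_ids

    all_tips = frozenset(names)
    best_side: frozenset[str] | None = None
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            side = frozenset([node.name])
            sides = (side, all_tips - side)
        else:
            side = frozenset(t.name for t in node.tips())
            sides = (side, all_tips - side)
        for s in sides:
            if diatom_refs <= s and not (other_refs & s) and s != all_tips:
                if best_side is None or len(s) < len(best_side):
                    best_side = s
    if best_side is None:
        logger.warning(
            "no clade separates diatom plastid references from other cultured "
            "homologues; keeping filter-stage set"
        )
        return meta_ids
    return meta_ids & best_side


# ---------------------------------------------------------------------------
# abundance aggregation and signed significance
# ---------------------------------------------------------------------------


def station_sums(
    records: Sequence[AbundanceRecord],
    family_id: str,
    combo: tuple[str, str],
    meta_genes: set[str] | None = None,
) -> dict[str, tuple[float, float | None]]:
    """Per-station (sum MetaT, sum MetaG) over retained meta-genes.

    Stations with no record for this family and combo are omitted, not
    zero-filled. ``meta_genes`` optionally restricts the sum to a retained
    set (e.g. the clade-extraction output). A station's MetaG sum is None
    when no contributing record carries MetaG.
    """
    depth, size = combo
    sums: dict[str, tuple[float, float | None]] = {}
    for rec in records:
        if rec.family_id != family_id or (rec.depth_layer, rec.size_fraction) != combo:
            continue
        if meta_genes is not None and rec.meta_gene_id not in meta_genes:
            continue
        t, g = sums.get(rec.station_id, (0.0, None))
        t += rec.metaT
        if rec.metaG is not None:
            g = (g or 0.0) + rec.metaG
        sums[rec.station_id] = (t, g)
    return sums


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, y)[0, 1]
    if not np.isfinite(r):
        return None
    return float(np.clip(r, -1.0, 1.0))


def correlation_pvalue(r: float, n: int) -> float:
    """Two-tailed p-value of Pearson r via t = r sqrt((n-2)/(1-r^2)),
    df = n - 2."""
    if n < 3:
        raise ValueError("need at least 3 observations")
    if abs(r) >= 1.0:
        return 0.0
    t = r * sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * float(stats.t.sf(abs(t), n - 2))


def signed_significance(
    sum_T: Mapping[str, float],
    sum_G: Mapping[str, float | None],
    env_values: Mapping[str, float],
    cfg: ThresholdConfig,
    family_id: str = "",
    parameter: str = "",
    combo: tuple[str, str] = ("", ""),
) -> EnvCorrelation:
    """Signed significance call for one family x parameter x combo.

    r_T and r_G are Pearson correlations of the MetaT and MetaG station
    sums with the parameter over pairwise-complete stations. The tested
    statistic is r_T by default (``cfg.env_stat_mode='metaT'``); the
    alternative mode correlates the per-station difference sum_T - sum_G.
    The call is positive when r_T² exceeds r_G² (transcript abundance
    tracks the parameter more tightly than gene abundance), negative
    otherwise; families without MetaG take the sign of r_T. Fewer than 3
    usable stations, or zero variance, yields an undefined, non-significant
    result.
    """
    stations_T = sorted(s for s in sum_T if s in env_values)
    xT = np.array([sum_T[s] for s in stations_T])
    eT = np.array([env_values[s] for s in stations_T])
    r_T = _pearson(xT, eT)

    stations_G = sorted(
        s for s in sum_G if sum_G[s] is not None and s in env_values
    )
    r_G = _pearson(
        np.array([sum_G[s] for s in stations_G]),
        np.array([env_values[s] for s in stations_G]),
    )

    if cfg.env_stat_mode == "difference":
        both = [s for s in stations_T if s in stations_G]
        diff = np.array([sum_T[s] - sum_G[s] for s in both])
        envb = np.array([env_values[s] for s in both])
        r_stat = _pearson(diff, envb)
        n_stat = len(both)
    else:
        r_stat, n_stat = r_T, len(stations_T)

    if r_stat is None:
        return EnvCorrelation(family_id, parameter, combo, r_T, r_G, n_stat, None, +1, False)

    p = correlation_pvalue(r_stat, n_stat)
    if cfg.env_stat_mode == "difference":
        sign = +1 if r_stat >= 0 else -1
    elif r_G is None:
        sign = +1 if r_T >= 0 else -1
    elif r_T * r_T > r_G * r_G:
        sign = +1
    elif r_T * r_T < r_G * r_G:
        sign = -1
    else:
        sign = +1 if r_T >= 0 else -1
    return EnvCorrelation(
        family_id, parameter, combo, r_T, r_G, n_stat, p, sign, p < cfg.env_alpha
    )


def aggregate_combos(
    family_id: str,
    parameter: str,
    results: Sequence[EnvCorrelation],
    cfg: ThresholdConfig,
) -> AggregateCell:
    """Count significant signed calls over the depth x size combinations."""
    seen: set[tuple[str, str]] = set()
    n_pos = n_neg = 0
    for res in results:
        if res.combo in seen:
            raise ValueError(f"duplicate combo {res.combo}")
        seen.add(res.combo)
        if res.significant:
            if res.sign > 0:
                n_pos += 1
            else:
                n_neg += 1
    return AggregateCell(
        family_id=family_id,
        parameter=parameter,
        n_sig_pos=n_pos,
        n_sig_neg=n_neg,
        strong_positive=n_pos >= cfg.env_min_combos,
        strong_negative=n_neg >= cfg.env_min_combos,
    )


def primary_production_flag(
    family_id: str,
    cells: Mapping[str, AggregateCell],
    cfg: ThresholdConfig,
    merged_params: Sequence[str] = DEFAULT_PRIMARY_PRODUCTION_PARAMS,
) -> tuple[bool, int]:
    """Merged primary-production relationship flag for one family.

    True when at least ``cfg.pp_min_params`` of the merged parameters are
    strong; by default strength must point the same way, and the returned
    direction is +1 / -1 (0 when the flag is False).
    """
    if not merged_params:
        raise ValueError("merged parameter list must be non-empty")
    n_pos = sum(
        1 for p in merged_params if p in cells and cells[p].strong_positive
    )
    n_neg = sum(
        1 for p in merged_params if p in cells and cells[p].strong_negative
    )
    if cfg.pp_same_direction:
        if n_pos >= cfg.pp_min_params:
            return True, +1
        if n_neg >= cfg.pp_min_params:
            return True, -1
        return False, 0
    if n_pos + n_neg >= cfg.pp_min_params:
        return True, +1 if n_pos >= n_neg else -1
    return False, 0


# ---------------------------------------------------------------------------
# file dialects
# ---------------------------------------------------------------------------


def read_station_table(path) -> list[StationRecord]:
    """Read a station/environment TSV: station_id, depth_layer,
    size_fraction, then one column per environmental parameter."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    required = ["station_id", "depth_layer", "size_fraction"]
    if list(df.columns[:3]) != required:
        raise FormatError(f"{path}: expected leading columns {required}")
    params = list(df.columns[3:])
    records = []
    for _, row in df.iterrows():
        env = tuple(
            (p, float(row[p]) if not pd.isna(row[p]) else float("nan")) for p in params
        )
        records.append(
            StationRecord(str(row["station_id"]), row["depth_layer"], str(row["size_fraction"]), env)
        )
    return records


def read_abundance_table(path) -> list[AbundanceRecord]:
    """Read an abundance TSV: family_id, meta_gene_id, station_id,
    depth_layer, size_fraction, metaT, metaG (metaG may be NA)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    required = [
        "family_id",
        "meta_gene_id",
        "station_id",
        "depth_layer",
        "size_fraction",
        "metaT",
        "metaG",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        metaG = None if pd.isna(row["metaG"]) else float(row["metaG"])
        records.append(
            AbundanceRecord(
                str(row["family_id"]),
                str(row["meta_gene_id"]),
                str(row["station_id"]),
                row["depth_layer"],
                str(row["size_fraction"]),
                float(row["metaT"]),
                metaG,
            )
        )
    return records


def env_values_for_combo(
    stations: Sequence[StationRecord], parameter: str, combo: tuple[str, str]
) -> dict[str, float]:
    """Parameter values per station for one depth x size combination,
    skipping missing covariates (pairwise-complete deletion downstream)."""
    depth, size = combo
    out = {}
    for s in stations:
        if (s.depth_layer, s.size_fraction) == combo:
            v = s.env_value(parameter)
            if v is not None:
                out[s.station_id] = v
    return out
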