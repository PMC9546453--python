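"""Shared domain types, readers/writers and configuration.

All tabular output is TSV with a fixed column order per stage; floats are
written with 6 significant digits so that repeated runs are byte-stable and
diffable. Readers never coerce missing values to zero: an ``NA`` cell in an
expression matrix stays missing (NaN) and downstream correlations use
pairwise-complete observations.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("plastid_atlas")

#: amino-acid alphabet accepted in protein sequences
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: controlled vocabulary for targeting-prediction labels
COMPARTMENT_LABELS = frozenset(
    {
        "plastid",
        "mitochondrion",
        "secretory/ER",
        "plasma-membrane",
        "nucleus",
        "vacuole",
        "golgi",
        "other",
        "none",
    }
)

#: targeting predictors whose labels are consumed (never run) by the pipeline
PREDICTOR_TOOLS = ("ASAFind", "HECTAR", "MitoFates", "WolfPSort")

#: the ten depth-layer x size-fraction sampling combinations used for the
#: environmental stage (surface layer SRF and deep chlorophyll maximum DCM,
#: five plankton size fractions in micrometres each)
DEFAULT_COMBOS: tuple[tuple[str, str], ...] = tuple(
    (depth, size)
    for depth in ("DCM", "SRF")
    for size in ("<0.8", "0.8-5", "5-20", "20-180", "180-2000")
)

#: merged "primary production" parameter panel: six accessory pigments plus
#: net primary production and three particulate-carbon metrics
DEFAULT_PRIMARY_PRODUCTION_PARAMS: tuple[str, ...] = (
    "Chlorophyll_c3",
    "Peridinin",
    "Fucoxanthin",
    "Prasinoxanthin",
    "19-Hexanoyloxyfucoxanthin",
    "Alloxanthin",
    "NPP",
    "PIC",
    "POC",
    "Carbon_Total",
)


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


def fmt6(x: float) -> str:
    """Format a float with 6 significant digits (stable TSV output)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.6g}"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: an identifier, its species, sequence and functional terms.

    ``functional_terms`` holds KEGG K-numbers, GO ids, PFAM ids or free-text
    flags; the selection stage only tests membership against a configurable
    transport-term list, so the identifiers are opaque here.
    """

    gene_id: str
    species_id: str
    sequence: str
    functional_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.gene_id!r}")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"sequence of {self.gene_id!r} contains invalid residues: {sorted(bad)}"
            )


@dataclass(frozen=True)
class TargetingPrediction:
    """One (gene, predictor) targeting label.

    ``score`` is only meaningful for MitoFates, where it is a probability-like
    value in [0, 1] compared against the configured cut-off.
    """

    gene_id: str
    tool: str
    label: str
    score: float | None = None

    def __post_init__(self) -> None:
        if self.tool not in PREDICTOR_TOOLS:
            raise ValueError(f"unknown predictor tool {self.tool!r}")
        if self.label not in COMPARTMENT_LABELS:
            raise ValueError(f"unknown compartment label {self.label!r}")
        if (self.tool == "MitoFates") != (self.score is not None):
            raise ValueError("score must be present iff tool is MitoFates")


@dataclass
class ThresholdConfig:
    """Every numeric cut-off used across the pipeline, in one place.

    Defaults are the published operating points: BLAST-style homology filters
    (E <= 1e-05, identity >= 30 %), correlation evidence strictly above 0.5,
    composite evidence score of at least 3, pathway linkage requiring more
    than three associated genes, MitoFates presequence probability 0.35,
    organelle crosstalk mean correlation magnitude 0.5 on both axes,
    environmental significance alpha 0.05 with at least 3 of the 10
    depth x size combinations, and at least 8 of the 10 merged
    primary-production parameters.
    """

    max_evalue: float = 1e-05
    min_identity_pct: float = 30.0
    corr_threshold: float = 0.5
    assoc_min_score: int = 3
    pathway_min_genes: int = 4
    mitofates_cut: float = 0.35
    crosstalk_cut: float = 0.5
    env_alpha: float = 0.05
    env_min_combos: int = 3
    pp_min_params: int = 8
    combos: tuple[tuple[str, str], ...] = DEFAULT_COMBOS
    # behavioural switches (paper-silent choices, see docs/methods.md)
    strip_id_prefix: str | None = None
    log2_expression: bool = False
    loss_match_mode: str = "equal"  # or "subset"
    env_stat_mode: str = "metaT"  # or "difference"
    pp_same_direction: bool = True
    group_reduce: str = "mean"  # or "none" (per-array correlations)

    def __post_init__(self) -> None:
        for name in (
            "max_evalue",
            "min_identity_pct",
            "corr_threshold",
            "assoc_min_score",
            "pathway_min_genes",
            "mitofates_cut",
            "crosstalk_cut",
            "env_alpha",
            "env_min_combos",
            "pp_min_params",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 <= self.min_identity_pct <= 100):
            raise ValueError("min_identity_pct must lie in [0, 100]")
        combos = tuple(tuple(c) for c in self.combos)
        if not combos or len(set(combos)) != len(combos):
            raise ValueError("combos must be non-empty and unique")
        self.combos = combos
        if self.loss_match_mode not in ("equal", "subset"):
            raise ValueError("loss_match_mode must be 'equal' or 'subset'")
        if self.env_stat_mode not in ("metaT", "difference"):
            raise ValueError("env_stat_mode must be 'metaT' or 'difference'")
        if self.group_reduce not in ("mean", "none"):
            raise ValueError("group_reduce must be 'mean' or 'none'")

    def normalize_id(self, gene_id: str) -> str:
        """Apply the optional prefix-strip rule ('Phatr3_' style ids)."""
        if self.strip_id_prefix and gene_id.startswith(self.strip_id_prefix):
            return gene_id[len(self.strip_id_prefix):]
        return gene_id

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        thresholds = data.get("thresholds", data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(thresholds) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        if "combos" in thresholds:
            thresholds["combos"] = tuple(tuple(c) for c in thresholds["combos"])
        return cls(**thresholds)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["combos"] = [list(c) for c in self.combos]
        with open(path, "w") as fh:
            yaml.safe_dump({"thresholds": data}, fh, sort_keys=True)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with optional condition-group labels.

    ``values`` is float with NaN for missing; missing cells are never
    imputed. ``sample_groups`` maps sample id -> condition-group label (for
    example 17 light:dark acclimation processing groups).
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    sample_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("duplicate gene ids in expression matrix")
        self._index = {g: i for i, g in enumerate(self.genes)}

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def row(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[self._index[gene_id]]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in expression matrix") from None

    def group_means(self) -> "ExpressionMatrix":
        """Collapse samples to per-condition-group means (NaN-aware).

        A group mean is missing only when every member sample is missing.
        """
        if not self.sample_groups:
            raise ValueError("no sample_groups defined")
        groups = sorted(set(self.sample_groups.values()))
        out = np.full((len(self.genes), len(groups)), np.nan)
        for j, g in enumerate(groups):
            cols = [i for i, s in enumerate(self.samples) if self.sample_groups.get(s) == g]
            if cols:
                block = self.values[:, cols]
                with np.errstate(invalid="ignore"):
                    out[:, j] = np.nanmean(block, axis=1)
        return ExpressionMatrix(list(self.genes), groups, out, {g: g for g in groups})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, species_id: str = "") -> list[ProteinRecord]:
    """Read a protein FASTA into an ordered ProteinRecord list.

    The header token before the first whitespace is the gene id; sequences
    are upper-cased. Malformed records raise :class:`FormatError` naming the
    offending line number.
    """
    path = Path(path)
    # pre-scan header line numbers so parse errors can name their line
    header_lines: dict[int, int] = {}
    n_headers = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                header_lines[n_headers] = lineno
                n_headers += 1
                if line[1:].strip() == "":
                    raise FormatError(f"{path}:{lineno}: FASTA header has no id")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        lineno = header_lines.get(idx, 0)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}:{lineno}: record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise FormatError(f"{path}:{lineno}: duplicate gene id {rec.id!r}")
        seen.add(rec.id)
        try:
            records.append(ProteinRecord(rec.id, species_id, seq))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.gene_id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# 12-column tabular hits (BLAST outfmt-6 dialect)
# ---------------------------------------------------------------------------

HIT_COLUMNS = (
    "query_id",
    "subject_id",
    "identity_pct",
    "aln_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bitscore",
)


def read_hit_table(path: str | Path):
    """Read a 12-column tabular hit file into a HomologyHit list.

    Coordinates stay 1-based inclusive as in the dialect; e-values accept
    scientific notation. Column-count mismatches raise :class:`FormatError`.
    """
    from .homology import HomologyHit  # local import: avoid cycle

    path = Path(path)
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            try:
                hit = HomologyHit(
                    query_id=parts[0],
                    subject_id=parts[1],
                    identity_pct=float(parts[2]),
                    aln_length=int(parts[3]),
                    mismatches=int(parts[4]),
                    gap_opens=int(parts[5]),
                    q_start=int(parts[6]),
                    q_end=int(parts[7]),
                    s_start=int(parts[8]),
                    s_end=int(parts[9]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            hits.append(hit)
    return hits


def write_hit_table(hits, path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        fmt6(h.identity_pct),
                        str(h.aln_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        fmt6(h.evalue),
                        fmt6(h.bitscore),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# expression matrices and generic TSV tables
# ---------------------------------------------------------------------------


def read_matrix(
    path: str | Path, groups_path: str | Path | None = None, na_token: str = "NA"
) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene ids, header samples).

    ``na_token`` cells are preserved as missing, never as zero. An optional
    companion two-column TSV (sample, group) attaches condition-group labels.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[na_token], keep_default_na=False
    )
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene ids {dups}")
    groups: dict[str, str] = {}
    if groups_path is not None:
        gdf = pd.read_csv(groups_path, sep="\t", dtype=str)
        if list(gdf.columns[:2]) != ["sample", "group"]:
            raise FormatError(f"{groups_path}: expected columns 'sample', 'group'")
        groups = dict(zip(gdf["sample"], gdf["group"]))
    return ExpressionMatrix(
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        sample_groups=groups,
    )


def write_matrix(matrix: ExpressionMatrix, path: str | Path, na_token: str = "NA") -> None:
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(matrix.samples) + "\n")
        for gene, row in zip(matrix.genes, matrix.values):
            fh.write(gene + "\t" + "\t".join(fmt6(v) for v in row) + "\n")


def read_targeting_predictions(path: str | Path) -> list[TargetingPrediction]:
    """Read a targeting-prediction TSV (gene_id, tool, label[, score])."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "tool": str, "label": str})
    required = {"gene_id", "tool", "label"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    preds: list[TargetingPrediction] = []
    seen: set[tuple[str, str]] = set()
    for _, row in df.iterrows():
        key = (row["gene_id"], row["tool"])
        if key in seen:
            raise FormatError(f"{path}: duplicate record for {key}")
        seen.add(key)
        score = None
        if "score" in df.columns and not pd.isna(row.get("score")):
            score = float(row["score"])
        if row["tool"] != "MitoFates":
            score = None
        preds.append(TargetingPrediction(row["gene_id"], row["tool"], row["label"], score))
    return preds


def write_targeting_predictions(preds: Sequence[TargetingPrediction], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttool\tlabel\tscore\n")
        for p in preds:
            score = "" if p.score is None else fmt6(p.score)
            fh.write(f"{p.gene_id}\t{p.tool}\t{p.label}\t{score}\n")


def read_two_column_map(path: str | Path, key: str, value: str) -> dict[str, str]:
    """Read a simple TSV mapping (named key/value columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if key not in df.columns or value not in df.columns:
        raise FormatError(f"{path}: expected columns {key!r} and {value!r}")
    return dict(zip(df[key], df[value]))


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as TSV with 6-significant-digit floats, no index."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=None,  # defaults to stderr
        level=getattr(logging, level.upper()),
        format="%(levelname)s %(name)s: %(message)s",
    )
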