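"""End-to-end orchestration: fixture simulation, stage running, reporting.

``simulate_bundle`` writes a complete, self-consistent input bundle (all
file dialects the stages consume) plus the planted-truth JSON and a config
file; ``run_atlas`` executes the five analysis stages in dependency order
from such a config and assembles a versioned per-transporter report;
``render_tables`` derives the figure-equivalent summary tables from a
report. Everything is deterministic: rerunning with the same seed and
config yields byte-identical artifacts.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import conservation as cons
from . import envcorr as env
from . import evidence as ev
from . import homology as hom
from . import mito as mito_mod
from . import synthetic as syn
from .core_io import (
    DEFAULT_PRIMARY_PRODUCTION_PARAMS,
    ExpressionMatrix,
    FormatError,
    ProteinRecord,
    ThresholdConfig,
    fmt6,
    read_fasta,
    read_matrix,
    read_targeting_predictions,
    write_fasta,
    write_hit_table,
    write_matrix,
    write_targeting_predictions,
    write_tsv,
)

logger = logging.getLogger("plastid_atlas.pipeline")

REPORT_SCHEMA_VERSION = 1

STAGES = ("homology", "score", "mito", "conserve", "envcorr")


# ---------------------------------------------------------------------------
# fixture simulation (writes every input dialect + truth)
# ---------------------------------------------------------------------------


def simulate_bundle(
    outdir: str | Path,
    seed: int = 0,
    n_transporters: int = 7,
    n_candidates: int = 15,
    n_decoys: int = 10,
    n_stations: int = 30,
) -> dict:
    """Write a complete synthetic input bundle at roughly 1/10 study scale.

    Plants: one transporter co-regulated with the mitochondrial panel and
    responding to the merged primary-production covariates; two transporters
    with associated gene blocks and linked pathways; two diatom-unique
    presence profiles; single-parameter environmental responses of both
    signs; one family without MetaG data; and an environmental homologue
    pool with known clade membership for the first transporter. Returns the
    config dict (also written to ``config.yaml``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = ThresholdConfig()

    # --- proteomes & targeting -------------------------------------------
    prot = syn.make_proteomes(
        n_genes=n_transporters + n_decoys,
        n_orthologs=n_transporters,
        identity_levels=(0.9, 0.75, 0.6, 0.5, 0.85, 0.7, 0.55),
        seq_len=80,
        seed=seed,
        species=("Pt", "At"),
    )
    transporters = [f"Pt_tr{i:02d}" for i in range(n_transporters)]
    candidates = [f"Pt_g{i:02d}" for i in range(n_candidates)]
    mito_panel = [
        ("mt_rps07", "biogenesis"),
        ("mt_rps12", "biogenesis"),
        ("mt_rpl06", "biogenesis"),
        ("mt_tatC", "biogenesis"),
        ("mt_nad1", "respiratory_complex"),
        ("mt_cob", "respiratory_complex"),
        ("mt_cox1", "respiratory_complex"),
        ("mt_atp6", "respiratory_complex"),
    ]
    mito_ids = [g for g, _ in mito_panel]

    write_fasta(prot.proteome_a, outdir / "proteome_query.fasta")
    write_fasta(prot.proteome_b, outdir / "proteome_subject.fasta")

    # plastid targeting for the candidate genes of the planted blocks
    preds_a = list(prot.predictions_a)
    for g in candidates[:10]:
        preds_a.append(syn.TargetingPrediction(g, "ASAFind", "plastid"))
    for g in candidates[10:]:
        preds_a.append(syn.TargetingPrediction(g, "HECTAR", "none"))
    write_targeting_predictions(preds_a, outdir / "targeting_query.tsv")
    write_targeting_predictions(prot.predictions_b, outdir / "targeting_subject.tsv")

    terms = [(r.gene_id, t) for r in prot.proteome_a for t in sorted(r.functional_terms)]
    _write_pairs(outdir / "transport_terms.tsv", ("gene_id", "term"), terms)

    # --- expression, modules, annotations --------------------------------
    rng = syn.stream_rng(seed, syn.STREAM_EXPRESSION)
    blocks_micro = {
        "mod_crosstalk": [transporters[0], *mito_ids],
        "mod_assoc1": [transporters[1], *candidates[0:5]],
        "mod_assoc2": [transporters[2], *candidates[5:10]],
    }
    micro_genes = transporters + candidates + mito_ids
    sim_micro = syn.make_expression(micro_genes, blocks_micro, loading=0.95, rng=rng)
    blocks_rna = {k: [g for g in v if g not in mito_ids] for k, v in blocks_micro.items()}
    rna_genes = transporters + candidates
    sim_rna = syn.make_expression(rna_genes, blocks_rna, loading=0.95, rng=rng)

    write_matrix(sim_micro.matrix, outdir / "expr_microarray.tsv")
    _write_pairs(
        outdir / "expr_microarray_groups.tsv",
        ("sample", "group"),
        sorted(sim_micro.matrix.sample_groups.items()),
    )
    write_matrix(sim_rna.matrix, outdir / "expr_rnaseq.tsv")
    _write_pairs(
        outdir / "expr_rnaseq_groups.tsv",
        ("sample", "group"),
        sorted(sim_rna.matrix.sample_groups.items()),
    )
    _write_pairs(
        outdir / "modules.tsv", ("gene_id", "module"),
        sorted(sim_micro.modules.items()),
    )
    _write_pairs(outdir / "mito_panel.tsv", ("gene_id", "function_class"), mito_panel)

    # origin/loss annotations: each planted block shares a history
    origins = {}
    for g in [transporters[1], *candidates[0:5]]:
        origins[g] = ("ochrophyte_ca", "pelagophytes;dictyochophytes")
    for g in [transporters[2], *candidates[5:10]]:
        origins[g] = ("diatom_ca", "")
    for g in rna_genes:
        origins.setdefault(g, (f"anc_{g}", ""))
    _write_rows(
        outdir / "evolution.tsv",
        ("gene_id", "origin_ancestor", "loss_clades"),
        [(g, o, l) for g, (o, l) in sorted(origins.items())],
    )

    pathway_rows = (
        [(g, "pw_calvin") for g in candidates[0:5]]
        + [(g, "pw_lhc") for g in candidates[1:5]]
        + [(g, "pw_psb") for g in candidates[5:10]]
        + [(g, "pw_aa_sparse") for g in candidates[10:12]]
    )
    _write_pairs(outdir / "pathway_genes.tsv", ("gene_id", "pathway"), pathway_rows)
    _write_pairs(
        outdir / "pathway_categories.tsv",
        ("pathway", "category"),
        [
            ("pw_calvin", "carbon-related"),
            ("pw_lhc", "photosynthesis-related"),
            ("pw_psb", "photosynthesis-related"),
            ("pw_aa_sparse", "amino-acid-related"),
        ],
    )

    # --- taxon presence ---------------------------------------------------
    taxmap = syn.default_taxonomy(n_diatom_groups=2, n_other_groups=2, species_per_group=4)
    planted_unique = [transporters[3], transporters[5]]
    pres = syn.make_taxon_presence(taxmap, transporters, planted_unique, seed=seed)
    _write_rows(
        outdir / "taxonomy.tsv",
        ("species_id", "group", "lineage_class"),
        sorted(
            (s, g, taxmap.group_lineage[g]) for s, g in taxmap.species_group.items()
        ),
    )
    _write_rows(
        outdir / "presence.tsv",
        ("transporter_id", "group", "count"),
        [
            (p.transporter_id, g, c)
            for p in pres.profiles
            for g, c in p.group_counts
        ],
    )

    # --- environment ------------------------------------------------------
    planted_env = [
        (transporters[0], syn.PRODUCTIVITY, +1, 0.8),
        (transporters[1], "Temperature", +1, 0.75),
        (transporters[2], "pH", -1, 0.7),
        (transporters[4], "Iron", +1, -0.75),
    ]
    env_sim = syn.make_environment(
        transporters,
        planted_effects=planted_env,
        n_stations=n_stations,
        family_without_metaG=transporters[6],
        seed=seed,
    )
    _write_stations(env_sim.stations, outdir / "stations.tsv")
    _write_abundance(env_sim.records, outdir / "abundance.tsv")

    # --- environmental homologue pool for the first transporter ----------
    query_rec = prot.proteome_a[0]
    pool = syn.make_meta_pool(
        family_id=transporters[0], query=query_rec, seed=seed
    )
    write_fasta(pool.meta, outdir / "meta_pool.fasta")
    write_fasta([r.record for r in pool.references], outdir / "references.fasta")
    _write_rows(
        outdir / "reference_labels.tsv",
        ("gene_id", "lineage", "plastid_targeted"),
        [(r.gene_id, r.lineage, int(r.plastid_targeted)) for r in pool.references],
    )

    truth = syn.TruthTable(
        seed=seed,
        planted_orthologs=prot.truth.planted_orthologs,
        planted_associations=(
            [(transporters[1], g) for g in candidates[0:5]]
            + [(transporters[2], g) for g in candidates[5:10]]
        ),
        planted_unique_transporters=planted_unique,
        planted_env_effects=planted_env,
        planted_mito_coupling=[(transporters[0], 0.95)],
        planted_in_clade=pool.truth.planted_in_clade,
    )
    truth.to_json(outdir / "truth.json")

    config = {
        "thresholds": _cfg_dict(cfg),
        "inputs": {
            "proteome_query": "proteome_query.fasta",
            "proteome_subject": "proteome_subject.fasta",
            "targeting_query": "targeting_query.tsv",
            "targeting_subject": "targeting_subject.tsv",
            "transport_terms": "transport_terms.tsv",
            "expr_rnaseq": "expr_rnaseq.tsv",
            "expr_rnaseq_groups": "expr_rnaseq_groups.tsv",
            "expr_microarray": "expr_microarray.tsv",
            "expr_microarray_groups": "expr_microarray_groups.tsv",
            "modules": "modules.tsv",
            "evolution": "evolution.tsv",
            "pathway_genes": "pathway_genes.tsv",
            "pathway_categories": "pathway_categories.tsv",
            "mito_panel": "mito_panel.tsv",
            "taxonomy": "taxonomy.tsv",
            "presence": "presence.tsv",
            "stations": "stations.tsv",
            "abundance": "abundance.tsv",
            "meta_pool": "meta_pool.fasta",
            "references": "references.fasta",
            "reference_labels": "reference_labels.tsv",
            "env_query_family": transporters[0],
        },
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config


def _cfg_dict(cfg: ThresholdConfig) -> dict:
    import dataclasses

    data = dataclasses.asdict(cfg)
    data["combos"] = [list(c) for c in cfg.combos]
    return data


def _write_pairs(path: Path, header: tuple[str, str], rows: Iterable[tuple]) -> None:
    _write_rows(path, header, rows)


def _write_rows(path: Path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def _write_stations(stations: Sequence[env.StationRecord], path: Path) -> None:
    params = sorted({k for s in stations for k, _ in s.env})
    with open(path, "w") as fh:
        fh.write("station_id\tdepth_layer\tsize_fraction\t" + "\t".join(params) + "\n")
        for s in stations:
            envmap = dict(s.env)
            fh.write(
                f"{s.station_id}\t{s.depth_layer}\t{s.size_fraction}\t"
                + "\t".join(fmt6(envmap.get(p, float("nan"))) for p in params)
                + "\n"
            )


def _write_abundance(records: Sequence[env.AbundanceRecord], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "family_id\tmeta_gene_id\tstation_id\tdepth_layer\tsize_fraction\tmetaT\tmetaG\n"
        )
        for r in records:
            metaG = "NA" if r.metaG is None else fmt6(r.metaG)
            fh.write(
                f"{r.family_id}\t{r.meta_gene_id}\t{r.station_id}\t{r.depth_layer}\t"
                f"{r.size_fraction}\t{fmt6(r.metaT)}\t{metaG}\n"
            )


# ---------------------------------------------------------------------------
# running the atlas
# ---------------------------------------------------------------------------


def _load_config(config_path: str | Path) -> tuple[ThresholdConfig, dict[str, Path], str]:
    config_path = Path(config_path)
    with open(config_path) as fh:
        raw = yaml.safe_load(fh)
    cfg = ThresholdConfig(**_coerce_combos(raw.get("thresholds", {})))
    inputs = {}
    env_family = ""
    for key, value in (raw.get("inputs") or {}).items():
        if key == "env_query_family":
            env_family = value
            continue
        inputs[key] = (config_path.parent / value).resolve()
    missing = [str(p) for p in inputs.values() if not p.exists()]
    if missing:
        raise FormatError(f"config references missing inputs: {missing}")
    return cfg, inputs, env_family


def _coerce_combos(thresholds: dict) -> dict:
    thresholds = dict(thresholds)
    if "combos" in thresholds:
        thresholds["combos"] = tuple(tuple(c) for c in thresholds["combos"])
    return thresholds


def _read_terms(path: Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set[str]] = defaultdict(set)
    for _, row in df.iterrows():
        out[row["gene_id"]].add(row["term"])
    return dict(out)


def _attach_terms(
    proteome: list[ProteinRecord], terms: Mapping[str, set[str]]
) -> list[ProteinRecord]:
    return [
        ProteinRecord(
            r.gene_id, r.species_id, r.sequence, frozenset(terms.get(r.gene_id, set()))
        )
        for r in proteome
    ]


def run_atlas(
    config_path: str | Path,
    outdir: str | Path,
    skip: Sequence[str] = (),
) -> dict:
    """Run all (non-skipped) stages and write the report + stage tables.

    Missing optional inputs mark the corresponding report section absent;
    the remaining sections are produced normally. The report validates
    against :func:`validate_report` before being written.
    """
    for stage in skip:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; stages are {STAGES}")
    cfg, inputs, env_family = _load_config(config_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "sections": {},
        "transporters": {},
    }
    sections = report["sections"]

    transporter_ids: list[str] = []

    # ---- homology stage --------------------------------------------------
    if "homology" not in skip and {"proteome_query", "proteome_subject"} <= set(inputs):
        sections["homology"] = _stage_homology(cfg, inputs, outdir, report)
        transporter_ids = sections["homology"]["transporters"]
    else:
        sections["homology"] = None

    # ---- evidence scoring ------------------------------------------------
    if "score" not in skip and {"expr_microarray", "modules"} <= set(inputs):
        sections["score"] = _stage_score(cfg, inputs, outdir, report, transporter_ids)
    else:
        sections["score"] = None

    # ---- mitochondrial co-regulation ------------------------------------
    if "mito" not in skip and {"expr_microarray", "mito_panel"} <= set(inputs):
        sections["mito"] = _stage_mito(cfg, inputs, outdir, report, transporter_ids)
    else:
        sections["mito"] = None

    # ---- taxonomic conservation -----------------------------------------
    if "conserve" not in skip and {"presence", "taxonomy"} <= set(inputs):
        sections["conserve"] = _stage_conserve(cfg, inputs, outdir, report)
    else:
        sections["conserve"] = None

    # ---- environmental correlation --------------------------------------
    if "envcorr" not in skip and {"stations", "abundance"} <= set(inputs):
        sections["envcorr"] = _stage_envcorr(cfg, inputs, outdir, report, env_family)
    else:
        sections["envcorr"] = None

    validate_report(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")
    return report


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def _round(x: float | None) -> float | None:
    return None if x is None else float(f"{x:.6g}")


def _transporter_entry(report: dict, tid: str) -> dict:
    return report["transporters"].setdefault(tid, {})


def _stage_homology(cfg, inputs, outdir: Path, report: dict) -> dict:
    terms = _read_terms(inputs["transport_terms"]) if "transport_terms" in inputs else {}
    proteome_q = _attach_terms(read_fasta(inputs["proteome_query"], "query"), terms)
    proteome_s = read_fasta(inputs["proteome_subject"], "subject")
    preds_q = read_targeting_predictions(inputs["targeting_query"])
    preds_s = (
        read_targeting_predictions(inputs["targeting_subject"])
        if "targeting_subject" in inputs
        else []
    )

    hits_qs = hom.pairwise_homology_search(proteome_q, proteome_s, cfg)
    hits_sq = hom.pairwise_homology_search(proteome_s, proteome_q, cfg)
    write_hit_table(hits_qs, outdir / "hits_query_subject.tsv")
    write_hit_table(hits_sq, outdir / "hits_subject_query.tsv")
    rbh = hom.reciprocal_best_hits(hits_qs, hits_sq, cfg)
    _write_rows(
        outdir / "rbh_pairs.tsv",
        ("id_query", "id_subject", "identity_pct", "evalue"),
        [
            (p.id_a, p.id_b, fmt6(p.forward_hit.identity_pct), fmt6(p.forward_hit.evalue))
            for p in rbh
        ],
    )

    transport_term_set = sorted({t for ts in terms.values() for t in ts})
    selected = sorted(
        hom.select_plastid_transporters(proteome_q, preds_q, transport_term_set, cfg)
        if transport_term_set
        else []
    )

    by_gene_s = defaultdict(list)
    for p in preds_s:
        by_gene_s[p.gene_id].append(p)
    profiles_s = {
        g: hom.consensus_targeting(ps, cfg, convention="plant")
        for g, ps in by_gene_s.items()
    }
    one_to_many = hom.one_to_many_table(hits_qs)
    loc_table = hom.cross_species_localization_table(one_to_many, profiles_s)
    _write_rows(
        outdir / "localization_query.tsv",
        ("query_id", "homolog_categories"),
        [
            (q, ";".join(f"{c}:{n}" for c, n in sorted(counts.items())))
            for q, counts in loc_table.items()
        ],
    )

    for pair in rbh:
        entry = _transporter_entry(report, pair.id_a)
        entry["rbh_subject"] = pair.id_b
    for tid in selected:
        entry = _transporter_entry(report, tid)
        entry["selected_transporter"] = True
        entry["homolog_categories"] = {
            c: n for c, n in sorted(loc_table.get(tid, {}).items())
        }

    return {
        "n_hits_forward": len(hits_qs),
        "n_hits_reverse": len(hits_sq),
        "n_rbh_pairs": len(rbh),
        "transporters": selected,
    }


def _read_expression(inputs, key: str) -> ExpressionMatrix | None:
    if key not in inputs:
        return None
    groups = inputs.get(f"{key}_groups")
    return read_matrix(inputs[key], groups)


def _stage_score(cfg, inputs, outdir: Path, report: dict, transporter_ids) -> dict:
    micro = _read_expression(inputs, "expr_microarray")
    rna = _read_expression(inputs, "expr_rnaseq")
    modules = (
        pd.read_csv(inputs["modules"], sep="\t", dtype=str)
        .set_index("gene_id")["module"]
        .to_dict()
    )
    evolution: dict[str, ev.EvolutionAnnotation] = {}
    if "evolution" in inputs:
        edf = pd.read_csv(inputs["evolution"], sep="\t", dtype=str).fillna("")
        for _, row in edf.iterrows():
            losses = frozenset(c for c in row["loss_clades"].split(";") if c)
            evolution[row["gene_id"]] = ev.EvolutionAnnotation(
                row["gene_id"], row["origin_ancestor"], losses
            )
    pmap = None
    if {"pathway_genes", "pathway_categories"} <= set(inputs):
        gdf = pd.read_csv(inputs["pathway_genes"], sep="\t", dtype=str)
        gene_pathways: dict[str, set[str]] = defaultdict(set)
        for _, row in gdf.iterrows():
            gene_pathways[row["gene_id"]].add(row["pathway"])
        cdf = pd.read_csv(inputs["pathway_categories"], sep="\t", dtype=str)
        pmap = ev.PathwayMap(dict(gene_pathways), dict(zip(cdf["pathway"], cdf["category"])))

    preds_q = read_targeting_predictions(inputs["targeting_query"])
    by_gene = defaultdict(list)
    for p in preds_q:
        by_gene[p.gene_id].append(p)
    plastid_of = {
        g: hom.consensus_targeting(ps, cfg).plastid for g, ps in by_gene.items()
    }

    # optional cross-species condition: RBH homolog map + homolog matrix
    tp_expr = _read_expression(inputs, "expr_tp_microarray")
    tp_map: dict[str, str] = {}
    if tp_expr is not None and "tp_homolog_map" in inputs:
        mdf = pd.read_csv(inputs["tp_homolog_map"], sep="\t", dtype=str)
        tp_map = dict(zip(mdf["gene_id"], mdf["homolog_id"]))
        if cfg.group_reduce == "mean" and tp_expr.sample_groups:
            tp_expr = tp_expr.group_means()

    def corr(matrix: ExpressionMatrix | None, a: str, b: str) -> float | None:
        if matrix is None or a not in matrix or b not in matrix:
            return None
        m = matrix.group_means() if (cfg.group_reduce == "mean" and matrix.sample_groups) else matrix
        return mito_mod.condition_correlation(m.row(a), m.row(b))

    transporters = list(transporter_ids) or sorted(
        {g for g in modules if g in plastid_of and plastid_of[g]}
    )
    candidates = sorted(g for g in modules if g not in transporters)

    rows = []
    profiles: dict[str, frozenset[str]] = {}
    n_associated = {}
    for tid in transporters:
        bundles = []
        for g in candidates:
            t_ann, g_ann = evolution.get(tid), evolution.get(g)
            bundle = ev.EvidenceBundle(
                transporter_id=tid,
                gene_id=g,
                same_wgcna_module=modules.get(g) == modules.get(tid)
                and modules.get(tid) is not None,
                r_rnaseq=corr(rna, tid, g),
                r_microarray=corr(micro, tid, g),
                r_tp_homolog_microarray=(
                    ev.tp_homolog_correlation(tid, g, tp_map, tp_expr)
                    if tp_expr is not None
                    else None
                ),
                plastid_targeted=bool(plastid_of.get(g, False)),
                same_origin=(
                    t_ann is not None
                    and g_ann is not None
                    and t_ann.origin_ancestor == g_ann.origin_ancestor
                ),
                same_loss_pattern=(
                    t_ann is not None and g_ann is not None and ev.same_loss(t_ann, g_ann, cfg)
                ),
            )
            bundles.append(bundle)
            score = ev.composite_score(bundle, cfg)
            rows.append(
                (
                    tid,
                    g,
                    int(bundle.same_wgcna_module),
                    fmt6(bundle.r_rnaseq) if bundle.r_rnaseq is not None else "NA",
                    fmt6(bundle.r_microarray) if bundle.r_microarray is not None else "NA",
                    fmt6(bundle.r_tp_homolog_microarray)
                    if bundle.r_tp_homolog_microarray is not None
                    else "NA",
                    int(bundle.plastid_targeted),
                    int(bundle.same_origin),
                    int(bundle.same_loss_pattern),
                    score,
                )
            )
        associated = ev.associated_genes(tid, bundles, cfg)
        n_associated[tid] = len(associated)
        entry = _transporter_entry(report, tid)
        entry["associated_genes"] = sorted(associated)
        if pmap is not None:
            linked = ev.pathway_links(tid, associated, pmap, cfg)
            profile = ev.category_profile(tid, linked, pmap)
            profiles[tid] = profile
            entry["linked_pathways"] = sorted(linked)
            entry["categories"] = sorted(profile)
    _write_rows(
        outdir / "association_scores.tsv",
        (
            "transporter_id",
            "gene_id",
            "same_module",
            "r_rnaseq",
            "r_microarray",
            "r_tp_homolog",
            "plastid_targeted",
            "same_origin",
            "same_loss",
            "score",
        ),
        rows,
    )
    venn = ev.venn_counts(profiles) if profiles else {}
    _write_rows(
        outdir / "venn_counts.tsv",
        ("categories", "n_transporters"),
        sorted((";".join(sorted(k)), v) for k, v in venn.items()),
    )
    return {
        "n_transporters": len(transporters),
        "n_candidates": len(candidates),
        "n_associated": n_associated,
        "venn_total": sum(venn.values()),
    }


def _stage_mito(cfg, inputs, outdir: Path, report: dict, transporter_ids) -> dict:
    micro = _read_expression(inputs, "expr_microarray")
    pdf = pd.read_csv(inputs["mito_panel"], sep="\t", dtype=str)
    panel = [
        mito_mod.MitoGene(row["gene_id"], row["function_class"]) for _, row in pdf.iterrows()
    ]
    panel_ids = {g.gene_id for g in panel}
    transporters = [t for t in transporter_ids if t in micro] or sorted(
        g for g in micro.genes if g not in panel_ids
    )
    results = [
        mito_mod.mean_mito_correlation(t, micro, panel, cfg) for t in transporters
    ]
    positive, negative = mito_mod.crosstalk_candidates(results, cfg)
    _write_rows(
        outdir / "mito_scatter.tsv",
        (
            "transporter_id",
            "mean_r_biogenesis",
            "mean_r_respiratory",
            "mean_r_overall",
            "n_mito_genes_used",
        ),
        [
            (
                r.transporter_id,
                fmt6(r.mean_r_biogenesis) if r.mean_r_biogenesis is not None else "NA",
                fmt6(r.mean_r_respiratory) if r.mean_r_respiratory is not None else "NA",
                fmt6(r.mean_r_overall) if r.mean_r_overall is not None else "NA",
                r.n_mito_genes_used,
            )
            for r in results
        ],
    )
    for r in results:
        entry = _transporter_entry(report, r.transporter_id)
        entry["mito"] = {
            "mean_r_biogenesis": _round(r.mean_r_biogenesis),
            "mean_r_respiratory": _round(r.mean_r_respiratory),
            "mean_r_overall": _round(r.mean_r_overall),
            "crosstalk": (
                "positive"
                if r.transporter_id in positive
                else "negative"
                if r.transporter_id in negative
                else "none"
            ),
        }
    return {
        "n_transporters": len(results),
        "crosstalk_positive": sorted(positive),
        "crosstalk_negative": sorted(negative),
    }


def _stage_conserve(cfg, inputs, outdir: Path, report: dict) -> dict:
    tdf = pd.read_csv(inputs["taxonomy"], sep="\t", dtype=str)
    taxmap = cons.TaxonomyMap(
        dict(zip(tdf["species_id"], tdf["group"])),
        dict(
            (g, l)
            for g, l in zip(tdf["group"], tdf["lineage_class"])
        ),
    )
    pdf = pd.read_csv(inputs["presence"], sep="\t")
    profiles = []
    for tid, sub in pdf.groupby("transporter_id", sort=True):
        counts = {g: 0 for g in taxmap.groups}
        counts.update(dict(zip(sub["group"], sub["count"].astype(int))))
        profiles.append(cons.PresenceProfile(str(tid), tuple(sorted(counts.items()))))
    matrix, tallies = cons.conservation_matrix(profiles, taxmap)
    matrix.to_csv(outdir / "presence_matrix.tsv", sep="\t")
    tallies.to_frame().to_csv(outdir / "conservation_tallies.tsv", sep="\t")
    unique = {p.transporter_id: cons.is_diatom_unique(p, taxmap) for p in profiles}
    _write_rows(
        outdir / "diatom_unique.tsv",
        ("transporter_id", "diatom_unique"),
        sorted((t, int(u)) for t, u in unique.items()),
    )
    for p in profiles:
        entry = _transporter_entry(report, p.transporter_id)
        entry["presence"] = p.as_dict()
        entry["diatom_unique"] = unique[p.transporter_id]
    return {
        "n_profiles": len(profiles),
        "diatom_unique": sorted(t for t, u in unique.items() if u),
        "tallies": tallies.to_dict(),
    }


def _stage_envcorr(cfg, inputs, outdir: Path, report: dict, env_family: str) -> dict:
    stations = env.read_station_table(inputs["stations"])
    records = env.read_abundance_table(inputs["abundance"])
    params = sorted({k for s in stations for k, _ in s.env})
    families = sorted({r.family_id for r in records})

    clade_info = None
    retained_by_family: dict[str, set[str]] = {}
    if env_family and {"meta_pool", "references", "reference_labels", "proteome_query"} <= set(
        inputs
    ):
        meta = read_fasta(inputs["meta_pool"], "tara")
        refs_fa = {r.gene_id: r for r in read_fasta(inputs["references"], "ref")}
        ldf = pd.read_csv(inputs["reference_labels"], sep="\t", dtype=str)
        references = [
            env.ReferenceSeq(
                refs_fa[row["gene_id"]], row["lineage"], bool(int(row["plastid_targeted"]))
            )
            for _, row in ldf.iterrows()
        ]
        proteome_q = read_fasta(inputs["proteome_query"], "query")
        query_seq = {r.gene_id: r.sequence for r in proteome_q}.get(env_family)
        filtered = env.filter_meta_homologues(
            meta, references, proteome_q, env_family, cfg
        )
        retained = env.clade_extract(
            [m for m in meta if m.gene_id in filtered], references, query_seq
        )
        retained_by_family[env_family] = retained
        clade_info = {
            "family": env_family,
            "n_pool": len(meta),
            "n_filtered": len(filtered),
            "n_in_clade": len(retained),
            "retained": sorted(retained),
        }

    combo_rows = []
    agg_rows = []
    pp_flags = {}
    for fam in families:
        cells: dict[str, env.AggregateCell] = {}
        for param in params:
            results = []
            for combo in cfg.combos:
                sums = env.station_sums(records, fam, combo)
                env_vals = env.env_values_for_combo(stations, param, combo)
                res = env.signed_significance(
                    {s: t for s, (t, g) in sums.items()},
                    {s: g for s, (t, g) in sums.items()},
                    env_vals,
                    cfg,
                    family_id=fam,
                    parameter=param,
                    combo=combo,
                )
                results.append(res)
                combo_rows.append(
                    (
                        fam,
                        param,
                        f"{combo[0]} {combo[1]}",
                        fmt6(res.r_T) if res.r_T is not None else "NA",
                        fmt6(res.r_G) if res.r_G is not None else "NA",
                        res.n,
                        fmt6(res.p) if res.p is not None else "NA",
                        res.sign,
                        int(res.significant),
                    )
                )
            cell = env.aggregate_combos(fam, param, results, cfg)
            cells[param] = cell
            agg_rows.append(
                (
                    fam,
                    param,
                    cell.signed_score,
                    cell.n_sig_pos,
                    cell.n_sig_neg,
                    int(cell.strong_positive),
                    int(cell.strong_negative),
                )
            )
        flag, direction = env.primary_production_flag(fam, cells, cfg)
        pp_flags[fam] = (flag, direction)
        entry = _transporter_entry(report, fam)
        entry["env"] = {
            "aggregate": {
                p: {"signed_score": c.signed_score} for p, c in cells.items()
            },
            "strong_positive": sorted(p for p, c in cells.items() if c.strong_positive),
            "strong_negative": sorted(p for p, c in cells.items() if c.strong_negative),
            "primary_production": {"flag": flag, "direction": direction},
        }
    _write_rows(
        outdir / "env_per_combo.tsv",
        ("family_id", "parameter", "combo", "r_T", "r_G", "n", "p", "sign", "significant"),
        combo_rows,
    )
    _write_rows(
        outdir / "env_aggregate.tsv",
        (
            "family_id",
            "parameter",
            "signed_score",
            "n_sig_pos",
            "n_sig_neg",
            "strong_positive",
            "strong_negative",
        ),
        agg_rows,
    )
    strong_rows = []
    for fam in families:
        entry = report["transporters"][fam]["env"]
        strong_rows.append(
            (
                fam,
                ";".join(entry["strong_positive"]),
                ";".join(entry["strong_negative"]),
                int(entry["primary_production"]["flag"]),
                entry["primary_production"]["direction"],
            )
        )
    _write_rows(
        outdir / "env_strong_sets.tsv",
        ("family_id", "strong_positive", "strong_negative", "pp_flag", "pp_direction"),
        strong_rows,
    )
    return {
        "n_families": len(families),
        "parameters": params,
        "clade_extraction": clade_info,
        "pp_positive": sorted(f for f, (fl, d) in pp_flags.items() if fl and d > 0),
        "pp_negative": sorted(f for f, (fl, d) in pp_flags.items() if fl and d < 0),
    }


# ---------------------------------------------------------------------------
# report validation and rendering
# ---------------------------------------------------------------------------


def validate_report(report: dict) -> None:
    """Check the report's schema: version, section keys, unique transporter
    entries with typed fields."""
    if report.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ValueError("bad or missing schema_version")
    if set(report["sections"]) - set(STAGES):
        raise ValueError(f"unknown sections: {sorted(set(report['sections']) - set(STAGES))}")
    for tid, entry in report["transporters"].items():
        if not isinstance(tid, str) or not isinstance(entry, dict):
            raise ValueError("malformed transporter entry")
        if "env" in entry and "aggregate" not in entry["env"]:
            raise ValueError(f"env section of {tid} lacks aggregate")


def render_tables(report: dict, outdir: str | Path) -> list[Path]:
    """Derive the figure-equivalent summary tables from a report.

    Raises KeyError when a requested section was not run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def require(section: str):
        if report["sections"].get(section) is None:
            raise KeyError(f"report has no {section!r} section")
        return report["sections"][section]

    hom_sec = require("homology")
    rows = [
        (
            tid,
            entry.get("rbh_subject", ""),
            ";".join(
                f"{c}:{n}" for c, n in sorted(entry.get("homolog_categories", {}).items())
            ),
        )
        for tid, entry in sorted(report["transporters"].items())
        if entry.get("selected_transporter")
    ]
    path = outdir / "table_localization.tsv"
    _write_rows(path, ("transporter_id", "rbh_subject", "homolog_categories"), rows)
    written.append(path)

    require("score")
    venn: dict[str, int] = defaultdict(int)
    for tid, entry in report["transporters"].items():
        cats = entry.get("categories")
        if cats:
            venn[";".join(sorted(cats))] += 1
    path = outdir / "table_venn.tsv"
    _write_rows(path, ("categories", "n_transporters"), sorted(venn.items()))
    written.append(path)

    mito_sec = require("mito")
    rows = [
        (
            tid,
            entry["mito"]["mean_r_biogenesis"],
            entry["mito"]["mean_r_respiratory"],
            entry["mito"]["crosstalk"],
        )
        for tid, entry in sorted(report["transporters"].items())
        if "mito" in entry
    ]
    path = outdir / "table_mito.tsv"
    _write_rows(
        path, ("transporter_id", "mean_r_biogenesis", "mean_r_respiratory", "class"), rows
    )
    written.append(path)

    cons_sec = require("conserve")
    path = outdir / "table_conservation.tsv"
    _write_rows(
        path,
        ("group", "n_transporters_conserved"),
        sorted(cons_sec["tallies"].items()),
    )
    written.append(path)

    require("envcorr")
    rows = []
    for tid, entry in sorted(report["transporters"].items()):
        if "env" not in entry:
            continue
        for param, cell in sorted(entry["env"]["aggregate"].items()):
            score = cell["signed_score"]
            shade = "positive" if score > 0 else "negative" if score < 0 else "zero"
            rows.append((tid, param, score, abs(score), shade))
    path = outdir / "table_env_aggregate.tsv"
    _write_rows(
        path, ("family_id", "parameter", "signed_score", "magnitude", "class"), rows
    )
    written.append(path)
    return written
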