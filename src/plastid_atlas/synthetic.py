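"""Seeded generators for every input the pipeline consumes, with planted
truth for parameter-recovery tests.

A single root seed fans out to independent per-generator streams through
``numpy.random.SeedSequence(entropy=seed, spawn_key=(stream,))`` with a
fixed stream number per generator (0 proteomes, 1 expression, 2 taxon
presence, 3 environment, 4 meta pool), so adding a generator never perturbs
the output of another. The same seed always yields byte-identical files.

What the generators emulate — and what they do not — is documented in
docs/methods.md; in brief they reproduce the statistical structure the
analysis rules key on (planted ortholog identity, block-correlated
expression, rule-satisfying presence profiles, environmental responses that
differ between meta-transcriptome and meta-genome) without any claim of
biological sequence realism beyond point mutation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .conservation import PresenceProfile, TaxonomyMap, is_diatom_unique
from .core_io import (
    DEFAULT_COMBOS,
    DEFAULT_PRIMARY_PRODUCTION_PARAMS,
    ExpressionMatrix,
    ProteinRecord,
    TargetingPrediction,
)
from .envcorr import AbundanceRecord, ReferenceSeq, StationRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: stream numbers of the seed fan-out scheme
STREAM_PROTEOMES = 0
STREAM_EXPRESSION = 1
STREAM_PRESENCE = 2
STREAM_ENVIRONMENT = 3
STREAM_META_POOL = 4

#: functional term marking a gene as transport-associated in fixtures
TRANSPORT_TERM = "PF00083"

#: uniform sampling ranges for environmental covariates (units per name)
DEFAULT_ENV_RANGES: dict[str, tuple[float, float]] = {
    "Temperature": (-2.0, 31.0),  # deg C
    "Iron": (1e-5, 2e-3),  # mmol/m3
    "pH": (7.9, 8.3),
    "CDOM": (0.0, 0.5),  # a.u.
    "Chlorophyll_c3": (0.0, 2.5),  # mg/m3
    "Peridinin": (0.0, 2.5),
    "Fucoxanthin": (0.0, 2.5),
    "Prasinoxanthin": (0.0, 2.5),
    "19-Hexanoyloxyfucoxanthin": (0.0, 2.5),
    "Alloxanthin": (0.0, 2.5),
    "NPP": (50.0, 1500.0),  # mg C/m2/day
    "PIC": (0.0, 0.01),  # mol/m3
    "POC": (1.0, 300.0),  # ug/kg
    "Carbon_Total": (1900.0, 2300.0),  # umol/kg
}

#: pseudo-parameter name: a planted effect on the shared productivity latent
PRODUCTIVITY = "PP"


def stream_rng(seed: int, stream: int) -> np.random.Generator:
    """Deterministic per-generator random stream from the root seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


@dataclass
class TruthTable:
    """Machine-readable record of everything the generators planted."""

    seed: int
    planted_orthologs: list[tuple[str, str, float]] = field(default_factory=list)
    planted_associations: list[tuple[str, str]] = field(default_factory=list)
    planted_unique_transporters: list[str] = field(default_factory=list)
    planted_env_effects: list[tuple[str, str, int, float]] = field(default_factory=list)
    planted_mito_coupling: list[tuple[str, float]] = field(default_factory=list)
    planted_in_clade: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        with open(path) as fh:
            data = json.load(fh)
        data = {
            k: [tuple(x) if isinstance(x, list) else x for x in v]
            if isinstance(v, list)
            else v
            for k, v in data.items()
        }
        return cls(**data)


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def mutate_to_identity(sequence: str, identity: float, rng: np.random.Generator) -> str:
    """Point-mutate a sequence down to a target fractional identity.

    Mutated positions are spread evenly along the sequence so that no
    conserved sub-region survives with much higher local identity than the
    target (local alignments then measure close to the target).
    """
    if not (0.0 < identity <= 1.0):
        raise ValueError(f"identity target {identity} outside (0, 1]")
    n = len(sequence)
    k = round((1.0 - identity) * n)
    if k == 0:
        return sequence
    positions = np.unique(np.floor(np.linspace(0, n - 1, k)).astype(int))
    out = list(sequence)
    for pos in positions:
        choices = [a for a in AA20 if a != out[pos]]
        out[pos] = rng.choice(choices)
    return "".join(out)


def mutate_at_rate(sequence: str, rate: float, rng: np.random.Generator) -> str:
    """Independent point mutations at the given per-site rate."""
    out = list(sequence)
    for pos in np.flatnonzero(rng.random(len(sequence)) < rate):
        choices = [a for a in AA20 if a != out[pos]]
        out[pos] = rng.choice(choices)
    return "".join(out)


@dataclass
class ProteomePairSim:
    proteome_a: list[ProteinRecord]
    proteome_b: list[ProteinRecord]
    predictions_a: list[TargetingPrediction]
    predictions_b: list[TargetingPrediction]
    truth: TruthTable


def make_proteomes(
    n_genes: int = 12,
    n_orthologs: int = 4,
    identity_levels: Sequence[float] | None = None,
    seq_len: int = 80,
    seed: int = 0,
    species: tuple[str, str] = ("A", "B"),
    n_dual: int = 1,
) -> ProteomePairSim:
    """Two proteomes with planted one-to-one orthologs among decoys.

    Each planted pair descends from a common ancestor point-mutated to its
    target identity; decoys are independent shuffled-composition sequences.
    Planted orthologs carry a transport functional term and a plastid
    targeting prediction; the first ``n_dual`` also carry an above-threshold
    MitoFates score (dual plastid/mitochondria candidates).
    """
    if n_orthologs > n_genes:
        raise ValueError("n_orthologs cannot exceed n_genes")
    if identity_levels is None:
        identity_levels = (0.9, 0.75, 0.6, 0.45)
    rng = stream_rng(seed, STREAM_PROTEOMES)
    sp_a, sp_b = species
    truth = TruthTable(seed=seed)
    proteome_a, proteome_b = [], []
    preds_a, preds_b = [], []

    for i in range(n_orthologs):
        ident = float(identity_levels[i % len(identity_levels)])
        ancestor = random_protein(rng, seq_len)
        # place all divergence on one branch: every mutated site differs
        # between the descendants, so pairwise identity hits the target
        seq_a = ancestor
        seq_b = mutate_to_identity(ancestor, ident, rng)
        id_a, id_b = f"{sp_a}_tr{i:02d}", f"{sp_b}_tr{i:02d}"
        proteome_a.append(
            ProteinRecord(id_a, sp_a, seq_a, frozenset({TRANSPORT_TERM}))
        )
        proteome_b.append(
            ProteinRecord(id_b, sp_b, seq_b, frozenset({TRANSPORT_TERM}))
        )
        preds_a.append(TargetingPrediction(id_a, "ASAFind", "plastid"))
        preds_b.append(TargetingPrediction(id_b, "ASAFind", "plastid"))
        if i < n_dual:
            preds_a.append(
                TargetingPrediction(id_a, "MitoFates", "mitochondrion", 0.5)
            )
        truth.planted_orthologs.append((id_a, id_b, ident))

    for i in range(n_genes - n_orthologs):
        for sp, proteome, preds in (
            (sp_a, proteome_a, preds_a),
            (sp_b, proteome_b, preds_b),
        ):
            gid = f"{sp}_dec{i:02d}"
            proteome.append(ProteinRecord(gid, sp, random_protein(rng, seq_len)))
            preds.append(TargetingPrediction(gid, "HECTAR", "none"))
    return ProteomePairSim(proteome_a, proteome_b, preds_a, preds_b, truth)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionSim:
    matrix: ExpressionMatrix
    modules: dict[str, str]
    truth: TruthTable


def make_expression(
    genes: Sequence[str],
    blocks: Mapping[str, Sequence[str]],
    n_groups: int = 17,
    loading: float = 0.9,
    noise_sd: float | None = None,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> ExpressionSim:
    """Block-correlated expression over condition groups with planted
    modules.

    Genes of one block share a latent condition profile with the given
    loading; the planted pairwise Pearson r between two block members is
    ``loading**2 / (loading**2 + noise_sd**2)``. ``noise_sd`` defaults to
    ``sqrt(1 - loading**2)`` so the planted r is simply ``loading**2``; at
    ``noise_sd = 0`` within-block r is exactly 1. Every unassigned gene
    receives its own singleton latent (module label ``singleton_<gene>``).
    When the total latent count is at most ``n_groups - 1`` the latents are
    orthogonalized, making between-block sample correlations exactly zero —
    the zero-noise regime is then free of chance correlation.
    """
    block_of: dict[str, str] = {}
    for name, members in blocks.items():
        for g in members:
            if g in block_of:
                raise ValueError(f"gene {g!r} assigned to two blocks")
            block_of[g] = name
    unknown = set(block_of) - set(genes)
    if unknown:
        raise ValueError(f"block genes not in gene list: {sorted(unknown)}")
    if noise_sd is None:
        noise_sd = float(np.sqrt(max(0.0, 1.0 - loading**2)))
    if rng is None:
        rng = stream_rng(seed, STREAM_EXPRESSION)

    latent_names = list(blocks) + [f"singleton_{g}" for g in genes if g not in block_of]
    Z = rng.standard_normal((len(latent_names), n_groups))
    Z -= Z.mean(axis=1, keepdims=True)
    if len(latent_names) <= n_groups - 1:
        # orthonormalize within the mean-zero hyperplane, then restandardize
        Q, _ = np.linalg.qr(Z.T)
        Z = Q.T
        Z -= Z.mean(axis=1, keepdims=True)
    Z /= Z.std(axis=1, keepdims=True)
    latent = dict(zip(latent_names, Z))

    modules: dict[str, str] = {}
    values = np.empty((len(genes), n_groups))
    for i, g in enumerate(genes):
        mod = block_of.get(g, f"singleton_{g}")
        modules[g] = mod
        eps = rng.standard_normal(n_groups)
        values[i] = loading * latent[mod] + noise_sd * eps

    samples = [f"grp{j:02d}" for j in range(n_groups)]
    matrix = ExpressionMatrix(
        list(genes), samples, values, {s: s for s in samples}
    )
    truth = TruthTable(seed=seed)
    return ExpressionSim(matrix, modules, truth)


# ---------------------------------------------------------------------------
# taxon presence
# ---------------------------------------------------------------------------


@dataclass
class PresenceSim:
    profiles: list[PresenceProfile]
    taxmap: TaxonomyMap
    truth: TruthTable


def default_taxonomy(
    n_diatom_groups: int = 2,
    n_other_groups: int = 2,
    species_per_group: int = 4,
) -> TaxonomyMap:
    """A toy grouped species library (diatom vs non-diatom lineages)."""
    group_lineage: dict[str, str] = {}
    species_group: dict[str, str] = {}
    other_classes = ("other_ochrophyte", "aplastidic_stramenopile", "other_secondary_red")
    for i in range(n_diatom_groups):
        group_lineage[f"diatom_g{i}"] = "diatom"
    for i in range(n_other_groups):
        group_lineage[f"nondiatom_g{i}"] = other_classes[i % len(other_classes)]
    for group in group_lineage:
        for s in range(species_per_group):
            species_group[f"{group}_sp{s}"] = group
    return TaxonomyMap(species_group, group_lineage)


def make_taxon_presence(
    taxmap: TaxonomyMap,
    transporter_ids: Sequence[str],
    planted_unique: Sequence[str],
    seed: int = 0,
    forced_counts: Mapping[str, Mapping[str, int]] | None = None,
) -> PresenceSim:
    """Presence profiles in which exactly the planted set satisfies the
    diatom-uniqueness rule.

    ``forced_counts`` overrides generated counts per transporter; a forced
    profile that breaks the planted-uniqueness contract raises ValueError
    (the generator refuses to emit inconsistent truth).
    """
    unknown = set(planted_unique) - set(transporter_ids)
    if unknown:
        raise ValueError(f"planted uniques not in transporter list: {sorted(unknown)}")
    rng = stream_rng(seed, STREAM_PRESENCE)
    group_size = {
        g: sum(1 for s, sg in taxmap.species_group.items() if sg == g)
        for g in taxmap.groups
    }
    diatom = taxmap.diatom_groups()
    non_diatom = taxmap.non_diatom_groups()
    profiles = []
    for tid in transporter_ids:
        counts: dict[str, int] = {}
        if tid in planted_unique:
            for g in diatom:
                counts[g] = int(rng.integers(2, max(group_size[g], 2) + 1))
            for g in non_diatom:
                counts[g] = 0
            total = int(rng.integers(0, 4))  # < 4 non-diatom species overall
            for _ in range(total):
                open_groups = [g for g in non_diatom if counts[g] < min(2, group_size[g])]
                if open_groups:
                    counts[rng.choice(open_groups)] += 1
        else:
            for g in taxmap.groups:
                counts[g] = int(rng.integers(0, group_size[g] + 1))
        if forced_counts and tid in forced_counts:
            counts.update(forced_counts[tid])
        profile = PresenceProfile(tid, tuple(sorted(counts.items())))
        unique = is_diatom_unique(profile, taxmap)
        if tid in planted_unique and not unique:
            raise ValueError(
                f"planted-unique transporter {tid!r} violates the uniqueness rule"
            )
        if tid not in planted_unique and unique:
            # background profile happened to satisfy the rule: break it by
            # silencing the first diatom group
            counts[diatom[0]] = int(rng.integers(0, 2))
            profile = PresenceProfile(tid, tuple(sorted(counts.items())))
        profiles.append(profile)
    truth = TruthTable(seed=seed, planted_unique_transporters=list(planted_unique))
    return PresenceSim(profiles, taxmap, truth)


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------


@dataclass
class EnvironmentSim:
    stations: list[StationRecord]
    records: list[AbundanceRecord]
    truth: TruthTable


def _shift_positive(x: np.ndarray) -> np.ndarray:
    """Affine shift to strictly positive values (Pearson-invariant)."""
    return x - x.min() + 0.1


def make_environment(
    families: Sequence[str],
    planted_effects: Sequence[tuple[str, str, int, float]] = (),
    parameters: Mapping[str, tuple[float, float]] | None = None,
    n_stations: int = 30,
    combos: Sequence[tuple[str, str]] = DEFAULT_COMBOS,
    metaG_coupling: float = 0.3,
    n_meta_genes: int = 2,
    family_without_metaG: str | None = None,
    productivity_loading: float = 0.9,
    seed: int = 0,
) -> EnvironmentSim:
    """Station covariates and MetaT/MetaG abundances with planted responses.

    Each planted effect (family, parameter, sign, effect_r) makes the
    family's per-station MetaT sum correlate with the parameter at
    ``effect_r`` in every combo. For sign +1 the MetaG sum couples weakly
    (``metaG_coupling * effect_r``), so the transcriptome-vs-genome call is
    positive; for sign -1 MetaG couples more tightly than MetaT, flipping
    the call. ``parameter`` may be the pseudo-parameter ``"PP"``: the effect
    then acts on a shared productivity latent from which all ten merged
    primary-production covariates are drawn (loading
    ``productivity_loading``), planting a merged primary-production
    relationship. Family sums are split across ``n_meta_genes`` meta-genes
    by fixed per-family proportions.
    """
    if parameters is None:
        parameters = DEFAULT_ENV_RANGES
    for fam, param, sign, r in planted_effects:
        if fam not in families:
            raise ValueError(f"planted effect references unknown family {fam!r}")
        if param != PRODUCTIVITY and param not in parameters:
            raise ValueError(f"planted effect references unknown parameter {param!r}")
        if abs(r) >= 1:
            raise ValueError(f"|effect_r| must be < 1, got {r}")
        if sign not in (+1, -1):
            raise ValueError("sign must be +1 or -1")
    effects = {(fam, param): (sign, r) for fam, param, sign, r in planted_effects}
    if len(effects) != len(planted_effects):
        raise ValueError("duplicate (family, parameter) planted effect")
    rng = stream_rng(seed, STREAM_ENVIRONMENT)

    station_ids = [f"TARA_{i:03d}" for i in range(n_stations)]
    depths = sorted({d for d, _ in combos})
    pp_params = [p for p in DEFAULT_PRIMARY_PRODUCTION_PARAMS if p in parameters]

    # covariates per (station, depth); size fractions share them
    env_by_depth: dict[str, dict[str, np.ndarray]] = {}
    productivity: dict[str, np.ndarray] = {}
    for depth in depths:
        prod = rng.standard_normal(n_stations)
        prod = (prod - prod.mean()) / prod.std()
        productivity[depth] = prod
        values: dict[str, np.ndarray] = {}
        for name, (low, high) in parameters.items():
            if name in pp_params:
                raw = productivity_loading * prod + np.sqrt(
                    1 - productivity_loading**2
                ) * rng.standard_normal(n_stations)
                u = (raw - raw.min()) / (raw.max() - raw.min())
            else:
                u = rng.random(n_stations)
            values[name] = low + (high - low) * u
        env_by_depth[depth] = values

    stations = []
    for depth, size in combos:
        for i, sid in enumerate(station_ids):
            env = tuple(
                (name, float(env_by_depth[depth][name][i]))
                for name in sorted(parameters)
            )
            stations.append(StationRecord(sid, depth, size, env))

    records: list[AbundanceRecord] = []
    for fam in families:
        fam_effects = {p: sr for (f, p), sr in effects.items() if f == fam}
        if len(fam_effects) > 1:
            raise ValueError(f"family {fam!r} has more than one planted effect")
        propT = rng.dirichlet(np.ones(n_meta_genes))
        propG = rng.dirichlet(np.ones(n_meta_genes))
        for depth, size in combos:
            if fam_effects:
                param, (sign, r) = next(iter(fam_effects.items()))
                if param == PRODUCTIVITY:
                    z = productivity[depth]
                else:
                    v = env_by_depth[depth][param]
                    z = (v - v.mean()) / v.std()
                eT = rng.standard_normal(n_stations)
                sum_T = _shift_positive(r * z + np.sqrt(1 - r * r) * eT)
                if sign > 0:
                    rG = metaG_coupling * r
                else:
                    rG = float(np.sign(r)) * min(0.99, abs(r) * 1.2)
                eG = rng.standard_normal(n_stations)
                sum_G = _shift_positive(rG * z + np.sqrt(1 - rG * rG) * eG)
            else:
                sum_T = _shift_positive(rng.standard_normal(n_stations))
                sum_G = _shift_positive(rng.standard_normal(n_stations))
            for i, sid in enumerate(station_ids):
                for m in range(n_meta_genes):
                    metaG = (
                        None
                        if fam == family_without_metaG
                        else float(sum_G[i] * propG[m])
                    )
                    records.append(
                        AbundanceRecord(
                            family_id=fam,
                            meta_gene_id=f"{fam}_mg{m}",
                            station_id=sid,
                            depth_layer=depth,
                            size_fraction=size,
                            metaT=float(sum_T[i] * propT[m]),
                            metaG=metaG,
                        )
                    )
    truth = TruthTable(
        seed=seed,
        planted_env_effects=[(f, p, s, r) for f, p, s, r in planted_effects],
    )
    return EnvironmentSim(stations, records, truth)


# ---------------------------------------------------------------------------
# meta-gene pool
# ---------------------------------------------------------------------------


@dataclass
class MetaPoolSim:
    query: ProteinRecord
    query_proteome: list[ProteinRecord]
    references: list[ReferenceSeq]
    meta: list[ProteinRecord]
    truth: TruthTable


def make_meta_pool(
    family_id: str = "fam0",
    query: ProteinRecord | None = None,
    seq_len: int = 80,
    n_diatom_refs: int = 3,
    n_outgroup_refs: int = 3,
    n_in_clade: int = 4,
    n_out_clade: int = 3,
    n_proteome_decoys: int = 4,
    mutation_rate: float = 0.05,
    seed: int = 0,
) -> MetaPoolSim:
    """Environmental homologue pool with planted clade membership.

    Diatom plastid-targeted references are light mutations of the query
    transporter; outgroup references (plastid-targeted but non-diatom) are
    heavy mutations of the same ancestor, so they align but branch apart.
    Planted in-clade meta-genes derive from diatom references, out-of-clade
    meta-genes from outgroups.
    """
    rng = stream_rng(seed, STREAM_META_POOL)
    if query is None:
        query = ProteinRecord(
            f"{family_id}_q", "query_species", random_protein(rng, seq_len),
            frozenset({TRANSPORT_TERM}),
        )
    references: list[ReferenceSeq] = []
    diatom_refs: list[ProteinRecord] = []
    for i in range(n_diatom_refs):
        rec = ProteinRecord(
            f"{family_id}_dref{i}", f"diatom_sp{i}",
            mutate_at_rate(query.sequence, 0.12, rng),
        )
        diatom_refs.append(rec)
        references.append(ReferenceSeq(rec, "diatom", True))
    # outgroups descend from their own common ancestor so they form a
    # coherent sister clade rather than a scatter of long branches
    outgroup_ancestor = mutate_at_rate(query.sequence, 0.30, rng)
    outgroup_refs: list[ProteinRecord] = []
    for i in range(n_outgroup_refs):
        rec = ProteinRecord(
            f"{family_id}_oref{i}", f"haptophyte_sp{i}",
            mutate_at_rate(outgroup_ancestor, 0.12, rng),
        )
        outgroup_refs.append(rec)
        references.append(ReferenceSeq(rec, "haptophyte", True))

    meta: list[ProteinRecord] = []
    in_clade: list[str] = []
    for i in range(n_in_clade):
        parent = diatom_refs[i % len(diatom_refs)]
        gid = f"{family_id}_meta_in{i}"
        meta.append(
            ProteinRecord(gid, "tara", mutate_at_rate(parent.sequence, mutation_rate, rng))
        )
        in_clade.append(gid)
    for i in range(n_out_clade):
        parent = outgroup_refs[i % len(outgroup_refs)]
        gid = f"{family_id}_meta_out{i}"
        meta.append(
            ProteinRecord(gid, "tara", mutate_at_rate(parent.sequence, mutation_rate, rng))
        )

    query_proteome = [query] + [
        ProteinRecord(f"{family_id}_pdec{i}", query.species_id, random_protein(rng, seq_len))
        for i in range(n_proteome_decoys)
    ]
    truth = TruthTable(seed=seed, planted_in_clade=in_clade)
    return MetaPoolSim(query, query_proteome, references, meta, truth)
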