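import pytest

from plastid_atlas.core_io import ProteinRecord, TargetingPrediction, ThresholdConfig
from plastid_atlas.homology import (
    HomologyHit,
    best_hit,
    consensus_targeting,
    cross_species_localization_table,
    one_to_many_table,
    pairwise_homology_search,
    reciprocal_best_hits,
    select_plastid_transporters,
)
from plastid_atlas.synthetic import make_proteomes


def hit(q="q", s="s", bitscore=50.0, ev=1e-10, ident=80.0):
    return HomologyHit(q, s, ident, 40, 5, 0, 1, 40, 1, 40, ev, bitscore)


class TestSearch:
    def test_identical_query_subject_full_identity(self, cfg):
        rec = ProteinRecord("g1", "a", "MKVLAWGHTDERRAGHKILMNWCEF" * 2)
        hits = pairwise_homology_search([rec], [ProteinRecord("h1", "b", rec.sequence)], cfg)
        assert len(hits) == 1
        assert hits[0].identity_pct == 100.0

    def test_evalue_threshold_is_inclusive(self, cfg):
        rec = ProteinRecord("g1", "a", "MKVLAWGHTDERRAGHKILMNWCEF")
        sub = ProteinRecord("h1", "b", rec.sequence)
        loose = ThresholdConfig(max_evalue=1e3)
        (h,) = pairwise_homology_search([rec], [sub], loose)
        exact = ThresholdConfig(max_evalue=h.evalue)
        assert pairwise_homology_search([rec], [sub], exact), "E == cut must be retained"

    def test_planted_ortholog_is_only_hit_among_decoys(self, cfg):
        sim = make_proteomes(n_genes=8, n_orthologs=1, identity_levels=(0.4,), seed=3)
        hits = pairwise_homology_search(sim.proteome_a, sim.proteome_b, cfg)
        pairs = {(h.query_id, h.subject_id) for h in hits}
        assert pairs == {(a, b) for a, b, _ in sim.truth.planted_orthologs}

    def test_filtering_is_monotone(self, cfg):
        sim = make_proteomes(n_genes=6, n_orthologs=3, seed=5)
        base = pairwise_homology_search(sim.proteome_a, sim.proteome_b, cfg)
        stricter = ThresholdConfig(min_identity_pct=60.0, max_evalue=1e-10)
        subset = pairwise_homology_search(sim.proteome_a, sim.proteome_b, stricter)
        assert {(h.query_id, h.subject_id) for h in subset} <= {
            (h.query_id, h.subject_id) for h in base
        }

    def test_empty_inputs_rejected(self, cfg):
        with pytest.raises(ValueError):
            pairwise_homology_search([], [ProteinRecord("g", "a", "MK")], cfg)


class TestBestHit:
    def test_single_hit(self):
        h = hit()
        assert best_hit([h]) is h

    def test_higher_bitscore_wins(self):
        h80, h90 = hit(s="s1", bitscore=80), hit(s="s2", bitscore=90)
        assert best_hit([h80, h90]) is h90

    def test_tie_breaks_to_smallest_subject(self):
        hb, ha = hit(s="sB"), hit(s="sA")
        assert best_hit([hb, ha]).subject_id == "sA"

    def test_empty_returns_none(self):
        assert best_hit([]) is None

    def test_mixed_queries_rejected(self):
        with pytest.raises(ValueError):
            best_hit([hit(q="q1"), hit(q="q2")])


class TestRbh:
    def test_self_search_gives_identity_mapping(self, cfg):
        sim = make_proteomes(n_genes=5, n_orthologs=2, seed=1)
        hits = pairwise_homology_search(sim.proteome_a, sim.proteome_a, cfg)
        pairs = reciprocal_best_hits(hits, hits, cfg)
        self_pairs = {(p.id_a, p.id_b) for p in pairs}
        assert {(r.gene_id, r.gene_id) for r in sim.proteome_a} <= self_pairs

    def test_non_reciprocal_best_hit_excluded(self, cfg):
        # a1 -> b1 best, but b1 -> a2 best: no pair for a1
        ab = [hit(q="a1", s="b1", bitscore=90)]
        ba = [hit(q="b1", s="a2", bitscore=95), hit(q="b1", s="a1", bitscore=50)]
        assert reciprocal_best_hits(ab, ba, ThresholdConfig()) == []

    def test_planted_orthologs_recovered_and_symmetric(self, cfg):
        sim = make_proteomes(n_genes=9, n_orthologs=4, seed=2)
        ab = pairwise_homology_search(sim.proteome_a, sim.proteome_b, cfg)
        ba = pairwise_homology_search(sim.proteome_b, sim.proteome_a, cfg)
        fwd = {(p.id_a, p.id_b) for p in reciprocal_best_hits(ab, ba, cfg)}
        rev = {(p.id_b, p.id_a) for p in reciprocal_best_hits(ba, ab, cfg)}
        assert fwd == {(a, b) for a, b, _ in sim.truth.planted_orthologs}
        assert fwd == rev  # role swap preserves the unordered pair set


class TestConsensusTargeting:
    def test_asafind_plastid_gives_category_p(self, cfg):
        prof = consensus_targeting([TargetingPrediction("g", "ASAFind", "plastid")], cfg)
        assert prof.plastid and not prof.mitochondrion
        assert prof.category_code == "P"

    def test_mitofates_above_cut_makes_dual(self, cfg):
        prof = consensus_targeting(
            [
                TargetingPrediction("g", "ASAFind", "plastid"),
                TargetingPrediction("g", "MitoFates", "mitochondrion", 0.40),
            ],
            cfg,
        )
        assert prof.dual_targeted
        assert prof.category_code == "P+M"

    def test_mitofates_below_cut_is_unknown(self, cfg):
        prof = consensus_targeting(
            [TargetingPrediction("g", "MitoFates", "mitochondrion", 0.34)], cfg
        )
        assert not prof.mitochondrion
        assert prof.category_code == "U"

    def test_wolfpsort_is_fallback_only(self, cfg):
        only_wolf = consensus_targeting(
            [TargetingPrediction("g", "WolfPSort", "vacuole")], cfg, convention="plant"
        )
        assert only_wolf.category_code == "V"
        with_primary = consensus_targeting(
            [
                TargetingPrediction("g", "HECTAR", "plastid"),
                TargetingPrediction("g", "WolfPSort", "vacuole"),
            ],
            cfg,
        )
        assert with_primary.category_code == "P"


class TestSelection:
    PROT = [
        ProteinRecord("g1", "a", "MKVL", frozenset({"PF00083"})),
        ProteinRecord("g2", "a", "MKVL", frozenset({"PF00083"})),
        ProteinRecord("g3", "a", "MKVL"),
    ]
    PREDS = [
        TargetingPrediction("g1", "ASAFind", "plastid"),
        TargetingPrediction("g3", "ASAFind", "plastid"),
    ]

    def test_rule_conjunction(self, cfg):
        # g1: term+plastid -> in; g2: term only -> out; g3: plastid only -> out
        assert select_plastid_transporters(self.PROT, self.PREDS, ["PF00083"], cfg) == {"g1"}

    def test_order_invariance(self, cfg):
        fwd = select_plastid_transporters(self.PROT, self.PREDS, ["PF00083"], cfg)
        rev = select_plastid_transporters(
            self.PROT[::-1], self.PREDS[::-1], ["PF00083"], cfg
        )
        assert fwd == rev

    def test_empty_term_list_rejected(self, cfg):
        with pytest.raises(ValueError):
            select_plastid_transporters(self.PROT, self.PREDS, [], cfg)


class TestLocalizationTable:
    def test_category_multisets(self, cfg):
        profiles = {
            "h1": consensus_targeting([TargetingPrediction("h1", "ASAFind", "plastid")], cfg),
            "h2": consensus_targeting(
                [TargetingPrediction("h2", "HECTAR", "mitochondrion")], cfg
            ),
        }
        table = cross_species_localization_table(
            {"q1": ["h1"], "q2": ["h1", "h2", "h3"]}, profiles
        )
        assert dict(table["q1"]) == {"P": 1}
        assert dict(table["q2"]) == {"P": 1, "M": 1, "U": 1}

    def test_one_to_many_lists_all_subjects(self):
        hits = [hit(q="q", s="s1", bitscore=90), hit(q="q", s="s2", bitscore=50)]
        assert one_to_many_table(hits) == {"q": ["s1", "s2"]}
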