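import itertools

import numpy as np
import pytest

from plastid_atlas.core_io import ThresholdConfig
from plastid_atlas.evidence import (
    EvidenceBundle,
    EvolutionAnnotation,
    PathwayMap,
    associated_genes,
    category_profile,
    composite_score,
    pathway_links,
    same_loss,
    venn_counts,
)
from plastid_atlas.mito import condition_correlation
from plastid_atlas.synthetic import make_expression


def bundle(**kw):
    defaults = dict(transporter_id="t", gene_id="g")
    defaults.update(kw)
    return EvidenceBundle(**defaults)


class TestCompositeScore:
    def test_all_seven_conditions_give_seven(self, cfg):
        b = bundle(
            same_wgcna_module=True,
            r_rnaseq=0.9,
            r_microarray=0.9,
            r_tp_homolog_microarray=0.9,
            plastid_targeted=True,
            same_origin=True,
            same_loss_pattern=True,
        )
        assert composite_score(b, cfg) == 7

    def test_correlation_exactly_at_threshold_scores_zero(self, cfg):
        b = bundle(r_rnaseq=0.5, r_microarray=0.5, r_tp_homolog_microarray=0.5)
        assert composite_score(b, cfg) == 0  # strictly greater than 0.5 required

    def test_hand_summed_example(self, cfg):
        b = bundle(
            same_wgcna_module=True,
            r_rnaseq=0.6,
            r_microarray=0.3,
            r_tp_homolog_microarray=None,
            plastid_targeted=True,
            same_origin=True,
            same_loss_pattern=False,
        )
        assert composite_score(b, cfg) == 4

    def test_truth_table_matches_brute_force(self, cfg):
        """Exhaustive grid: all boolean combinations x r in
        {None, 0.49, 0.5, 0.51} per correlation slot."""
        r_values = (None, 0.49, 0.5, 0.51)
        for bools in itertools.product([False, True], repeat=4):
            m, p, o, l = bools
            for rs in itertools.product(r_values, repeat=3):
                b = bundle(
                    same_wgcna_module=m,
                    r_rnaseq=rs[0],
                    r_microarray=rs[1],
                    r_tp_homolog_microarray=rs[2],
                    plastid_targeted=p,
                    same_origin=o,
                    same_loss_pattern=l,
                )
                expected = sum(bools) + sum(
                    1 for r in rs if r is not None and r > 0.5
                )
                assert composite_score(b, cfg) == expected

    def test_monotone_in_each_condition(self, cfg):
        base = bundle(r_rnaseq=0.6)
        assert composite_score(bundle(r_rnaseq=0.6, plastid_targeted=True), cfg) >= (
            composite_score(base, cfg)
        )

    def test_correlation_outside_range_rejected(self):
        with pytest.raises(ValueError):
            bundle(r_rnaseq=1.5)


class TestAssociation:
    def make_bundles(self, scores_by_gene):
        out = []
        for g, s in scores_by_gene.items():
            kw = {}
            flags = [
                "same_wgcna_module",
                "plastid_targeted",
                "same_origin",
                "same_loss_pattern",
            ]
            for f in flags[:s]:
                kw[f] = True
            out.append(bundle(gene_id=g, **kw))
        return out

    def test_score_three_included_two_excluded(self, cfg):
        bundles = self.make_bundles({"g3": 3, "g2": 2})
        assert associated_genes("t", bundles, cfg) == {"g3"}

    def test_anti_monotone_in_min_score(self):
        bundles = self.make_bundles({"g1": 1, "g2": 2, "g3": 3, "g4": 4})
        sets = [
            associated_genes("t", bundles, ThresholdConfig(assoc_min_score=k))
            for k in (1, 2, 3, 4)
        ]
        for lo, hi in zip(sets[1:], sets):
            assert lo <= hi

    def test_foreign_transporter_rejected(self, cfg):
        with pytest.raises(ValueError):
            associated_genes("other", [bundle()], cfg)

    def test_zero_noise_recovery_is_exact(self, cfg):
        """With orthogonalized latents and no noise, association recovery
        from planted co-expression blocks has sensitivity = specificity = 1."""
        genes = ["t"] + [f"g{i}" for i in range(12)]
        planted = {"g0", "g1", "g2", "g3"}
        sim = make_expression(
            genes, {"blk": ["t", *sorted(planted)]}, loading=1.0, noise_sd=0.0, seed=11
        )
        bundles = []
        for g in genes[1:]:
            r = condition_correlation(sim.matrix.row("t"), sim.matrix.row(g))
            bundles.append(
                bundle(
                    gene_id=g,
                    same_wgcna_module=sim.modules[g] == sim.modules["t"],
                    r_rnaseq=r,
                    r_microarray=r,
                )
            )
        assert associated_genes("t", bundles, cfg) == planted

    def test_noisy_recovery_sensitivity(self, cfg):
        """Planted pairwise r = 0.8 at 17 condition groups: sensitivity of
        the three-condition association call stays above 0.9 over 200 seeds."""
        recovered = total = 0
        planted = [f"g{i}" for i in range(4)]
        genes = ["t", *planted]
        for seed in range(200):
            sim = make_expression(
                genes, {"blk": genes}, loading=np.sqrt(0.8), seed=seed
            )
            for g in planted:
                r = condition_correlation(sim.matrix.row("t"), sim.matrix.row(g))
                b = bundle(
                    gene_id=g,
                    same_wgcna_module=True,
                    plastid_targeted=True,
                    r_rnaseq=r,
                )
                total += 1
                recovered += composite_score(b, cfg) >= cfg.assoc_min_score
        assert recovered / total >= 0.9


class TestPathways:
    PMAP = PathwayMap(
        gene_pathways={
            "g1": {"pwA"},
            "g2": {"pwA"},
            "g3": {"pwA"},
            "g4": {"pwA"},
            "g5": {"pwB"},
            "g6": {"pwB"},
            "g7": {"pwB"},
        },
        pathway_category={"pwA": "carbon-related", "pwB": "photosynthesis-related"},
    )

    def test_four_genes_link_pathway(self, cfg):
        assert pathway_links("t", {"g1", "g2", "g3", "g4"}, self.PMAP, cfg) == {"pwA"}

    def test_three_genes_do_not_link(self, cfg):
        assert pathway_links("t", {"g5", "g6", "g7"}, self.PMAP, cfg) == set()

    def test_empty_associated_set(self, cfg):
        assert pathway_links("t", set(), self.PMAP, cfg) == set()

    def test_category_profile_singleton_and_error(self):
        assert category_profile("t", {"pwA"}, self.PMAP) == {"carbon-related"}
        with pytest.raises(ValueError):
            category_profile("t", {"pwZ"}, self.PMAP)


class TestVenn:
    def test_counts_match_hand_enumeration(self):
        profiles = {
            "t1": frozenset({"carbon-related"}),
            "t2": frozenset({"carbon-related"}),
            "t3": frozenset({"carbon-related", "photosynthesis-related"}),
            "t4": frozenset(),
        }
        counts = venn_counts(profiles)
        assert counts == {
            frozenset({"carbon-related"}): 2,
            frozenset({"carbon-related", "photosynthesis-related"}): 1,
        }
        assert sum(counts.values()) == 3  # transporters with >= 1 category


class TestTpHomologCorrelation:
    def test_mapped_homolog_pair_correlated(self, cfg):
        from plastid_atlas.evidence import tp_homolog_correlation

        sim = make_expression(
            ["Tp_t", "Tp_g"], {"blk": ["Tp_t", "Tp_g"]}, loading=1.0, noise_sd=0.0, seed=1
        )
        rbh = {"t": "Tp_t", "g": "Tp_g"}
        r = tp_homolog_correlation("t", "g", rbh, sim.matrix)
        assert r == pytest.approx(1.0)
        assert composite_score(bundle(r_tp_homolog_microarray=r), cfg) == 1

    def test_unmapped_transporter_scores_zero(self, cfg):
        from plastid_atlas.evidence import tp_homolog_correlation

        sim = make_expression(["Tp_g"], {}, seed=1)
        assert tp_homolog_correlation("t", "g", {"g": "Tp_g"}, sim.matrix) is None


class TestLossMatching:
    A = EvolutionAnnotation("a", "anc", frozenset({"c1", "c2"}))
    B = EvolutionAnnotation("b", "anc", frozenset({"c1"}))

    def test_equality_mode(self):
        cfg = ThresholdConfig(loss_match_mode="equal")
        assert not same_loss(self.A, self.B, cfg)
        assert same_loss(self.A, self.A, cfg)

    def test_subset_mode(self):
        cfg = ThresholdConfig(loss_match_mode="subset")
        assert same_loss(self.A, self.B, cfg)
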