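import numpy as np
import pytest
from scipy.special import betainc

from plastid_atlas.core_io import ProteinRecord, ThresholdConfig
from plastid_atlas.envcorr import (
    AbundanceRecord,
    EnvCorrelation,
    ReferenceSeq,
    aggregate_combos,
    clade_extract,
    correlation_pvalue,
    filter_meta_homologues,
    primary_production_flag,
    signed_significance,
    station_sums,
)
from plastid_atlas.synthetic import make_environment, make_meta_pool, stream_rng

COMBO = ("SRF", "<0.8")


def exact_r_vectors(r: float, n: int, seed: int = 0):
    """Construct (x, y) whose sample Pearson correlation is exactly r."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    xs = (x - x.mean()) / x.std()
    # orthogonalize z against xs, then standardize
    z = z - z.mean()
    z -= (z @ xs) / (xs @ xs) * xs
    zs = z / z.std()
    y = r * xs + np.sqrt(1 - r * r) * zs
    return xs, y


class TestFilter:
    def test_planted_pool_truth_recovered(self, cfg):
        pool = make_meta_pool(seed=2, mutation_rate=0.0)
        retained = filter_meta_homologues(
            pool.meta, pool.references, pool.query_proteome, pool.query.gene_id, cfg
        )
        assert retained == set(pool.truth.planted_in_clade)

    def test_outgroup_derived_pool_empty(self, cfg):
        pool = make_meta_pool(seed=2, n_in_clade=0, n_out_clade=4)
        retained = filter_meta_homologues(
            pool.meta, pool.references, pool.query_proteome, pool.query.gene_id, cfg
        )
        assert retained == set()

    def test_empty_reference_set_rejected(self, cfg):
        with pytest.raises(ValueError):
            filter_meta_homologues([], [], [], "q", cfg)


class TestCladeExtract:
    def test_meta_near_diatom_reference_retained(self):
        pool = make_meta_pool(seed=5, n_in_clade=2, n_out_clade=2)
        retained = clade_extract(pool.meta, pool.references, pool.query.sequence)
        assert retained == set(pool.truth.planted_in_clade)

    def test_planted_membership_over_seeds(self):
        hits = 0
        for seed in range(10):
            pool = make_meta_pool(seed=seed, n_in_clade=4, n_out_clade=4)
            retained = clade_extract(pool.meta, pool.references, pool.query.sequence)
            hits += retained == set(pool.truth.planted_in_clade)
        assert hits == 10

    def test_never_adds_meta_genes(self, cfg):
        pool = make_meta_pool(seed=9)
        filtered = filter_meta_homologues(
            pool.meta, pool.references, pool.query_proteome, pool.query.gene_id, cfg
        )
        retained = clade_extract(
            [m for m in pool.meta if m.gene_id in filtered],
            pool.references,
            pool.query.sequence,
        )
        assert retained <= filtered

    def test_too_few_sequences_returns_input_set(self):
        pool = make_meta_pool(seed=1, n_in_clade=1, n_out_clade=0, n_diatom_refs=1,
                              n_outgroup_refs=1)
        retained = clade_extract(pool.meta, pool.references, pool.query.sequence)
        assert retained == {m.gene_id for m in pool.meta}


class TestStationSums:
    def rec(self, mg, station, t, g=None):
        return AbundanceRecord("f", mg, station, *COMBO, t, g)

    def test_single_record(self):
        sums = station_sums([self.rec("m1", "s1", 0.4, 0.2)], "f", COMBO)
        assert sums == {"s1": (0.4, 0.2)}

    def test_two_meta_genes_summed(self):
        recs = [self.rec("m1", "s1", 0.2, 0.1), self.rec("m2", "s1", 0.3, None)]
        assert station_sums(recs, "f", COMBO) == {"s1": (0.5, 0.1)}

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(3)
        recs = []
        for station in ("s1", "s2", "s3"):
            for mg in ("m1", "m2", "m3"):
                recs.append(self.rec(mg, station, float(rng.random()), float(rng.random())))
        sums = station_sums(recs, "f", COMBO)
        for station in ("s1", "s2", "s3"):
            brute_t = sum(r.metaT for r in recs if r.station_id == station)
            brute_g = sum(r.metaG for r in recs if r.station_id == station)
            assert sums[station][0] == pytest.approx(brute_t)
            assert sums[station][1] == pytest.approx(brute_g)

    def test_other_combo_omitted_not_zero(self):
        recs = [self.rec("m1", "s1", 0.4, 0.2)]
        assert station_sums(recs, "f", ("DCM", "<0.8")) == {}


class TestSignedSignificance:
    def run(self, sum_T, sum_G, env, **cfg_kw):
        cfg = ThresholdConfig(**cfg_kw)
        return signed_significance(sum_T, sum_G, env, cfg, "f", "p", COMBO)

    def test_proportional_abundance_significant_positive(self):
        stations = [f"s{i}" for i in range(10)]
        env = {s: float(i) for i, s in enumerate(stations)}
        sum_T = {s: 2.0 * env[s] + 1 for s in stations}
        rng = np.random.default_rng(0)
        sum_G = {s: float(rng.random()) for s in stations}
        res = self.run(sum_T, sum_G, env)
        assert res.significant and res.sign == +1
        assert res.r_T == pytest.approx(1.0)

    def test_pvalue_matches_closed_form_t(self):
        # n=20, r=0.7: t = 0.7 sqrt(18/0.51) = 4.1595, p ~ 5.6e-4
        x, y = exact_r_vectors(0.7, 20)
        stations = [f"s{i}" for i in range(20)]
        res = self.run(
            dict(zip(stations, y - y.min() + 0.1)),
            {s: None for s in stations},
            dict(zip(stations, x)),
        )
        t = 0.7 * np.sqrt(18 / (1 - 0.49))
        expected = float(betainc(9.0, 0.5, 18 / (18 + t * t)))
        assert res.p == pytest.approx(expected, rel=1e-10)
        assert res.significant

    def test_constant_abundance_undefined_not_significant(self):
        stations = [f"s{i}" for i in range(5)]
        res = self.run(
            {s: 1.0 for s in stations},
            {s: None for s in stations},
            {s: float(i) for i, s in enumerate(stations)},
        )
        assert res.r_T is None and not res.significant

    def test_fewer_than_three_stations_not_significant(self):
        res = self.run({"s1": 1.0, "s2": 2.0}, {}, {"s1": 0.0, "s2": 1.0})
        assert not res.significant and res.p is None

    def test_stronger_metaG_flips_sign_negative(self):
        stations = [f"s{i}" for i in range(12)]
        env = {s: float(i) for i, s in enumerate(stations)}
        rng = np.random.default_rng(1)
        sum_T = {s: env[s] + rng.normal(scale=6.0) + 50 for s in stations}
        sum_G = {s: 2 * env[s] + 1 for s in stations}  # perfect MetaG tracking
        res = self.run(sum_T, sum_G, env)
        assert res.sign == -1

    def test_no_metaG_takes_sign_of_r_T(self):
        stations = [f"s{i}" for i in range(10)]
        env = {s: float(i) for i, s in enumerate(stations)}
        sum_T = {s: -3.0 * env[s] + 100 for s in stations}
        res = self.run(sum_T, {s: None for s in stations}, env)
        assert res.sign == -1 and res.r_T == pytest.approx(-1.0)


class TestAggregation:
    def cell(self, signs_sig, cfg):
        results = [
            EnvCorrelation("f", "p", combo, 0.5, 0.1, 30, 0.01 if sig else 0.5, sign, sig)
            for combo, (sign, sig) in zip(cfg.combos, signs_sig)
        ]
        return aggregate_combos("f", "p", results, cfg)

    def test_all_ten_positive(self, cfg):
        cell = self.cell([(+1, True)] * 10, cfg)
        assert cell.signed_score == 10 and cell.strong_positive

    def test_four_pos_one_neg(self, cfg):
        signs = [(+1, True)] * 4 + [(-1, True)] + [(+1, False)] * 5
        cell = self.cell(signs, cfg)
        assert cell.signed_score == 3
        assert cell.strong_positive and not cell.strong_negative

    def test_none_significant(self, cfg):
        cell = self.cell([(+1, False)] * 10, cfg)
        assert cell.signed_score == 0
        assert not cell.strong_positive and not cell.strong_negative

    def test_duplicate_combo_rejected(self, cfg):
        res = EnvCorrelation("f", "p", COMBO, 0.5, 0.1, 30, 0.01, 1, True)
        with pytest.raises(ValueError):
            aggregate_combos("f", "p", [res, res], cfg)


class TestPrimaryProductionFlag:
    def cells(self, n_pos, n_neg, cfg):
        from plastid_atlas.core_io import DEFAULT_PRIMARY_PRODUCTION_PARAMS as P

        out = {}
        for i, p in enumerate(P):
            pos = i < n_pos
            neg = n_pos <= i < n_pos + n_neg
            out[p] = aggregate_combos(
                "f",
                p,
                [
                    EnvCorrelation(
                        "f", p, combo, 0.5, 0.1, 30, 0.01, +1 if pos else -1, pos or neg
                    )
                    for combo in cfg.combos
                ],
                cfg,
            )
        return out

    def test_nine_of_ten_flags_positive(self, cfg):
        assert primary_production_flag("f", self.cells(9, 0, cfg), cfg) == (True, +1)

    def test_seven_of_ten_not_flagged(self, cfg):
        assert primary_production_flag("f", self.cells(7, 0, cfg), cfg) == (False, 0)

    def test_split_directions_not_flagged_by_default(self, cfg):
        assert primary_production_flag("f", self.cells(5, 3, cfg), cfg) == (False, 0)

    def test_split_directions_flagged_when_toggled(self):
        cfg = ThresholdConfig(pp_same_direction=False)
        assert primary_production_flag("f", self.cells(5, 3, cfg), cfg) == (True, +1)

    def test_empty_merged_list_rejected(self, cfg):
        with pytest.raises(ValueError):
            primary_production_flag("f", {}, cfg, merged_params=[])


class TestEnvironmentGenerator:
    def test_signed_score_antisymmetric_under_parameter_negation(self, cfg):
        """For a family without MetaG the signed aggregate flips sign and
        keeps magnitude when the environmental parameter is negated."""
        sim = make_environment(
            ["f"],
            planted_effects=[("f", "Temperature", +1, 0.8)],
            n_stations=40,
            family_without_metaG="f",
            seed=6,
        )
        from plastid_atlas.envcorr import env_values_for_combo

        def aggregate(flip):
            results = []
            for combo in cfg.combos:
                sums = station_sums(sim.records, "f", combo)
                env = env_values_for_combo(sim.stations, "Temperature", combo)
                if flip:
                    env = {k: -v for k, v in env.items()}
                results.append(
                    signed_significance(
                        {s: t for s, (t, g) in sums.items()},
                        {s: g for s, (t, g) in sums.items()},
                        env,
                        cfg,
                        "f",
                        "Temperature",
                        combo,
                    )
                )
            return aggregate_combos("f", "Temperature", results, cfg)

        plus, minus = aggregate(False), aggregate(True)
        assert plus.signed_score == -minus.signed_score
        assert abs(plus.signed_score) == abs(minus.signed_score)

    def test_invalid_effect_rejected(self):
        with pytest.raises(ValueError):
            make_environment(["f"], planted_effects=[("f", "Temperature", +1, 1.0)])
        with pytest.raises(ValueError):
            make_environment(["f"], planted_effects=[("f", "nope", +1, 0.5)])


def test_correlation_pvalue_closed_form_grid():
    """p from t = r sqrt((n-2)/(1-r^2)) matches the incomplete-beta closed
    form of the t distribution across an (n, r) grid."""
    for n in (10, 20, 50):
        for r in (0.1, 0.3, 0.5, 0.7, 0.9):
            t = r * np.sqrt((n - 2) / (1 - r * r))
            df = n - 2
            expected = float(betainc(df / 2.0, 0.5, df / (df + t * t)))
            assert correlation_pvalue(r, n) == pytest.approx(expected, rel=1e-10)
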