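"""HCT designation, knockout gene sets, and the intersection screen."""

import numpy as np
import pandas as pd
import pytest

from consensome import (
    HCTEntry,
    HCTLibrary,
    IntersectionScreen,
    KOGeneSets,
    benchmark_confidence_set,
    derive_ko_gene_sets,
    designate_hcts,
    hypergeom_overlap,
    intersection_screen,
    node_set_enrichment,
)
from consensome.errors import InputError

from conftest import make_contrast


def ranked_consensome(n):
    return pd.DataFrame(
        {"gene_id": [f"g{i:05d}" for i in range(1, n + 1)], "rank": range(1, n + 1)}
    )


class TestDesignateHCTs:
    def test_top_five_of_hundred(self):
        hct = designate_hcts(ranked_consensome(100), pct=95)
        assert hct == {f"g{i:05d}" for i in range(1, 6)}

    def test_pct_zero_returns_all(self):
        assert len(designate_hcts(ranked_consensome(40), pct=0)) == 40

    def test_ceiling_rule_at_study_scale(self):
        # ceil(5% of 12525) = 627
        assert len(designate_hcts(ranked_consensome(12525), pct=95)) == 627

    def test_invalid_pct(self):
        with pytest.raises(InputError):
            designate_hcts(ranked_consensome(10), pct=100)


class TestDeriveKOGeneSets:
    def test_fold_change_cut_is_linear_scale(self):
        # log2 FC 0.35 is below log2(1.5) ~ 0.585: excluded despite p
        ko = make_contrast(
            "ko", ["Cebpa", "Irf5", "gC"], [0.35, -2.6, 2.0], [0.01, 1e-6, 0.2]
        )
        sets = derive_ko_gene_sets(ko)
        assert "Cebpa" not in sets.up | sets.down
        assert "Irf5" in sets.down
        assert "gC" not in sets.up  # fails the p cut

    def test_volcano_style_thresholds_selectable(self):
        ko = make_contrast("ko", ["gA", "gB"], [0.35, -0.4], [0.005, 0.5])
        sets = derive_ko_gene_sets(ko, fc_min=1.2, p_max=0.01)
        assert sets.up == {"gA"} and sets.down == frozenset()

    def test_empty_table(self):
        ko = make_contrast("ko", [], [], [])
        sets = derive_ko_gene_sets(ko)
        assert sets.up == frozenset() and sets.down == frozenset()

    def test_fc_min_must_exceed_one(self):
        ko = make_contrast("ko", ["gA"], [1.0], [0.01])
        with pytest.raises(InputError):
            derive_ko_gene_sets(ko, fc_min=1.0)


def library_of(sets, modality="transcriptomic"):
    lib = HCTLibrary()
    for i, genes in enumerate(sets):
        lib.add(
            HCTEntry(
                node_id=f"node{i:03d}",
                node_family=f"fam{i:03d}",
                modality=modality,
                hct_genes=frozenset(genes),
            )
        )
    return lib


class TestIntersectionScreen:
    def test_identical_hct_and_ko_set_is_top_hit(self):
        uni = [f"g{i:04d}" for i in range(500)]
        down = frozenset(uni[:30])
        lib = library_of([down, uni[100:130]])
        ko = KOGeneSets(up=frozenset(), down=down)
        table = intersection_screen(lib, ko, uni)
        hit = table.loc[
            (table["node_id"] == "node000") & (table["direction"] == "down")
        ].iloc[0]
        oracle = hypergeom_overlap(down, down, uni)
        assert hit["k"] == 30
        assert hit["pvalue"] == pytest.approx(oracle.pvalue, rel=1e-12)
        assert table.loc[table["direction"] == "down", "qvalue"].min() == hit["qvalue"]

    def test_bh_family_per_modality_and_direction(self):
        rng = np.random.default_rng(9)
        uni = [f"g{i:04d}" for i in range(400)]
        lib = HCTLibrary()
        for i in range(10):
            lib.add(
                HCTEntry(
                    f"t{i}", "fam", "transcriptomic",
                    frozenset(rng.choice(uni, 40, replace=False)),
                )
            )
            lib.add(
                HCTEntry(
                    f"c{i}", "fam", "chipseq",
                    frozenset(rng.choice(uni, 40, replace=False)),
                )
            )
        ko = KOGeneSets(
            up=frozenset(rng.choice(uni, 50, replace=False)), down=frozenset()
        )
        table = intersection_screen(lib, ko, uni)
        from _oracles import bh_stepup_reference

        for (_, _), grp in table.groupby(["modality", "direction"]):
            assert np.allclose(
                grp["qvalue"], bh_stepup_reference(grp["pvalue"].to_numpy()),
                rtol=1e-12,
            )

    def test_null_library_calibration(self):
        rng = np.random.default_rng(23)
        uni = [f"g{i:05d}" for i in range(2000)]
        lib = library_of(
            [rng.choice(uni, 100, replace=False) for _ in range(100)]
        )
        ko = KOGeneSets(
            up=frozenset(rng.choice(uni, 200, replace=False)), down=frozenset()
        )
        table = intersection_screen(lib, ko, uni)
        up = table.loc[table["direction"] == "up"]
        # conservative discrete test: nominal rate near or below 5%
        assert (up["pvalue"] < 0.05).mean() < 0.05 + 3 * np.sqrt(0.05 * 0.95 / 100)
        assert (up["qvalue"] < 0.05).sum() == 0

    def test_empty_inputs_rejected(self):
        with pytest.raises(InputError):
            intersection_screen(HCTLibrary(), KOGeneSets(frozenset(), frozenset()), ["g1"])
        lib = library_of([["g1"]])
        with pytest.raises(InputError):
            intersection_screen(lib, KOGeneSets(frozenset(), frozenset()), [])


class TestNodeSetEnrichment:
    def test_small_universe_spot_value(self):
        uni = [f"n{i}" for i in range(10)]
        hits = set(uni[:5])
        annotated = set(uni[1:5])
        res = node_set_enrichment(hits, annotated, uni)
        assert res.k == 4
        assert res.pvalue == pytest.approx(6 / 252, rel=1e-12)

    def test_annotation_covering_universe_is_degenerate(self):
        uni = [f"n{i}" for i in range(20)]
        res = node_set_enrichment(set(uni[:5]), set(uni), uni)
        assert res.pvalue == 1.0
        assert res.degenerate


class TestBenchmarkConfidenceSet:
    def test_self_benchmark_is_maximal(self):
        uni = [f"g{i}" for i in range(100)]
        s = frozenset(uni[:20])
        res = benchmark_confidence_set(s, s, uni)
        assert res.k == 20

    def test_disjoint_sets_pvalue_one(self):
        uni = [f"g{i}" for i in range(100)]
        res = benchmark_confidence_set(frozenset(uni[:10]), frozenset(uni[50:60]), uni)
        assert res.k == 0 and res.pvalue == 1.0


class TestScreenModel:
    def test_fit_summary_and_enrich(self, small_study, small_universe):
        from consensome import simulate_hct_library, simulate_ko_table

        cfg, compendium, truth = small_study
        ko = simulate_ko_table(small_universe, truth, cfg)
        ko_sets = derive_ko_gene_sets(ko)
        lib = simulate_hct_library(
            small_universe, truth, n_nodes=40, hct_size=40,
            active_overlap_frac=0.6, n_active=6, seed=cfg.seed,
        )
        res = IntersectionScreen(
            lib, ko_sets, ko_universe=frozenset(small_universe)
        ).fit()
        assert set(res.table["direction"]) == {"up", "down"}
        assert "HCT intersection screen" in res.summary()
        # every planted active node footprints in one of the two directions
        sig = res.significant_nodes("up") | res.significant_nodes("down")
        assert truth.active_nodes <= sig
        # annotation enrichment runs end to end at the node level
        r = res.enrich(truth.active_nodes, direction="down")
        assert r.universe_size == 40
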