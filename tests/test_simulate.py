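"""The synthetic-data generator: determinism, null calibration, planted
structure."""

import numpy as np
import pytest
from scipy import stats as sps

from consensome import (
    SimConfig,
    SimTruth,
    derive_ko_gene_sets,
    gene_universe,
    simulate_annotations,
    simulate_compendium,
    simulate_hct_library,
    simulate_ko_table,
    simulate_peak_table,
)
from consensome.errors import ConfigurationError, InputError


class TestSimConfig:
    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"n_genes": 5}, "n_genes"),
            ({"n_contrasts": 0}, "n_contrasts"),
            ({"frac_true": 1.2}, "frac_true"),
            ({"detect_prob": -0.1}, "detect_prob"),
            ({"assay_rate": 0.0}, "assay_rate"),
            ({"null_sd": -1.0}, "null_sd"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(ConfigurationError, match=field):
            SimConfig(**kwargs)


class TestSimulateCompendium:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_genes=200, seed=42)
        comp1, truth1 = simulate_compendium(cfg)
        comp2, truth2 = simulate_compendium(cfg)
        assert truth1.planted_up == truth2.planted_up
        for a, b in zip(comp1, comp2):
            assert a.data.equals(b.data)

    def test_no_planted_signal_when_frac_true_zero(self):
        cfg = SimConfig(n_genes=200, frac_true=0.0, seed=1)
        _, truth = simulate_compendium(cfg)
        assert truth.planted_up == frozenset()
        assert truth.planted_down == frozenset()

    def test_null_significant_fraction_calibrated(self):
        # ~5e4 fully-assayed cells: p<0.05 rate within 3 binomial SEs
        cfg = SimConfig(
            n_genes=10_000, n_contrasts=5, frac_true=0.0, assay_rate=1.0, seed=7
        )
        comp, _ = simulate_compendium(cfg)
        pvals = np.concatenate([ct.data["pvalue"].to_numpy() for ct in comp])
        frac = (pvals < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / pvals.size)
        assert abs(frac - 0.05) < 3 * se

    def test_planted_detection_rate(self):
        # detect_prob=0.9, E=5: mean significant count over planted genes
        # ~ 5*0.9 plus ~0.5*0.05 expected null extras
        cfg = SimConfig(
            n_genes=2000, n_contrasts=5, frac_true=0.25, detect_prob=0.9,
            assay_rate=1.0, seed=13,
        )
        comp, truth = simulate_compendium(cfg)
        planted = sorted(truth.planted_up | truth.planted_down)
        sig = np.zeros(len(planted))
        for ct in comp:
            d = ct.data.set_index("gene_id").loc[planted]
            sig += (d["pvalue"] < 0.05).to_numpy()
        expected = 5 * 0.9 + 5 * 0.1 * 0.05
        assert sig.mean() == pytest.approx(expected, abs=0.1)

    def test_planted_separation(self):
        # P[Bin(5, 0.8) >= 2] > 0.993: almost all planted genes have k >= 2
        assert float(sps.binom.sf(1, 5, 0.8)) > 0.993
        cfg = SimConfig(
            n_genes=4000, n_contrasts=5, frac_true=0.25, detect_prob=0.8,
            assay_rate=1.0, seed=19,
        )
        comp, truth = simulate_compendium(cfg)
        planted = sorted(truth.planted_up | truth.planted_down)
        sig = np.zeros(len(planted))
        for ct in comp:
            d = ct.data.set_index("gene_id").loc[planted]
            sig += (d["pvalue"] < 0.05).to_numpy()
        assert (sig >= 2).mean() >= 0.99

    def test_assay_rate_masks_cells(self):
        cfg = SimConfig(n_genes=1000, n_contrasts=4, assay_rate=0.7, seed=3)
        comp, _ = simulate_compendium(cfg)
        rate = np.mean([ct.data["assayed"].mean() for ct in comp])
        assert rate == pytest.approx(0.7, abs=0.03)
        first = comp[0].data
        assert first.loc[~first["assayed"], "pvalue"].isna().all()


class TestSimulateKOTable:
    def test_null_filter_size_matches_closed_form(self):
        cfg = SimConfig(n_genes=20_000, frac_true=0.0, null_sd=0.5, seed=5)
        uni = gene_universe(cfg.n_genes)
        _, truth = simulate_compendium(cfg)
        ko = simulate_ko_table(uni, truth, cfg)
        sets = derive_ko_gene_sets(ko, fc_min=1.5, p_max=0.05)
        # P(|N(0, 0.5)| > log2 1.5) * 0.05 per direction
        p_lfc = 2 * sps.norm.sf(np.log2(1.5), scale=0.5)
        expected = cfg.n_genes * p_lfc * 0.05
        got = len(sets.up) + len(sets.down)
        assert got == pytest.approx(expected, abs=4 * np.sqrt(expected))

    def test_planted_gene_lands_in_up_set(self):
        cfg = SimConfig(n_genes=100, frac_true=0.0, effect_mu=3.0, seed=2)
        uni = gene_universe(cfg.n_genes)
        truth = SimTruth(planted_up=frozenset({uni[0]}))
        ko = simulate_ko_table(uni, truth, cfg)
        sets = derive_ko_gene_sets(ko)
        assert uni[0] in sets.up

    def test_determinism_and_universe_check(self):
        cfg = SimConfig(n_genes=300, seed=8)
        uni = gene_universe(cfg.n_genes)
        _, truth = simulate_compendium(cfg)
        assert simulate_ko_table(uni, truth, cfg).data.equals(
            simulate_ko_table(uni, truth, cfg).data
        )
        with pytest.raises(InputError):
            simulate_ko_table(uni, SimTruth(planted_up=frozenset({"gX"})), cfg)


class TestSimulateHCTLibrary:
    def test_full_overlap_node_subsets_planted(self):
        cfg = SimConfig(n_genes=500, frac_true=0.2, seed=21)
        uni = gene_universe(cfg.n_genes)
        _, truth = simulate_compendium(cfg)
        lib = simulate_hct_library(
            uni, truth, n_nodes=4, hct_size=len(truth.planted_up),
            active_overlap_frac=1.0, n_active=1, seed=21,
        )
        (active,) = truth.active_nodes
        assert lib[active].hct_genes <= truth.planted_up

    def test_inactive_nodes_have_no_planted_bias(self):
        cfg = SimConfig(n_genes=2000, frac_true=0.1, seed=31)
        uni = gene_universe(cfg.n_genes)
        _, truth = simulate_compendium(cfg)
        lib = simulate_hct_library(
            uni, truth, n_nodes=50, hct_size=100, active_overlap_frac=0.0,
            n_active=5, seed=31,
        )
        planted = truth.planted_up | truth.planted_down
        fracs = [len(e.hct_genes & planted) / 100 for e in lib]
        # with zero planted overlap, every node's fraction is ~ |planted|/G
        assert np.mean(fracs) == pytest.approx(len(planted) / 2000, abs=0.02)

    def test_node_metadata_and_errors(self):
        cfg = SimConfig(n_genes=100, seed=1)
        uni = gene_universe(cfg.n_genes)
        _, truth = simulate_compendium(cfg)
        lib = simulate_hct_library(uni, truth, n_nodes=10, hct_size=5, seed=1)
        assert len(lib) == 10
        assert {e.modality for e in lib} == {"transcriptomic", "chipseq"}
        with pytest.raises(InputError):
            simulate_hct_library(uni, truth, n_nodes=5, hct_size=101, seed=1)


class TestSimulateAnnotations:
    def test_enriched_term_draws_from_active_nodes(self):
        truth = SimTruth(active_nodes=frozenset(f"n{i}" for i in range(20)))
        nodes = [f"n{i}" for i in range(100)]
        amap = simulate_annotations(
            nodes, truth, n_terms=5, term_size=10, enrich_frac=1.0,
            n_enriched=1, seed=3,
        )
        (term_id,) = truth.enriched_terms
        assert amap[term_id].members <= truth.active_nodes

    def test_term_equal_to_active_nodes_is_maximal_overlap(self):
        active = frozenset(f"n{i}" for i in range(16))
        truth = SimTruth(active_nodes=active)
        nodes = [f"n{i}" for i in range(691)]
        amap = simulate_annotations(
            nodes, truth, n_terms=1, term_size=16, enrich_frac=1.0,
            n_enriched=1, seed=4,
        )
        assert amap["term0001"].members == active

    def test_term_size_error(self):
        with pytest.raises(InputError):
            simulate_annotations(["n1"], SimTruth(), n_terms=1, term_size=2, seed=1)


class TestSimulatePeakTable:
    def test_determinism_and_shape(self):
        uni = gene_universe(500)
        a = simulate_peak_table(uni, n_peaks=100, seed=9)
        b = simulate_peak_table(uni, n_peaks=100, seed=9)
        assert a.equals(b)
        assert len(a) == 100
        assert set(a["gene_id"]) <= set(uni)

    def test_planted_bias_raises_planted_rank(self):
        cfg = SimConfig(n_genes=1000, frac_true=0.1, seed=6)
        uni = gene_universe(cfg.n_genes)
        _, truth = simulate_compendium(cfg)
        peaks = simulate_peak_table(
            uni, truth, n_peaks=400, planted_frac=0.5,
            planted_strength_boost=4.0, seed=6,
        )
        planted = truth.planted_up | truth.planted_down
        frac_planted = peaks["gene_id"].isin(sorted(planted)).mean()
        assert frac_planted > 0.3
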