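{
  "config": {
    "alpha": 0.05,
    "benchmark_q_cut": 1e-20,
    "fc_min": 1.5,
    "hct_pct": 95,
    "lfc_min": 1.0,
    "lz_pct": 50,
    "p0": 0.05,
    "p_max": 0.05,
    "q_max": 0.05,
    "screen_q_sig": 0.05,
    "seed": 7,
    "simulate": {
      "active_overlap_frac": 0.5,
      "assay_rate": 0.9,
      "detect_prob": 0.9,
      "effect_mu": 2.0,
      "effect_sd": 0.5,
      "enrich_frac": 0.8,
      "frac_chipseq": 0.3,
      "frac_true": 0.05,
      "hct_size": 40,
      "n_active": 6,
      "n_contrasts": 5,
      "n_enriched": 2,
      "n_genes": 400,
      "n_nodes": 40,
      "n_peaks": 200,
      "n_terms": 20,
      "null_sd": 0.5,
      "planted_frac": 0.3,
      "planted_strength_boost": 2.0,
      "seed": 7,
      "term_size": 8
    }
  },
  "kind": "run_summary",
  "schema_version": 1,
  "stages": {
    "annotation_enrichment": {
      "n_p01": 4,
      "n_terms": 20
    },
    "chipseq_integration": {
      "fc_correlation": {
        "adj_r2": 0.9148321829197837,
        "n": 15,
        "pvalue": 1.5475646575027608e-08,
        "r": 0.9596434746433248,
        "r2": 0.9209155984255135
      },
      "induced": {
        "degenerate": false,
        "k": 8,
        "odds_ratio": 1556.0,
        "pvalue": 2.6614233192276905e-14,
        "size_a": 10,
        "size_b": 9,
        "universe": 400
      },
      "n_lz": 67,
      "n_mapped_genes": 133,
      "n_peaks": 200,
      "repressed": {
        "degenerate": false,
        "k": 7,
        "odds_ratio": 1365.0,
        "pvalue": 9.298006707743758e-13,
        "size_a": 8,
        "size_b": 9,
        "universe": 400
      }
    },
    "consensome": {
      "n_genes": 400,
      "n_induced_ct": 9,
      "n_repressed_ct": 9
    },
    "intersection_screen": {
      "n_nodes": 40,
      "n_q_sig": 6,
      "n_records": 80
    },
    "ko_gene_sets": {
      "n_down": 15,
      "n_up": 14
    }
  }
}
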