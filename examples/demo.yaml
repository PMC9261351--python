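# Packaged demo: a small fully-synthetic study with planted structure.
# All inputs are generated under <outdir>/inputs; the run is deterministic
# for a fixed seed.
seed: 7
outdir: demo_run
figures: false

simulate:
  n_genes: 400
  n_contrasts: 5
  frac_true: 0.05
  detect_prob: 0.9
  effect_mu: 2.0
  effect_sd: 0.5
  null_sd: 0.5
  assay_rate: 0.9
  seed: 7
  # library / annotation / peak geometry
  n_nodes: 40
  hct_size: 40
  active_overlap_frac: 0.5
  n_active: 6
  frac_chipseq: 0.3
  n_terms: 20
  term_size: 8
  enrich_frac: 0.8
  n_enriched: 2
  n_peaks: 200
  planted_frac: 0.3
  planted_strength_boost: 2.0

alpha: 0.05
p0: 0.05
q_max: 0.05
lfc_min: 1.0
fc_min: 1.5
p_max: 0.05
hct_pct: 95
lz_pct: 50
screen_q_sig: 0.05
benchmark_q_cut: 1.0e-20
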