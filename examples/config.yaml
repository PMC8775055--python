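# Six-scenario run on a simulated population
out_dir: results_run
base_seed: 1
sim:
  n_founders: 120
  n_generations: 3
  offspring_per_mating: 2
  n_markers_per_chr: 150
  n_chr: 3
  adjacent_r2_target: 0.6
  genotyped_fraction: 0.5
  call_rate: 0.99
trait:
  n_qtl: 300
  h2: 0.38
  category_probs: [0.719, 0.222, 0.051, 0.008]
  cg_count: 25
  cg_var_fraction: 0.10
varcomps: {sigma2_w: 0.10, sigma2_g: 0.38, sigma2_e: 0.52}
gibbs: {n_iter: 10000, burn_in: 1000, thin: 10, seed: 1}
hinv: {tau: 1.0, omega: 1.0, alpha: 0.90, beta: 0.10}
ld_thresholds: [0.15, 0.50, 0.80]
include_ncsnp: [false, true]
n_weight_iters: 3
top_level: 1.0e-5
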