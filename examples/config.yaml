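# Full-size synthetic study configuration (61 pairs, 6 runs).
# Any field omitted falls back to the documented default.
seed: 0
out_dir: yokedbml_full_run

motion:
  n_runs: 6
  total_collisions: 25
  near_misses_per_run_mean: 7.0
  seed: 0

truth:
  n_pairs: 61
  stressor_amp: 0.30          # % signal, controllable group
  effect_map:                 # uncontrollable - controllable amplitude
    L_BST: 0.08
    R_BST: 0.08
    L_dorsal_ant_insula: 0.08
  ar1: 0.3
  noise_sd: 0.8
  scr_coupling: {CTL: 0.2, UNCTL: 0.6}
  seed: 0

mcmc:
  chains: 4
  draws: 1000
  warmup: 1000

voxel:
  n_voxels: 200
  k_subrois: 5
  voxel_alpha: 0.001
  min_extent: 13
  connectivity: 6
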