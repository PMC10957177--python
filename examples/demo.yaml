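# Demonstration cohort emulating the study design: four groups
# (home cage, ISO, saline, KET; n = 6/6/8/6) over a 53-region panel,
# with a broad cortical-style KET activation, a narrower ISO activation
# overlapping it, and a two-module latent covariance with a connector
# hub (R46) loading on both factors.
output_dir: demo_out
seed: 1
synth:
  group_sizes: {homecage: 6, ISO: 6, saline: 8, KET: 6}
  regions: 53
  baseline_log_sd: 0.3
  effects:
    - group: KET
      regions: [R01, R02, R03, R04, R05, R06, R07, R08, R09, R10,
                R11, R12, R13, R14, R15, R16, R17, R18, R19, R20]
      fold: 4.48
    - group: ISO
      regions: [R15, R16, R17, R18, R19, R20, R21, R22, R23, R24]
      fold: 3.32
  factors:
    - regions: [R30, R31, R32, R33, R34, R35, R36, R37]
      loading: 0.6
    - regions: [R38, R39, R40, R41, R42, R43, R44, R45]
      loading: 0.6
  factor_corr: 0.5
  hub: {region: R46}
contrasts: [[KET, saline], [ISO, homecage]]
q: 0.05
effect_fraction: 0.40
cluster_cut: 0.5
module_cut: 0.7
r_min: 0.82
alpha: 0.05
hub_quantile: 0.80
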