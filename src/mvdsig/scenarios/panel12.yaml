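# Default calibrated scenario: a 12-model syngeneic-style panel.
#
# Scale mirrors the study design the pipeline targets: 14 single-cell
# clusters (~5,500 cells total), a panel of 12 tumor models with 5
# replicate samples and paired MVD(IHC) each, and four-arm growth studies
# with 8 animals per arm.  Noise levels are calibrated so the population
# (large-panel) correlation between the EC-marker signature score and
# simulated MVD(IHC) is ~0.8, so the n=12 sampling variability of the
# estimate is honestly represented.
name: panel12
seed: 0
profiles:
  n_genes: 1000
  n_clusters: 14
  markers_per_cluster: 40
  marker_log2fc: 2.0
  baseline_mean: 0.5
scrnaseq:
  cells_per_cluster: 395
  dispersion: 2.0
panel:
  n_models: 12
  replicates_per_model: 5
  ec_fraction_range: [0.02, 0.40]
  immune_fraction_range: [0.02, 0.40]
  mvd_slope: 500.0
  mvd_noise_sd: 25.0
  bulk_noise_sd: 0.8
growth:
  # untreated exponential rate per day (doubling time ~3.9 d): keeps the
  # control arm below the 2,000 mm3 humane endpoint through the day-15
  # evaluation
  growth_rate: 0.18
  days: 15
  n_animals: 8
  noise_sd: 0.1
markers:
  target_cluster: EC
  alpha: 0.05
  lfc_threshold: 1.0
signature:
  k: 20
  size: 6
  # With 14 clusters and 4-fold markers, a planted EC marker's noiseless
  # specificity index is ~0.23 and a uniformly expressed gene's is 1/14
  # ~0.07; 0.15 sits between the two.
  specificity_threshold: 0.15
  extra_markers: []
gep:
  target_cluster: Immune
  size: 6
efficacy:
  day: 15
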