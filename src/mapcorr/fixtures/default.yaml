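# Default generative fixture: 18 cortical/subcortical regions, two modalities.
#
# BPND is a unitless receptor binding potential (reference-tissue scale, low in
# subcortex, ~1 in neocortex); CBF is perfusion in mL/100 g/min.  The two mean
# profiles are calibrated so that their across-region Pearson correlation is
# 0.672, and their spread dominates the sampling noise of a regional mean at
# n = 24 (BPND ~11x, CBF ~6x the standard error), so that scenarios with
# region-specific means put the across-regions strategies in the
# confound-dominated regime.
modalities: [BPND, CBF]
regions:
  - middle/inferior frontal gyrus
  - superior frontal gyrus
  - superior temporal gyrus
  - occipital cortex
  - orbitofrontal cortex
  - parietal cortex
  - anterior cingulate cortex
  - insula
  - posterior cingulate cortex
  - ventrolateral prefrontal cortex
  - dorsolateral prefrontal cortex
  - sensory-motor cortex
  - amygdala
  - hippocampus
  - entorhinal cortex
  - thalamus
  - putamen
  - caudate

# Modality-level baselines, used whenever a scenario is not region-specific in
# the corresponding feature (the baseline mean is the profile average).
baseline:
  BPND: {mean: 0.88, sd: 0.20}
  CBF: {mean: 54.0, sd: 8.0}

# Compound (exchangeable) correlation between regions within each modality.
rho_within: {BPND: 0.5, CBF: 0.5}

mean_profile:
  BPND: [1.15, 1.20, 1.05, 1.10, 1.00, 1.25, 1.05, 0.95, 1.15, 1.10, 1.20,
         0.95, 0.55, 0.45, 0.70, 0.30, 0.40, 0.30]
  CBF:  [57.8007, 59.7637, 54.8747, 57.8377, 51.9116, 59.7267, 57.8747,
         53.9486, 65.8007, 55.8377, 59.7637, 55.9486, 42.2445, 44.3185,
         40.1336, 56.4294, 52.3555, 47.4294]

sd_profile:
  BPND: [0.257, 0.266, 0.239, 0.248, 0.230, 0.275, 0.239, 0.221, 0.257,
         0.248, 0.266, 0.221, 0.149, 0.131, 0.176, 0.104, 0.122, 0.104]
  CBF:  [8.67, 8.96, 8.23, 8.68, 7.79, 8.96, 8.68, 8.09, 9.87, 8.38, 8.96,
         8.39, 6.34, 6.65, 6.02, 8.46, 7.85, 7.11]

# Across-region Pearson correlation of the two mean profiles above.
profile_correlation: 0.672

# Scenario grid: which features vary by region, whether the two modalities are
# correlated, and the target marginal / conditional cross-modality correlations.
scenarios:
  A: {region_specific_mean: false, region_specific_variance: false,
      cross_modality_correlation: true,  marginal: 0.250, conditional: 0.500}
  B: {region_specific_mean: true,  region_specific_variance: false,
      cross_modality_correlation: false, marginal: 0.0,   conditional: 0.0}
  C: {region_specific_mean: true,  region_specific_variance: false,
      cross_modality_correlation: true,  marginal: 0.250, conditional: 0.500}
  D: {region_specific_mean: false, region_specific_variance: true,
      cross_modality_correlation: false, marginal: 0.0,   conditional: 0.0}
  E: {region_specific_mean: true,  region_specific_variance: true,
      cross_modality_correlation: true,  marginal: 0.135, conditional: 0.057}
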