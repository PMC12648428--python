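"""Run all four correlation-estimation strategies on one simulated cohort.

Scenario C has a true marginal correlation of 0.250 between the two
modalities, but also region-specific mean profiles that correlate at 0.672
across regions.  The across-regions strategies (1.1, 1.2) chase that mean
profile; the across-participants strategies (2, 3) recover the true
participant-level association.
"""

import mapcorr as mc

spec = mc.scenario_spec("C")
data = mc.simulate_dataset(spec, n=24, seed=7)

est_11 = mc.strategy_across_regions(data)
est_12 = mc.strategy_across_regions_split(data, seed=1)
regional = mc.strategy_per_region(data)
est_2 = mc.aggregate_regional(regional, data)
fit = mc.fit_mixed_model(data)

print(f"truth: marginal={spec.marginal_correlation:.3f} "
      f"conditional={spec.conditional_correlation:.3f}\n")
for name, e in [("1.1 across regions, one cohort ", est_11),
                ("1.2 across regions, two cohorts", est_12),
                ("2   regional average           ", est_2),
                ("3   mixed model (marginal)     ", fit.marginal)]:
    print(f"{name}: {e.estimate:+.3f} [{e.ci_low:+.3f}, {e.ci_high:+.3f}] "
          f"p={e.p_value:.4f}")
print(f"3   mixed model (conditional)  : {fit.conditional.estimate:+.3f} "
      f"[{fit.conditional.ci_low:+.3f}, {fit.conditional.ci_high:+.3f}]")
print("\nStrategies 1.x sit near the 0.672 mean-profile correlation even "
      "though the\nparticipant-level (marginal) correlation is 0.250 — the "
      "regional mean structure,\nnot the biology, drives the across-regions "
      "estimate.")
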