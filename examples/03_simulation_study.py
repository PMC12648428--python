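"""A small Monte-Carlo study: type-1 error under the region-mean confound.

Scenario B has NO cross-modality correlation (the null is true), but both
mean profiles vary over regions with similar rank order.  Repeating the
analysis over simulated cohorts shows the across-regions test rejecting the
null essentially always, while the regional-average test keeps its nominal
5% level.  400 replicates keep this demo fast; increase --reps for
publication-grade Monte-Carlo error (SE ~ sqrt(p(1-p)/reps)).
"""

import mapcorr as mc

spec = mc.scenario_spec("B")
summaries = mc.run_study(spec, n=24, reps=400, master_seed=3,
                         strategies=("1.1", "2"))

print("scenario B (truth: no cross-modality correlation), n=24, 400 reps")
print(f"{'strategy':10} {'mean est':>9} {'coverage':>9} {'type-1':>7}")
for s in summaries:
    print(f"{s.strategy:10} {s.mean_estimate:9.3f} {s.coverage:9.3f} "
          f"{s.rejection_rate:7.3f}  (MC SE {s.mc_se_rejection:.3f})")
print("\nStrategy 1.1 rejects the true null in every replicate (type-1 ~ 1) "
      "and its CI\nnever covers the truth; strategy 2 rejects at ~5% as it "
      "should.")
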