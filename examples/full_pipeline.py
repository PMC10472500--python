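"""Run the whole analysis chain on a two-area ephaptic simulation.

simulate -> bidomain field -> Bayesian model comparison -> spatial GC ->
RSA, with one master seed. Prints the per-stage headline numbers.
"""

from engramfield.pipeline import run_pipeline

report = run_pipeline({"master_seed": 1})

bmc = report.stages["bmc"]["summary"]
gc = report.stages["gc"]["summary"]["area1"]
rsa = report.stages["rsa"]["summary"]

print("stage status:", {k: v["status"] for k, v in report.stages.items()})
print(f"BMC area1: mean BF {bmc['area1']['mean_bf']:+.2f} -> {bmc['area1']['winner']}")
print(f"BMC area2: mean BF {bmc['area2']['mean_bf']:+.2f} -> {bmc['area2']['winner']}")
print(f"GC field->activity {gc['field_to_activity']['mean_strength']:.3f} "
      f"(CV {gc['field_to_activity']['cv_percent']:.0f}%)  "
      f"activity->field {gc['activity_to_field']['mean_strength']:.3f} "
      f"(CV {gc['activity_to_field']['cv_percent']:.0f}%)")
print(f"RSA deviation (field): {rsa['field']['deviation']:.3f}, "
      f"p = {rsa['field']['p_value']:.4f}; (lfp) p = {rsa['lfp']['p_value']:.4f}")
# On ephaptic-generator data the comparison decisively favours the
# ephaptic model in both areas, the field Granger-causes activity (not
# the reverse) with a steadier strength, and the two areas' field
# representations are significantly related.
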