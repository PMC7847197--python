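"""Full assessment: simulate a survey, score it, classify effects.

Runs the whole pipeline on one synthetic survey: CCUs per site, community
and fish metrics, then the two-gate classification — a metric at a
contaminated site is 'adverse' only if its mean falls outside the 90%
prediction-interval reference range AND differs significantly from its
elevation-paired reference site (single-step adjusted p < 0.05).
"""

from streamtox import RunConfig, run_pipeline

reports = run_pipeline(RunConfig(scenario_seed=42))

print("site CCUs:")
print(reports["ccu"][["site", "ccu"]].round(1).to_string(index=False))

cls = reports["classification"]
print(f"\n{len(cls)} metric × site classifications:",
      cls["label"].value_counts().to_dict())

adverse = cls[cls["label"] == "adverse"]
print("\nadverse effects (outside reference range AND significant):")
print(adverse[["metric", "site", "p_adjusted"]].to_string(index=False))
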