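"""Fish abundance, condition factor and hatchery-origin adjustment.

Simulates electrofishing captures in five ~50 m² areas per site, summarizes
masu salmon abundance (log10(x+1) per area), computes the Fulton-type
condition factor CF = 1000·W/L³ per individual, and shows how otolith-mark
subsamples turn total abundance into wild-only abundance.
"""

import numpy as np

from streamtox import ScenarioConfig, condition_factor
from streamtox.fish_metrics import abundance_by_area, abundance_summary, wild_abundance
from streamtox.simulate import generate_fish

captures, areas, otoliths = generate_fish(ScenarioConfig(seed=42))

counts = abundance_by_area(captures, "masu salmon", areas)
summary = abundance_summary(counts).set_index("site")
print("masu salmon abundance (mean log10(count+1) per 50 m² area):")
print(summary[["mean", "se"]].round(2).to_string())

masu = captures[captures["species"] == "masu salmon"]
cf = condition_factor(masu["weight_g"].to_numpy(), masu["fork_length_cm"].to_numpy())
print(f"\ncondition factor over {len(cf)} masu salmon: "
      f"median {np.median(cf):.1f}, IQR {np.percentile(cf, 25):.1f}–{np.percentile(cf, 75):.1f}")

print("\notolith subsamples (site, checked, hatchery):")
for _, row in otoliths.iterrows():
    p = row["n_hatchery"] / row["n_checked"]
    print(f"  {row['site']:>4}: {row['n_hatchery']:>2} of {row['n_checked']:>2} hatchery ({p:.0%})")
    if row["n_hatchery"]:
        site_counts = counts.loc[[row["site"]]]
        adj = wild_abundance(site_counts, p)
        print(f"        wild-only counts: {adj['count'].round(1).tolist()}")
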