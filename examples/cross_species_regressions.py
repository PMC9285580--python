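"""Cross-species predictors of recovery magnitude, timing and detectability.

Builds the full per-species summary table (500 stochastic runs per species
and scenario) and fits the regression battery: how well F/M predicts the
final abundance and biomass ratios, how recruitment variability and
response magnitude shape year-10 detectability, and how open- and
closed-model transient durations relate.
"""

from mpatimelines import load_species_table, regression_battery, summarize_all

summaries = summarize_all(load_species_table(), n_runs=500, seed=1)
print(f"{'response':24s} {'predictor':24s} {'excluded':16s} {'R^2':>6s}  n")
for reg in regression_battery(summaries):
    excl = reg.excluded[0] if reg.excluded else "-"
    pred = reg.predictor if reg.transform == "identity" else reg.transform
    print(f"{reg.response:24s} {pred:24s} {excl:16s} {reg.r_squared:6.3f}  {reg.n}")

print("\nF/M almost fully determines the final abundance ratio (R^2 ~ 0.99).")
print("Year-10 detectability falls with recruitment noise (R^2 ~ 0.5 on")
print("sigma_R); the red sea urchin's extreme F/M dominates any fit that")
print("includes it, hence the with/without-urchin pairs.")
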