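"""When does an MPA effect become statistically detectable?

For four contrasting species, simulates 500 stochastic trajectories with
the MPA in place and 500 with fishing continuing, then reports the AUC of
the abundance comparison at 2, 5, 10 and 20 years. AUC is the probability
that a randomly drawn MPA outcome exceeds a randomly drawn fished outcome:
0.5 means the effect is invisible, 1.0 that it is unmistakable.
"""

from mpatimelines import auc_timeline, get_species, load_species_table

table = load_species_table()
years = (2, 5, 10, 20)

print(f"{'species':22s}" + "".join(f"  AUC@{y:>2d}yr" for y in years))
for name in ("Bocaccio", "Blue rockfish", "China rockfish", "Red sea urchin"):
    sp = get_species(table, name)
    res = auc_timeline(sp, years=years, metric="abundance_ratio", n_runs=500, seed=1)
    row = "".join(f"  {res[y].auc:7.3f}" for y in years)
    print(f"{name:22s}{row}")

print("\nYear-2 values are exactly 1.0 whenever 2 < a_c: runs start at the")
print("deterministic fished equilibrium, so recruitment noise only reaches")
print("the fished ages (>= a_c) once the first post-MPA cohort grows into")
print("them. After that window, heavily fished red sea urchin stays fully")
print("separable, while bocaccio — nearly unfished before protection, with")
print("boom-bust recruitment (sigma_R = 1) — never yields a usable signal.")
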