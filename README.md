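# mpatimelines

Expected timelines of fished-population recovery inside marine protected
areas (MPAs): age-structured projection models, transient-dynamics metrics,
and ROC/AUC detectability analysis for adaptive MPA management.

## The problem

When fishing stops inside an MPA, a population's truncated age structure
"fills in": fish survive past the age at first capture `a_c`, grow larger,
and abundance and biomass rise toward a new equilibrium. Managers need to
know, species by species, *how much* increase to expect, *how fast*, and
*when* monitoring data could statistically distinguish the MPA from a
still-fished baseline given boom-bust larval recruitment. `mpatimelines`
answers those questions for a bundled table of 19 California nearshore
fishery species (rockfishes, lingcod, cabezon, sheephead, kelp bass, red
sea urchin, ...) and for any user-supplied species CSV.

## The models

**Open population** (recruitment is an external subsidy):
`N_{t+1} = A N_t + R_t`, with survival `e^{-(M+F_a)}` on the subdiagonal of
`A` (`F_a = F` for ages >= a_c while fished, 0 in the MPA) and lognormal
recruitment `R_t = 500 e^{G_t}`, `G_t ~ N(0, sigma_R)`. The abundance of
fished ages recovers as

    N'_t / N'_0 = (M+F)/M - ((M+F)/M - 1) e^{-Mt},

toward the discrete asymptote `(1 - e^{-(M+F)})/(1 - e^{-M})`, reaching 95%
of it in roughly `-ln(0.05)/M` years.

**Closed population** (all recruits produced locally): a Leslie matrix with
fecundity row `f_a = alpha W_a` (`a >= a_m`), `alpha` calibrated so the
unfished population exactly replaces itself (dominant eigenvalue 1). Its
spectrum yields the transient metrics theta (age-truncation angle), rho
(damping ratio, with characteristic time `1/ln rho`) and P (oscillation
period).

**Detectability**: ensembles of stochastic MPA and still-fished runs are
compared by the area under the ROC curve — the probability that a random
MPA outcome exceeds a random fished outcome (0.5 = invisible effect,
1.0 = unmistakable).

See `docs/methods.md` for assumptions, conventions and limitations.

## Worked example

```python
from mpatimelines import (
    abundance_ratio_series, asymptotic_ratio, biomass_ratio_series,
    constant_recruitment, fished_equilibrium, get_species,
    load_species_table, project_open, time_to_fraction,
)

sp = get_species(load_species_table(), "Blue rockfish")
traj = project_open(sp, fished_equilibrium(sp),
                    constant_recruitment(sp.max_age), fished=False)
print(abundance_ratio_series(traj)[10])   # 1.784
print(biomass_ratio_series(traj)[10])     # 2.305
print(asymptotic_ratio(sp))               # 2.040
print(time_to_fraction(sp, 0.95))         # 17
```

Ten years of protection lifts blue rockfish abundance (ages >= a_c) to
1.78x its fished level and biomass to 2.3x — biomass responds more because
protection restores the oldest, heaviest ages. The long-run abundance gain
is 2.04x, 95% of which is reached after 17 years.

The scripts in `examples/` walk through each capability (deterministic
recovery, detectability timelines, closed-model transients, cross-species
regressions) and print annotated output; each runs in seconds:

```bash
python examples/detectability_timeline.py
```

A thin CLI wraps the same functions for batch use:

```bash
mpatimelines summarize --runs 500 --seed 1 --out-dir results/
mpatimelines project --species "Blue rockfish" --scenario mpa --sigma-r-override 0
mpatimelines detect --species "Red sea urchin" --years 2,5,10,20
```

Every command writes a `manifest.json` with the resolved settings so a run
can be reproduced exactly.

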