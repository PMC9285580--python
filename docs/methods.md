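# Methods

`mpatimelines` projects how fished populations are expected to respond after
fishing stops inside a marine protected area (MPA), and when that response
should become statistically detectable against a still-fished baseline. It
implements two linear age-structured models spanning the extremes of larval
connectivity, a stochastic recruitment layer, ROC/AUC detectability analysis,
and a battery of cross-species regressions. This note records the models,
their assumptions, the numerical conventions, and the design choices made
where more than one reading was defensible.

## State, indexing and parameters

A population is a vector `N_t` of abundances over age classes `1..max_age`;
recruits enter age class 1. Each species is parameterised by (units in
parentheses):

| parameter | meaning | source of defaults |
|---|---|---|
| `M` (1/yr) | instantaneous natural mortality | bundled table |
| `F` (1/yr) | pre-MPA fishing mortality, applied to ages >= `a_c` | bundled table |
| `a_c`, `a_m` (yr) | age at first capture / maturity | bundled table |
| `max_age` (yr) | number of age classes (hard truncation) | bundled table |
| `L_inf` (cm), `k` (1/yr), `a_0` (yr) | von Bertalanffy growth | bundled table |
| `p`, `w` | length–weight power law `W = p L^w` | bundled table |
| `sigma_R` | SD of log recruitment deviates | bundled table |

The bundled table covers 19 California nearshore fishery species (12
rockfishes, lingcod, kelp greenling, cabezon, California scorpionfish and
sheephead, kelp bass, red sea urchin). Weight units are whatever `p` implies;
every weight-dependent output is a ratio, so units cancel. Annual survival
is `exp(-(M + F_a))` with `F_a = F` for ages >= `a_c` while fished and 0
otherwise; the transition out of age `a` uses the source age's `F_a`.

Tabulated `a_c` and `a_m` are taken as authoritative rather than recomputed
from length limits; the inverse von Bertalanffy conversion
`a = a_0 - ln(1 - L/L_inf)/k` (with round-to-nearest-year, minimum 1) is
provided for users who only have a length at first capture, and reproduces
the tabulated `a_c` where we checked it (blue rockfish 3.56 -> 4; black &
yellow rockfish 13.86 -> 14).

## Open population model

With recruitment an external subsidy (larval dispersal scale >> MPA size),

    N[t+1] = A N[t] + R[t],

where `A` is the survival-only matrix and `R[t]` puts the year's recruits
into age class 1. Recruitment is `mean_level * exp(G_t)` with
`G_t ~ N(0, sigma_R)` i.i.d. across years; `mean_level` defaults to 500 and
cancels out of every ratio. The lognormal is deliberately *not*
mean-corrected (the deviate multiplies the constant level, so the median
recruitment is `mean_level` and the mean is `mean_level * exp(sigma_R^2/2)`);
a correction would change no rank-based result and is not offered.

Projections start at the fished equilibrium — the fixed point of the fished
dynamics under constant recruitment, a geometric age profile truncated by
`F` above `a_c`. Stochastic runs start at the same deterministic state (no
stochastic burn-in), so every ratio trajectory leaves 1 at t = 0. A side
effect worth knowing: the sum over fished ages stays noise-free until the
first post-MPA cohort reaches `a_c`, so detectability is degenerately
perfect for `t < a_c`.

**Recovery ratios.** The reported abundance metric is the primed ratio
`N'_t/N'_0`, summing ages >= `a_c`, with the deterministic fished-equilibrium
denominator held fixed across stochastic runs. Its continuous-time
expectation rises as `(M+F)/M - ((M+F)/M - 1) e^{-Mt}` and the discrete
asymptote is

    N'_inf / N'_0 = (1 - e^{-(M+F)}) / (1 - e^{-M}),

which the simulated long-run ratio matches to a relative error bounded by
the truncated unfished tail, about `e^{-M (max_age - a_c)}`. The discrete
trajectory follows the continuous exponential shape but with the discrete
asymptote substituted; the continuous asymptote `(M+F)/M` overshoots it by
up to ~16% (red sea urchin), so the two forms are kept distinct in the API.

**Biomass** converts abundance through the growth curve and length–weight
law. Both the abundance and biomass ratios sum ages >= `a_c` by default.
The all-ages alternative is available via `all_ages=True`, but the primed
convention is the default because it is the one under which the
cross-species biomass results reproduce (all-ages biomass R² against F/M
drops from 0.92 to 0.65) and it keeps the two metrics comparable.

**Time to 95% recovery** is the first integer year at which the
deterministic ratio reaches 0.95 x its own long-run value (the value at
t = max_age, where the series becomes exactly constant). The familiar
`-ln(0.05)/M` formula approximates the time for the *increase* to complete
and is exposed separately as an upper bound; the ratio threshold is crossed
earlier, at `[ln 20 + ln((R-1)/R)]/M` with `R` the discrete asymptote.

**Recruitment-noise propagation.** Under additive recruitment noise of
standard deviation `sigma` (in recruits), the SD of the fished-age sum is

    sigma_total(t) = sqrt( sum_{a=0..t} (sigma e^{-M (a + a_c - 1)})^2 ).

The `a_c - 1` offset follows this package's recruit-at-age-1 indexing (a
cohort counted at age `a` has survived `a - 1` years); the test suite checks
the formula against a 10,000-run simulation ensemble (agreement ~0.4% at
t = 20 for blue rockfish). The argument is the numeric SD, not the
log-scale `sigma_R`, because the derivation is additive.

## Closed population model

With all recruits produced locally, the matrix gains a fecundity top row
`f_a = alpha W_a` for `a >= a_m` (fecundity proportional to body mass,
`alpha` a larval-survival constant). `alpha` is calibrated so the *unfished*
matrix has dominant eigenvalue exactly 1, via the Leslie identity
lambda = 1 <=> R0 = sum_a l_a f_a = 1 with `l_a = e^{-M(a-1)}`; an
eigen-solve confirms the calibration to 1e-8. This is a deliberately
conservative stance on an unknowable quantity: a protected population stops
declining but does not grow geometrically. Consequences: closed-model
results should be read for relative orderings and time scales, not absolute
magnitudes; and the reproductive-value-weighted total `v . N_t` is conserved
along deterministic runs (a tested invariant).

**Transient metrics.** Starting from the fished matrix's dominant
eigenvector (the declining population's stable structure):

* `theta` — angle in degrees between that fished structure and the unfished
  stable age distribution (SAD); measures how much fishing truncated the
  age profile. Largest for red sea urchin (25.6 deg).
* `rho = lambda_1/|lambda_2|` — damping ratio; `1/ln(rho)` is the
  characteristic transient duration (natural log). `lambda_2` is the
  eigenvalue of second-largest modulus, conjugate pairs counted once,
  modulus ties broken toward the larger imaginary part.
* `P = 2*pi/atan2(Im lambda_2, Re lambda_2)` — dominant oscillation period,
  reported as `None` when `lambda_2` is real.

Which matrix supplies the spectrum is a genuine modelling fork. The
asymptotic convergence rate to the SAD after protection is governed by the
*unfished* matrix (and the late-time decay of the distance to the SAD
empirically matches its `-ln rho` within a few percent). But the fished
(pre-MPA) spectrum is what the cross-species transient results reflect:
with it, the longest period and slowest convergence belong to China
rockfish and the transient-duration correlation with the open-model
recovery time is weak (R² ~ 0.30), both as reported; with the unfished
spectrum the correlation is 0.87 and red sea urchin has an 88-year period,
contradicting the reported orderings. `transient_metrics` therefore
defaults to `matrix="fished"` with `matrix="unfished"` available, and the
convergence-rate tests use the unfished spectrum.

**Convergence time** is the first year the normalized age distribution
comes within 0.95 proportional similarity (`1 - 0.5 * sum|n - w|`) of the
SAD. No distance metric is canonical here; the Keyfitz-delta formulation of
the same rule is provided, and absolute convergence times should be
expected to shift under other metrics.

Stochasticity in the closed model multiplies each year's whole top-row
product (recruitment) by an independent lognormal — variability in
recruitment success, not in per-age fecundity. Because the noise multiplies
a geometric process, log-abundance variance grows without bound, unlike the
open model's stationary band; detectability can therefore *decline* with
time in closed populations.

## Detectability (ROC/AUC)

For a given species, year and metric, 500 MPA and 500 still-fished
trajectories are simulated on independent streams, and the two samples of
the metric at that year are compared. Sensitivity at a threshold is the
fraction of MPA outcomes above it; specificity the fraction of fished
outcomes at or below it; thresholds are midpoints between distinct pooled
values plus sentinels. AUC is computed rank-based (Mann–Whitney, ties at
half credit) and equals the trapezoidal area under the empirical ROC — the
two are computed by independent routes and tested to 1e-12. MPA and fished
draws are unpaired, matching separately simulated scenarios. Because AUC is
rank-based, dividing both samples by the common deterministic baseline (the
ratio convention) changes nothing.

Random streams derive from a single root seed: per-species, per-scenario
substreams are seeded by a CRC of the species name and scenario, so adding
or reordering species does not perturb existing draws, and identical seeds
reproduce results bit for bit.

## Cross-species battery

`summarize_all` computes, per species: the deterministic final abundance
and biomass ratios (taken at t = max_age, where the series is exactly
constant; no closed-form biomass asymptote is used), time to 95%
recovery, year-10 AUCs, and the closed-model transient metrics.
`regression_battery` then fits ten OLS models (statsmodels, unadjusted R²):
time-to-95% ~ 1/M; final abundance and biomass ratios ~ F/M (each with and
without red sea urchin); year-10 abundance AUC ~ sigma_R and ~ final ratio
(with and without the urchin); characteristic transient time ~ 1/M and
~ time-to-95%. The final-ratio predictor defaults to the continuous form
`(M+F)/M`; the discrete simulated ratio can be substituted
(`continuous_ratio=False`) and changes R² by < 0.02.

The red sea urchin (F/M = 5.1, triple any fish in the table) is a
high-leverage point on every F/M axis. For the year-10 AUC regression this
is structural, not cosmetic: a fit to the other 18 species would predict
AUC ~ 1.8 at the urchin's F/M while AUC is capped at 1, so including it
collapses that R² from ~0.49 to ~0.22 regardless of seed. The
with/without-urchin pairs in the battery exist to keep this visible.

## Synthetic scenarios

`lognormal_recruitment` reproduces the stochastic recruitment process
exactly as used by the simulations. `random_species` draws parameter sets
uniformly within the envelope of the bundled table (integer fields on
integers, `a_m`/`a_c` capped at `max_age`, invalid draws resampled) — the
goal is coverage of the invariant surface for property tests, not realism.
What the generator does *not* emulate: correlations between life-history
traits (real `M`, `k` and `L_inf` covary), age-dependent mortality,
autocorrelated or regime-like recruitment, observation error in monitoring
data, density dependence, movement across MPA borders, or species
interactions. Passing tests therefore validate the internal consistency of
the linear-model machinery over a realistic parameter envelope; they say
nothing about those excluded processes.

## Numerical choices and degenerate inputs

* Projection horizons: trajectories used for "final" ratios run to
  t = max_age, beyond which the open-model ratio is exactly constant;
  the CLI default horizon is `max(50, ceil(5/M))` years.
* Ensembles of 500 runs reproduce the reported stochastic R² values with
  spread well under +-0.05 across seeds; property tests use 10,000 runs
  where a 5% moment comparison requires it.
* `M = 0` is rejected at validation (ratios undefined); `F = 0` is valid
  and collapses MPA/fished distinctions (AUC 0.5 exactly with
  `sigma_R = 0`). `sigma_R = 0` reproduces deterministic trajectories
  bit for bit through the stochastic code path.
* Eigen-computations use dense LAPACK solves (matrices are at most
  100 x 100); the dominant eigenvector is clipped to the nonnegative
  orthant before normalisation to absorb sign and rounding noise.
* `L_c >= L_inf` is rejected (age at length undefined); lengths below the
  growth-curve root are clamped to length 0, hence weight 0.

## Known limitations

* Both models are linear: no density dependence, Allee effects, or species
  interactions; recovery magnitudes are extrapolations of pre-MPA rates.
* The fished baseline is the pre-MPA equilibrium, not an outside-MPA
  reference site with displaced effort.
* The closed model's absolute magnitudes depend on the lambda = 1
  calibration; only relative comparisons are meaningful.
* Detectability covers process noise only — no survey/observation error,
  so real-world detection times will be longer.
* The open model holds coastwide recruitment fixed; an MPA network large
  enough to raise regional larval supply would violate the subsidy
  assumption.
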