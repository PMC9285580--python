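"""Open-population (external recruitment) age-structured projection.

The open model treats larval recruitment as an external subsidy that is
independent of local adult abundance, appropriate for an MPA that is small
relative to the larval dispersal scale. Dynamics follow

    N[t+1] = A N[t] + R[t]

where ``A`` carries survival ``exp(-(M + F_a))`` on its subdiagonal
(``F_a = F`` for ages >= a_c while fished, zero otherwise, and zero
everywhere after MPA implementation) and ``R[t]`` places the year-t
recruits into age class 1.

Analytic results for the abundance ratio of fished ages (the primed ratio
``N'_t / N'_0``, summing ages >= a_c) after fishing ceases:

* trajectory:   ``N'_t/N'_0 = (M+F)/M - ((M+F)/M - 1) exp(-M t)``
* asymptote:    ``N'_inf/N'_0 = (1 - exp(-(M+F))) / (1 - exp(-M))``
* time to reach a fraction q of the asymptote is approximately
  ``-ln(1-q)/M``.

Stochastic recruitment is lognormal: ``R_t = mean_level * exp(G_t)`` with
``G_t ~ Normal(0, sigma_R)`` drawn independently each year (no mean
correction, so the mean recruitment is ``mean_level * exp(sigma_R^2/2)``
and the median is ``mean_level``).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .species import SpeciesParams, weights_by_age

DEFAULT_MEAN_RECRUITS = 500.0

Scenario = Literal["mpa", "fished"]


@dataclass(frozen=True)
class RecruitmentSeries:
    """A realized annual-recruitment sequence ``R_t`` for t = 0..T-1."""

    values: np.ndarray
    mean_level: float = DEFAULT_MEAN_RECRUITS
    sigma_R: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if np.any(self.values < 0):
            raise ValueError("recruitment values must be >= 0")

    def __len__(self) -> int:
        return len(self.values)


def constant_recruitment(T: int, mean_level: float = DEFAULT_MEAN_RECRUITS) -> RecruitmentSeries:
    """Deterministic recruitment: the same number of recruits every year."""
    return RecruitmentSeries(np.full(T, float(mean_level)), mean_level, 0.0, None)


@dataclass(frozen=True)
class PopulationState:
    """Abundance in each age class (ages 1..max_age)."""

    abundance_by_age: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.abundance_by_age, dtype=float)
        if np.any(arr < 0):
            raise ValueError("abundances must be >= 0")
        object.__setattr__(self, "abundance_by_age", arr)

    @property
    def total(self) -> float:
        return float(self.abundance_by_age.sum())


@dataclass(frozen=True)
class Trajectory:
    """A projected time series of population states for t = 0..T.

    ``states`` has shape (T+1, max_age); row t is the age-abundance vector
    at year t since the start of the projection.
    """

    states: np.ndarray
    params: SpeciesParams
    scenario: Scenario
    recruitment: RecruitmentSeries | None = None

    def __post_init__(self):
        object.__setattr__(self, "states", np.asarray(self.states, dtype=float))
        if self.states.ndim != 2 or self.states.shape[1] != self.params.max_age:
            raise ValueError(
                f"states must be (T+1, {self.params.max_age}), got {self.states.shape}"
            )

    @property
    def T(self) -> int:
        return self.states.shape[0] - 1


def survival_vector(params: SpeciesParams, fished: bool) -> np.ndarray:
    """Annual survival from age a to a+1 for a = 1..max_age-1.

    The transition out of age a uses the fishing mortality of the *source*
    age: ``F_a = F`` for ``a >= a_c`` when fished, else 0.
    """
    a = np.arange(1, params.max_age)
    Fa = np.where(fished & (a >= params.a_c), params.F, 0.0)
    return np.exp(-(params.M + Fa))


def build_survival_matrix(params: SpeciesParams, fished: bool) -> np.ndarray:
    """Survival-only projection matrix (zero top row; no local reproduction)."""
    n = params.max_age
    A = np.zeros((n, n))
    A[np.arange(1, n), np.arange(0, n - 1)] = survival_vector(params, fished)
    return A


def fished_equilibrium(
    params: SpeciesParams, mean_recruits: float = DEFAULT_MEAN_RECRUITS
) -> PopulationState:
    """Stable age structure under constant recruitment and fishing at rate F.

    The fixed point of ``N = A_fished N + R``: abundance declines
    geometrically with age at rate ``exp(-M)`` below a_c and
    ``exp(-(M+F))`` from a_c on, truncated at max_age. With ``F = 0`` this
    is the unfished equilibrium.
    """
    if mean_recruits <= 0:
        raise ValueError("mean_recruits must be > 0")
    s = survival_vector(params, fished=True)
    N = np.empty(params.max_age)
    N[0] = mean_recruits
    N[1:] = mean_recruits * np.cumprod(s)
    return PopulationState(N)


def unfished_equilibrium(
    params: SpeciesParams, mean_recruits: float = DEFAULT_MEAN_RECRUITS
) -> PopulationState:
    """Stable age structure under constant recruitment with no fishing."""
    N = mean_recruits * np.exp(-params.M * (params.ages - 1))
    return PopulationState(N)


def project_open(
    params: SpeciesParams,
    initial: PopulationState,
    recruits: RecruitmentSeries,
    fished: bool,
) -> Trajectory:
    """Iterate ``N[t+1] = A N[t] + R[t]``; recruits enter age class 1.

    The recruitment series length sets the horizon T.
    """
    n = params.max_age
    N0 = initial.abundance_by_age
    if N0.shape != (n,):
        raise ValueError(f"initial state has length {N0.shape}, expected {n}")
    s = survival_vector(params, fished)
    T = len(recruits)
    states = np.empty((T + 1, n))
    states[0] = N0
    for t in range(T):
        states[t + 1, 1:] = states[t, :-1] * s
        states[t + 1, 0] = recruits.values[t]
    return Trajectory(states, params, "fished" if fished else "mpa", recruits)


def _fishable_slice(params: SpeciesParams) -> slice:
    return slice(params.a_c - 1, None)


def abundance_ratio_series(
    traj: Trajectory,
    baseline: float | None = None,
    all_ages: bool = False,
) -> np.ndarray:
    """Abundance ratio ``N'_t / N'_0`` relative to the fished equilibrium.

    By default the primed sums run over fished ages (a >= a_c). The
    denominator is the deterministic fished-equilibrium value (the t = 0
    state of a projection started there), so it stays fixed across
    stochastic replicate runs.
    """
    sl = slice(None) if all_ages else _fishable_slice(traj.params)
    series = traj.states[:, sl].sum(axis=1)
    denom = series[0] if baseline is None else baseline
    if denom == 0:
        raise ValueError("baseline abundance is zero; ratio undefined")
    return series / denom


def biomass_series(traj: Trajectory, all_ages: bool = False) -> np.ndarray:
    """Biomass ``B_t``: weight-at-age times abundance, summed over ages.

    Like the abundance ratio, the default sums fished ages (a >= a_c),
    which is the convention under which the cross-species biomass results
    reproduce; ``all_ages=True`` sums every age class.
    """
    W = weights_by_age(traj.params)
    sl = slice(None) if all_ages else _fishable_slice(traj.params)
    return traj.states[:, sl] @ W[sl]


def biomass_ratio_series(
    traj: Trajectory, baseline: float | None = None, all_ages: bool = False
) -> np.ndarray:
    """Biomass ratio ``B_t / B_0`` (fixed deterministic denominator)."""
    B = biomass_series(traj, all_ages=all_ages)
    denom = B[0] if baseline is None else baseline
    if denom == 0:
        raise ValueError("baseline biomass is zero; ratio undefined")
    return B / denom


def analytic_ratio(params: SpeciesParams, t) -> np.ndarray | float:
    """Continuous-time abundance-ratio trajectory after fishing ceases.

    ``(M+F)/M - ((M+F)/M - 1) exp(-M t)``; assumes an unbounded number of
    age classes.
    """
    if params.M == 0:
        raise ValueError("M must be > 0")
    r_inf = (params.M + params.F) / params.M
    return r_inf - (r_inf - 1.0) * np.exp(-params.M * np.asarray(t, dtype=float))


def asymptotic_ratio(params: SpeciesParams) -> float:
    """Discrete asymptotic abundance ratio ``(1 - e^-(M+F)) / (1 - e^-M)``."""
    if params.M == 0:
        raise ValueError("M must be > 0")
    return float(
        (1.0 - np.exp(-(params.M + params.F))) / (1.0 - np.exp(-params.M))
    )


def default_horizon(params: SpeciesParams) -> int:
    """Projection horizon long enough to reach >= 99% of the asymptote."""
    return max(50, int(np.ceil(5.0 / params.M)))


def _deterministic_mpa_ratio(params: SpeciesParams, T: int, metric: str) -> np.ndarray:
    traj = project_open(
        params, fished_equilibrium(params), constant_recruitment(T), fished=False
    )
    if metric == "abundance":
        return abundance_ratio_series(traj)
    if metric == "biomass":
        return biomass_ratio_series(traj)
    raise ValueError(f"unknown metric {metric!r}")


def time_to_fraction(
    params: SpeciesParams, q: float = 0.95, metric: str = "abundance"
) -> int:
    """Years for the deterministic post-MPA ratio to reach q of its asymptote.

    The asymptote is taken from the simulation itself: the ratio series is
    exactly constant once every pre-MPA cohort has died out (t >= max_age),
    so the value at t = max_age is the long-run ratio. Returns the smallest
    integer t with ``ratio[t] >= q * ratio[max_age]``.
    """
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    series = _deterministic_mpa_ratio(params, params.max_age, metric)
    target = q * series[-1]
    hits = np.nonzero(series >= target)[0]
    return int(hits[0])


def time_to_fraction_approx(params: SpeciesParams, q: float = 0.95) -> float:
    """Closed-form approximation ``-ln(1-q)/M`` to :func:`time_to_fraction`."""
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    return float(-np.log1p(-q) / params.M)


def _stream_seed(seed: int, species: str, scenario: str) -> np.random.SeedSequence:
    # Stable per-species, per-scenario substream: adding or reordering
    # species does not perturb the draws of the others.
    tag = zlib.crc32(f"{species}|{scenario}".encode()) % (2**31)
    return np.random.SeedSequence([int(seed) % (2**31), tag])


def simulate_open_ensemble(
    params: SpeciesParams,
    n_runs: int,
    T: int,
    seed: int,
    fished: bool,
    sigma_R: float | None = None,
    mean_level: float = DEFAULT_MEAN_RECRUITS,
) -> list[Trajectory]:
    """Simulate replicate stochastic trajectories from the fished equilibrium.

    Each run draws its own lognormal recruitment sequence; MPA and fished
    ensembles built from the same root seed use independent streams. With
    ``sigma_R = 0`` every run equals the deterministic trajectory.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    sig = params.sigma_R if sigma_R is None else float(sigma_R)
    rng = np.random.default_rng(
        _stream_seed(seed, params.name, "fished" if fished else "mpa")
    )
    N0 = fished_equilibrium(params, mean_level)
    G = rng.normal(0.0, sig, size=(n_runs, T)) if sig > 0 else np.zeros((n_runs, T))
    R = mean_level * np.exp(G)
    # propagate all runs at once: one time loop instead of one per run
    n = params.max_age
    s = survival_vector(params, fished)
    states = np.empty((T + 1, n_runs, n))
    states[0] = N0.abundance_by_age
    for t in range(T):
        states[t + 1, :, 1:] = states[t, :, :-1] * s
        states[t + 1, :, 0] = R[:, t]
    scenario = "fished" if fished else "mpa"
    return [
        Trajectory(
            states[:, i, :],
            params,
            scenario,
            RecruitmentSeries(R[i], mean_level, sig, seed),
        )
        for i in range(n_runs)
    ]


def ensemble_ratio_matrix(
    trajectories: Sequence[Trajectory],
    metric: str = "abundance_ratio",
) -> np.ndarray:
    """Stack per-run ratio series into an (n_runs, T+1) matrix.

    The denominator of every run is the shared deterministic fished
    equilibrium (all runs start there), so rows are directly comparable.
    """
    if metric == "abundance_ratio":
        rows = [abundance_ratio_series(tr) for tr in trajectories]
    elif metric == "biomass_ratio":
        rows = [biomass_ratio_series(tr) for tr in trajectories]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return np.vstack(rows)


def recruitment_sd_total(
    params: SpeciesParams, t: int, sigma_R_numeric: float
) -> float:
    """Standard deviation of the fished-age abundance sum under additive
    recruitment noise.

    With independent recruitment deviations of standard deviation
    ``sigma_R_numeric`` (in numbers of recruits, not log units), each cohort
    entering age class 1 carries its deviation forward, discounted by
    natural survival; it joins the fished-age sum once it passes a_c.
    Summing the surviving variances,

        sigma_total(t) = sqrt( sum_{a=0..t} (sigma e^{-M (a + a_c - 1)})^2 ).

    The exponent offset follows the package's recruit-at-age-1 indexing
    (a cohort counted at age a has survived a-1 years); it is validated
    against a direct simulation ensemble in the test suite. Monotone
    nondecreasing in t and convergent as t grows.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    a = np.arange(0, t + 1)
    terms = (sigma_R_numeric * np.exp(-params.M * (a + params.a_c - 1))) ** 2
    return float(np.sqrt(terms.sum()))


def trajectory_frame(traj: Trajectory, species: str | None = None, run: int = 0):
    """Tidy export: one row per (t, age) with abundance."""
    import pandas as pd

    T1, n = traj.states.shape
    t_idx = np.repeat(np.arange(T1), n)
    ages = np.tile(np.arange(1, n + 1), T1)
    return pd.DataFrame(
        {
            "species": species or traj.params.name,
            "scenario": traj.scenario,
            "run": run,
            "t": t_idx,
            "age": ages,
            "abundance": traj.states.ravel(),
        }
    )
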