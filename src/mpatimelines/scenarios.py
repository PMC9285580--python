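"""Synthetic scenarios: stochastic recruitment series and random species.

The recruitment generator reproduces the study's noise structure —
interannually independent lognormal deviates around a constant level (500
recruits by default; ratios are insensitive to the level). The random
species generator draws parameter sets uniformly within the envelope of
the bundled 19-species table, for property-based testing of the model
invariants beyond the fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .open_model import DEFAULT_MEAN_RECRUITS, RecruitmentSeries
from .species import SpeciesParams, SpeciesValidationError, load_species_table

_RANGE_FIELDS = [
    "max_age", "L_mat", "L_c", "M", "F", "L_inf", "k",
    "a_0", "a_m", "a_c", "p", "w", "sigma_R",
]
_INT_FIELDS = {"max_age", "a_m", "a_c"}


def table_envelope() -> dict[str, tuple[float, float]]:
    """Per-field (min, max) bounds over the bundled species table."""
    table = load_species_table()
    out = {}
    for f in _RANGE_FIELDS:
        vals = [getattr(s, f) for s in table]
        out[f] = (min(vals), max(vals))
    return out


@dataclass(frozen=True)
class ScenarioConfig:
    """Simulation settings: recruitment level/noise, horizon, replication."""

    mean_recruits: float = DEFAULT_MEAN_RECRUITS
    sigma_R: float = 0.0
    T: int = 50
    n_runs: int = 500
    seed: int = 1
    parameter_ranges: dict | None = None

    def __post_init__(self):
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.sigma_R < 0:
            raise ValueError("sigma_R must be >= 0")


def lognormal_recruitment(config: ScenarioConfig) -> RecruitmentSeries:
    """Annual recruitment ``mean_recruits * exp(G_t)``, G_t ~ N(0, sigma_R).

    A constant series when ``sigma_R = 0``; reproducible from the seed.
    """
    if config.sigma_R > 0:
        rng = np.random.default_rng(config.seed)
        vals = config.mean_recruits * np.exp(
            rng.normal(0.0, config.sigma_R, config.T)
        )
    else:
        vals = np.full(config.T, config.mean_recruits)
    return RecruitmentSeries(vals, config.mean_recruits, config.sigma_R, config.seed)


def random_species(
    config: ScenarioConfig, count: int, max_tries: int = 1000
) -> list[SpeciesParams]:
    """Draw validated random species parameter sets.

    Each field is sampled uniformly (integers on integer fields) within
    ``config.parameter_ranges``, defaulting to the envelope of the bundled
    table; draws violating a parameter invariant (e.g. L_c >= L_inf, or
    a_m > max_age) are resampled.
    """
    ranges = dict(table_envelope())
    ranges.update(config.parameter_ranges or {})
    for f, (lo, hi) in ranges.items():
        if lo > hi:
            raise ValueError(f"infeasible bounds for {f}: ({lo}, {hi})")
    rng = np.random.default_rng(config.seed)
    out: list[SpeciesParams] = []
    for i in range(count):
        for _ in range(max_tries):
            kwargs = {"name": f"synthetic-{i}"}
            for f in _RANGE_FIELDS:
                lo, hi = ranges[f]
                if f in _INT_FIELDS:
                    kwargs[f] = int(rng.integers(int(lo), int(hi) + 1))
                else:
                    kwargs[f] = float(rng.uniform(lo, hi))
            # Cap the age fields at the drawn lifespan rather than rejecting.
            kwargs["a_m"] = min(kwargs["a_m"], kwargs["max_age"])
            kwargs["a_c"] = min(kwargs["a_c"], kwargs["max_age"])
            try:
                out.append(SpeciesParams(**kwargs))
                break
            except SpeciesValidationError:
                continue
        else:
            raise RuntimeError(
                f"could not draw a valid species within {max_tries} tries"
            )
    return out
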