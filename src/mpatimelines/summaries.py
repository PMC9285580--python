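"""Cross-species summaries and the regression battery.

One row per species collects the recovery-magnitude, timing, transient and
detectability metrics; a fixed battery of ordinary least-squares
regressions then relates them to life-history and fishery predictors
(F/M, 1/M, sigma_R), reproducing the cross-species analysis. The red sea
urchin — far heavier fishing relative to natural mortality than any fish
in the set — is a high-leverage point on every F/M axis, so the battery
refits the affected models with it excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import closed_model, detect, open_model
from .species import SpeciesParams

HIGH_LEVERAGE_SPECIES = "Red sea urchin"


@dataclass(frozen=True)
class SpeciesSummary:
    species: str
    final_abundance_ratio: float
    final_biomass_ratio: float
    fm_ratio: float
    inv_M: float
    time_to_95_abundance: int
    auc10_abundance: float
    auc10_biomass: float
    sigma_R: float
    theta_deg: float
    damping_ratio: float
    period_yr: float | None
    characteristic_time_yr: float


@dataclass(frozen=True)
class RegressionSummary:
    response: str
    predictor: str
    transform: str
    slope: float
    intercept: float
    r_squared: float
    n: int
    excluded: tuple[str, ...] = ()


def summarize_species(
    params: SpeciesParams,
    n_runs: int = detect.DEFAULT_N_RUNS,
    seed: int = 1,
    years=detect.DEFAULT_YEARS,
) -> SpeciesSummary:
    """All summary metrics for one species (open, closed and detectability)."""
    alpha = closed_model.calibrate_alpha(params)
    tm = closed_model.transient_metrics(params, alpha)
    auc_ab = detect.auc_timeline(params, years, "abundance_ratio", n_runs, seed)
    auc_bm = detect.auc_timeline(params, years, "biomass_ratio", n_runs, seed)
    T = params.max_age
    traj = open_model.project_open(
        params,
        open_model.fished_equilibrium(params),
        open_model.constant_recruitment(T),
        fished=False,
    )
    return SpeciesSummary(
        species=params.name,
        final_abundance_ratio=float(
            open_model.abundance_ratio_series(traj)[-1]
        ),
        final_biomass_ratio=float(open_model.biomass_ratio_series(traj)[-1]),
        fm_ratio=params.F / params.M,
        inv_M=1.0 / params.M,
        time_to_95_abundance=open_model.time_to_fraction(params, 0.95, "abundance"),
        auc10_abundance=auc_ab[10].auc,
        auc10_biomass=auc_bm[10].auc,
        sigma_R=params.sigma_R,
        theta_deg=tm.theta_deg,
        damping_ratio=tm.damping_ratio,
        period_yr=tm.period_yr,
        characteristic_time_yr=tm.characteristic_time_yr,
    )


def summarize_all(
    species: Sequence[SpeciesParams],
    n_runs: int = detect.DEFAULT_N_RUNS,
    seed: int = 1,
    years=detect.DEFAULT_YEARS,
) -> list[SpeciesSummary]:
    """One :class:`SpeciesSummary` per species, with shared settings."""
    out = []
    for sp in species:
        try:
            out.append(summarize_species(sp, n_runs=n_runs, seed=seed, years=years))
        except Exception as exc:  # re-raise with species context
            raise RuntimeError(f"summarizing {sp.name!r} failed: {exc}") from exc
    return out


def fit_linear(
    x,
    y,
    labels: Sequence[str] | None = None,
    exclude: Iterable[str] = (),
    response: str = "y",
    predictor: str = "x",
    transform: str = "identity",
) -> RegressionSummary:
    """Ordinary least squares of y on x with optional label-based exclusion."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    exclude = tuple(exclude)
    if exclude:
        if labels is None:
            raise ValueError("exclusion requires labels")
        keep = np.array([lab not in exclude for lab in labels])
        x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 points after exclusion")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    r2 = 0.0 if np.ptp(y) == 0 else float(model.rsquared)
    return RegressionSummary(
        response=response,
        predictor=predictor,
        transform=transform,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=r2,
        n=int(x.size),
        excluded=exclude,
    )


def regression_battery(
    summaries: Sequence[SpeciesSummary],
    exclude_species: str = HIGH_LEVERAGE_SPECIES,
    continuous_ratio: bool = True,
) -> list[RegressionSummary]:
    """The fixed battery of cross-species regressions.

    (a) time to 95% of final abundance ~ 1/M;
    (b) final abundance ratio ~ F/M, with and without the high-leverage
        species; (c) same for the final biomass ratio;
    (d) year-10 abundance AUC ~ sigma_R;
    (e) year-10 abundance AUC ~ final abundance ratio (the continuous form
        (M+F)/M = 1 + F/M by default; ``continuous_ratio=False`` uses the
        discrete simulated ratio), with and without the high-leverage
        species;
    (f) characteristic transient time 1/ln(rho) ~ 1/M;
    (g) characteristic transient time ~ time to 95% of final abundance.
    """
    labels = [s.species for s in summaries]
    fm = [s.fm_ratio for s in summaries]
    inv_m = [s.inv_M for s in summaries]
    ab = [s.final_abundance_ratio for s in summaries]
    bm = [s.final_biomass_ratio for s in summaries]
    t95 = [s.time_to_95_abundance for s in summaries]
    auc10 = [s.auc10_abundance for s in summaries]
    sr = [s.sigma_R for s in summaries]
    ct = [s.characteristic_time_yr for s in summaries]
    ratio_pred = (
        [1.0 + s.fm_ratio for s in summaries] if continuous_ratio else ab
    )

    def fit(x, y, response, predictor, transform="identity", excl=()):
        return fit_linear(
            x, y, labels=labels, exclude=excl,
            response=response, predictor=predictor, transform=transform,
        )

    out = [
        fit(inv_m, t95, "time_to_95_abundance", "M", "1/M"),
        fit(fm, ab, "final_abundance_ratio", "F/M"),
        fit(fm, ab, "final_abundance_ratio", "F/M", excl=(exclude_species,)),
        fit(fm, bm, "final_biomass_ratio", "F/M"),
        fit(fm, bm, "final_biomass_ratio", "F/M", excl=(exclude_species,)),
        fit(sr, auc10, "auc10_abundance", "sigma_R"),
        fit(ratio_pred, auc10, "auc10_abundance", "final_abundance_ratio"),
        fit(ratio_pred, auc10, "auc10_abundance", "final_abundance_ratio",
            excl=(exclude_species,)),
        fit(inv_m, ct, "characteristic_time_yr", "M", "1/M"),
        fit(t95, ct, "characteristic_time_yr", "time_to_95_abundance"),
    ]
    return out


def summaries_frame(summaries: Sequence[SpeciesSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def regressions_frame(regs: Sequence[RegressionSummary]) -> pd.DataFrame:
    rows = []
    for r in regs:
        d = dict(r.__dict__)
        d["excluded"] = ";".join(r.excluded)
        rows.append(d)
    return pd.DataFrame(rows)
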