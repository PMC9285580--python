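"""Species parameter sets and individual growth/weight conversions.

Each species is described by the life-history and fishery parameters that
drive the age-structured models: natural and fishing mortality rates
(``M``, ``F``, per year), von Bertalanffy growth (``L_inf``, ``k``, ``a_0``),
a length--weight power law (``p``, ``w``), ages at maturity and at first
capture (``a_m``, ``a_c``), the number of age classes (``max_age``) and the
log-scale recruitment variability ``sigma_R``.

Age-class convention used throughout the package: age classes run 1..max_age
and recruits enter age class 1.

A table of 19 California nearshore fishery species (rockfishes, lingcod,
cabezon, sheephead, kelp bass, red sea urchin, ...) ships with the package
and is returned by :func:`load_species_table` when no path is given.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column order of the species CSV schema (and of the bundled table).
CSV_COLUMNS = [
    "name", "max_age", "L_mat", "L_c", "M", "F", "L_inf", "k",
    "a_0", "a_m", "a_c", "p", "w", "sigma_R",
]

_INT_FIELDS = {"max_age", "a_m", "a_c"}


class SpeciesValidationError(ValueError):
    """A species parameter set violates a model invariant."""


@dataclass(frozen=True)
class SpeciesParams:
    """Life-history and fishery parameters for one species.

    Attributes
    ----------
    name : str
        Species label.
    max_age : int
        Number of age classes ``n``; ages run 1..max_age.
    L_mat, L_c : float
        Length at maturity and at first capture (cm). ``L_mat`` is carried
        for completeness; the models take ``a_m`` directly.
    M, F : float
        Instantaneous natural and pre-MPA fishing mortality (per year).
    L_inf, k, a_0 : float
        von Bertalanffy asymptotic length (cm), growth rate (per year) and
        hypothetical age at length zero (years; may be negative).
    a_m, a_c : int
        Age at maturity and age at first capture (years).
    p, w : float
        Length--weight coefficient and exponent (weight units implied by
        ``p``; all model outputs using weight are ratios, so units cancel).
    sigma_R : float
        Log-scale standard deviation of annual recruitment.
    """

    name: str
    max_age: int
    L_mat: float
    L_c: float
    M: float
    F: float
    L_inf: float
    k: float
    a_0: float
    a_m: int
    a_c: int
    p: float
    w: float
    sigma_R: float

    def __post_init__(self) -> None:
        def bad(msg: str) -> None:
            raise SpeciesValidationError(f"species {self.name!r}: {msg}")

        for f in fields(self):
            if f.name == "name":
                continue
            v = getattr(self, f.name)
            if not np.isfinite(v):
                bad(f"field {f.name} is not finite ({v!r})")
        if self.max_age < 1:
            bad(f"max_age must be >= 1, got {self.max_age}")
        if self.M <= 0:
            bad(f"M must be > 0, got {self.M}")
        if self.F < 0:
            bad(f"F must be >= 0, got {self.F}")
        if self.k <= 0 or self.L_inf <= 0:
            bad(f"k and L_inf must be > 0, got k={self.k}, L_inf={self.L_inf}")
        if self.p <= 0 or self.w <= 0:
            bad(f"p and w must be > 0, got p={self.p}, w={self.w}")
        if self.sigma_R < 0:
            bad(f"sigma_R must be >= 0, got {self.sigma_R}")
        if not (1 <= self.a_m <= self.max_age):
            bad(f"a_m must lie in 1..max_age, got {self.a_m}")
        if not (1 <= self.a_c <= self.max_age):
            bad(f"a_c must lie in 1..max_age, got {self.a_c}")
        if self.L_c >= self.L_inf:
            bad(f"L_c must be < L_inf, got L_c={self.L_c}, L_inf={self.L_inf}")

    @property
    def ages(self) -> np.ndarray:
        """Integer age classes 1..max_age."""
        return np.arange(1, self.max_age + 1)


def _builtin_path():
    return resources.files("mpatimelines.data") / "nearshore_species.csv"


def load_species_table(source: str | Path | None = None) -> list[SpeciesParams]:
    """Read a species parameter table from CSV.

    Parameters
    ----------
    source : path-like or None
        Path to a CSV with the :data:`CSV_COLUMNS` schema. ``None`` (or the
        string ``"builtin"``) loads the bundled 19-species California
        nearshore table.

    Returns
    -------
    list of SpeciesParams, in file order.

    Raises
    ------
    SpeciesValidationError
        Missing column, non-numeric cell, or invariant violation; the error
        names the offending species/row and field.
    """
    if source is None or source == "builtin":
        with resources.as_file(_builtin_path()) as path:
            df = pd.read_csv(path)
    else:
        df = pd.read_csv(source)

    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SpeciesValidationError(f"missing column(s): {', '.join(missing)}")
    unknown = [c for c in df.columns if c not in CSV_COLUMNS]
    if unknown:
        logger.warning("ignoring unknown column(s): %s", ", ".join(unknown))

    out = []
    for i, row in df.iterrows():
        label = str(row["name"])
        kwargs = {"name": label}
        for col in CSV_COLUMNS[1:]:
            val = row[col]
            try:
                fval = float(val)
            except (TypeError, ValueError):
                raise SpeciesValidationError(
                    f"row {i} ({label!r}): non-numeric value {val!r} in column {col}"
                ) from None
            if col in _INT_FIELDS:
                if fval != int(fval):
                    raise SpeciesValidationError(
                        f"row {i} ({label!r}): column {col} must be an integer, got {val!r}"
                    )
                kwargs[col] = int(fval)
            else:
                kwargs[col] = fval
        out.append(SpeciesParams(**kwargs))
    return out


def write_species_table(species: Iterable[SpeciesParams], path: str | Path) -> None:
    """Write species records to CSV in the standard column schema."""
    rows = [{c: getattr(s, c) for c in CSV_COLUMNS} for s in species]
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def length_at_age(params: SpeciesParams, a) -> np.ndarray | float:
    """von Bertalanffy length at age: ``L_a = L_inf (1 - exp(-k (a - a_0)))``.

    Clamped below at zero for ages younger than ``a_0``; approaches
    ``L_inf`` from below for large ``a``. Non-integer ages are allowed.
    """
    a = np.asarray(a, dtype=float)
    L = params.L_inf * (1.0 - np.exp(-params.k * (a - params.a_0)))
    return np.maximum(L, 0.0)[()] if L.ndim == 0 else np.maximum(L, 0.0)


def weight_at_age(params: SpeciesParams, a) -> np.ndarray | float:
    """Length--weight power law evaluated at age: ``W_a = p L_a^w``."""
    return params.p * np.asarray(length_at_age(params, a)) ** params.w


def weights_by_age(params: SpeciesParams) -> np.ndarray:
    """Weight at each integer age class 1..max_age."""
    return np.asarray(weight_at_age(params, params.ages), dtype=float)


def age_at_length(params: SpeciesParams, L: float) -> float:
    """Invert the von Bertalanffy curve: age at which length ``L`` is reached.

    ``a = a_0 - (1/k) ln(1 - L / L_inf)`` for ``0 <= L < L_inf``.

    Raises
    ------
    ValueError
        If ``L`` is negative or at/above the asymptote ``L_inf``.
    """
    if L < 0 or L >= params.L_inf:
        raise ValueError(
            f"length must satisfy 0 <= L < L_inf={params.L_inf}, got {L}"
        )
    return params.a_0 - math.log(1.0 - L / params.L_inf) / params.k


def age_at_length_rounded(params: SpeciesParams, L: float) -> int:
    """:func:`age_at_length` rounded to the nearest whole year (minimum 1).

    Convenience for deriving an age at first capture from a length limit;
    the bundled table carries tabulated ``a_c`` values directly.
    """
    return max(1, round(age_at_length(params, L)))


def get_species(species: Sequence[SpeciesParams], name: str) -> SpeciesParams:
    """Look up one species by exact name, with suggestions on failure."""
    for s in species:
        if s.name == name:
            return s
    names = ", ".join(s.name for s in species)
    raise KeyError(f"unknown species {name!r}; valid names: {names}")
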