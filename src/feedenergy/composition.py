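"""Nutrient-composition data model and basis algebra.

A feed's composition can be declared per kg of fresh material (*as-fed*) or
per kg of dry matter (*DM*). Every :class:`NutrientProfile` carries an
explicit basis flag, and all conversions go through :func:`convert_basis`;
operations elsewhere in the package refuse to mix bases silently, because
basis confusion is the dominant error source when ingredient tables from
different labs are combined.

The conversion is the standard one: a concentration ``x`` on the as-fed
basis equals ``x / (DM/100)`` on the DM basis, and vice versa. The dry-matter
percentage itself is basis-free (it is always "per kg fresh").
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import InsufficientDataError, InvalidProfileError, UndefinedStatisticError

__all__ = [
    "Basis",
    "NutrientProfile",
    "SummaryStats",
    "NUTRIENT_FIELDS",
    "convert_basis",
    "cv_summary",
    "panel_cv_table",
]


class Basis(str, enum.Enum):
    """Reporting basis for concentrations and energy densities."""

    AS_FED = "as_fed"
    DRY_MATTER = "dry_matter"

    @classmethod
    def coerce(cls, value: "Basis | str") -> "Basis":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            raise InvalidProfileError(f"unknown basis {value!r}") from None


#: Component fields scaled by a basis change (dm_pct is basis-free).
NUTRIENT_FIELDS = (
    "ash_pct",
    "ee_pct",
    "ndf_pct",
    "adf_pct",
    "cp_pct",
    "starch_pct",
)

# Starch + CP + EE + ash are (nearly) disjoint fractions; NDF/ADF overlap
# them and each other, so they are excluded from the closure check.
_CLOSURE_FIELDS = ("starch_pct", "cp_pct", "ee_pct", "ash_pct")
_CLOSURE_TOL = 1.0  # % units of slack on the mass-closure check


@dataclass(frozen=True)
class NutrientProfile:
    """Composition of one ingredient or diet on a declared basis.

    Percentages are on the printed 0–100 scale, never fractions. ``ge_mj_per_kg``
    is gross energy in MJ per kg of material *on the declared basis*.
    """

    name: str
    basis: Basis
    dm_pct: float
    ash_pct: float
    ee_pct: float
    ndf_pct: float
    adf_pct: float
    cp_pct: float
    starch_pct: float
    ge_mj_per_kg: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "basis", Basis.coerce(self.basis))
        if not (0.0 < self.dm_pct <= 100.0):
            raise InvalidProfileError(
                f"{self.name}: dm_pct must be in (0, 100], got {self.dm_pct}"
            )
        for field in NUTRIENT_FIELDS:
            value = getattr(self, field)
            if not (0.0 <= value <= 100.0) or math.isnan(value):
                raise InvalidProfileError(
                    f"{self.name}: {field} must be in [0, 100], got {value}"
                )
        if not self.ge_mj_per_kg > 0.0:
            raise InvalidProfileError(
                f"{self.name}: ge_mj_per_kg must be > 0, got {self.ge_mj_per_kg}"
            )
        if self.basis is Basis.DRY_MATTER:
            closure = sum(getattr(self, f) for f in _CLOSURE_FIELDS)
            if closure > 100.0 + _CLOSURE_TOL:
                raise InvalidProfileError(
                    f"{self.name}: starch+CP+EE+ash = {closure:.2f}% exceeds 100% "
                    "on the DM basis"
                )

    def nutrient(self, key: str) -> float:
        """Concentration (%) of a nutrient by short name (ash, EE, NDF, ADF, CP, starch)."""
        attr = _SHORT_NAMES.get(key.lower())
        if attr is None:
            raise KeyError(f"unknown nutrient {key!r}")
        return getattr(self, attr)


_SHORT_NAMES = {
    "ash": "ash_pct",
    "ee": "ee_pct",
    "ndf": "ndf_pct",
    "adf": "adf_pct",
    "cp": "cp_pct",
    "starch": "starch_pct",
    "dm": "dm_pct",
    "ge": "ge_mj_per_kg",
}


def convert_basis(profile: NutrientProfile, target: Basis | str) -> NutrientProfile:
    """Re-express a profile on ``target`` basis.

    Going to as-fed multiplies every concentration and GE by ``dm_pct/100``;
    going to dry matter divides. ``dm_pct`` and the name are unchanged. The
    round trip reproduces the original to floating-point accuracy.
    """
    target = Basis.coerce(target)
    if profile.dm_pct <= 0:
        raise InvalidProfileError(f"{profile.name}: dm_pct must be positive")
    if target is profile.basis:
        return profile
    dm_frac = profile.dm_pct / 100.0
    factor = dm_frac if target is Basis.AS_FED else 1.0 / dm_frac
    updates = {f: getattr(profile, f) * factor for f in NUTRIENT_FIELDS}
    updates["ge_mj_per_kg"] = profile.ge_mj_per_kg * factor
    updates["basis"] = target
    return replace(profile, **updates)


@dataclass(frozen=True)
class SummaryStats:
    """n, mean, sample SD (n−1 denominator) and CV% of one variable."""

    n: int
    mean: float
    sd: float
    cv_pct: float


def cv_summary(values: Sequence[float] | np.ndarray) -> SummaryStats:
    """Descriptive summary with the coefficient of variation, CV% = 100·SD/mean.

    SD uses the sample (n−1) denominator. Raises for n < 2 or a zero mean,
    where the CV is undefined.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    n = arr.size
    if n < 2:
        raise InsufficientDataError(f"CV needs at least 2 values, got {n}")
    mean = float(arr.mean())
    if mean == 0.0:
        raise UndefinedStatisticError("CV is undefined for a zero-mean vector")
    sd = float(arr.std(ddof=1))
    return SummaryStats(n=n, mean=mean, sd=sd, cv_pct=100.0 * sd / abs(mean))


def panel_cv_table(profiles: Iterable[NutrientProfile], fields: Sequence[str] | None = None):
    """CV summaries across an ingredient panel, one row per composition field.

    All profiles must share a basis. Returns a pandas DataFrame indexed by
    field with columns n/mean/sd/cv_pct.
    """
    import pandas as pd

    from .errors import BasisMismatchError

    profiles = list(profiles)
    if not profiles:
        raise InsufficientDataError("empty panel")
    bases = {p.basis for p in profiles}
    if len(bases) > 1:
        raise BasisMismatchError(f"panel mixes bases: {sorted(b.value for b in bases)}")
    if fields is None:
        fields = ("dm_pct",) + NUTRIENT_FIELDS + ("ge_mj_per_kg",)
    rows = {}
    for field in fields:
        stats = cv_summary([getattr(p, field) for p in profiles])
        rows[field] = {"n": stats.n, "mean": stats.mean, "sd": stats.sd, "cv_pct": stats.cv_pct}
    return pd.DataFrame.from_dict(rows, orient="index")
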