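"""Energy-balance arithmetic for total-collection digestibility trials.

A *balance record* is one pig × period measurement set: dry-matter feed
intake and fecal output over the collection window together with the gross
energy of feed, feces and urine, and nutrient concentrations of diet and
feces. From it follow, in order:

* diet digestible energy        DE = (GE_i − GE_f) / FI           (MJ/kg DM)
* diet metabolizable energy     ME = (GE_i − GE_f − GE_u) / FI    (MJ/kg DM)
* diet apparent digestibility   ATTD = (N_d·FI − N_f·FO)/(N_d·FI) (fraction of
  an ingested nutrient not recovered in feces, reported in %)

Diet-level values carry no inclusion correction; the division by the
energy-bearing inclusion (e.g. 0.974) happens only at the ingredient step
(:func:`ingredient_energy_direct`). Under this convention diet and
ingredient tables are mutually consistent.

The difference method supports two algebraic readings:

* ``"as_printed"`` — the formula as trial reports commonly print it:
  DE_ingredient = (DE_d − DE_basal·(1 − r)) / f_test, with DE_d and DE_basal
  the inclusion-corrected test and basal diet values and r the replacement
  fraction.
* ``"contribution"`` — the energy-contribution balance:
  DE_ingredient = (DE_testdiet − w_basal·DE_basal_ingredient) / w_test, the
  exact inverse of inclusion-weighted mixing.

Neither is a library default: callers state the mode. (The command-line
pipeline defaults to ``contribution`` and logs the choice.)

Energy is MJ throughout; kcal inputs are converted at ingest
(1 kcal = 4.184 kJ).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

from .composition import Basis
from .errors import InvalidRecordError, UndefinedStatisticError
from .formulation import DifferenceDesign

__all__ = [
    "KCAL_TO_MJ",
    "BalanceRecord",
    "EnergyResult",
    "DigestibilityResult",
    "DifferenceMode",
    "diet_energy",
    "ingredient_energy_direct",
    "ingredient_energy_difference",
    "diet_attd",
    "ingredient_attd_direct",
    "ingredient_attd_difference",
    "round_half_up",
]

#: Thermochemical calorie: 1 kcal = 4.184 kJ = 0.004184 MJ.
KCAL_TO_MJ = 4.184e-3


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed tables do (not banker's)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class DifferenceMode(str, enum.Enum):
    AS_PRINTED = "as_printed"
    CONTRIBUTION = "contribution"


@dataclass(frozen=True)
class BalanceRecord:
    """One pig × period total-collection measurement set.

    Masses are kg DM summed over the collection window; energies are MJ over
    the same window. ``diet_nutrient_pct`` / ``feces_nutrient_pct`` hold
    nutrient concentrations (% of DM) keyed by short nutrient name
    (DM, CP, NDF, ADF, ash, EE, ...).
    """

    pig_id: str
    period: int
    diet_name: str
    feed_intake_kg: float
    feces_output_kg: float
    ge_intake_mj: float
    ge_feces_mj: float
    ge_urine_mj: float
    diet_nutrient_pct: Mapping[str, float] = field(default_factory=dict)
    feces_nutrient_pct: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "diet_nutrient_pct", dict(self.diet_nutrient_pct))
        object.__setattr__(self, "feces_nutrient_pct", dict(self.feces_nutrient_pct))
        for name in ("feces_output_kg", "ge_intake_mj", "ge_feces_mj", "ge_urine_mj"):
            v = getattr(self, name)
            if v < 0 or math.isnan(v):
                raise InvalidRecordError(f"{self.pig_id}/p{self.period}: {name} = {v} < 0")
        if not self.feed_intake_kg > 0:
            raise InvalidRecordError(
                f"{self.pig_id}/p{self.period}: feed_intake_kg must be > 0, "
                f"got {self.feed_intake_kg}"
            )

    def physical_flags(self) -> list[str]:
        """Soft validation: physically impossible records are flagged, not dropped."""
        flags = []
        if self.ge_feces_mj + self.ge_urine_mj > self.ge_intake_mj:
            flags.append("energy_output_exceeds_intake")
        if self.feces_output_kg > self.feed_intake_kg:
            flags.append("fecal_dm_exceeds_intake_dm")
        return flags


@dataclass(frozen=True)
class EnergyResult:
    """DE/ME of a diet or ingredient on a declared basis (MJ/kg)."""

    level: str  # "diet" | "ingredient"
    name: str
    basis: Basis
    de_mj_per_kg: float
    me_mj_per_kg: float
    flags: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "basis", Basis.coerce(self.basis))
        if self.level not in ("diet", "ingredient"):
            raise ValueError(f"level must be diet|ingredient, got {self.level!r}")

    @property
    def me_de_ratio_pct(self) -> float:
        """ME as % of DE; ≈96–99 % in cereals (urinary loss is small)."""
        return 100.0 * self.me_mj_per_kg / self.de_mj_per_kg

    def to_basis(self, target: Basis | str, dm_pct: float) -> "EnergyResult":
        """Re-express on ``target`` basis given the material's DM %."""
        target = Basis.coerce(target)
        if target is self.basis:
            return self
        dm_frac = dm_pct / 100.0
        factor = dm_frac if target is Basis.AS_FED else 1.0 / dm_frac
        return replace(
            self,
            basis=target,
            de_mj_per_kg=self.de_mj_per_kg * factor,
            me_mj_per_kg=self.me_mj_per_kg * factor,
        )


@dataclass(frozen=True)
class DigestibilityResult:
    """Apparent total tract digestibility (%) of one nutrient."""

    level: str
    name: str
    nutrient: str
    attd_pct: float
    flags: tuple = ()


def diet_energy(record: BalanceRecord) -> EnergyResult:
    """Diet DE and ME from one balance record (DM basis, MJ/kg).

    DE = (GE_i − GE_f)/FI, ME = (GE_i − GE_f − GE_u)/FI. An ME > DE (only
    possible through data errors, since ME subtracts one more loss) or a
    non-positive DE is flagged, never silently repaired.
    """
    de = (record.ge_intake_mj - record.ge_feces_mj) / record.feed_intake_kg
    me = (record.ge_intake_mj - record.ge_feces_mj - record.ge_urine_mj) / record.feed_intake_kg
    flags = []
    if me > de:
        flags.append("me_exceeds_de")
    if de <= 0:
        flags.append("nonpositive_de")
    return EnergyResult(
        level="diet",
        name=record.diet_name,
        basis=Basis.DRY_MATTER,
        de_mj_per_kg=de,
        me_mj_per_kg=me,
        flags=tuple(flags),
    )


def ingredient_energy_direct(
    diet_result: EnergyResult, inclusion: float, ingredient_name: str | None = None
) -> EnergyResult:
    """Direct method: ingredient value = diet value / energy-bearing inclusion.

    ``inclusion`` is a fraction in (0, 1]; the ME/DE ratio is preserved. The
    result stays on the diet result's basis.
    """
    if not (0.0 < inclusion <= 1.0):
        raise ValueError(f"inclusion must be in (0, 1], got {inclusion}")
    return replace(
        diet_result,
        level="ingredient",
        name=ingredient_name or diet_result.name,
        de_mj_per_kg=diet_result.de_mj_per_kg / inclusion,
        me_mj_per_kg=diet_result.me_mj_per_kg / inclusion,
    )


def _basal_ingredient_energy(design: DifferenceDesign) -> EnergyResult:
    if design.basal_ingredient_energy is not None:
        return design.basal_ingredient_energy
    if design.basal_diet_energy is None:
        raise ValueError(
            "difference design carries neither basal ingredient nor basal diet energy"
        )
    return ingredient_energy_direct(design.basal_diet_energy, design.direct_fraction)


def ingredient_energy_difference(
    test_diet_result: EnergyResult,
    design: DifferenceDesign,
    mode: DifferenceMode | str,
    weights: tuple[float, float] | None = None,
) -> EnergyResult:
    """Difference method: solve the test ingredient's DE/ME from two diets.

    ``mode`` must be given explicitly (see module docstring). In
    ``contribution`` mode, ``weights`` override the as-fed
    (basal_inclusion, test_inclusion) pair — required on the DM basis, where
    mixing weights are DM-mass shares (see
    :meth:`~feedenergy.formulation.DifferenceDesign.dm_basis_weights`).
    A negative solution (possible with noisy inputs) is flagged and returned.
    """
    mode = DifferenceMode(mode)
    if mode is DifferenceMode.AS_PRINTED:
        basal = design.basal_diet_energy
        if basal is None:
            raise ValueError("as_printed mode needs the basal diet energy")
        if basal.basis is not test_diet_result.basis:
            from .errors import BasisMismatchError

            raise BasisMismatchError(
                f"basal diet on {basal.basis.value}, test diet on "
                f"{test_diet_result.basis.value}"
            )
        keep = 1.0 - design.replacement_fraction
        f_dir = design.direct_fraction
        de = (
            test_diet_result.de_mj_per_kg / f_dir
            - (basal.de_mj_per_kg / f_dir) * keep
        ) / design.test_inclusion
        me = (
            test_diet_result.me_mj_per_kg / f_dir
            - (basal.me_mj_per_kg / f_dir) * keep
        ) / design.test_inclusion
    else:
        basal_ing = _basal_ingredient_energy(design)
        if basal_ing.basis is not test_diet_result.basis:
            from .errors import BasisMismatchError

            raise BasisMismatchError(
                f"basal ingredient on {basal_ing.basis.value}, test diet on "
                f"{test_diet_result.basis.value}"
            )
        w_b, w_t = weights if weights is not None else (
            design.basal_inclusion,
            design.test_inclusion,
        )
        if w_t <= 0:
            raise ValueError(f"test-ingredient weight must be > 0, got {w_t}")
        de = (test_diet_result.de_mj_per_kg - w_b * basal_ing.de_mj_per_kg) / w_t
        me = (test_diet_result.me_mj_per_kg - w_b * basal_ing.me_mj_per_kg) / w_t
    flags = list(test_diet_result.flags)
    if de <= 0 or me <= 0:
        flags.append("nonpositive_difference_estimate")
    return EnergyResult(
        level="ingredient",
        name=design.test_ingredient,
        basis=test_diet_result.basis,
        de_mj_per_kg=de,
        me_mj_per_kg=me,
        flags=tuple(flags),
    )


def diet_attd(record: BalanceRecord, nutrient: str) -> DigestibilityResult:
    """Apparent total tract digestibility of one nutrient at the diet level.

    ATTD% = 100·(N_d·FI − N_f·FO)/(N_d·FI) with N the % concentration in
    diet and feces DM and FI/FO the DM mass flows.
    """
    try:
        n_d = record.diet_nutrient_pct[nutrient]
    except KeyError:
        raise UndefinedStatisticError(
            f"{record.diet_name}: no diet concentration for {nutrient!r}"
        ) from None
    if n_d <= 0:
        raise UndefinedStatisticError(
            f"{record.diet_name}: ATTD of {nutrient} undefined at zero diet concentration"
        )
    n_f = record.feces_nutrient_pct.get(nutrient, 0.0)
    intake = n_d * record.feed_intake_kg
    excreted = n_f * record.feces_output_kg
    attd = 100.0 * (intake - excreted) / intake
    flags = ("negative_attd",) if attd < 0 else ()
    return DigestibilityResult(
        level="diet",
        name=record.diet_name,
        nutrient=nutrient,
        attd_pct=attd,
        flags=flags,
    )


def ingredient_attd_direct(
    diet_result: DigestibilityResult,
    nutrient_share: float = 1.0,
    ingredient_name: str | None = None,
) -> DigestibilityResult:
    """Direct method for digestibility.

    ``nutrient_share`` is the fraction of the diet's nutrient supplied by the
    test ingredient. For organic nutrients carried only by the cereal the
    share is 1 and the ingredient inherits the diet ATTD unchanged; for dry
    matter, where the mineral filler contributes indigestible mass, the share
    is the cereal's DM fraction of the diet.
    """
    if not (0.0 < nutrient_share <= 1.0):
        raise ValueError(f"nutrient_share must be in (0, 1], got {nutrient_share}")
    attd = diet_result.attd_pct / nutrient_share
    return replace(
        diet_result,
        level="ingredient",
        name=ingredient_name or diet_result.name,
        attd_pct=attd,
    )


def ingredient_attd_difference(
    test_diet_result: DigestibilityResult,
    basal_ingredient_result: DigestibilityResult,
    basal_contribution: float,
    test_contribution: float,
    diet_concentration: float | None = None,
    ingredient_name: str | None = None,
) -> DigestibilityResult:
    """Difference method for digestibility via nutrient contributions.

    ``basal_contribution`` and ``test_contribution`` are the amounts of the
    nutrient that the retained basal cereal and the test ingredient each
    contribute per kg of test diet (weight × ingredient concentration, any
    common unit). ``diet_concentration`` is the diet's total concentration in
    the same unit; it defaults to the sum of the two contributions, but must
    be given when a third component carries the nutrient indigestibly (e.g.
    mineral-filler dry matter). Solving the contribution balance:

        ATTD_test = (ATTD_diet·N_diet − ATTD_basal·c_b) / c_t

    Estimates may fall outside [0, 100] with noisy inputs; they are flagged
    and returned, never truncated.
    """
    if test_contribution <= 0:
        raise UndefinedStatisticError(
            f"{test_diet_result.nutrient}: test ingredient contributes no nutrient"
        )
    if basal_contribution < 0:
        raise ValueError("basal_contribution must be >= 0")
    total = (
        diet_concentration
        if diet_concentration is not None
        else basal_contribution + test_contribution
    )
    attd = (
        test_diet_result.attd_pct * total
        - basal_ingredient_result.attd_pct * basal_contribution
    ) / test_contribution
    flags = ("attd_outside_0_100",) if not (0.0 <= attd <= 100.0) else ()
    return DigestibilityResult(
        level="ingredient",
        name=ingredient_name or test_diet_result.name,
        nutrient=test_diet_result.nutrient,
        attd_pct=attd,
        flags=flags,
    )
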