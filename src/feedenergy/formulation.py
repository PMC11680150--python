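"""Diet recipes and the replacement geometry of ingredient evaluation.

Two evaluation geometries are supported:

* **Direct method** — a diet whose only energy-bearing ingredient is the test
  cereal (plus a small mineral/vitamin filler). The ingredient value is the
  diet value divided by the energy-bearing inclusion fraction.
* **Difference method** — a known as-fed fraction of the basal cereal is
  replaced by the test ingredient; the test ingredient's value is solved from
  the basal and test diets.

Mineral fillers (premix, limestone, dicalcium phosphate, salt) are modelled
as zero-energy, zero-organic-nutrient carriers by default: the trials this
package targets never assign them nutrient values. An optional filler-ash
table can refine diet ash only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping

from .composition import Basis, NutrientProfile, convert_basis
from .errors import BasisMismatchError, DesignError, UnknownIngredientError

if TYPE_CHECKING:  # pragma: no cover
    from .balance import EnergyResult

__all__ = [
    "FormulationSpec",
    "DifferenceDesign",
    "expected_diet_profile",
    "direct_inclusion_fraction",
    "dm_share_weights",
    "nutrient_contributions",
]

_SUM_TOL = 1e-6


@dataclass(frozen=True)
class FormulationSpec:
    """One diet recipe: as-fed inclusion percentages plus the energy-bearing set.

    ``inclusions`` map ingredient name → as-fed % and must sum to 100.
    ``energy_bearing`` lists the ingredients treated as energy/nutrient
    contributors (cereals, oilseed meals); everything else is filler.
    """

    diet_name: str
    inclusions: Mapping[str, float]
    energy_bearing: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "inclusions", dict(self.inclusions))
        object.__setattr__(self, "energy_bearing", frozenset(self.energy_bearing))
        total = sum(self.inclusions.values())
        if abs(total - 100.0) > _SUM_TOL:
            raise DesignError(
                f"{self.diet_name}: inclusions sum to {total}, expected 100"
            )
        missing = self.energy_bearing - self.inclusions.keys()
        if missing:
            raise DesignError(
                f"{self.diet_name}: energy-bearing ingredients {sorted(missing)} "
                "not present in the recipe"
            )

    def energy_bearing_inclusions(self) -> dict[str, float]:
        return {k: v for k, v in self.inclusions.items() if k in self.energy_bearing}


def direct_inclusion_fraction(spec: FormulationSpec) -> float:
    """Fraction (0–1) of the diet made up of energy-bearing ingredients.

    This is the divisor of the direct method (0.974 in a 97.4 % cereal diet).
    """
    return sum(spec.energy_bearing_inclusions().values()) / 100.0


def expected_diet_profile(
    spec: FormulationSpec,
    panel: Mapping[str, NutrientProfile],
    filler_ash_pct: Mapping[str, float] | None = None,
) -> NutrientProfile:
    """Inclusion-weighted as-fed composition of a diet.

    Energy-bearing ingredients must all be present in ``panel`` on a common
    basis; they are converted to as-fed before mixing. Fillers contribute
    dry matter (taken as 100 % DM mineral matter) and, optionally, ash via
    ``filler_ash_pct`` (name → ash % as-fed), but no organic nutrients or GE.
    """
    filler_ash_pct = filler_ash_pct or {}
    profiles: dict[str, NutrientProfile] = {}
    bases = set()
    for name in spec.energy_bearing:
        if name not in panel:
            raise UnknownIngredientError(
                f"{spec.diet_name}: no composition for ingredient {name!r}"
            )
        bases.add(panel[name].basis)
    if len(bases) > 1:
        raise BasisMismatchError(
            f"{spec.diet_name}: ingredient panel mixes bases "
            f"{sorted(b.value for b in bases)}"
        )
    for name in spec.energy_bearing:
        profiles[name] = convert_basis(panel[name], Basis.AS_FED)

    totals = {f: 0.0 for f in ("ash_pct", "ee_pct", "ndf_pct", "adf_pct", "cp_pct", "starch_pct")}
    ge = 0.0
    dm = 0.0
    # sorted order: the mixture is bit-identical under recipe permutation
    for name, incl_pct in sorted(spec.inclusions.items()):
        w = incl_pct / 100.0
        if name in spec.energy_bearing:
            p = profiles[name]
            for f in totals:
                totals[f] += w * getattr(p, f)
            ge += w * p.ge_mj_per_kg
            dm += w * p.dm_pct
        else:
            dm += w * 100.0  # mineral fillers are essentially moisture-free
            totals["ash_pct"] += w * filler_ash_pct.get(name, 0.0)
    return NutrientProfile(
        name=spec.diet_name,
        basis=Basis.AS_FED,
        dm_pct=min(dm, 100.0),  # guard summation round-off at the 100 % bound
        ge_mj_per_kg=ge,
        **totals,
    )


def dm_share_weights(
    spec: FormulationSpec, panel: Mapping[str, NutrientProfile]
) -> dict[str, float]:
    """Each ingredient's share of the diet's dry matter (fillers count as 100 % DM).

    These are the mixing weights of every DM-basis quantity: a diet value per
    kg DM is the share-weighted sum of ingredient values per kg DM.
    """
    dm = {}
    for name, incl_pct in spec.inclusions.items():
        if name in spec.energy_bearing:
            if name not in panel:
                raise UnknownIngredientError(f"{spec.diet_name}: no composition for {name!r}")
            dm[name] = incl_pct * panel[name].dm_pct
        else:
            dm[name] = incl_pct * 100.0
    total = sum(dm.values())
    return {name: v / total for name, v in dm.items()}


def nutrient_contributions(
    spec: FormulationSpec,
    panel: Mapping[str, NutrientProfile],
    nutrient: str,
) -> dict[str, float]:
    """Nutrient amount (% of diet DM units) each ingredient contributes.

    ``nutrient`` uses short names; ``"DM"`` means dry matter itself, where
    every component (including filler) contributes at concentration 100.
    The values sum to the diet's expected concentration on the DM basis.
    Panel profiles may be on either basis; concentrations are taken per kg
    ingredient DM.
    """
    weights = dm_share_weights(spec, panel)
    out = {}
    for name, w in weights.items():
        if nutrient.lower() == "dm":
            out[name] = w * 100.0
        elif name in spec.energy_bearing:
            conc = convert_basis(panel[name], Basis.DRY_MATTER).nutrient(nutrient)
            out[name] = w * conc
        else:
            out[name] = 0.0
    return out


@dataclass(frozen=True)
class DifferenceDesign:
    """Replacement geometry linking a basal diet and a test diet.

    ``replacement_fraction`` is the share of the basal diet's cereal replaced
    by the test ingredient (0.40 in a 40 % substitution); ``test_inclusion``
    and ``basal_inclusion`` are the as-fed fractions of the *test diet* that
    are test ingredient and retained basal cereal (0.3896 and 0.5844 for a
    97.4 % cereal core); ``direct_fraction`` is the basal diet's energy-bearing
    inclusion (0.974). ``basal_diet_energy`` carries the basal diet's measured
    DE/ME so the difference formulas can be applied; ``basal_ingredient_energy``
    may be supplied directly, otherwise it is derived by the direct method.
    """

    basal_diet: str
    test_diet: str
    test_ingredient: str
    replacement_fraction: float = 0.40
    test_inclusion: float = 0.3896
    basal_inclusion: float = 0.5844
    direct_fraction: float = 0.974
    basal_diet_energy: "EnergyResult | None" = None
    basal_ingredient_energy: "EnergyResult | None" = None

    def __post_init__(self) -> None:
        if not (0.0 < self.replacement_fraction < 1.0):
            raise DesignError(
                f"replacement_fraction must be in (0,1), got {self.replacement_fraction}"
            )
        if not (0.0 < self.test_inclusion < 1.0):
            raise DesignError(f"test_inclusion must be in (0,1), got {self.test_inclusion}")
        expected = self.direct_fraction * self.replacement_fraction
        if abs(self.test_inclusion - expected) > 1e-9:
            raise DesignError(
                f"test_inclusion {self.test_inclusion} inconsistent with "
                f"direct_fraction × replacement_fraction = {expected}"
            )

    @classmethod
    def from_formulations(
        cls,
        basal: FormulationSpec,
        test: FormulationSpec,
        test_ingredient: str,
        **kwargs,
    ) -> "DifferenceDesign":
        """Derive the geometry from two recipes sharing a basal cereal."""
        if test_ingredient not in test.energy_bearing:
            raise DesignError(
                f"{test_ingredient!r} is not energy-bearing in {test.diet_name}"
            )
        f_dir = direct_inclusion_fraction(basal)
        f_test = test.inclusions[test_ingredient] / 100.0
        f_basal = sum(
            v for k, v in test.energy_bearing_inclusions().items() if k != test_ingredient
        ) / 100.0
        return cls(
            basal_diet=basal.diet_name,
            test_diet=test.diet_name,
            test_ingredient=test_ingredient,
            replacement_fraction=f_test / f_dir,
            test_inclusion=f_test,
            basal_inclusion=f_basal,
            direct_fraction=f_dir,
            **kwargs,
        )

    def dm_basis_weights(
        self,
        test_spec: FormulationSpec,
        panel: Mapping[str, NutrientProfile],
    ) -> tuple[float, float]:
        """(basal cereal, test ingredient) shares of the test diet's dry matter.

        On the DM basis the difference method must weight by DM mass, not
        as-fed inclusion. Fillers count as 100 % DM.
        """
        diet = expected_diet_profile(test_spec, panel)
        basal_names = [
            k for k in test_spec.energy_bearing if k != self.test_ingredient
        ]
        if len(basal_names) != 1:
            raise DesignError(
                f"{test_spec.diet_name}: expected exactly one retained basal cereal, "
                f"got {basal_names}"
            )
        basal_dm = convert_basis(panel[basal_names[0]], Basis.AS_FED).dm_pct
        test_dm = convert_basis(panel[self.test_ingredient], Basis.AS_FED).dm_pct
        w_b = self.basal_inclusion * basal_dm / diet.dm_pct
        w_t = self.test_inclusion * test_dm / diet.dm_pct
        return w_b, w_t
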