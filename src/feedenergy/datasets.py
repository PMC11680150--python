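"""Bundled reference panel: a 13-cereal growing-pig digestibility benchmark.

The package ships one complete reference dataset — 5 corn, 2 wheat and 6 rice
samples with measured chemical compositions (DM basis), the 13 experimental
diet recipes (11 direct-method diets with the cereal at 97.4 % plus mineral
filler; two difference-method diets in which rice 5 or rice 6 replaces 40 %
of the corn 5 cereal core), measured diet- and ingredient-level DE/ME and
nutrient digestibilities, and the four published-style prediction equations.

These values serve three purposes: worked examples, the default truth preset
of the synthetic-trial generator (so simulated data are magnitude-realistic),
and documentation of which printed summary values do and do not reconcile
internally (see the notes on individual constants).
"""

from __future__ import annotations

from functools import lru_cache

import pandas as pd

from .composition import Basis, NutrientProfile
from .formulation import DifferenceDesign, FormulationSpec
from .modeling import PredictionEquation
from .synthetic import TrueIngredientParams

__all__ = [
    "INGREDIENTS",
    "FILLER_INCLUSIONS",
    "REFERENCE_CV_PCT",
    "cereal_panel",
    "trial_diets",
    "difference_designs",
    "diet_energy_reference",
    "ingredient_energy_reference",
    "ingredient_attd_reference",
    "default_true_params",
    "reference_equations",
]

INGREDIENTS = (
    "corn 1", "corn 2", "corn 3", "corn 4", "corn 5",
    "wheat 1", "wheat 2",
    "rice 1", "rice 2", "rice 3", "rice 4", "rice 5", "rice 6",
)

# Chemical compositions, % of DM (GE in MJ/kg DM); DM itself is % of fresh.
_COMPOSITION = {
    #            DM     ash   EE     NDF    ADF    CP     starch GE
    "corn 1":  (87.01, 1.36, 3.62, 12.94, 3.42, 8.11, 65.85, 18.43),
    "corn 2":  (88.11, 1.37, 4.35, 11.62, 2.80, 8.89, 66.54, 18.50),
    "corn 3":  (86.16, 1.65, 2.74, 13.33, 3.25, 9.30, 64.78, 18.22),
    "corn 4":  (86.91, 1.79, 3.01, 11.55, 2.31, 8.98, 67.77, 18.37),
    "corn 5":  (86.58, 1.18, 2.97, 7.18, 1.60, 12.63, 68.34, 18.58),
    "wheat 1": (89.28, 1.93, 1.34, 14.84, 3.50, 16.25, 57.52, 18.41),
    "wheat 2": (87.95, 1.73, 1.30, 19.51, 3.62, 16.14, 53.43, 18.28),
    "rice 1":  (86.86, 1.46, 2.75, 6.74, 1.78, 9.35, 71.45, 18.32),
    "rice 2":  (87.49, 4.44, 1.59, 16.01, 10.78, 8.27, 61.76, 17.92),
    "rice 3":  (89.80, 4.20, 16.12, 18.19, 7.61, 16.13, 37.53, 21.20),
    "rice 4":  (88.70, 1.94, 3.58, 18.04, 3.95, 9.31, 59.22, 18.31),
    "rice 5":  (88.85, 5.40, 2.02, 22.23, 14.76, 7.88, 54.48, 17.84),
    "rice 6":  (89.09, 5.55, 1.74, 27.65, 14.80, 7.88, 49.45, 17.72),
}

#: Reference CV column of the composition table, % . The starch and GE
#: entries are NOT consistent with the 13 stated values (recomputation gives
#: ≈15.7 and ≈4.66 against 9.37 and 4.70); they are kept verbatim for
#: documentation and excluded from reconciliation checks.
REFERENCE_CV_PCT = {
    "dm_pct": 1.33,
    "ash_pct": 62.54,
    "ee_pct": 106.82,
    "ndf_pct": 38.08,
    "adf_pct": 83.09,
    "cp_pct": 31.23,
    "starch_pct": 9.37,   # irreconcilable with the stated values
    "ge_mj_per_kg": 4.70,  # recomputes to 4.66
}

#: Shared mineral/vitamin filler of every diet, as-fed % (2.6 % in total).
FILLER_INCLUSIONS = {
    "dicalcium phosphate": 0.9,
    "limestone": 0.9,
    "NaCl": 0.3,
    "premix": 0.5,
}

_DIRECT_INCLUSION = 97.4
_BASAL_INCLUSION = 58.44   # corn 5 retained in the replacement diets
_TEST_INCLUSION = 38.96    # rice 5 / rice 6 share (40 % of the 97.4 % core)
# The rice 5/6 diets use corn 5 as their basal cereal (the diets were
# formulated from the corn 5 sample, and corn 5 is the stated basal of the
# replacement design), even though some summary sheets line the 58.44 % up
# with the corn 1 row.
_BASAL_CEREAL = "corn 5"


@lru_cache(maxsize=None)
def cereal_panel() -> dict[str, NutrientProfile]:
    """The 13 ingredient composition profiles, DM basis."""
    panel = {}
    for name, (dm, ash, ee, ndf, adf, cp, starch, ge) in _COMPOSITION.items():
        panel[name] = NutrientProfile(
            name=name,
            basis=Basis.DRY_MATTER,
            dm_pct=dm,
            ash_pct=ash,
            ee_pct=ee,
            ndf_pct=ndf,
            adf_pct=adf,
            cp_pct=cp,
            starch_pct=starch,
            ge_mj_per_kg=ge,
        )
    return panel


@lru_cache(maxsize=None)
def trial_diets() -> dict[str, FormulationSpec]:
    """The 13 diet recipes keyed by diet name (named after the test cereal)."""
    diets = {}
    for name in INGREDIENTS:
        if name in ("rice 5", "rice 6"):
            inclusions = {
                _BASAL_CEREAL: _BASAL_INCLUSION,
                name: _TEST_INCLUSION,
                **FILLER_INCLUSIONS,
            }
            energy_bearing = {_BASAL_CEREAL, name}
        else:
            inclusions = {name: _DIRECT_INCLUSION, **FILLER_INCLUSIONS}
            energy_bearing = {name}
        diets[name] = FormulationSpec(
            diet_name=name, inclusions=inclusions, energy_bearing=energy_bearing
        )
    return diets


def difference_designs() -> dict[str, DifferenceDesign]:
    """Replacement geometry of the two difference-method diets."""
    diets = trial_diets()
    return {
        name: DifferenceDesign.from_formulations(
            basal=diets[_BASAL_CEREAL], test=diets[name], test_ingredient=name
        )
        for name in ("rice 5", "rice 6")
    }


# Measured diet-level energy (MJ/kg) — as-fed and DM basis DE/ME. Values are
# carried verbatim; note the corn 1 as-fed ME (14.72) exceeds its DE (14.45),
# which is physically impossible and marks that cell as a reporting error —
# it is never used in reconciliation checks.
_DIET_ENERGY = {
    #            DE_af  ME_af  DE_dm  ME_dm
    "corn 1":  (14.45, 14.72, 16.18, 15.87),
    "corn 2":  (14.08, 13.75, 15.96, 15.59),
    "corn 3":  (13.32, 12.99, 15.31, 14.93),
    "corn 4":  (13.62, 13.26, 15.55, 15.14),
    "corn 5":  (13.76, 13.47, 15.88, 15.54),
    "wheat 1": (13.44, 13.09, 15.25, 14.85),
    "wheat 2": (13.71, 13.25, 15.42, 14.90),
    "rice 1":  (14.19, 13.87, 16.16, 15.80),
    "rice 2":  (12.35, 12.23, 13.96, 13.82),
    "rice 3":  (13.55, 13.14, 14.89, 14.44),
    "rice 4":  (14.37, 14.08, 16.23, 15.90),
    "rice 5":  (13.07, 12.81, 14.87, 14.57),
    "rice 6":  (12.94, 12.66, 14.75, 14.53),
}

# Measured ingredient-level energy (MJ/kg). The DM-basis cells of corn 5,
# rice 5 and rice 6 are not consistent with their as-fed counterparts divided
# by ingredient DM; they are carried verbatim and never used as targets.
_INGREDIENT_ENERGY = {
    "corn 1":  (14.84, 14.55, 17.05, 16.73),
    "corn 2":  (14.45, 14.12, 16.40, 16.02),
    "corn 3":  (13.68, 13.34, 15.88, 15.48),
    "corn 4":  (13.98, 13.61, 16.09, 15.67),
    "corn 5":  (14.13, 13.83, 16.75, 16.40),
    "wheat 1": (13.79, 13.43, 15.45, 15.05),
    "wheat 2": (14.08, 13.60, 16.00, 15.46),
    "rice 1":  (14.57, 14.24, 16.78, 16.40),
    "rice 2":  (12.68, 12.56, 14.49, 14.35),
    "rice 3":  (13.91, 13.49, 15.49, 15.02),
    "rice 4":  (14.75, 14.46, 16.63, 16.30),
    "rice 5":  (13.42, 13.15, 14.18, 13.87),
    "rice 6":  (13.29, 13.00, 13.77, 13.40),
}

# Measured ingredient-level apparent total tract digestibility, %.
_INGREDIENT_ATTD = {
    #            GE     DM     ash    NDF    ADF    CP
    "corn 1":  (87.77, 88.43, 45.83, 55.09, 50.39, 76.36),
    "corn 2":  (90.27, 91.15, 50.12, 54.12, 47.27, 83.01),
    "corn 3":  (86.07, 87.52, 53.86, 50.96, 9.31, 73.89),
    "corn 4":  (86.96, 87.90, 46.04, 56.32, 49.78, 77.70),
    "corn 5":  (87.72, 88.58, 41.99, 54.82, 57.60, 78.48),
    "wheat 1": (87.58, 88.54, 48.39, 64.21, 40.74, 87.58),
    "wheat 2": (87.17, 87.47, 36.87, 56.78, 25.80, 83.63),
    "rice 1":  (93.28, 93.84, 57.33, 58.91, 40.70, 86.81),
    "rice 2":  (81.96, 81.77, 35.24, 25.61, 15.60, 77.19),
    "rice 3":  (72.50, 67.38, 22.50, 17.79, 7.31, 66.23),
    "rice 4":  (90.75, 90.32, 30.52, 63.27, 13.01, 80.32),
    "rice 5":  (69.10, 74.67, 10.66, 57.48, 35.99, 86.40),
    "rice 6":  (63.15, 66.08, 16.38, 40.69, 39.44, 80.77),
}


def diet_energy_reference() -> pd.DataFrame:
    """Measured diet-level DE/ME, MJ/kg, indexed by diet name."""
    return pd.DataFrame.from_dict(
        _DIET_ENERGY,
        orient="index",
        columns=["de_as_fed", "me_as_fed", "de_dm", "me_dm"],
    ).rename_axis("diet_name")


def ingredient_energy_reference() -> pd.DataFrame:
    """Measured ingredient-level DE/ME, MJ/kg, indexed by ingredient."""
    return pd.DataFrame.from_dict(
        _INGREDIENT_ENERGY,
        orient="index",
        columns=["de_as_fed", "me_as_fed", "de_dm", "me_dm"],
    ).rename_axis("ingredient")


def ingredient_attd_reference() -> pd.DataFrame:
    """Measured ingredient-level ATTD (%), indexed by ingredient."""
    return pd.DataFrame.from_dict(
        _INGREDIENT_ATTD,
        orient="index",
        columns=["GE", "DM", "ash", "NDF", "ADF", "CP"],
    ).rename_axis("ingredient")


@lru_cache(maxsize=None)
def default_true_params() -> dict[str, TrueIngredientParams]:
    """Simulator truth preset mirroring the reference panel.

    True DE/ME are the DM-basis ingredient values; true digestibilities are
    the ingredient-level ATTD fractions. This makes default synthetic trials
    land in the realistic range for cereal diets fed to growing pigs.
    """
    panel = cereal_panel()
    params = {}
    for name in INGREDIENTS:
        _, _, de_dm, me_dm = _INGREDIENT_ENERGY[name]
        ge, dm, ash, ndf, adf, cp = _INGREDIENT_ATTD[name]
        params[name] = TrueIngredientParams(
            profile=panel[name],
            true_de_mj_per_kg_dm=de_dm,
            true_me_mj_per_kg_dm=me_dm,
            true_attd={
                "DM": dm / 100.0,
                "ash": ash / 100.0,
                "NDF": ndf / 100.0,
                "ADF": adf / 100.0,
                "CP": cp / 100.0,
            },
        )
    return params


def reference_equations() -> list[PredictionEquation]:
    """The four bundled DE/ME prediction equations (as-fed composition inputs).

    p-values are stored as 0.01, the stated upper bound. These equations are
    shipped as published artifacts for the ``predict`` step; refitting the 13
    bundled ingredient means does NOT reproduce their coefficients on either
    basis (the per-animal observations behind them are not available), and the
    package never claims otherwise.
    """
    return [
        PredictionEquation(
            response="DE", basis=Basis.AS_FED, intercept=14.3722,
            coefficients={"ADF": -0.1740}, r2=0.7899, p_value=0.01,
        ),
        PredictionEquation(
            response="DE", basis=Basis.AS_FED, intercept=11.4467,
            coefficients={"starch": 0.1364, "ADF": -0.2352}, r2=0.8633, p_value=0.01,
        ),
        PredictionEquation(
            response="ME", basis=Basis.AS_FED, intercept=0.0636,
            coefficients={"DE": 0.9716}, r2=0.9907, p_value=0.01,
        ),
        PredictionEquation(
            response="ME", basis=Basis.AS_FED, intercept=0.0538,
            coefficients={"DE": 0.9838, "CP": -0.0165}, r2=0.9943, p_value=0.01,
        ),
    ]
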