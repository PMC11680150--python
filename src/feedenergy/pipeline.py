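"""End-to-end evaluation: balance records → diet table → ingredient table →
correlations → prediction equations.

The chain mirrors how a total-collection trial is analysed:

1. per-record diet DE/ME and nutrient ATTD (``balance``);
2. least-squares diet means adjusted for period (``aggregate``);
3. ingredient-level values by the direct method (single-cereal diets) or the
   difference method (replacement diets), with basis conversions driven by
   the formulation geometry;
4. Pearson screening of composition against DE/ME and stepwise equations
   (``modeling``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from . import io as fio
from .aggregate import LSMeansResult, lsmeans, zscore_screen
from .balance import (
    BalanceRecord,
    DifferenceMode,
    DigestibilityResult,
    EnergyResult,
    diet_attd,
    diet_energy,
    ingredient_attd_difference,
    ingredient_attd_direct,
    ingredient_energy_difference,
    ingredient_energy_direct,
    round_half_up,
)
from .composition import Basis, NutrientProfile, convert_basis
from .errors import DesignError, FeedEnergyError
from .formulation import (
    DifferenceDesign,
    FormulationSpec,
    direct_inclusion_fraction,
    expected_diet_profile,
    nutrient_contributions,
)
from .modeling import PredictionEquation, pearson_matrix, stepwise_fit, write_equations

__all__ = [
    "PipelineConfig",
    "TrialEvaluation",
    "records_response_frame",
    "diet_lsmeans_table",
    "evaluate_trial",
    "ingredient_modeling_table",
    "run_pipeline",
]

#: Correlation/modeling variable set: composition plus measured energies.
MODEL_VARIABLES = ("DM", "ash", "EE", "NDF", "ADF", "CP", "starch", "GE", "DE", "ME")


def records_response_frame(records: Iterable[BalanceRecord]) -> pd.DataFrame:
    """Per-record diet-level responses: DE, ME, ME/DE and ATTD per nutrient."""
    rows = []
    for r in records:
        res = diet_energy(r)
        row = {
            "pig_id": r.pig_id,
            "period": r.period,
            "diet_name": r.diet_name,
            "de_mj_per_kg_dm": res.de_mj_per_kg,
            "me_mj_per_kg_dm": res.me_mj_per_kg,
            "me_de_ratio_pct": res.me_de_ratio_pct,
        }
        for nutrient, conc in r.diet_nutrient_pct.items():
            if conc > 0:
                row[f"attd_{nutrient}"] = diet_attd(r, nutrient).attd_pct
        rows.append(row)
    return pd.DataFrame(rows)


def diet_lsmeans_table(
    frame: pd.DataFrame, responses: Sequence[str] | None = None
) -> tuple[pd.DataFrame, dict[str, LSMeansResult]]:
    """Period-adjusted diet means, one row per response (printed-table shape)."""
    if responses is None:
        responses = [
            c
            for c in frame.columns
            if c not in ("pig_id", "period", "diet_name") and frame[c].notna().any()
        ]
    results = {}
    rows = []
    for resp in responses:
        ls = lsmeans(frame, resp)
        results[resp] = ls
        rows.append(
            {"response": resp, **ls.means, "sem": ls.sem, "p_value": ls.p_value}
        )
    return pd.DataFrame(rows).set_index("response"), results


@dataclass(frozen=True)
class TrialEvaluation:
    """Bundle of diet- and ingredient-level results for one trial."""

    diet_table: pd.DataFrame
    ingredient_energy: dict[str, dict[str, EnergyResult]]  # basis -> name -> result
    ingredient_attd: dict[str, dict[str, DigestibilityResult]]  # name -> nutrient -> result
    lsmeans: Mapping[str, LSMeansResult]

    def energy_frame(self) -> pd.DataFrame:
        rows = []
        for basis, results in self.ingredient_energy.items():
            for name, res in results.items():
                rows.append(
                    {
                        "ingredient": name,
                        "basis": basis,
                        "de_mj_per_kg": res.de_mj_per_kg,
                        "me_mj_per_kg": res.me_mj_per_kg,
                        "me_de_ratio_pct": res.me_de_ratio_pct,
                        "flags": ";".join(res.flags),
                    }
                )
        return pd.DataFrame(rows)

    def attd_frame(self) -> pd.DataFrame:
        rows = [
            {
                "ingredient": name,
                "nutrient": nutrient,
                "attd_pct": res.attd_pct,
                "flags": ";".join(res.flags),
            }
            for name, by_nutrient in self.ingredient_attd.items()
            for nutrient, res in by_nutrient.items()
        ]
        return pd.DataFrame(rows)


def _infer_difference_design(
    spec: FormulationSpec, diets: Mapping[str, FormulationSpec]
) -> DifferenceDesign:
    """Identify the basal cereal of a two-ingredient replacement diet.

    The basal cereal is the energy-bearing ingredient that is itself the sole
    cereal of one of the direct diets; the other one is the test ingredient.
    """
    bearing = sorted(spec.energy_bearing)
    if len(bearing) != 2:
        raise DesignError(
            f"{spec.diet_name}: cannot infer a replacement design with "
            f"{len(bearing)} energy-bearing ingredients"
        )
    direct_cereals = {
        next(iter(d.energy_bearing))
        for d in diets.values()
        if len(d.energy_bearing) == 1
    }
    basal = [b for b in bearing if b in direct_cereals]
    if len(basal) != 1:
        raise DesignError(
            f"{spec.diet_name}: ambiguous basal cereal among {bearing}; "
            "supply an explicit DifferenceDesign"
        )
    test = bearing[0] if bearing[1] == basal[0] else bearing[1]
    basal_spec = next(
        d for d in diets.values() if d.energy_bearing == frozenset({basal[0]})
    )
    return DifferenceDesign.from_formulations(basal_spec, spec, test)


def evaluate_trial(
    records: Iterable[BalanceRecord],
    diets: Mapping[str, FormulationSpec],
    panel: Mapping[str, NutrientProfile],
    difference_mode: DifferenceMode | str = DifferenceMode.CONTRIBUTION,
    designs: Mapping[str, DifferenceDesign] | None = None,
) -> TrialEvaluation:
    """Full diet→ingredient evaluation of one trial.

    Diet-level responses are aggregated to period-adjusted least-squares
    means; single-cereal diets then yield their cereal's value by the direct
    method and replacement diets by the difference method (``difference_mode``
    applies to energy; digestibility always uses the contribution balance).
    Ingredient energies are reported on both bases; digestibilities on the
    DM basis, as measured.
    """
    difference_mode = DifferenceMode(difference_mode)
    frame = records_response_frame(records)
    diet_table, ls = diet_lsmeans_table(frame)

    profiles = {name: expected_diet_profile(spec, panel) for name, spec in diets.items()}
    de_dm = ls["de_mj_per_kg_dm"].means
    me_dm = ls["me_mj_per_kg_dm"].means
    attd_means = {
        resp[len("attd_"):]: ls[resp].means for resp in ls if resp.startswith("attd_")
    }

    diet_energy_af: dict[str, EnergyResult] = {}
    for name in de_dm:
        if name not in diets:
            raise DesignError(f"records reference diet {name!r} with no formulation")
        dm_pct = profiles[name].dm_pct
        diet_energy_af[name] = EnergyResult(
            level="diet",
            name=name,
            basis=Basis.DRY_MATTER,
            de_mj_per_kg=de_dm[name],
            me_mj_per_kg=me_dm[name],
        ).to_basis(Basis.AS_FED, dm_pct)

    direct_names = [n for n in de_dm if len(diets[n].energy_bearing) == 1]
    replacement_names = [n for n in de_dm if n not in direct_names]

    energy_af: dict[str, EnergyResult] = {}
    energy_dm: dict[str, EnergyResult] = {}
    attd_ing: dict[str, dict[str, DigestibilityResult]] = {}

    def _ingredient_dm_pct(ingredient: str) -> float:
        return panel[ingredient].dm_pct

    # --- direct diets
    for diet_name in direct_names:
        spec = diets[diet_name]
        ingredient = next(iter(spec.energy_bearing))
        f = direct_inclusion_fraction(spec)
        res_af = ingredient_energy_direct(diet_energy_af[diet_name], f, ingredient)
        energy_af[ingredient] = res_af
        energy_dm[ingredient] = res_af.to_basis(
            Basis.DRY_MATTER, _ingredient_dm_pct(ingredient)
        )
        attd_ing[ingredient] = {}
        for nutrient, means in attd_means.items():
            if diet_name not in means or pd.isna(means[diet_name]):
                continue
            contribs = nutrient_contributions(spec, panel, nutrient)
            total = sum(contribs.values())
            if contribs.get(ingredient, 0.0) <= 0:
                continue
            share = contribs[ingredient] / total
            attd_ing[ingredient][nutrient] = ingredient_attd_direct(
                DigestibilityResult(
                    level="diet",
                    name=diet_name,
                    nutrient=nutrient,
                    attd_pct=means[diet_name],
                ),
                nutrient_share=share,
                ingredient_name=ingredient,
            )

    # --- replacement diets (need the basal cereal's direct results)
    for diet_name in replacement_names:
        spec = diets[diet_name]
        design = (
            designs[diet_name]
            if designs and diet_name in designs
            else _infer_difference_design(spec, diets)
        )
        basal_name = next(iter(diets[design.basal_diet].energy_bearing))
        design = dataclasses.replace(
            design,
            basal_diet_energy=diet_energy_af[design.basal_diet],
            basal_ingredient_energy=energy_af.get(basal_name),
        )
        res_af = ingredient_energy_difference(
            diet_energy_af[diet_name], design, difference_mode
        )
        ingredient = design.test_ingredient
        energy_af[ingredient] = res_af
        energy_dm[ingredient] = res_af.to_basis(
            Basis.DRY_MATTER, _ingredient_dm_pct(ingredient)
        )

        attd_ing[ingredient] = {}
        for nutrient, means in attd_means.items():
            if diet_name not in means or pd.isna(means[diet_name]):
                continue
            contribs = nutrient_contributions(spec, panel, nutrient)
            c_t = contribs.get(ingredient, 0.0)
            if c_t <= 0:
                continue
            c_b = contribs.get(basal_name, 0.0)
            basal_attd = attd_ing.get(basal_name, {}).get(nutrient)
            if basal_attd is None:
                continue
            attd_ing[ingredient][nutrient] = ingredient_attd_difference(
                DigestibilityResult(
                    level="diet",
                    name=diet_name,
                    nutrient=nutrient,
                    attd_pct=means[diet_name],
                ),
                basal_attd,
                basal_contribution=c_b,
                test_contribution=c_t,
                diet_concentration=sum(contribs.values()),
                ingredient_name=ingredient,
            )

    return TrialEvaluation(
        diet_table=diet_table,
        ingredient_energy={
            "as_fed": energy_af,
            "dry_matter": energy_dm,
        },
        ingredient_attd=attd_ing,
        lsmeans=ls,
    )


def ingredient_modeling_table(
    panel: Mapping[str, NutrientProfile],
    energy: Mapping[str, EnergyResult],
    basis: Basis | str = Basis.DRY_MATTER,
) -> pd.DataFrame:
    """Join composition and measured energy into one row per ingredient.

    Columns follow the short-name convention so the output feeds
    :func:`~feedenergy.modeling.pearson_matrix` and
    :func:`~feedenergy.modeling.stepwise_fit` directly. Both inputs are
    re-expressed on ``basis``.
    """
    basis = Basis.coerce(basis)
    rows = []
    for name, res in energy.items():
        if name not in panel:
            continue
        p = convert_basis(panel[name], basis)
        r = res if res.basis is basis else res.to_basis(basis, panel[name].dm_pct)
        rows.append(
            {
                "ingredient": name,
                "DM": p.dm_pct,
                "ash": p.ash_pct,
                "EE": p.ee_pct,
                "NDF": p.ndf_pct,
                "ADF": p.adf_pct,
                "CP": p.cp_pct,
                "starch": p.starch_pct,
                "GE": p.ge_mj_per_kg,
                "DE": r.de_mj_per_kg,
                "ME": r.me_mj_per_kg,
            }
        )
    return pd.DataFrame(rows).set_index("ingredient")


# ---------------------------------------------------------------------------
# configuration and the orchestrated run


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative configuration of one end-to-end run."""

    ingredient_csv: str
    diet_csv: str
    balance_csv: str
    output_dir: str
    modeling_basis: str = Basis.DRY_MATTER.value
    difference_mode: str = DifferenceMode.CONTRIBUTION.value
    sle: float = 0.15
    sls: float = 0.15
    seed: int = 0
    round_digits: int = 2
    drop_flagged: bool = False

    def __post_init__(self) -> None:
        Basis.coerce(self.modeling_basis)
        DifferenceMode(self.difference_mode)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FeedEnergyError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the full chain and write the report bundle.

    Outputs (all CSV except the equation registry): ``diet_table``,
    ``ingredient_energy``, ``ingredient_attd``, ``correlation_r``,
    ``correlation_p``, ``equations.txt``, ``validation.csv`` and a rounded
    human-readable ``report.txt``. Numeric CSVs are unrounded. Returns the
    mapping of artifact name → path.
    """
    panel = fio.read_ingredient_csv(config.ingredient_csv)
    diets = fio.read_diet_csv(config.diet_csv)
    records = fio.read_balance_csv(config.balance_csv)

    validation = pd.DataFrame(
        [
            {
                "pig_id": r.pig_id,
                "period": r.period,
                "diet_name": r.diet_name,
                "flags": ";".join(r.physical_flags()),
            }
            for r in records
        ]
    )
    if config.drop_flagged:
        keep = validation["flags"] == ""
        records = [r for r, k in zip(records, keep) if k]

    evaluation = evaluate_trial(
        records, diets, panel, difference_mode=config.difference_mode
    )
    frame = records_response_frame(records)
    screen = zscore_screen(frame, "de_mj_per_kg_dm")
    validation = validation.join(screen[["zscore", "outlier"]])

    model_table = ingredient_modeling_table(
        panel,
        evaluation.ingredient_energy[Basis.coerce(config.modeling_basis).value],
        basis=config.modeling_basis,
    )
    corr = pearson_matrix(model_table, MODEL_VARIABLES)
    de_path = stepwise_fit(
        model_table,
        "DE",
        ["DM", "ash", "EE", "NDF", "ADF", "CP", "starch", "GE"],
        sle=config.sle,
        sls=config.sls,
        basis=config.modeling_basis,
    )
    me_path = stepwise_fit(
        model_table,
        "ME",
        ["DM", "ash", "EE", "NDF", "ADF", "CP", "starch", "GE", "DE"],
        sle=config.sle,
        sls=config.sls,
        basis=config.modeling_basis,
    )

    out = fio.ensure_dir(config.output_dir)
    paths = {
        "diet_table": out / "diet_table.csv",
        "ingredient_energy": out / "ingredient_energy.csv",
        "ingredient_attd": out / "ingredient_attd.csv",
        "correlation_r": out / "correlation_r.csv",
        "correlation_p": out / "correlation_p.csv",
        "equations": out / "equations.txt",
        "validation": out / "validation.csv",
        "report": out / "report.txt",
    }
    evaluation.diet_table.to_csv(paths["diet_table"])
    evaluation.energy_frame().to_csv(paths["ingredient_energy"], index=False)
    evaluation.attd_frame().to_csv(paths["ingredient_attd"], index=False)
    corr.r.to_csv(paths["correlation_r"])
    corr.p.to_csv(paths["correlation_p"])
    write_equations(paths["equations"], de_path + me_path)
    validation.to_csv(paths["validation"], index=False)
    paths["report"].write_text(
        _render_report(evaluation, de_path + me_path, config.round_digits),
        encoding="utf-8",
    )
    return paths


def _render_report(
    evaluation: TrialEvaluation, equations: list[PredictionEquation], digits: int
) -> str:
    lines = ["Ingredient energy values (MJ/kg)", ""]
    for basis, results in evaluation.ingredient_energy.items():
        lines.append(f"[{basis}]")
        for name in sorted(results):
            r = results[name]
            lines.append(
                f"  {name:<12} DE {round_half_up(r.de_mj_per_kg, digits):>7} "
                f"ME {round_half_up(r.me_mj_per_kg, digits):>7} "
                f"ME/DE {round_half_up(r.me_de_ratio_pct, digits):>7} %"
            )
        lines.append("")
    lines.append("Stepwise prediction equations")
    for eq in equations:
        lines.append(f"  {eq.formula()}   R2={eq.r2:.4f}")
    lines.append("")
    return "\n".join(lines)
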