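"""CSV dialects for ingredient panels, diet recipes and balance records.

All tables are plain UTF-8 CSV with a mandatory header and decimal points.
Machine outputs are written unrounded; rounding is applied only in the
human-readable report.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .balance import BalanceRecord
from .composition import NutrientProfile
from .errors import FeedEnergyError
from .formulation import FormulationSpec

__all__ = [
    "read_ingredient_csv",
    "write_ingredient_csv",
    "read_diet_csv",
    "write_diet_csv",
    "read_balance_csv",
    "write_balance_csv",
]

_INGREDIENT_COLUMNS = [
    "name", "basis", "dm_pct", "ash_pct", "ee_pct", "ndf_pct",
    "adf_pct", "cp_pct", "starch_pct", "ge_mj_per_kg",
]

_BALANCE_COLUMNS = [
    "pig_id", "period", "diet_name", "feed_intake_kg_dm", "feces_output_kg_dm",
    "ge_intake_mj", "ge_feces_mj", "ge_urine_mj",
]


class ParseError(FeedEnergyError):
    """A table failed to parse; the message carries row/column context."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")


def read_ingredient_csv(path) -> dict[str, NutrientProfile]:
    """Ingredient composition table → profiles keyed by name."""
    df = pd.read_csv(path)
    _require_columns(df, _INGREDIENT_COLUMNS, path)
    panel = {}
    for i, row in df.iterrows():
        try:
            profile = NutrientProfile(
                name=str(row["name"]),
                basis=str(row["basis"]),
                **{c: float(row[c]) for c in _INGREDIENT_COLUMNS[2:]},
            )
        except (ValueError, FeedEnergyError) as exc:
            raise ParseError(f"{path}: row {i + 2} ({row['name']!r}): {exc}") from exc
        panel[profile.name] = profile
    return panel


def write_ingredient_csv(path, panel: Mapping[str, NutrientProfile]) -> None:
    rows = [
        {
            "name": p.name,
            "basis": p.basis.value,
            **{c: getattr(p, c) for c in _INGREDIENT_COLUMNS[2:]},
        }
        for p in panel.values()
    ]
    pd.DataFrame(rows, columns=_INGREDIENT_COLUMNS).to_csv(path, index=False)


def read_diet_csv(path) -> dict[str, FormulationSpec]:
    """Long-format diet table (diet_name, ingredient, inclusion_pct, energy_bearing)."""
    df = pd.read_csv(path)
    _require_columns(df, ["diet_name", "ingredient", "inclusion_pct", "energy_bearing"], path)
    diets = {}
    for diet_name, grp in df.groupby("diet_name", sort=False):
        inclusions = dict(zip(grp["ingredient"], grp["inclusion_pct"].astype(float)))
        bearing = set(grp.loc[grp["energy_bearing"].astype(int) == 1, "ingredient"])
        try:
            diets[str(diet_name)] = FormulationSpec(
                diet_name=str(diet_name), inclusions=inclusions, energy_bearing=bearing
            )
        except FeedEnergyError as exc:
            raise ParseError(f"{path}: diet {diet_name!r}: {exc}") from exc
    return diets


def write_diet_csv(path, diets: Mapping[str, FormulationSpec]) -> None:
    rows = []
    for spec in diets.values():
        for ingredient, incl in spec.inclusions.items():
            rows.append(
                {
                    "diet_name": spec.diet_name,
                    "ingredient": ingredient,
                    "inclusion_pct": incl,
                    "energy_bearing": int(ingredient in spec.energy_bearing),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_balance_csv(path) -> list[BalanceRecord]:
    """Balance-record table → records; nutrient concentrations from the
    optional ``dietconc_<nutrient>_pct`` / ``fecesconc_<nutrient>_pct`` pairs."""
    df = pd.read_csv(path)
    if df.empty:
        raise ParseError(f"{path}: balance table is empty")
    _require_columns(df, _BALANCE_COLUMNS, path)
    diet_cols = {
        c: c[len("dietconc_"):-len("_pct")]
        for c in df.columns
        if c.startswith("dietconc_") and c.endswith("_pct")
    }
    feces_cols = {
        c: c[len("fecesconc_"):-len("_pct")]
        for c in df.columns
        if c.startswith("fecesconc_") and c.endswith("_pct")
    }
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                BalanceRecord(
                    pig_id=str(row["pig_id"]),
                    period=int(row["period"]),
                    diet_name=str(row["diet_name"]),
                    feed_intake_kg=float(row["feed_intake_kg_dm"]),
                    feces_output_kg=float(row["feces_output_kg_dm"]),
                    ge_intake_mj=float(row["ge_intake_mj"]),
                    ge_feces_mj=float(row["ge_feces_mj"]),
                    ge_urine_mj=float(row["ge_urine_mj"]),
                    diet_nutrient_pct={
                        n: float(row[c]) for c, n in diet_cols.items() if pd.notna(row[c])
                    },
                    feces_nutrient_pct={
                        n: float(row[c]) for c, n in feces_cols.items() if pd.notna(row[c])
                    },
                )
            )
        except (ValueError, FeedEnergyError) as exc:
            raise ParseError(f"{path}: row {i + 2}: {exc}") from exc
    return records


def write_balance_csv(path, records: Iterable[BalanceRecord]) -> None:
    records = list(records)
    nutrients = sorted({n for r in records for n in r.diet_nutrient_pct})
    rows = []
    for r in records:
        row = {
            "pig_id": r.pig_id,
            "period": r.period,
            "diet_name": r.diet_name,
            "feed_intake_kg_dm": r.feed_intake_kg,
            "feces_output_kg_dm": r.feces_output_kg,
            "ge_intake_mj": r.ge_intake_mj,
            "ge_feces_mj": r.ge_feces_mj,
            "ge_urine_mj": r.ge_urine_mj,
        }
        for n in nutrients:
            if n in r.diet_nutrient_pct:
                row[f"dietconc_{n}_pct"] = r.diet_nutrient_pct[n]
            if n in r.feces_nutrient_pct:
                row[f"fecesconc_{n}_pct"] = r.feces_nutrient_pct[n]
        rows.append(row)
    columns = _BALANCE_COLUMNS + [
        f"{kind}_{n}_pct" for n in nutrients for kind in ("dietconc", "fecesconc")
    ]
    pd.DataFrame(rows).reindex(columns=columns).to_csv(path, index=False)


def records_frame(records: Iterable[BalanceRecord]) -> pd.DataFrame:
    """Flat per-record frame with derived diet-level responses attached."""
    from .balance import diet_energy

    rows = []
    for r in records:
        res = diet_energy(r)
        rows.append(
            {
                "pig_id": r.pig_id,
                "period": r.period,
                "diet_name": r.diet_name,
                "de_mj_per_kg_dm": res.de_mj_per_kg,
                "me_mj_per_kg_dm": res.me_mj_per_kg,
                "me_de_ratio_pct": res.me_de_ratio_pct,
            }
        )
    return pd.DataFrame(rows)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
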