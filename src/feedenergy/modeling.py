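"""Correlation screening and stepwise prediction-equation construction.

Available energy in cereals tracks their chemical makeup: fiber fractions
(NDF, especially ADF) dilute digestible energy while starch concentrates
it. The screening step computes a Pearson correlation matrix between
composition variables and measured DE/ME across an ingredient panel; the
modeling step builds linear prediction equations

    DE (MJ/kg) = b0 + b1·x1 + ... ,   ME = f(DE, CP, ...)

by classical forward stepwise selection with elimination: at each step the
candidate with the smallest partial-F p-value enters if p ≤ SLE, then any
entered variable whose p has risen above SLS is removed; the procedure stops
at a fixed point. Entry/stay thresholds default to 0.15, the long-standing
stepwise default; ties in partial F break lexicographically by predictor
name so the path is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .composition import Basis, NutrientProfile
from .errors import BasisMismatchError, InsufficientDataError, UndefinedStatisticError

__all__ = [
    "CorrelationMatrix",
    "PredictionEquation",
    "pearson_matrix",
    "stepwise_fit",
    "apply_equation",
    "write_equations",
    "read_equations",
]

DEFAULT_SLE = 0.15
DEFAULT_SLS = 0.15
_COND_LIMIT = 1e10  # collinearity guard on the candidate design matrix


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise Pearson coefficients with two-sided p-values (t transform, n−2 df)."""

    variables: tuple
    r: pd.DataFrame
    p: pd.DataFrame
    n: int

    def annotate(self) -> pd.DataFrame:
        """Lower triangle of r with the conventional stars.

        ``**`` marks p < 0.05 and ``*`` a tendency (0.05 ≤ p < 0.10).
        """
        out = pd.DataFrame("", index=self.r.index, columns=self.r.columns)
        for i, vi in enumerate(self.variables):
            for j, vj in enumerate(self.variables[: i + 1]):
                star = ""
                if i != j:
                    pv = self.p.loc[vi, vj]
                    star = " **" if pv < 0.05 else (" *" if pv < 0.10 else "")
                out.loc[vi, vj] = f"{self.r.loc[vi, vj]:.2f}{star}"
        return out


def pearson_matrix(table: pd.DataFrame, variables: Sequence[str]) -> CorrelationMatrix:
    """Pearson correlation matrix over ``variables`` of ``table``.

    Requires n ≥ 3 complete rows; a zero-variance variable makes its
    correlations undefined and raises.
    """
    data = table[list(variables)]
    if data.isna().any().any():
        raise InsufficientDataError("correlation input contains missing values")
    n = len(data)
    if n < 3:
        raise InsufficientDataError(f"pearson_matrix needs n >= 3, got {n}")
    for v in variables:
        if np.isclose(data[v].std(ddof=1), 0.0):
            raise UndefinedStatisticError(
                f"variable {v!r} has zero variance; its correlations are undefined"
            )
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i):
            res = stats.pearsonr(data.iloc[:, i], data.iloc[:, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = list(variables)
    return CorrelationMatrix(
        variables=tuple(variables),
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=n,
    )


@dataclass(frozen=True)
class PredictionEquation:
    """A linear DE/ME prediction equation with its fit diagnostics.

    ``coefficients`` map predictor name → slope (MJ/kg per %, or MJ/kg per
    MJ/kg for an energy predictor); ``basis`` declares the basis the
    composition inputs must be on.
    """

    response: str  # "DE" | "ME"
    basis: Basis
    intercept: float
    coefficients: Mapping[str, float]
    r2: float
    p_value: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "basis", Basis.coerce(self.basis))
        object.__setattr__(self, "coefficients", dict(self.coefficients))
        if not (0.0 <= self.r2 <= 1.0 or np.isnan(self.r2)):
            raise ValueError(f"r2 must be in [0,1], got {self.r2}")

    def predict(self, values: Mapping[str, float]) -> float:
        total = self.intercept
        for name, coef in self.coefficients.items():
            if name not in values:
                raise KeyError(f"predictor {name!r} missing from input")
            total += coef * values[name]
        return total

    def formula(self) -> str:
        terms = " ".join(
            f"{c:+.4f}×{name}" for name, c in self.coefficients.items()
        )
        return f"{self.response} (MJ/kg) = {terms} {self.intercept:+.4f}"


def apply_equation(
    eq: PredictionEquation, profile: "NutrientProfile | Mapping[str, float]"
) -> float:
    """Evaluate an equation on an ingredient profile or plain mapping.

    A :class:`NutrientProfile` must be on the equation's declared basis;
    predictor names follow the short convention (DM, ash, EE, NDF, ADF, CP,
    starch, GE, DE).
    """
    if isinstance(profile, NutrientProfile):
        if profile.basis is not eq.basis:
            raise BasisMismatchError(
                f"equation expects {eq.basis.value} inputs, profile is "
                f"{profile.basis.value}"
            )
        values = {
            "DM": profile.dm_pct,
            "ash": profile.ash_pct,
            "EE": profile.ee_pct,
            "NDF": profile.ndf_pct,
            "ADF": profile.adf_pct,
            "CP": profile.cp_pct,
            "starch": profile.starch_pct,
            "GE": profile.ge_mj_per_kg,
        }
    else:
        values = dict(profile)
    return eq.predict(values)


def _fit_ols(y: np.ndarray, X: pd.DataFrame):
    import statsmodels.api as sm

    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def stepwise_fit(
    table: pd.DataFrame,
    response: str,
    candidates: Sequence[str],
    sle: float = DEFAULT_SLE,
    sls: float = DEFAULT_SLS,
    basis: Basis | str = Basis.DRY_MATTER,
) -> list[PredictionEquation]:
    """Forward stepwise selection with elimination.

    Returns the fitted equation after each successful entry (sizes 1, 2, ...),
    so callers can pick a size or take the final model; R² is monotone along
    the path. Candidates whose addition makes the design numerically singular
    are skipped with a warning. Raises if n is too small to ever fit the
    largest admissible model with an error df.
    """
    candidates = sorted(candidates)  # lexicographic base order for tie-breaks
    data = table[[response, *candidates]].dropna()
    n = len(data)
    if n < 3:
        raise InsufficientDataError(f"stepwise needs n >= 3, got {n}")
    y = data[response].to_numpy(dtype=float)

    included: list[str] = []
    path: list[PredictionEquation] = []
    while True:
        # --- entry step: smallest partial-F p-value among admissible candidates
        best_name, best_p = None, np.inf
        for name in candidates:
            if name in included:
                continue
            if len(included) + 2 >= n:  # keep at least 1 error df
                continue
            X = data[included + [name]]
            cond = np.linalg.cond(np.column_stack([np.ones(n), X.to_numpy()]))
            if not np.isfinite(cond) or cond > _COND_LIMIT:
                warnings.warn(
                    f"skipping collinear candidate {name!r} "
                    f"(condition number {cond:.2e})",
                    stacklevel=2,
                )
                continue
            fit = _fit_ols(y, X)
            p_in = fit.pvalues[name]
            if p_in < best_p - 1e-15:  # ties resolve to the earlier (lexicographic) name
                best_name, best_p = name, p_in
        if best_name is None or best_p > sle:
            break
        included.append(best_name)

        # --- elimination step: drop anything whose p has risen above SLS
        while True:
            fit = _fit_ols(y, data[included])
            worst = max(included, key=lambda v: (fit.pvalues[v], v))
            if fit.pvalues[worst] <= sls:
                break
            included.remove(worst)
            if worst == best_name:
                # the entering variable itself fell out: fixed point reached
                break
        if best_name not in included:
            break

        fit = _fit_ols(y, data[included])
        path.append(
            PredictionEquation(
                response=response,
                basis=basis,
                intercept=float(fit.params["const"]),
                coefficients={v: float(fit.params[v]) for v in included},
                r2=float(fit.rsquared),
                p_value=float(fit.f_pvalue),
            )
        )
    return path


# ---------------------------------------------------------------------------
# plain-text equation registry

def write_equations(path, equations: Sequence[PredictionEquation]) -> None:
    """Serialize equations to a plain-text registry, one block per equation.

    Floats are written with ``repr`` so the round trip is bit-exact.
    """
    lines = []
    for eq in equations:
        lines.append(f"response = {eq.response}")
        lines.append(f"basis = {eq.basis.value}")
        lines.append(f"intercept = {eq.intercept!r}")
        for name, coef in eq.coefficients.items():
            lines.append(f"coef.{name} = {coef!r}")
        lines.append(f"r2 = {eq.r2!r}")
        lines.append(f"p = {eq.p_value!r}")
        lines.append("")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))


def read_equations(path) -> list[PredictionEquation]:
    """Parse a registry written by :func:`write_equations`."""
    equations = []
    block: dict = {}
    coefs: dict = {}

    def flush():
        nonlocal block, coefs
        if block:
            equations.append(
                PredictionEquation(
                    response=block["response"],
                    basis=block["basis"],
                    intercept=float(block["intercept"]),
                    coefficients=coefs,
                    r2=float(block["r2"]),
                    p_value=float(block["p"]),
                )
            )
        block, coefs = {}, {}

    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                flush()
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key.startswith("coef."):
                coefs[key[5:]] = float(value)
            else:
                block[key] = value
    flush()
    return equations
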