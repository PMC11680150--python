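"""Design-aware aggregation: least-squares means over a row–column trial.

Digestibility trials rotate each animal through several diets (an incomplete
Latin square — a Youden square — when there are more diets than periods).
Raw per-diet averages are then confounded with period effects; the standard
remedy is a two-way fixed-effects model

    response ~ diet + period

whose *least-squares means* (model-adjusted diet means, averaged over
periods) are reported with a pooled SEM and an overall diet-effect F test.
Period is treated as a fixed factor: with one observation per pig–period and
a balanced arrangement, the adjusted diet means coincide with those of a
mixed model, and nothing extra is estimable from these data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DesignError, EstimabilityError

__all__ = ["TrialDesign", "LSMeansResult", "lsmeans", "zscore_screen"]


@dataclass(frozen=True)
class TrialDesign:
    """Assignment of diets to (pig, period) cells.

    A proper Youden arrangement with t treatments and p ≤ t periods has every
    diet exactly once per period (so t pigs per period) and p distinct diets
    per pig, giving each diet p replicates overall.
    """

    n_pigs: int
    n_periods: int
    assignment: Mapping[tuple, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment", dict(self.assignment))

    @property
    def diets(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    def validate_youden(self) -> None:
        """Raise :class:`DesignError` unless this is a proper Youden arrangement."""
        diets = self.diets
        t = len(diets)
        per_pig: dict = {}
        per_period: dict = {}
        for (pig, period), diet in self.assignment.items():
            per_pig.setdefault(pig, []).append(diet)
            per_period.setdefault(period, []).append(diet)
        if len(self.assignment) != self.n_pigs * self.n_periods:
            raise DesignError(
                f"expected {self.n_pigs * self.n_periods} cells, "
                f"got {len(self.assignment)}"
            )
        for pig, ds in per_pig.items():
            if len(ds) != len(set(ds)):
                raise DesignError(f"pig {pig} receives a diet more than once")
        for period, ds in per_period.items():
            if sorted(ds) != diets:
                raise DesignError(
                    f"period {period} does not contain every diet exactly once"
                )
        counts = pd.Series(list(self.assignment.values())).value_counts()
        if counts.nunique() != 1:
            raise DesignError(f"unequal diet replication: {counts.to_dict()}")
        if t != self.n_pigs:
            raise DesignError(
                f"{t} diets but {self.n_pigs} pigs; a Youden arrangement needs one "
                "pig column per treatment"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"pig_id": pig, "period": period, "diet_name": diet}
            for (pig, period), diet in sorted(self.assignment.items())
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class LSMeansResult:
    """Least-squares diet means with a pooled SEM and the diet-effect p-value."""

    response: str
    means: Mapping[str, float]
    se: Mapping[str, float]
    sem: float
    df_resid: int
    p_value: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "diet_name": list(self.means),
                "lsmean": list(self.means.values()),
                "se": [self.se[d] for d in self.means],
            }
        ).assign(response=self.response)


def lsmeans(
    records: pd.DataFrame,
    response: str,
    diet_col: str = "diet_name",
    period_col: str = "period",
) -> LSMeansResult:
    """Least-squares means of ``response`` by diet, adjusted for period.

    Fits ``response ~ C(diet) + C(period)`` by OLS; each diet's LSMean is the
    model prediction averaged over every period level, and its standard error
    follows from the coefficient covariance. The reported ``sem`` is the mean
    of the per-diet standard errors (they coincide in a balanced design).
    ``p_value`` is the type-II F test of the diet factor.

    Requires at least two diets and a connected diet × period incidence;
    a disconnected layout leaves diet contrasts inestimable.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from patsy import build_design_matrices

    data = records[[diet_col, period_col, response]].dropna().copy()
    data[diet_col] = data[diet_col].astype(str)
    data[period_col] = data[period_col].astype(str)
    diets = sorted(data[diet_col].unique())
    periods = sorted(data[period_col].unique())
    if len(diets) < 2:
        raise DesignError("lsmeans needs at least two diets")
    _check_connected(data, diet_col, period_col)

    formula = f"Q('{response}') ~ C(Q('{diet_col}')) + C(Q('{period_col}'))"
    model = smf.ols(formula, data=data)
    fit = model.fit()

    design_info = model.data.design_info
    means: dict[str, float] = {}
    ses: dict[str, float] = {}
    cov = np.asarray(fit.cov_params())
    for diet in diets:
        grid = pd.DataFrame({diet_col: diet, period_col: periods})
        (X,) = build_design_matrices([design_info], grid)
        L = np.asarray(X).mean(axis=0)
        means[diet] = float(L @ fit.params.values)
        ses[diet] = float(np.sqrt(L @ cov @ L))

    anova = sm.stats.anova_lm(fit, typ=2)
    diet_row = [ix for ix in anova.index if diet_col in str(ix)]
    p_value = float(anova.loc[diet_row[0], "PR(>F)"])
    return LSMeansResult(
        response=response,
        means=means,
        se=ses,
        sem=float(np.mean(list(ses.values()))),
        df_resid=int(fit.df_resid),
        p_value=p_value,
    )


def _check_connected(data: pd.DataFrame, diet_col: str, period_col: str) -> None:
    """Diet and period levels must form one connected bipartite component."""
    edges = data[[diet_col, period_col]].drop_duplicates()
    nodes = {("d", d) for d in edges[diet_col]} | {("p", p) for p in edges[period_col]}
    adj: dict = {n: set() for n in nodes}
    for _, row in edges.iterrows():
        a, b = ("d", row[diet_col]), ("p", row[period_col])
        adj[a].add(b)
        adj[b].add(a)
    start = next(iter(nodes))
    seen = {start}
    stack = [start]
    while stack:
        for nxt in adj[stack.pop()]:
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    if seen != nodes:
        raise EstimabilityError(
            "diet × period incidence is disconnected; diet contrasts are not estimable"
        )


def zscore_screen(
    records: pd.DataFrame, response: str, group_col: str = "diet_name", threshold: float = 3.0
) -> pd.DataFrame:
    """Within-group z-scores for outlier screening; reported, never dropped."""
    out = records.copy()
    grp = out.groupby(group_col)[response]
    out["zscore"] = (out[response] - grp.transform("mean")) / grp.transform("std")
    out["outlier"] = out["zscore"].abs() > threshold
    return out[[group_col, response, "zscore", "outlier"]]
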