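import numpy as np
import pandas as pd
import pytest

from feedenergy.aggregate import TrialDesign, lsmeans, zscore_screen
from feedenergy.errors import DesignError, EstimabilityError
from feedenergy.synthetic import youden_design


def complete_layout(n_diets=4, n_periods=3, seed=0, period_effects=None, diet_means=None):
    """Complete two-way layout: every diet observed in every period."""
    rng = np.random.default_rng(seed)
    diet_means = diet_means if diet_means is not None else rng.uniform(14, 17, n_diets)
    period_effects = (
        period_effects if period_effects is not None else np.zeros(n_periods)
    )
    rows = []
    for d in range(n_diets):
        for p in range(n_periods):
            rows.append(
                {
                    "pig_id": f"pig{d}",
                    "period": p + 1,
                    "diet_name": f"diet{d}",
                    "y": diet_means[d] + period_effects[p],
                }
            )
    return pd.DataFrame(rows), diet_means


class TestYoudenValidation:
    def test_accepts_cyclic_13x6(self, design13x6):
        design13x6.validate_youden()

    def test_rejects_broken_period(self):
        design = youden_design(4, 3)
        broken = dict(design.assignment)
        key = next(iter(broken))
        broken[key] = "diet4"  # duplicate one diet within a period
        with pytest.raises(DesignError):
            TrialDesign(4, 3, broken).validate_youden()


class TestLsmeans:
    def test_balanced_layout_equals_raw_means(self):
        """On a complete design with no period effect, LSMeans are the
        per-diet arithmetic means."""
        data, truth = complete_layout()
        res = lsmeans(data, "y")
        for d, mu in enumerate(truth):
            assert res.means[f"diet{d}"] == pytest.approx(mu, rel=1e-10)

    def test_known_shift_recovered_exactly(self):
        data, _ = complete_layout(n_diets=2, diet_means=np.array([15.0, 16.0]))
        res = lsmeans(data, "y")
        assert res.means["diet1"] - res.means["diet0"] == pytest.approx(1.0, rel=1e-10)

    def test_period_adjustment_removes_period_bias(self):
        """On an unbalanced layout, raw diet means absorb period effects but
        LSMeans recover the true diet contrasts exactly (no noise)."""
        period_fx = {1: 0.5, 2: -0.5}
        truth = {"A": 15.0, "B": 16.0}
        cells = [("A", 1), ("A", 1), ("A", 2), ("B", 1), ("B", 2), ("B", 2)]
        data = pd.DataFrame(
            [
                {
                    "pig_id": f"pig{i}",
                    "period": p,
                    "diet_name": d,
                    "y": truth[d] + period_fx[p],
                }
                for i, (d, p) in enumerate(cells)
            ]
        )
        res = lsmeans(data, "y")
        grand_fx = np.mean(list(period_fx.values()))
        for diet, mu in truth.items():
            assert res.means[diet] == pytest.approx(mu + grand_fx, abs=1e-9)
        raw = data.groupby("diet_name")["y"].mean()
        assert raw["B"] - raw["A"] != pytest.approx(1.0, abs=0.1)  # biased by period

    def test_shift_invariance(self):
        data, _ = complete_layout(seed=3)
        res0 = lsmeans(data, "y")
        shifted = data.assign(y=data["y"] + 2.5)
        res1 = lsmeans(shifted, "y")
        for diet in res0.means:
            assert res1.means[diet] == pytest.approx(res0.means[diet] + 2.5, rel=1e-10)
        assert res1.sem == pytest.approx(res0.sem, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        """Brute-force dummy-coded least squares on a noisy complete layout
        reproduces the LSMeans and their standard errors."""
        rng = np.random.default_rng(42)
        data, _ = complete_layout(n_diets=5, n_periods=4, seed=42)
        data["y"] = data["y"] + rng.normal(0, 0.3, len(data))
        res = lsmeans(data, "y")

        diets = sorted(data["diet_name"].unique())
        periods = sorted(data["period"].unique())
        X = np.zeros((len(data), 1 + len(diets) - 1 + len(periods) - 1))
        X[:, 0] = 1.0
        for i, row in data.iterrows():
            d = diets.index(row["diet_name"])
            p = periods.index(row["period"])
            if d > 0:
                X[i, d] = 1.0
            if p > 0:
                X[i, len(diets) - 1 + p] = 1.0
        beta, *_ = np.linalg.lstsq(X, data["y"].to_numpy(), rcond=None)
        resid = data["y"].to_numpy() - X @ beta
        dof = len(data) - X.shape[1]
        sigma2 = resid @ resid / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        for d, diet in enumerate(diets):
            L = np.zeros(X.shape[1])
            L[0] = 1.0
            if d > 0:
                L[d] = 1.0
            L[len(diets):] = 1.0 / len(periods)  # average over period dummies
            expect = L @ beta
            assert res.means[diet] == pytest.approx(expect, rel=1e-9)
            assert res.se[diet] == pytest.approx(np.sqrt(L @ cov @ L), rel=1e-9)

    def test_single_diet_rejected(self):
        data = pd.DataFrame(
            {"pig_id": ["a", "b"], "period": [1, 2], "diet_name": ["d", "d"], "y": [1.0, 2.0]}
        )
        with pytest.raises(DesignError):
            lsmeans(data, "y")

    def test_disconnected_design_rejected(self):
        data = pd.DataFrame(
            {
                "pig_id": list("abcd"),
                "period": [1, 1, 2, 2],
                "diet_name": ["d1", "d1", "d2", "d2"],
                "y": [1.0, 2.0, 3.0, 4.0],
            }
        )
        with pytest.raises(EstimabilityError):
            lsmeans(data, "y")


def test_period_effect_simulation_coverage():
    """Over repeated noisy Youden trials with ±0.5 MJ/kg period effects, the
    LSMean ± 2·SE interval covers the true diet value at its nominal ~95 %
    rate (asserted above the 4-sigma binomial lower bound for this sample)."""
    rng = np.random.default_rng(2024)
    design = youden_design(6, 4)
    truth = {f"diet{i + 1}": 14.0 + 0.4 * i for i in range(6)}
    period_fx = {1: 0.5, 2: -0.5, 3: 0.25, 4: -0.25}
    grand_fx = np.mean(list(period_fx.values()))
    hits = total = 0
    for _ in range(200):
        rows = [
            {
                "pig_id": pig,
                "period": period,
                "diet_name": diet,
                "y": truth[diet] + period_fx[period] + rng.normal(0, 0.2),
            }
            for (pig, period), diet in design.assignment.items()
        ]
        res = lsmeans(pd.DataFrame(rows), "y")
        for diet, mu in truth.items():
            total += 1
            if abs(res.means[diet] - (mu + grand_fx)) <= 2.0 * res.se[diet]:
                hits += 1
    assert hits / total >= 0.93


def test_zscore_screen_flags_gross_outlier():
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        {
            "diet_name": ["d1"] * 30,
            "y": np.concatenate([rng.normal(15, 0.1, 29), [25.0]]),
        }
    )
    out = zscore_screen(data, "y")
    assert out["outlier"].sum() == 1
    assert out.loc[out["outlier"], "y"].iloc[0] == 25.0
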