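import itertools

import numpy as np
import pandas as pd
import pytest

from feedenergy.composition import Basis
from feedenergy.datasets import ingredient_energy_reference, reference_equations
from feedenergy.errors import (
    BasisMismatchError,
    InsufficientDataError,
    UndefinedStatisticError,
)
from feedenergy.modeling import (
    PredictionEquation,
    apply_equation,
    pearson_matrix,
    read_equations,
    stepwise_fit,
    write_equations,
)


class TestPearsonMatrix:
    def test_perfect_linearity(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [2.0, 4.0, 6.0, 8.0]})
        corr = pearson_matrix(df, ["x", "y"])
        assert corr.r.loc["x", "y"] == pytest.approx(1.0)
        assert corr.p.loc["x", "y"] < 1e-6
        assert (np.diag(corr.r) == 1.0).all()

    def test_perfect_anticorrelation(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [-1.0, -2.0, -3.0]})
        corr = pearson_matrix(df, ["x", "y"])
        assert corr.r.loc["x", "y"] == pytest.approx(-1.0)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        corr = pearson_matrix(df, list("abcd"))
        assert np.allclose(corr.r, corr.r.T)
        assert (corr.r.abs() <= 1.0 + 1e-12).all().all()

    def test_de_me_nearly_collinear_on_reference_panel(self):
        """Measured DE and ME across the 13 bundled cereals correlate ≥ 0.99:
        urinary losses are a small, nearly constant fraction of DE."""
        ref = ingredient_energy_reference()
        corr = pearson_matrix(ref, ["de_dm", "me_dm"])
        assert corr.r.loc["de_dm", "me_dm"] >= 0.99

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(UndefinedStatisticError):
            pearson_matrix(df, ["x", "y"])

    def test_too_few_rows(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]})
        with pytest.raises(InsufficientDataError):
            pearson_matrix(df, ["x", "y"])


class TestStepwise:
    def test_noiseless_single_predictor(self):
        x = np.linspace(0, 10, 30)
        df = pd.DataFrame({"x": x, "y": 2.0 + 3.0 * x})
        path = stepwise_fit(df, "y", ["x"])
        assert len(path) == 1
        eq = path[0]
        assert eq.intercept == pytest.approx(2.0, abs=1e-8)
        assert eq.coefficients["x"] == pytest.approx(3.0, abs=1e-9)
        assert eq.r2 == pytest.approx(1.0)

    def test_selects_true_predictors_and_recovers_coefficients(self):
        """y = 0.14·starch − 0.24·ADF + 11 + N(0, 0.05²) at n = 200: stepwise
        must pick exactly {ADF, starch} and land within 5 % of the truth."""
        rng = np.random.default_rng(314)
        n = 200
        df = pd.DataFrame(
            {
                "starch": rng.uniform(35, 72, n),
                "ADF": rng.uniform(1.5, 15, n),
                "CP": rng.uniform(7, 17, n),
                "NDF": rng.uniform(6, 28, n),
                "ash": rng.uniform(1, 6, n),
            }
        )
        df["y"] = 0.14 * df["starch"] - 0.24 * df["ADF"] + 11.0 + rng.normal(0, 0.05, n)
        path = stepwise_fit(df, "y", ["ADF", "CP", "NDF", "ash", "starch"])
        final = path[-1]
        assert set(final.coefficients) == {"ADF", "starch"}
        assert final.coefficients["starch"] == pytest.approx(0.14, rel=0.05)
        assert final.coefficients["ADF"] == pytest.approx(-0.24, rel=0.05)
        assert final.intercept == pytest.approx(11.0, rel=0.05)

    def test_r2_monotone_along_path(self):
        rng = np.random.default_rng(99)
        n = 60
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
        y = X["a"] + 0.5 * X["b"] + 0.25 * X["c"] + rng.normal(0, 0.5, n)
        path = stepwise_fit(X.assign(y=y), "y", list("abcde"))
        r2s = [eq.r2 for eq in path]
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))

    def test_collinear_candidate_skipped_with_warning(self):
        rng = np.random.default_rng(1)
        n = 40
        x = rng.normal(size=n)
        df = pd.DataFrame({"x1": x, "x2": 2.0 * x, "y": x + rng.normal(0, 0.1, n)})
        with pytest.warns(UserWarning, match="collinear"):
            path = stepwise_fit(df, "y", ["x1", "x2"])
        assert len(path[-1].coefficients) == 1

    def test_never_beats_exhaustive_subsets_and_usually_matches(self):
        """Size-k stepwise models cannot exceed the exhaustive best size-k R²
        and match it in ≥ 90 % of random Gaussian instances (6 candidates)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        n, p = 50, 6
        names = [f"x{i}" for i in range(p)]
        matches = trials = 0
        for _ in range(100):
            X = pd.DataFrame(rng.normal(size=(n, p)), columns=names)
            beta = rng.normal(0, 1, p) * rng.binomial(1, 0.5, p)
            y = X.to_numpy() @ beta + rng.normal(0, 1.0, n)
            df = X.assign(y=y)
            path = stepwise_fit(df, "y", names, sle=0.5, sls=0.5)
            for eq in path:
                k = len(eq.coefficients)
                best = max(
                    sm.OLS(y, sm.add_constant(X[list(combo)])).fit().rsquared
                    for combo in itertools.combinations(names, k)
                )
                assert eq.r2 <= best + 1e-10
                trials += 1
                if eq.r2 >= best - 1e-10:
                    matches += 1
        assert matches / trials >= 0.90


class TestApplyEquation:
    def test_intercept_only_point(self):
        eq = reference_equations()[0]  # DE from ADF alone
        assert eq.predict({"ADF": 0.0}) == pytest.approx(14.3722)

    def test_two_term_hand_arithmetic(self):
        eq = reference_equations()[1]
        value = eq.predict({"starch": 50.0, "ADF": 10.0})
        assert value == pytest.approx(0.1364 * 50 - 0.2352 * 10 + 11.4467, abs=1e-9)
        assert value == pytest.approx(15.9147, abs=1e-4)

    def test_me_from_de_and_cp(self):
        eq = reference_equations()[3]
        value = eq.predict({"DE": 14.0, "CP": 10.0})
        assert value == pytest.approx(13.6620, abs=1e-4)

    def test_profile_basis_must_match(self, panel):
        eq = reference_equations()[1]  # as-fed equation
        with pytest.raises(BasisMismatchError):
            apply_equation(eq, panel["corn 1"])  # panel is DM basis

    def test_missing_predictor_rejected(self):
        eq = reference_equations()[1]
        with pytest.raises(KeyError):
            eq.predict({"starch": 50.0})

    def test_linearity_in_coefficients(self):
        eq = reference_equations()[1]
        doubled = PredictionEquation(
            response=eq.response,
            basis=eq.basis,
            intercept=2 * eq.intercept,
            coefficients={k: 2 * v for k, v in eq.coefficients.items()},
            r2=eq.r2,
            p_value=eq.p_value,
        )
        point = {"starch": 43.0, "ADF": 7.5}
        assert doubled.predict(point) == pytest.approx(2 * eq.predict(point), rel=1e-12)


def test_equation_registry_round_trip_bit_exact(tmp_path):
    """The four bundled equations serialize and re-parse with identical floats."""
    path = tmp_path / "registry.txt"
    eqs = reference_equations()
    write_equations(path, eqs)
    back = read_equations(path)
    assert len(back) == len(eqs)
    for a, b in zip(eqs, back):
        assert a.response == b.response and a.basis is b.basis
        assert a.intercept == b.intercept
        assert a.coefficients == b.coefficients
        assert a.r2 == b.r2 and a.p_value == b.p_value
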