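"""Orthogonal polynomials, codings, OLS/mixed fits, selection, contrasts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from turnload.inference import (
    ModelSpec,
    RankError,
    contrast_code,
    deviation_code,
    emm_simple_effects,
    fit_lm,
    fit_mixed,
    fit_polynomial_model,
    orthogonal_poly,
    predict_position_curve,
    select_polynomial_model,
)


class TestOrthogonalPoly:
    def test_columns_orthonormal(self, rng):
        for _ in range(10):
            x = rng.normal(size=60)
            basis = orthogonal_poly(x, 4)
            gram = basis.columns.T @ basis.columns
            assert np.abs(gram - np.eye(4)).max() < 1e-8

    def test_symmetric_input_gives_odd_and_even_columns(self):
        x = np.linspace(-1, 1, 21)
        basis = orthogonal_poly(x, 2)
        lin, quad = basis.columns.T
        assert lin == pytest.approx(-lin[::-1])
        assert quad == pytest.approx(quad[::-1])
        assert abs(lin @ quad) < 1e-12

    def test_equispaced_points_match_classical_contrasts(self):
        # classical discrete orthogonal-polynomial contrasts for 5 levels
        classical = {
            1: np.array([-2, -1, 0, 1, 2], dtype=float),
            2: np.array([2, -1, -2, -1, 2], dtype=float),
            3: np.array([-1, 2, 0, -2, 1], dtype=float),
        }
        basis = orthogonal_poly(np.arange(5, dtype=float), 3)
        for k, expected in classical.items():
            col = basis.columns[:, k - 1]
            nz = expected != 0
            ratio = col[nz] / expected[nz]
            assert np.ptp(ratio) < 1e-10  # proportional
            assert np.abs(col[~nz]).max(initial=0.0) < 1e-12

    def test_matches_gram_schmidt_oracle(self, rng):
        x = rng.uniform(0, 1, size=40)
        degree = 3
        # brute-force: orthonormalise [1, x, x^2, x^3] and drop the constant
        V = np.column_stack([x ** k for k in range(degree + 1)])
        Q = np.zeros_like(V)
        for j in range(degree + 1):
            v = V[:, j].copy()
            for i in range(j):
                v -= (Q[:, i] @ V[:, j]) * Q[:, i]
            Q[:, j] = v / np.linalg.norm(v)
        oracle = Q[:, 1:]
        basis = orthogonal_poly(x, degree)
        for k in range(degree):
            col = basis.columns[:, k]
            sign = np.sign(col @ oracle[:, k])
            assert col == pytest.approx(sign * oracle[:, k], abs=1e-8)

    def test_transform_reproduces_fit_columns(self, rng):
        x = rng.uniform(-2, 3, size=30)
        basis = orthogonal_poly(x, 5)
        assert basis.transform(x) == pytest.approx(basis.columns, abs=1e-10)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(RankError):
            orthogonal_poly(np.array([0.0, 1.0, 0.0, 1.0]), 2)


class TestCodings:
    def test_contrast_codes_sum_to_zero(self):
        s = pd.Series(["speaker", "recipient", "speaker"])
        coded = contrast_code(s, {"speaker": 0.5, "recipient": -0.5})
        assert coded.tolist() == [0.5, -0.5, 0.5]
        with pytest.raises(ValueError, match="sum to zero"):
            contrast_code(s, {"speaker": 1.0, "recipient": 0.0})

    def test_deviation_columns(self):
        s = pd.Series(["function", "noun", "insert"])
        codes = deviation_code(s, ("function", "noun", "insert"),
                               omit="function")
        assert codes["noun"].tolist() == [-1.0, 1.0, 0.0]
        assert codes["insert"].tolist() == [-1.0, 0.0, 1.0]
        assert codes.sum(axis=0).tolist() == [0.0, 0.0]

    def test_releveling_changes_coefficients_not_predictions(self, rng):
        levels = ("function", "noun", "insert")
        cls = pd.Series(rng.choice(levels, size=90))
        y = cls.map({"function": 1.0, "noun": 3.0, "insert": -2.0}).to_numpy()
        y = y + rng.normal(0, 0.5, size=90)
        preds = {}
        for omit in levels:
            codes = deviation_code(cls, levels, omit=omit)
            df = pd.DataFrame({"y": y})
            cols = [c for c in levels if c != omit]
            for c in cols:
                df[c] = codes[c].to_numpy()
            res = fit_lm(ModelSpec("y", cols), df)
            X = np.column_stack([np.ones(90)] + [df[c] for c in cols])
            preds[omit] = X @ res.params.to_numpy()
        base = preds["function"]
        for omit in ("noun", "insert"):
            assert preds[omit] == pytest.approx(base, abs=1e-8)


class TestFitLm:
    def test_exact_linear_data(self, rng):
        x = rng.uniform(0, 1, size=30)
        df = pd.DataFrame({"x": x, "y": 2.0 + 3.0 * x})
        res = fit_lm(ModelSpec("y", ["x"]), df)
        assert res.params["x"] == pytest.approx(3.0, abs=1e-10)
        assert res.params["Intercept"] == pytest.approx(2.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            X = rng.normal(size=(25, 3))
            y = rng.normal(size=25)
            df = pd.DataFrame(X, columns=["a", "b", "c"])
            df["y"] = y
            res = fit_lm(ModelSpec("y", ["a", "b", "c"]), df)
            Xd = np.column_stack([np.ones(25), X])
            beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
            assert res.params.to_numpy() == pytest.approx(beta, abs=1e-8)

    def test_rank_deficiency_names_aliased_terms(self, rng):
        x = rng.normal(size=20)
        df = pd.DataFrame({"x": x, "x2": 2 * x, "y": rng.normal(size=20)})
        with pytest.raises(RankError, match="aliased"):
            fit_lm(ModelSpec("y", ["x", "x2"]), df)

    def test_type_one_error_rate_near_nominal(self, rng):
        hits = 0
        reps = 300
        for _ in range(reps):
            df = pd.DataFrame({"x": rng.normal(size=120),
                               "y": rng.normal(size=120)})
            res = fit_lm(ModelSpec("y", ["x"]), df)
            if abs(res.table.loc[res.table["term"] == "x", "stat"].iloc[0]) > 1.96:
                hits += 1
        assert 0.02 <= hits / reps <= 0.09


class TestFitMixed:
    def test_zero_variance_matches_ols(self, rng):
        # balanced design: every participant sees the same x grid, so the
        # mixed fixed effects coincide with plain least squares when no
        # group variance was simulated
        x_grid = np.linspace(-1, 1, 50)
        df = pd.DataFrame({
            "x": np.tile(x_grid, 8),
            "participant": np.repeat([f"p{i}" for i in range(8)], 50),
        })
        df["conversation"] = df["participant"].map(
            lambda p: f"c{int(p[1:]) // 2}")
        df["y"] = 1.0 + 0.8 * df["x"] + rng.normal(0, 1.0, size=len(df))
        mixed = fit_mixed(ModelSpec("y", ["x"],
                                    ("participant", "conversation")), df)
        ols = fit_lm(ModelSpec("y", ["x"]), df)
        assert mixed.params.to_numpy() == pytest.approx(
            ols.params.to_numpy(), abs=1e-4)

    def test_balanced_two_group_effect_recovery(self, rng):
        delta, sigma_u = 1.5, 1.0
        groups = np.repeat([f"g{i}" for i in range(20)], 30)
        offsets = dict(zip([f"g{i}" for i in range(20)],
                           rng.normal(0, sigma_u, 20)))
        x = np.tile([0.5, -0.5], 300)
        y = (delta * x + np.array([offsets[g] for g in groups])
             + rng.normal(0, 1.0, 600))
        df = pd.DataFrame({"x": x, "y": y, "g": groups})
        res = fit_mixed(ModelSpec("y", ["x"], ("g",)), df)
        se = res.table.loc[res.table["term"] == "x", "se"].iloc[0]
        assert abs(res.params["x"] - delta) < 3 * se
        assert res.random_variances["g"] == pytest.approx(sigma_u ** 2,
                                                          rel=0.8)

    def test_nested_grouping_recovers_both_variances(self, rng):
        # 6 participants nested in 3 conversations, real variance at both levels
        conv_sd, part_sd = 2.0, 1.5
        rows = []
        conv_off = {f"c{j}": rng.normal(0, conv_sd) for j in range(3)}
        for j in range(3):
            for k in range(2):
                pid = f"c{j}_p{k}"
                p_off = rng.normal(0, part_sd)
                for _ in range(120):
                    x = rng.normal()
                    y = (0.5 * x + conv_off[f"c{j}"] + p_off
                         + rng.normal(0, 1.0))
                    rows.append((x, y, pid, f"c{j}"))
        df = pd.DataFrame(rows, columns=["x", "y", "participant",
                                         "conversation"])
        res = fit_mixed(ModelSpec("y", ["x"],
                                  ("participant", "conversation")), df)
        assert res.params["x"] == pytest.approx(0.5, abs=0.15)
        assert res.random_variances["participant"] > 0.1

    def test_requires_grouping_levels(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0],
                           "g": ["a", "a"]})
        with pytest.raises(ValueError, match="levels"):
            fit_mixed(ModelSpec("y", ["x"], ("g",)), df)


class TestPolynomialSelection:
    @staticmethod
    def _linear_data(rng, n=4000):
        x = rng.uniform(0, 1, size=n)
        return pd.DataFrame({"pos": x,
                             "y": 2.0 - 3.0 * x + rng.normal(0, 1.0, n)})

    def test_pure_linear_trend_stops_at_degree_one(self, rng):
        # the quadratic step has a ~5% type-I chance per replicate, so the
        # large-n behaviour is checked over replicates, not a single draw
        selected = [
            select_polynomial_model(self._linear_data(rng), "y", "pos",
                                    max_degree=4).selected_degree
            for _ in range(10)
        ]
        assert sum(d == 1 for d in selected) >= 8

    def test_large_cubic_trend_selects_degree_three(self, rng):
        # x on [0, 1]: a strong cubic projects onto all three orthogonal
        # polynomial directions, so stepwise growth reaches degree 3
        x = rng.uniform(0, 1, size=3000)
        y = 40.0 * x ** 3 - 2.0 * x + rng.normal(0, 1.0, 3000)
        df = pd.DataFrame({"pos": x, "y": y})
        res = select_polynomial_model(df, "y", "pos", max_degree=5)
        assert res.selected_degree == 3

    def test_max_degree_one_returns_linear_untouched(self, rng):
        res = select_polynomial_model(self._linear_data(rng), "y", "pos",
                                      max_degree=1)
        assert res.selected_degree == 1
        assert [t for t in res.params.index] == ["Intercept", "Position"]

    def test_nonsignificant_control_interaction_pruned(self, rng):
        n = 3000
        x = rng.uniform(0, 1, size=n)
        z = rng.normal(size=n)
        # control has a main effect but no interaction with position
        y = 1.0 - 2.0 * x + 0.5 * z + rng.normal(0, 1.0, n)
        df = pd.DataFrame({"pos": x, "y": y, "z": z})
        res = select_polynomial_model(df, "y", "pos", controls=["z"],
                                      max_degree=2)
        trace = pd.DataFrame(res.trace)
        pruned = trace[(trace["phase"] == "prune")
                       & (trace["action"] == "removed")]
        assert "Position:z" in set(pruned["term"])
        assert "Position:z" not in res.params.index
        assert "z" in res.params.index

    def test_selection_trace_is_reproducible(self, rng):
        df = self._linear_data(rng, n=800)
        r1 = select_polynomial_model(df, "y", "pos", max_degree=3)
        r2 = select_polynomial_model(df, "y", "pos", max_degree=3)
        assert r1.trace == r2.trace
        assert r1.params.to_numpy() == pytest.approx(r2.params.to_numpy())


class TestEmmSimpleEffects:
    @staticmethod
    def _fit_with_role(rng, interaction):
        n = 2000
        x = rng.uniform(0, 1, n)
        role = np.where(rng.random(n) < 0.5, 0.5, -0.5)
        y = 1.0 + 2.0 * x + interaction * x * role + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"pos": x, "Role": role, "y": y})
        return fit_polynomial_model(df, "y", "pos", 1,
                                    factors={"Role": ["Role"]})

    def test_zero_interaction_levels_equal_main_effect(self, rng):
        res = self._fit_with_role(rng, interaction=0.0)
        emm = emm_simple_effects(res, ["Position"], by="Role",
                                 levels={"speaker": 0.5, "recipient": -0.5})
        main = res.params["Position"]
        assert emm["estimate"].to_numpy() == pytest.approx(
            [main + 0.5 * res.params["Position:Role"],
             main - 0.5 * res.params["Position:Role"]])

    def test_coding_algebra_identity(self, rng):
        res = self._fit_with_role(rng, interaction=3.0)
        emm = emm_simple_effects(res, ["Position"], by="Role",
                                 levels={"speaker": 0.5, "recipient": -0.5})
        main = res.params["Position"]
        inter = res.params["Position:Role"]
        by_level = dict(zip(emm["level"], emm["estimate"]))
        assert by_level["speaker"] == pytest.approx(main + 0.5 * inter)
        assert by_level["recipient"] == pytest.approx(main - 0.5 * inter)

    def test_adjusted_p_not_below_unadjusted(self, rng):
        res = self._fit_with_role(rng, interaction=1.0)
        emm = emm_simple_effects(res, ["Position"], by="Role",
                                 levels={"speaker": 0.5, "recipient": -0.5})
        assert (emm["p_adjusted"] >= emm["p_unadjusted"] - 1e-15).all()

    def test_missing_interaction_rejected(self, rng):
        df = pd.DataFrame({"pos": rng.uniform(0, 1, 50),
                           "y": rng.normal(size=50)})
        res = fit_polynomial_model(df, "y", "pos", 1)
        with pytest.raises(KeyError, match="does not interact"):
            emm_simple_effects(res, ["Position"], by="Role",
                               levels={"speaker": 0.5, "recipient": -0.5})


def test_predicted_curve_matches_manual_combination(rng):
    x = rng.uniform(0, 1, 500)
    y = 1.0 + 4.0 * x - 2.0 * x ** 2 + rng.normal(0, 0.3, 500)
    df = pd.DataFrame({"pos": x, "y": y})
    res = fit_polynomial_model(df, "y", "pos", 2)
    grid = np.linspace(0, 1, 7)
    cols = res.basis.transform(grid)
    manual = (res.params["Intercept"] + res.params["Position"] * cols[:, 0]
              + res.params["Position^2"] * cols[:, 1])
    assert predict_position_curve(res, grid) == pytest.approx(manual)
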