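"""2^3 full-factorial model: contrasts, diagnostics, prediction, grids."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedshield import factorial_doe as fd
from seedshield import synthetic_data

SL_PRINTED = {"I": 4.28, "A": -0.03, "B": -0.04, "C": 0.16,
              "AB": 0.01, "AC": -0.01, "BC": -0.02, "ABC": 0.01}


def design_from_responses(y, name="y"):
    corners = [(a, b, c) for c in (-1, 1) for b in (-1, 1) for a in (-1, 1)]
    rows = [{"A": a, "B": b, "C": c, name: v} for (a, b, c), v in zip(corners, y)]
    return fd.FactorialDesign(runs=pd.DataFrame(rows))


class TestDesignValidation:
    def test_model_matrix_is_orthogonal(self, fixtures):
        X = fixtures.design().model_matrix()
        np.testing.assert_allclose(X.T @ X, 8 * np.eye(8))

    def test_missing_corner_rejected(self, fixtures):
        with pytest.raises(ValueError, match="missing runs"):
            fd.FactorialDesign(runs=fixtures.table1.iloc[:7].copy())

    def test_non_coded_levels_rejected(self, fixtures):
        bad = fixtures.table1.copy()
        bad["A"] = bad["A"].astype(float)
        bad.loc[0, "A"] = 0.5
        with pytest.raises(ValueError, match="coded"):
            fd.FactorialDesign(runs=bad)

    def test_factor_decoding(self, fixtures):
        d = fixtures.design()
        assert d.decode("C", -1) == pytest.approx(0.1)
        assert d.decode("C", 1) == pytest.approx(0.5)
        assert d.decode("A", 1) == pytest.approx(2.0)


class TestFit:
    def test_weevil_model_matches_printed_coefficients(self, fixtures):
        """All 8 printed S. lineatus coefficients reproduce at 2 d.p."""
        fit = fd.fit(fixtures.design(), "pLD50_SL")
        assert fit.rounded_coefficients() == SL_PRINTED
        assert fit.coefficients["C"] == pytest.approx(0.16, abs=1e-12)
        assert fit.coefficients["I"] == pytest.approx(4.2825, abs=1e-12)

    def test_bruchid_main_effects_match_printed(self, fixtures):
        fit = fd.fit(fixtures.design(), "pLD50_BP")
        assert fit.coefficients["C"] == pytest.approx(0.13, abs=1e-12)
        rounded = fit.rounded_coefficients()
        assert rounded["I"] == 4.40
        assert rounded["A"] == -0.01 and rounded["B"] == -0.02

    def test_constant_response(self):
        fit = fd.fit(design_from_responses([7.0] * 8), "y")
        assert fit.coefficients["I"] == pytest.approx(7.0)
        assert all(abs(fit.coefficients[t]) < 1e-12 for t in fd.TERMS if t != "I")

    def test_saturated_fit_interpolates_exactly(self, fixtures):
        fit = fd.fit(fixtures.design(), "pLD50_SL")
        np.testing.assert_allclose(fit.fitted, fit.y, atol=1e-12)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.floats(-10, 10), min_size=8, max_size=8))
    def test_contrasts_equal_normal_equation_solution(self, y):
        """The contrast formula solves the 8x8 normal equations exactly."""
        design = design_from_responses(y)
        fit = fd.fit(design, "y")
        X = design.model_matrix()
        beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(y))
        np.testing.assert_allclose(fit.coef_vector, beta, atol=1e-9)

    def test_exact_recovery_of_generating_coefficients(self):
        mu = (4.28, -0.03, -0.04, 0.16, 0.01, -0.01, -0.02, 0.01)
        design = synthetic_data.simulate_factorial(
            synthetic_data.FactorialSimSpec(coefficients=mu, sigma=0.0)
        )
        fit = fd.fit(design, "response")
        np.testing.assert_allclose(fit.coef_vector, mu, atol=1e-12)

    def test_orthogonality_coefficients_stable_under_term_drop(self, fixtures):
        """Main-effect estimates match single-column regressions."""
        design = fixtures.design()
        fit = fd.fit(design, "pLD50_SL")
        y = design.runs["pLD50_SL"].to_numpy()
        for col in ("A", "B", "C"):
            x = design.runs[col].to_numpy(dtype=float)
            single = np.polyfit(x, y, 1)[0]
            assert fit.coefficients[col] == pytest.approx(single, abs=1e-12)


class TestPredict:
    def test_printed_model_at_optimum_corner(self, fixtures):
        """The model evaluated at (-1,-1,+1) returns the observed optimum 4.56."""
        fit = fd.fit(fixtures.design(), "pLD50_SL")
        assert fd.predict(fit, (-1, -1, 1)) == pytest.approx(4.56)

    def test_corner_prediction_equals_observation(self, fixtures):
        design = fixtures.design()
        fit = fd.fit(design, "pLD50_SL")
        for _, row in design.runs.iterrows():
            got = fd.predict(fit, (row["A"], row["B"], row["C"]))
            assert got == pytest.approx(row["pLD50_SL"], abs=1e-12)

    def test_center_point_is_intercept(self, fixtures):
        fit = fd.fit(fixtures.design(), "pLD50_BP")
        assert fd.predict(fit, (0, 0, 0)) == pytest.approx(fit.coefficients["I"])

    def test_extrapolation_warns(self, fixtures):
        fit = fd.fit(fixtures.design(), "pLD50_SL")
        with pytest.warns(UserWarning, match="outside"):
            fd.predict(fit, (1.5, 0, 0))


class TestSummaryStats:
    def test_response_means_match_printed_table(self, fixtures):
        sl = fd.summary_stats(fd.fit(fixtures.design(), "pLD50_SL"))
        bp = fd.summary_stats(fd.fit(fixtures.design(), "pLD50_BP"))
        assert round(sl["mean"], 2) == 4.28
        assert round(bp["mean"], 2) == 4.40

    def test_saturated_model_flags_undefined_error_stats(self, fixtures):
        stats = fd.summary_stats(fd.fit(fixtures.design(), "pLD50_SL"))
        assert stats["residual_df"] == 0
        assert stats["r_squared"] == pytest.approx(1.0)
        for key in ("sd", "cv_pct", "f_value", "p_value", "adequate_precision",
                    "pred_r_squared"):
            assert stats[key] == "undefined (saturated model)"

    def test_replicated_zero_noise_fit_has_perfect_prediction(self):
        mu = (4.0, 0.1, -0.2, 0.3, 0.0, 0.0, 0.0, 0.0)
        design = synthetic_data.simulate_factorial(
            synthetic_data.FactorialSimSpec(coefficients=mu, sigma=0.0, replicates=2)
        )
        stats = fd.summary_stats(fd.fit(design, "response"))
        assert stats["residual_df"] == 8
        assert stats["sd"] == pytest.approx(0.0, abs=1e-12)
        assert stats["r_squared"] == pytest.approx(1.0)
        assert stats["pred_r_squared"] == pytest.approx(1.0)

    def test_press_matches_brute_force_loo(self):
        """Implementation PRESS equals an explicit leave-one-out refit loop."""
        mu = (4.3, -0.05, 0.02, 0.15, 0.01, 0.0, -0.02, 0.0)
        design = synthetic_data.simulate_factorial(
            synthetic_data.FactorialSimSpec(coefficients=mu, sigma=0.05,
                                            replicates=2, seed=21)
        )
        fit = fd.fit(design, "response")
        stats = fd.summary_stats(fit)
        X = design.model_matrix()
        y = fit.y
        press = 0.0
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            beta, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
            press += (y[i] - X[i] @ beta) ** 2
        assert stats["press"] == pytest.approx(press, rel=1e-10)
        assert stats["pred_r_squared"] <= stats["r_squared"]
        assert stats["adj_r_squared"] <= stats["r_squared"]

    def test_cv_is_sd_over_mean(self):
        mu = (5.0, 0.2, 0.0, 0.4, 0.0, 0.0, 0.0, 0.0)
        design = synthetic_data.simulate_factorial(
            synthetic_data.FactorialSimSpec(coefficients=mu, sigma=0.1,
                                            replicates=3, seed=2)
        )
        stats = fd.summary_stats(fd.fit(design, "response"))
        assert stats["cv_pct"] == pytest.approx(100 * stats["sd"] / stats["mean"])


class TestContourGrid:
    def test_constant_model_gives_flat_grid(self):
        fit = fd.fit(design_from_responses([3.0] * 8), "y")
        grid = fd.contour_grid(fit, ("A", "B"), fixed_level=-1, resolution=5)
        np.testing.assert_allclose(grid["y"], 3.0)

    def test_grid_corners_match_predict(self, fixtures):
        fit = fd.fit(fixtures.design(), "pLD50_SL")
        grid = fd.contour_grid(fit, ("A", "C"), fixed_level=-1, resolution=5)
        for _, row in grid[grid["A"].abs().eq(1) & grid["C"].abs().eq(1)].iterrows():
            assert row["pLD50_SL"] == pytest.approx(
                fd.predict(fit, (row["A"], -1, row["C"]))
            )

    def test_weevil_response_maximised_at_low_collagen_high_toxin(self, fixtures):
        """Signs of the A and C effects put the optimum at A=-1, C=+1."""
        fit = fd.fit(fixtures.design(), "pLD50_SL")
        grid = fd.contour_grid(fit, ("A", "C"), fixed_level=-1, resolution=5)
        best = grid.loc[grid["pLD50_SL"].idxmax()]
        assert (best["A"], best["C"]) == (-1.0, 1.0)

    def test_unknown_factor_rejected(self, fixtures):
        fit = fd.fit(fixtures.design(), "pLD50_SL")
        with pytest.raises(ValueError):
            fd.contour_grid(fit, ("A", "Z"))
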