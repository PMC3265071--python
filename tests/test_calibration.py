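"""Tests for the coefficient-derivation (fitting) pipeline.

Every least-squares result is cross-checked against a hand-rolled
normal-equations solver, independent of the statsmodels-backed implementation.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from estrorisk import (
    DoublingRiskModel,
    InvalidInputError,
    LogLinearModel,
    SaturationPolicy,
    compose_risk_model,
    fit_ert_ratio,
    fit_loglinear_concentration,
    fit_rr_doubling_through_reference,
)
from estrorisk.calibration import (
    AlignmentError,
    InsufficientStrataError,
    ReferenceRowError,
    SingularFitError,
)
from estrorisk.synthetic import (
    generate_concentration_table,
    generate_quantile_risk_table,
    generate_ratio_tables,
)
from conftest import sig_round

POSTMENO = LogLinearModel(0.068847, -29.984)
PREMENO = LogLinearModel(-0.039851, -24.906)
RATIO = LogLinearModel(-0.023098, 1.2617)


def ols_oracle(x, y, w=None):
    """Weighted normal equations, solved directly: returns (intercept, slope)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.ones_like(x) if w is None else np.asarray(w, float)
    A = np.array([[w.sum(), (w * x).sum()], [(w * x).sum(), (w * x * x).sum()]])
    b = np.array([(w * y).sum(), (w * x * y).sum()])
    return np.linalg.solve(A, b)


def through_reference_oracle(x, y, w=None):
    """No-intercept least-squares slope: sum(w x y) / sum(w x^2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.ones_like(x) if w is None else np.asarray(w, float)
    return float((w * x * y).sum() / (w * x * x).sum())


class TestConcentrationFit:
    def test_noise_free_recovery_of_default_coefficients(self):
        table = generate_concentration_table(
            POSTMENO.slope, POSTMENO.intercept, median_bmis=(21, 24, 27, 31)
        )
        model = fit_loglinear_concentration(table)
        assert model.slope == pytest.approx(0.068847, abs=1e-10)
        assert model.intercept == pytest.approx(-29.984, abs=1e-9)

    @given(
        slope=st.floats(-0.2, 0.2), intercept=st.floats(-35.0, -20.0)
    )
    def test_noise_free_recovery_is_exact_for_any_line(self, slope, intercept):
        table = generate_concentration_table(slope, intercept)
        model = fit_loglinear_concentration(table)
        assert model.slope == pytest.approx(slope, abs=1e-9)
        assert model.intercept == pytest.approx(intercept, abs=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            x = np.sort(rng.uniform(18, 35, size=6))
            y = -30 + 0.07 * x + rng.normal(0, 0.2, size=6)
            n = rng.integers(50, 500, size=6)
            table = pd.DataFrame(
                {
                    "bmi_low": np.nan,
                    "bmi_high": np.nan,
                    "median_bmi": x,
                    "mean_log_e2f": y,
                    "n": n,
                }
            )
            for weighted in (False, True):
                model = fit_loglinear_concentration(table, weight_by_n=weighted)
                ref = ols_oracle(x, y, n if weighted else None)
                assert model.intercept == pytest.approx(ref[0], abs=1e-10)
                assert model.slope == pytest.approx(ref[1], abs=1e-10)

    def test_equal_shift_of_symmetric_points_preserves_slope(self):
        # adding the same delta at two medians equidistant from the mean BMI
        # leaves the OLS slope unchanged (only the intercept moves)
        medians = (20.0, 24.0, 28.0, 32.0)
        base = generate_concentration_table(0.05, -29.0, median_bmis=medians)
        shifted = base.copy()
        delta = 0.3
        shifted.loc[1, "mean_log_e2f"] += delta  # median 24, mean - 2
        shifted.loc[2, "mean_log_e2f"] += delta  # median 28, mean + 2
        s0 = fit_loglinear_concentration(base).slope
        s1 = fit_loglinear_concentration(shifted).slope
        assert s1 == pytest.approx(s0, abs=1e-12)

    def test_too_few_strata_rejected(self):
        with pytest.raises(InsufficientStrataError):
            generate_concentration_table(0.07, -30.0, median_bmis=(21, 25))
        table = generate_concentration_table(0.07, -30.0).iloc[:2]
        with pytest.raises(InsufficientStrataError):
            fit_loglinear_concentration(table)

    def test_identical_medians_rejected(self):
        table = generate_concentration_table(0.07, -30.0)
        table["median_bmi"] = 25.0
        with pytest.raises(SingularFitError):
            fit_loglinear_concentration(table)

    def test_variance_shrinks_with_more_strata(self, rng):
        # Monte-Carlo: the slope estimator's variance is smaller with 16
        # strata than with 4, at equal per-stratum noise.
        def slope_var(medians, reps=300):
            slopes = [
                fit_loglinear_concentration(
                    generate_concentration_table(
                        0.068847, -29.984, medians, noise_sd=0.5,
                        n_per_stratum=25, rng=rng,
                    )
                ).slope
                for _ in range(reps)
            ]
            return np.var(slopes)

        var4 = slope_var(np.linspace(20, 32, 4))
        var16 = slope_var(np.linspace(20, 32, 16))
        assert var16 < var4


class TestErtRatioFit:
    def test_noise_free_recovery(self):
        user, nonuser = generate_ratio_tables(POSTMENO, RATIO)
        model = fit_ert_ratio(user, nonuser)
        assert model.slope == pytest.approx(RATIO.slope, abs=1e-10)
        assert model.intercept == pytest.approx(RATIO.intercept, abs=1e-9)
        # recovered ratio composed with the base model at the reference BMI
        combined = POSTMENO.compose(model)
        assert combined.predict(23.0) == pytest.approx(
            9.617008108983258e-13, rel=1e-9
        )

    def test_identical_tables_give_unit_ratio(self):
        table = generate_concentration_table(0.07, -30.0)
        model = fit_ert_ratio(table, table)
        assert model.slope == pytest.approx(0.0, abs=1e-12)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_categories_rejected(self):
        user, _ = generate_ratio_tables(POSTMENO, RATIO, median_bmis=(21, 24, 27, 31))
        _, nonuser = generate_ratio_tables(POSTMENO, RATIO, median_bmis=(20, 24, 27, 31))
        with pytest.raises(AlignmentError):
            fit_ert_ratio(user, nonuser)

    def test_weighted_matches_oracle(self, rng):
        user, nonuser = generate_ratio_tables(
            POSTMENO, RATIO, noise_sd=0.3, n_per_stratum=50, rng=rng
        )
        user["n"] = [40, 80, 120, 160]
        nonuser["n"] = [400, 300, 200, 100]
        model = fit_ert_ratio(user, nonuser, weight_by_n=True)
        x = user["median_bmi"].to_numpy()
        y = user["mean_log_e2f"].to_numpy() - nonuser["mean_log_e2f"].to_numpy()
        w = 1.0 / (1.0 / user["n"].to_numpy() + 1.0 / nonuser["n"].to_numpy())
        ref = ols_oracle(x, y, w)
        assert model.intercept == pytest.approx(ref[0], abs=1e-10)
        assert model.slope == pytest.approx(ref[1], abs=1e-10)


class TestThroughReferenceFit:
    MIDPOINTS = (1.5e-12, 2.5e-12, 4.0e-12, 6.5e-12)

    def test_published_slope_maps_to_per_doubling_risk(self):
        table = generate_quantile_risk_table(0.7671, self.MIDPOINTS)
        risk = fit_rr_doubling_through_reference(table)
        assert sig_round(risk.rr_per_doubling, 5) == 1.7018

    @pytest.mark.parametrize(
        "exponent,expected",
        [(1.0, 2.0), (np.log2(1.5), 1.5), (0.0, 1.0)],
    )
    def test_exponent_inversion(self, exponent, expected):
        table = generate_quantile_risk_table(exponent, self.MIDPOINTS)
        risk = fit_rr_doubling_through_reference(table)
        assert risk.rr_per_doubling == pytest.approx(expected, rel=1e-10)

    def test_line_passes_through_reference(self, rng):
        table = generate_quantile_risk_table(
            0.8, self.MIDPOINTS, reference_index=1, noise_sd=0.1, rng=rng
        )
        risk, res = fit_rr_doubling_through_reference(table, full_output=True)
        # at the reference concentration the fitted log-log line is exactly 0
        assert res.intercept is None
        x = np.log(table["e2f_mid_mol_per_L"]) - np.log(
            table.loc[table["is_reference"], "e2f_mid_mol_per_L"].iloc[0]
        )
        assert res.slope * x[table["is_reference"]].iloc[0] == 0.0

    def test_matches_oracle_and_reference_inclusion_is_neutral(self, rng):
        table = generate_quantile_risk_table(
            0.7671, self.MIDPOINTS, noise_sd=0.15, n_cases=80, rng=rng
        )
        ref_e = table.loc[table["is_reference"], "e2f_mid_mol_per_L"].iloc[0]
        nonref = table[~table["is_reference"]]
        x = np.log(nonref["e2f_mid_mol_per_L"] / ref_e)
        y = np.log(nonref["rr"])
        for weighted in (False, True):
            w = nonref["n_cases"].to_numpy(float) if weighted else None
            expected = 2.0 ** through_reference_oracle(x, y, w)
            fit_a = fit_rr_doubling_through_reference(table, weight_by_cases=weighted)
            fit_b = fit_rr_doubling_through_reference(
                table, weight_by_cases=weighted, include_reference=True
            )
            assert fit_a.rr_per_doubling == pytest.approx(expected, rel=1e-10)
            assert fit_b.rr_per_doubling == pytest.approx(expected, rel=1e-10)

    def test_reference_row_validation(self):
        table = generate_quantile_risk_table(0.8, self.MIDPOINTS)
        bad = table.copy()
        bad["is_reference"] = False
        with pytest.raises(ReferenceRowError):
            fit_rr_doubling_through_reference(bad)
        bad = table.copy()
        bad["is_reference"] = True
        with pytest.raises(ReferenceRowError):
            fit_rr_doubling_through_reference(bad)
        bad = table.copy()
        bad.loc[2, "rr"] = -0.5
        with pytest.raises(InvalidInputError):
            fit_rr_doubling_through_reference(bad)


class TestComposition:
    def test_postmenopausal_composition_matches_printed_line(self):
        model = compose_risk_model(
            POSTMENO, DoublingRiskModel(1.50), 23.0, SaturationPolicy(7.50e-13)
        )
        assert sig_round(model.slope, 5) == 0.040273
        assert sig_round(model.intercept, 5) == -0.92628

    def test_premenopausal_composition_matches_printed_line(self):
        model = compose_risk_model(PREMENO, DoublingRiskModel(1.7018), 23.0)
        assert sig_round(model.slope, 4) == -0.03057
        assert round(model.intercept, 5) == 0.70307

    def test_null_risk_model_gives_flat_rr(self):
        model = compose_risk_model(POSTMENO, DoublingRiskModel(1.0), 23.0)
        assert model.slope == 0.0
        for b in (16, 23, 38):
            assert model.rr(b) == 1.0

    def test_reference_above_cap_rejected(self):
        with pytest.raises(InvalidInputError):
            compose_risk_model(
                POSTMENO, DoublingRiskModel(1.5), 32.0, SaturationPolicy(7.50e-13)
            )
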