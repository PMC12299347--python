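"""Residual-model prediction, closed-form inversions and OLS refitting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clleach.errors import (
    DegenerateModelError,
    DomainError,
    InsufficientDataError,
    SingularDesignError,
)
from clleach.residual import (
    PUBLISHED_MODEL,
    ResidualModel,
    ResidualRegression,
    allowable_cl_dose,
    predict,
    refit,
    required_rainfall,
)

rain_st = st.floats(0, 150)
dose_st = st.floats(0, 112.5)
clay_st = st.floats(5, 20)


class TestPredict:
    @pytest.mark.parametrize(
        "rain, dose, clay, expected",
        [
            (0.0, 0.0, 0.0, 38.518),  # intercept
            (270.0, 112.5, 12.9, 2.6608),
            (100.0, 37.5, 9.8, 27.4391),
        ],
    )
    def test_worked_examples(self, rain, dose, clay, expected):
        p = predict(PUBLISHED_MODEL, rain, dose, clay)
        assert p.value == pytest.approx(expected, abs=1e-9)
        assert not p.clamped

    def test_fully_leached_prediction_clamps_to_zero(self):
        p = predict(PUBLISHED_MODEL, 300.0, 0.0, 9.8)
        assert p.raw == pytest.approx(-21.7234, abs=1e-4)
        assert p.value == 0.0 and p.clamped

    def test_clay_outside_envelope_flags_extrapolation(self):
        assert predict(PUBLISHED_MODEL, 50, 37.5, 30.0).extrapolation
        assert not predict(PUBLISHED_MODEL, 50, 37.5, 10.5).extrapolation

    def test_rejects_non_finite(self):
        with pytest.raises(DomainError):
            predict(PUBLISHED_MODEL, float("nan"), 0, 10)

    @given(rain_st, rain_st, dose_st, dose_st, clay_st, clay_st,
           st.floats(0, 1))
    def test_affine_in_inputs(self, r1, r2, d1, d2, c1, c2, alpha):
        """Raw prediction is affine: it commutes with convex combinations."""
        m = PUBLISHED_MODEL
        blend = m.raw(
            alpha * r1 + (1 - alpha) * r2,
            alpha * d1 + (1 - alpha) * d2,
            alpha * c1 + (1 - alpha) * c2,
        )
        parts = alpha * m.raw(r1, d1, c1) + (1 - alpha) * m.raw(r2, d2, c2)
        assert blend == pytest.approx(parts, abs=1e-9)

    def test_monotonicity_with_default_signs(self):
        m = PUBLISHED_MODEL
        base = m.raw(100, 75, 11)
        assert m.raw(120, 75, 11) < base  # more rain leaches
        assert m.raw(100, 90, 11) > base  # more dose adds
        assert m.raw(100, 75, 12) > base  # more clay retains


class TestInversions:
    def test_required_rainfall_example(self):
        inv = required_rainfall(PUBLISHED_MODEL, 20.0, 75.0, 12.9)
        assert inv.value == pytest.approx(166.3393, abs=1e-4)
        assert inv.flag is None

    def test_rainfall_zero_when_already_at_target(self):
        assert required_rainfall(PUBLISHED_MODEL, 38.518, 0.0, 0.0).value == 0.0

    def test_rainfall_flag_when_below_target(self):
        inv = required_rainfall(PUBLISHED_MODEL, 60.0, 0.0, 10.0)
        assert inv.value == 0.0 and inv.flag == "already_below_target"

    def test_allowable_dose_example(self):
        # zero-dose prediction at 100 mm, clay 12.9 is 23.8033 mg/kg
        inv = allowable_cl_dose(PUBLISHED_MODEL, 30.0, 100.0, 12.9)
        assert inv.value == pytest.approx((30.0 - 23.8033) / 0.143, abs=1e-4)

    def test_allowable_dose_unreachable(self):
        inv = allowable_cl_dose(PUBLISHED_MODEL, 20.0, 100.0, 12.9)
        assert inv.value == 0.0 and inv.flag == "target_unreachable_at_zero_dose"

    def test_degenerate_slopes_raise(self):
        flat_rain = ResidualModel(slope_rain=0.0)
        with pytest.raises(DegenerateModelError):
            required_rainfall(flat_rain, 20, 75, 12.9)
        flat_dose = ResidualModel(slope_cl=0.0)
        with pytest.raises(DegenerateModelError):
            allowable_cl_dose(flat_dose, 20, 100, 12.9)

    @given(rain_st, dose_st, clay_st)
    def test_rainfall_inversion_is_identity(self, rain, dose, clay):
        p = predict(PUBLISHED_MODEL, rain, dose, clay)
        if p.clamped:
            return
        inv = required_rainfall(PUBLISHED_MODEL, p.value, dose, clay)
        assert inv.value == pytest.approx(rain, abs=1e-9)

    @given(rain_st, dose_st, clay_st)
    def test_dose_inversion_is_identity(self, rain, dose, clay):
        p = predict(PUBLISHED_MODEL, rain, dose, clay)
        if p.clamped:
            return
        inv = allowable_cl_dose(PUBLISHED_MODEL, p.value, rain, clay)
        assert inv.value == pytest.approx(dose, abs=1e-9)


def _grid():
    rain = np.arange(0, 301, 50, dtype=float)
    dose = np.array([0.0, 37.5, 75.0, 112.5])
    clay = np.array([9.8, 12.9])
    pts = np.array([(r, d, c) for r in rain for d in dose for c in clay])
    return pts


def _ols_normal_equations(y, x):
    """Brute-force OLS oracle via the normal equations."""
    design = np.column_stack([np.ones(len(x)), x])
    return np.linalg.solve(design.T @ design, design.T @ y)


class TestRefit:
    def test_noiseless_grid_recovers_published_coefficients(self):
        pts = _grid()
        y = PUBLISHED_MODEL.raw(pts[:, 0], pts[:, 1], pts[:, 2])
        res = refit(list(zip(map(tuple, pts), y)))
        np.testing.assert_allclose(
            res.params.to_numpy(), [38.518, -0.219, 0.143, 0.557], atol=1e-9
        )
        assert res.model_.sign_consistent()

    def test_noisy_grid_within_three_standard_errors(self):
        pts = _grid()
        rng = np.random.default_rng(42)
        y = PUBLISHED_MODEL.raw(pts[:, 0], pts[:, 1], pts[:, 2]) + rng.normal(
            0, 1.0, len(pts)
        )
        res = ResidualRegression(y, pts[:, 0], pts[:, 1], pts[:, 2]).fit()
        truth = np.array([38.518, -0.219, 0.143, 0.557])
        z = np.abs(res.params.to_numpy() - truth) / res.bse.to_numpy()
        assert np.all(z < 3.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        for n in (10, 37, 100):
            x = rng.uniform([0, 0, 5], [300, 120, 20], size=(n, 3))
            y = rng.normal(20, 8, n)
            res = ResidualRegression(y, x[:, 0], x[:, 1], x[:, 2]).fit()
            np.testing.assert_allclose(
                res.params.to_numpy(), _ols_normal_equations(y, x), atol=1e-8
            )

    def test_collinear_design_names_columns(self):
        rain = np.arange(10.0, 20.0)
        dose = 2.0 * rain  # perfectly collinear with rainfall
        clay = np.full(10, 11.0)
        with pytest.raises(SingularDesignError) as err:
            ResidualRegression(np.ones(10), rain, dose, clay)
        assert "clay" in err.value.columns  # constant column
        assert {"rainfall", "cl_rate"} <= set(err.value.columns)

    def test_too_few_observations(self):
        with pytest.raises(InsufficientDataError):
            ResidualRegression([1, 2, 3, 4], [1, 2, 3, 4], [0, 1, 0, 1], [9, 9, 10, 10])

    def test_summary_is_printable(self):
        pts = _grid()
        rng = np.random.default_rng(0)
        y = PUBLISHED_MODEL.raw(*pts.T) + rng.normal(0, 1, len(pts))
        res = ResidualRegression(y, *pts.T).fit()
        assert "rainfall" in str(res.summary())
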