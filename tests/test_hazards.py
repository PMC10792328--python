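"""Closed-form lifetime laws: printed values, internal identities,
quadrature oracles, numerical stability at extreme shapes."""

import numpy as np
import pytest
from scipy.integrate import quad

from lifeyears import hazards as hz


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(42)


class TestLogLogistic:
    def test_pointwise_values(self):
        assert hz.loglogistic_pdf(1.0, hz.LogLogisticParams(1.0, 2.0)) == pytest.approx(0.5)
        assert hz.loglogistic_survival(1.0, hz.LogLogisticParams(1.0, 1.0)) == pytest.approx(0.5)
        assert hz.loglogistic_survival(0.0, hz.LogLogisticParams(3.0, 5.0)) == 1.0
        assert hz.loglogistic_hazard(3.0, hz.LogLogisticParams(1.0, 1.0)) == pytest.approx(0.25)
        assert hz.loglogistic_hazard(1.0, hz.LogLogisticParams(1.0, 2.0)) == pytest.approx(1.0)

    def test_pdf_equals_hazard_times_survival(self, rng):
        x = rng.uniform(0.01, 100, 100)
        for lam, l in [(1.0, 2.0), (1e-10, 5.0), (1e-17, 9.0)]:
            p = hz.LogLogisticParams(lam, l)
            np.testing.assert_allclose(
                hz.loglogistic_pdf(x, p),
                hz.loglogistic_hazard(x, p) * hz.loglogistic_survival(x, p),
                rtol=1e-12,
            )

    def test_survival_strictly_decreasing(self):
        x = np.arange(111, dtype=float)
        s = hz.loglogistic_survival(x, hz.LogLogisticParams(1e-15, 8.0))
        assert np.all(np.diff(s) < 0)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            hz.loglogistic_pdf(-1.0, hz.LogLogisticParams(1.0, 2.0))

    def test_cumhaz_closed_form(self):
        assert hz.loglogistic_cumhaz(1.0, 1.0) == pytest.approx(np.log(2), rel=1e-12)
        x = np.linspace(0.1, 30, 40)
        for l in (1.0, 3.7, 8.0):
            # atol floor: -log(exp(-c)) double-rounds at c ~ 1e-8
            np.testing.assert_allclose(
                hz.loglogistic_cumhaz(x, l),
                -np.log(hz.loglogistic_survival(x, hz.LogLogisticParams(1.0, l))),
                rtol=1e-12, atol=1e-12,
            )

    @pytest.mark.parametrize("x,l", [(1.0, 1.0), (2.5, 3.7), (10.0, 6.0)])
    def test_cumhaz_matches_hazard_quadrature(self, x, l):
        """ln(1 + x^l) equals the integral of the unit-scale hazard over
        [0, x] — the analytic derivation validated numerically."""
        p = hz.LogLogisticParams(1.0, l)
        val, err = quad(lambda s: hz.loglogistic_hazard(s, p), 0, x, limit=200)
        assert abs(hz.loglogistic_cumhaz(x, l) - val) < 1e-8

    def test_bx_closed_form_and_limit(self):
        assert hz.loglogistic_bx(1.0, 1.0) == pytest.approx(1 / (2 * np.log(2)), rel=1e-12)
        # b(x) -> l as x -> 0+
        assert hz.loglogistic_bx(1e-6, 5.0) == pytest.approx(5.0, rel=1e-4)
        with pytest.raises(ValueError):
            hz.loglogistic_bx(0.0, 2.0)

    def test_bx_times_cumhaz_is_x_times_hazard(self, rng):
        x = rng.uniform(0.05, 50, 100)
        for l in (1.0, 4.0, 9.0):
            p = hz.LogLogisticParams(1.0, l)
            np.testing.assert_allclose(
                hz.loglogistic_bx(x, l) * hz.loglogistic_cumhaz(x, l),
                x * hz.loglogistic_hazard(x, p),
                rtol=1e-12,
            )


class TestWeibull:
    def test_scale_definition(self):
        for l in (0.5, 1.0, 7.0):
            p = hz.WeibullParams(0.02, l)
            assert hz.weibull_survival(1 / 0.02, p) == pytest.approx(np.exp(-1), rel=1e-12)

    def test_shape_one_is_constant_hazard(self):
        p = hz.WeibullParams(0.013, 1.0)
        x = np.linspace(0, 100, 50)
        np.testing.assert_allclose(hz.weibull_hazard(x, p), 0.013, rtol=1e-12)

    def test_pdf_equals_hazard_times_survival(self, rng):
        x = rng.uniform(0.01, 110, 100)
        for b, l in [(0.005, 5.0), (0.02, 8.0)]:
            p = hz.WeibullParams(b, l)
            np.testing.assert_allclose(
                hz.weibull_pdf(x, p),
                hz.weibull_hazard(x, p) * hz.weibull_survival(x, p),
                rtol=1e-12,
            )


class TestGompertz:
    def test_cdf_at_mode(self):
        p = hz.GompertzParams(0.1, -7.0)
        assert hz.gompertz_cdf(p.modal_age, p) == pytest.approx(np.exp(-1), rel=1e-12)

    def test_ratio_identity(self, rng):
        x = rng.uniform(0, 110, 100)  # F underflows to 0 far below the mode
        p = hz.GompertzParams(0.09, -6.5)
        np.testing.assert_allclose(
            hz.gompertz_pdf(x, p) / hz.gompertz_cdf(x, p),
            hz.gompertz_ratio(x, p),
            rtol=1e-12,
        )
        np.testing.assert_allclose(
            hz.gompertz_ratio(x, p), p.b * np.exp(-(p.l + p.b * x)), rtol=1e-12
        )

    def test_cdf_plus_survival_is_one(self):
        x = np.linspace(-50, 150, 201)
        p = hz.GompertzParams(0.12, -8.0)
        np.testing.assert_allclose(
            hz.gompertz_cdf(x, p) + hz.gompertz_survival(x, p), 1.0, rtol=1e-12
        )

    def test_carriere_alias(self):
        """mu(x) = B c^x with B = b e^{-l}, c = e^{-b} equals the f/S hazard
        only asymptotically; here check the alias mapping itself."""
        p = hz.GompertzParams(0.1, -7.0)
        assert p.B == pytest.approx(0.1 * np.exp(7.0), rel=1e-12)
        assert p.c == pytest.approx(np.exp(-0.1), rel=1e-12)


@pytest.mark.parametrize(
    "pdf,params",
    [(hz.loglogistic_pdf, hz.LogLogisticParams(lam, l))
     for lam, l in [(1.0, 1.5), (1e-10, 5.0), (1e-17, 9.0)]]
    + [(hz.weibull_pdf, hz.WeibullParams(b, l))
       for b, l in [(0.005, 5.0), (0.02, 8.0)]]
    + [(hz.gompertz_pdf, hz.GompertzParams(b, l))
       for b, l in [(0.05, -5.0), (0.12, -8.0)]],
    ids=str,
)
def test_pdf_normalization(pdf, params):
    """Every density integrates to 1 over its support (quadrature oracle)."""
    lo = -np.inf if isinstance(params, hz.GompertzParams) else 0.0
    total, err = quad(lambda x: float(pdf(x, params)), lo, np.inf, limit=400)
    assert total == pytest.approx(1.0, abs=1e-6)


def test_no_overflow_at_extreme_shape():
    """x = 110 with shape 12 means x^l ~ 1e24; log-space evaluation must
    return finite values everywhere."""
    x = np.array([0.0, 1.0, 50.0, 110.0])
    p = hz.LogLogisticParams(1.0, 12.0)
    for fn in (hz.loglogistic_pdf, hz.loglogistic_survival, hz.loglogistic_hazard):
        assert np.all(np.isfinite(fn(x, p)))
    assert np.all(np.isfinite(hz.loglogistic_cumhaz(x, 12.0)))
    assert np.isfinite(hz.loglogistic_bx(110.0, 12.0))


def test_params_json_roundtrip():
    for p in (hz.LogLogisticParams(1e-15, 8.0), hz.WeibullParams(0.0125, 7.0),
              hz.GompertzParams(0.1, -7.0)):
        assert type(p).from_json(p.to_json()) == p
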