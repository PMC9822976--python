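import numpy as np
import pytest

from acertail import (
    DataError,
    DomainError,
    FitError,
    ReturnSpec,
    TailParams,
    confidence_band,
    evaluate_tail,
    extrapolate_band,
    fit_tail,
    gen_exact_tail_curve,
    return_level,
    select_cuton,
    target_probability,
)
from acertail.exceedance import AcerCurve


def analytic_return_level(a, b, c, d, p):
    return ((d - np.log(p)) ** (1 / c) - b) / a


def test_evaluate_tail_reference_values():
    p = TailParams(a=1, b=0, c=1, d=0, lambda0=0.1)
    assert evaluate_tail(p, 1.0) == pytest.approx(np.exp(-1))
    q = TailParams(a=2, b=0.5, c=1.8, d=-3, lambda0=0.1)
    assert evaluate_tail(q, 0.6) == pytest.approx(np.exp(-(1.7**1.8) - 3))


def test_evaluate_tail_monotone_and_domain():
    q = TailParams(a=2, b=0.5, c=1.8, d=-3, lambda0=0.1)
    lam = np.linspace(0.1, 3.0, 50)
    vals = evaluate_tail(q, lam)
    assert np.all(np.diff(vals) < 0)
    neg = TailParams(a=1, b=-0.5, c=2, d=0, lambda0=0.6)
    with pytest.raises(DomainError):
        evaluate_tail(neg, 0.2)  # a*lambda + b < 0 below the cut-on


@pytest.mark.parametrize(
    "truth",
    [
        (2.0, 0.5, 1.8, -3.0),
        (0.7, 0.2, 2.5, -1.0),
        (3.0, 1.0, 0.8, -2.0),
    ],
)
def test_noise_free_recovery_within_one_percent(truth):
    """Curves generated exactly from the tail form give back all four
    parameters within 1 % and the rare-level inversion within 2 %."""
    a, b, c, d = truth
    grid = np.linspace(0.05, 1.0, 50)
    curve = gen_exact_tail_curve(a, b, c, d, grid, n=10**7)
    params, diag = fit_tail(curve, lambda0=0.05)
    assert params.a == pytest.approx(a, rel=0.01)
    assert params.b == pytest.approx(b, abs=max(0.01 * abs(b), 1e-4))
    assert params.c == pytest.approx(c, rel=0.01)
    assert params.d == pytest.approx(d, abs=max(0.01 * abs(d), 1e-4))
    assert diag.n_points >= 4

    p_t = 1e-5
    lam_star = return_level(params, p_t)
    assert lam_star == pytest.approx(analytic_return_level(a, b, c, d, p_t), rel=0.02)


def test_pure_exponential_recovers_identified_parameters():
    """At c = 1 the model is exp(-a*lambda - (b - d)): b and d enter only
    through their difference, so the identified quantities are a, c and
    b - d; the fitted curve itself matches everywhere."""
    grid = np.linspace(0.05, 1.0, 50)
    curve = gen_exact_tail_curve(1.0, 0.0, 1.0, 0.0, grid, n=10**7)
    params, _ = fit_tail(curve, lambda0=0.05)
    assert params.a == pytest.approx(1.0, rel=0.01)
    assert params.c == pytest.approx(1.0, rel=0.05)
    assert params.b - params.d == pytest.approx(0.0, abs=1e-3)
    np.testing.assert_allclose(evaluate_tail(params, grid), curve.p, rtol=1e-6)
    assert return_level(params, 1e-5) == pytest.approx(np.log(1e5), rel=0.02)


def test_lnln_diagnostic_is_linear_for_exact_curves():
    curve = gen_exact_tail_curve(2.0, 0.5, 1.8, -3.0, np.linspace(0.1, 1.0, 40), n=10**7)
    _, diag = fit_tail(curve, lambda0=0.1)
    assert diag.r_squared == pytest.approx(1.0, abs=1e-6)


def test_fit_errors():
    curve = gen_exact_tail_curve(1.0, 0.1, 1.5, -1.0, np.linspace(0.2, 1.0, 30), n=10**6)
    with pytest.raises(DataError):
        fit_tail(curve, lambda0=0.999)  # too few tail points
    flat = AcerCurve(
        lambdas=np.linspace(0.1, 1.0, 10),
        p=np.full(10, 0.1),
        exceed_counts=np.full(10, 100.0),
        k=1,
        n=1000,
    )
    with pytest.raises(FitError):
        fit_tail(flat, lambda0=0.1)


def test_return_level_inversion_roundtrip():
    params = TailParams(a=1, b=0, c=1, d=0, lambda0=0.1)
    assert return_level(params, np.exp(-2.0)) == pytest.approx(2.0, rel=1e-12)

    rng = np.random.default_rng(11)
    for _ in range(25):
        p = TailParams(
            a=rng.uniform(0.5, 3),
            b=rng.uniform(0, 1),
            c=rng.uniform(0.5, 3),
            d=rng.uniform(-3, 0),
            lambda0=0.2,
        )
        p_t = 10 ** rng.uniform(-8, np.log10(evaluate_tail(p, p.lambda0) / 2))
        lam = return_level(p, p_t)
        assert evaluate_tail(p, lam) == pytest.approx(p_t, rel=1e-10)


def test_return_level_domain_checks():
    params = TailParams(a=1, b=0, c=1, d=0, lambda0=1.0)
    with pytest.raises(DomainError):
        return_level(params, 0.0)
    with pytest.raises(DomainError):
        return_level(params, 0.9)  # above p(lambda0)


def test_target_probability_conventions():
    spec = ReturnSpec(return_period_years=100, events_per_year=191)
    assert target_probability(spec) == pytest.approx(1 / 19100)
    assert target_probability(
        ReturnSpec(return_period_years=1, events_per_year=1)
    ) == pytest.approx(1.0)
    double = ReturnSpec(return_period_years=200, events_per_year=191)
    assert target_probability(double) == pytest.approx(target_probability(spec) / 2)
    alt = target_probability(spec, convention="annual_nonexceedance")
    assert alt == pytest.approx(-np.log(1 - 1 / 100) / 191)
    assert alt > target_probability(spec)  # -ln(1-x) > x
    with pytest.raises(DomainError):
        ReturnSpec(return_period_years=-1, events_per_year=1)


def test_manual_and_stability_cuton():
    grid = np.linspace(0.05, 1.0, 60)
    curve = gen_exact_tail_curve(2.0, 0.5, 1.8, -3.0, grid, n=10**7)
    assert select_cuton(curve, strategy="manual", value=0.0018) == 0.0018
    # globally valid model: stability picks the smallest candidate scanned
    lam0 = select_cuton(curve, strategy="stability")
    assert lam0 == pytest.approx(grid[0])
    with pytest.raises(DomainError):
        select_cuton(curve, strategy="manual")
    tiny = gen_exact_tail_curve(2.0, 0.5, 1.8, -3.0, np.linspace(0.2, 0.4, 5), n=10**6)
    with pytest.raises(DataError):
        select_cuton(tiny, strategy="quantile")


def test_quantile_cuton_skips_rising_branch():
    """A curve that rises to a peak before decaying (the k > 1 shape) must
    be cut past the peak."""
    lam = np.linspace(0.1, 1.0, 50)
    p = np.exp(-(((lam - 0.4) / 0.2) ** 2))  # peak at 0.4
    curve = AcerCurve(lambdas=lam, p=p / 2, exceed_counts=p / 2 * 1000, k=2, n=1001)
    lam0 = select_cuton(curve, strategy="quantile", p_cuton=0.3)
    assert lam0 >= 0.4


def test_weighting_monotone_in_band_width():
    """Widening a point's confidence band never increases its weight."""
    from acertail.tailfit import _weights

    p = np.array([0.2, 0.02, 0.002])
    w = _weights(p, 1000)
    # band ln-half-width ~ 1/sqrt(n p): wider band <-> smaller p <-> smaller w
    assert np.all(np.diff(w) < 0)


def test_band_extrapolation_brackets_central():
    grid = np.linspace(0.1, 1.0, 60)
    curve = gen_exact_tail_curve(2.0, 0.5, 1.8, -3.0, grid, n=10**6)
    band = confidence_band(curve, 0.95)
    central, _ = fit_tail(curve, lambda0=0.1)
    lam_eval = np.linspace(0.1, 1.6, 80)
    ext = extrapolate_band(band, curve, 0.1, lam_eval, central=central)
    centre = evaluate_tail(central, lam_eval)
    assert np.all(ext.lower <= centre * (1 + 1e-6))
    assert np.all(ext.upper >= centre * (1 - 1e-6))
    # the band widens towards rare levels
    rel_width = (ext.upper - ext.lower) / centre
    assert rel_width[-1] > rel_width[0]
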