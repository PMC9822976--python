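import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acertail import (
    DomainError,
    confidence_band,
    convergence_in_k,
    empirical_pk,
    mixture_pk,
    nonexceedance_probability,
    normal_multiplier,
)
from acertail.exceedance import AcerCurve

from helpers import random_merged


def naive_pk(values, limits, k, lam):
    """Independent triple-loop enumeration of the conditioning definition."""
    n = len(values)
    count = 0
    for j in range(k - 1, n):  # 0-based; j+1 runs k..N
        if values[j] <= limits[j] * lam:
            continue
        ok = True
        for back in range(1, k):
            if values[j - back] > limits[j - back] * lam:
                ok = False
                break
        if ok:
            count += 1
    return count, n - k + 1


def test_level_above_all_data_gives_zero():
    mv = random_merged(np.random.default_rng(0), 10)
    curve = empirical_pk(mv, 1, [4.0])
    assert curve.p[0] == 0.0


def test_conditioning_example_counts_three_of_five(small_merged):
    curve = empirical_pk(small_merged, 2, [0.8])
    assert curve.exceed_counts[0] == 3
    assert curve.n_effective == 5
    assert curve.p[0] == pytest.approx(3 / 5)


def test_empirical_pk_equals_enumeration_oracle():
    """Exact equality with brute-force enumeration over random instances."""
    rng = np.random.default_rng(42)
    grid = np.linspace(0.05, 1.2, 20)
    for _ in range(40):
        n = int(rng.integers(5, 51))
        mv = random_merged(rng, n)
        for k in range(1, 5):
            if k > n:
                continue
            curve = empirical_pk(mv, k, grid)
            for g, lam in enumerate(grid):
                cnt, den = naive_pk(mv.values, mv.limits, k, lam)
                assert curve.exceed_counts[g] == cnt
                assert curve.p[g] == pytest.approx(cnt / den)


def test_k1_monotone_and_nesting_bound():
    rng = np.random.default_rng(3)
    grid = np.linspace(0.05, 1.0, 25)
    for _ in range(20):
        mv = random_merged(rng, int(rng.integers(10, 60)))
        p1 = empirical_pk(mv, 1, grid).p
        assert np.all(np.diff(p1) <= 0)  # rigorous for k = 1
        for k in (2, 3, 4):
            pk = empirical_pk(mv, k, grid).p
            bound = p1 * mv.n / (mv.n - k + 1)
            assert np.all(pk <= bound + 1e-12)


def test_pk_domain_errors(small_merged):
    with pytest.raises(DomainError):
        empirical_pk(small_merged, 0, [0.5])
    with pytest.raises(DomainError):
        empirical_pk(small_merged, 7, [0.5])


def test_nonexceedance_probability_values(small_merged):
    curve = AcerCurve(
        lambdas=np.array([0.5, 1.0]),
        p=np.array([0.001, 0.0]),
        exceed_counts=np.array([1.0, 0.0]),
        k=1,
        n=1000,
    )
    P = nonexceedance_probability(curve)
    assert P[0] == pytest.approx(np.exp(-1.0))
    assert P[1] == 1.0
    assert np.all(np.diff(P) >= 0)


def test_poisson_form_matches_product_form_for_small_p():
    """exp(-N p) is the first-order form of the conditional product
    (1 - p)^(N-k+1); they agree closely when p is small."""
    rng = np.random.default_rng(5)
    mv = random_merged(rng, 50)
    grid = np.linspace(0.8, 1.0, 5)
    curve = empirical_pk(mv, 2, grid)
    P_pois = nonexceedance_probability(curve)
    P_prod = (1 - curve.p) ** curve.n_effective
    small = curve.p < 0.02
    np.testing.assert_allclose(P_pois[small], P_prod[small], rtol=0.05)


def test_mixture_identity_and_convexity(small_merged):
    grid = np.linspace(0.1, 1.0, 10)
    c = empirical_pk(small_merged, 1, grid)
    np.testing.assert_array_equal(mixture_pk([c], [1.0]).p, c.p)
    np.testing.assert_allclose(mixture_pk([c, c], [0.5, 0.5]).p, c.p)


def test_mixture_weighted_sum_exact():
    grid = np.array([0.2, 0.5])
    a = AcerCurve(lambdas=grid, p=np.array([0.2, 0.2]),
                  exceed_counts=np.array([20.0, 20.0]), k=1, n=100)
    b = AcerCurve(lambdas=grid, p=np.array([0.4, 0.4]),
                  exceed_counts=np.array([40.0, 40.0]), k=1, n=100)
    mixed = mixture_pk([a, b], [0.25, 0.75])
    np.testing.assert_allclose(mixed.p, 0.35)


@given(st.floats(0.01, 0.99))
@settings(deadline=None, max_examples=25)
def test_mixture_linearity_property(q):
    grid = np.array([0.3, 0.6, 0.9])
    rng = np.random.default_rng(int(q * 1e6))
    pa, pb = rng.uniform(0, 0.5, 3), rng.uniform(0, 0.5, 3)
    a = AcerCurve(lambdas=grid, p=pa, exceed_counts=pa * 100, k=1, n=100)
    b = AcerCurve(lambdas=grid, p=pb, exceed_counts=pb * 100, k=1, n=100)
    mixed = mixture_pk([a, b], [q, 1 - q])
    np.testing.assert_allclose(mixed.p, q * pa + (1 - q) * pb, atol=1e-15)


def test_mixture_errors():
    grid = np.array([0.5])
    c = AcerCurve(lambdas=grid, p=np.array([0.1]),
                  exceed_counts=np.array([10.0]), k=1, n=100)
    with pytest.raises(DomainError):
        mixture_pk([c, c], [0.5])
    with pytest.raises(DomainError):
        mixture_pk([c, c], [0.7, 0.5])


def test_normal_multiplier_reference_values():
    assert normal_multiplier(0.95) == pytest.approx(1.96, abs=5e-3)
    assert normal_multiplier(0.90) == pytest.approx(1.65, abs=1e-2)
    assert normal_multiplier(0.6827) == pytest.approx(1.00, abs=5e-3)
    with pytest.raises(DomainError):
        normal_multiplier(1.2)


def test_confidence_band_reference_point():
    # n_eff = 1000, p = 0.01, 95 %: 1 +- 1.96/sqrt(10)
    curve = AcerCurve(
        lambdas=np.array([0.5]), p=np.array([0.01]),
        exceed_counts=np.array([10.0]), k=1, n=1000,
    )
    band = confidence_band(curve, 0.95)
    assert band.lower[0] == pytest.approx(0.00380, abs=1e-5)
    assert band.upper[0] == pytest.approx(0.01620, abs=1e-5)


def test_confidence_band_undefined_at_zero_and_sqrt_scaling():
    curve = AcerCurve(
        lambdas=np.array([0.5, 0.9]), p=np.array([0.01, 0.0]),
        exceed_counts=np.array([10.0, 0.0]), k=1, n=1000,
    )
    band = confidence_band(curve)
    assert np.isnan(band.lower[1]) and np.isnan(band.upper[1])

    big = AcerCurve(
        lambdas=np.array([0.5]), p=np.array([0.01]),
        exceed_counts=np.array([40.0]), k=1, n=4000,
    )
    half_small = (band.upper[0] - curve.p[0]) / curve.p[0]
    band_big = confidence_band(big)
    half_big = (band_big.upper[0] - big.p[0]) / big.p[0]
    assert half_big == pytest.approx(half_small / 2, rel=1e-6)


def test_iid_sequences_make_conditioning_vacuous_in_tail(rng):
    """For independent data the conditioning is vacuous in the tail, where
    the previous maxima are almost surely below the level: p_1 ~ p_2
    within the 95 % band in the large majority of seeded replicates.
    (Away from the tail the joint-event rates differ by construction:
    p_2 = lambda * p_1 for iid uniforms.)"""
    inside = 0
    reps = 30
    for seed in range(reps):
        r = np.random.default_rng(seed)
        mv = random_merged(r, 400)
        grid = np.array([0.95])
        c1 = empirical_pk(mv, 1, grid)
        c2 = empirical_pk(mv, 2, grid)
        band = confidence_band(c2, 0.95)
        if band.lower[0] <= c1.p[0] <= band.upper[0]:
            inside += 1
    assert inside >= 0.9 * reps


def test_convergence_on_iid_selects_small_k(rng):
    mv = random_merged(rng, 5000)
    res = convergence_in_k(
        mv, np.linspace(0.5, 0.97, 40), k_max=4, tol=0.1, tail_from=0.9
    )
    assert res.converged
    assert res.k_star in (1, 2)
    assert set(res.curves) == {1, 2, 3, 4}


def test_convergence_never_silent(rng):
    mv = random_merged(rng, 30)
    res = convergence_in_k(mv, np.linspace(0.1, 0.9, 10), k_max=3, tol=1e-9)
    assert not res.converged
    assert res.k_star == 3
    with pytest.raises(DomainError):
        convergence_in_k(mv, [0.5], k_max=1)
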