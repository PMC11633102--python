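"""MLE, bounds, intervals and exact test, checked against independent oracles."""

import math

import numpy as np
import pytest

import oracles
from coaffinity import (
    CooccurrenceModel,
    EstimateUndefinedError,
    TwoByTwoTable,
    UndefinedBoundError,
    affinity_mean,
    alpha_ci,
    finite_bound,
    mle_alpha,
    mle_alpha_value,
    null_p_value,
    truncation_value,
)


def interior_tables(n_max):
    for n in range(2, n_max + 1):
        for m_a in range(1, n):
            for m_b in range(m_a, n):
                sup = CooccurrenceModel(n, m_a, m_b).support
                for k in range(sup.k_min + 1, sup.k_max):
                    yield n, m_a, m_b, k


def grid_argmax_alpha(n, m_a, m_b, k, lo=-15.0, hi=15.0, step=1e-4):
    """Dense-grid maximizer of the tilted log-likelihood (independent of brentq)."""
    alphas = np.arange(lo, hi + step / 2, step)
    ks = np.arange(max(m_a + m_b - n, 0), min(m_a, m_b) + 1)
    logw0 = np.array(
        [math.log(math.comb(m_a, j) * math.comb(n - m_a, m_b - j)) for j in ks]
    )
    logits = logw0[:, None] + np.outer(ks, alphas)
    m = logits.max(axis=0)
    log_z = m + np.log(np.exp(logits - m).sum(axis=0))
    return alphas[np.argmax(alphas * k - log_z)]


def test_mle_at_null_mean_is_zero():
    t = TwoByTwoTable.from_margins(100, 50, 50, 25)
    est = mle_alpha(t)
    assert est.alpha_hat == pytest.approx(0.0, abs=1e-8)
    assert not est.is_boundary


def test_mle_boundary_truncation():
    t = TwoByTwoTable.from_margins(100, 50, 50, 50)
    est = mle_alpha(t)
    assert est.is_boundary
    assert est.alpha_hat == pytest.approx(math.log(4 * 100**2), abs=1e-12)
    assert est.alpha_hat == pytest.approx(10.5966, abs=1e-4)
    low = mle_alpha(TwoByTwoTable.from_margins(100, 50, 50, 0))
    assert low.is_boundary and low.alpha_hat == -truncation_value(100)


def test_mle_matches_dense_grid_search():
    got, boundary = mle_alpha_value(40, 15, 20, 12)
    assert not boundary
    assert got == pytest.approx(grid_argmax_alpha(40, 15, 20, 12), abs=1e-3)


def test_mle_solves_mean_equation():
    for n, m_a, m_b, k in [(40, 15, 20, 12), (60, 30, 10, 2), (200, 80, 80, 45)]:
        alpha_hat, _ = mle_alpha_value(n, m_a, m_b, k)
        assert affinity_mean(
            CooccurrenceModel(n, m_a, m_b, alpha_hat)
        ) == pytest.approx(k, abs=1e-6)


def test_degenerate_margins_refused():
    with pytest.raises(EstimateUndefinedError):
        mle_alpha(TwoByTwoTable.from_margins(10, 0, 5, 0))
    with pytest.raises(EstimateUndefinedError):
        mle_alpha(TwoByTwoTable.from_margins(10, 10, 5, 5))


def test_finite_bound_example_and_cap(rng):
    t = TwoByTwoTable.from_margins(100, 67, 65, 43)
    assert finite_bound(t) == pytest.approx(math.log(2 * 34 * 65), abs=1e-12)
    for _ in range(1000):
        n = int(rng.integers(4, 300))
        m_a = int(rng.integers(1, n - 1))
        m_b = int(rng.integers(1, n - 1))
        sup = CooccurrenceModel(n, m_a, m_b).support
        if sup.k_max - sup.k_min < 2:
            continue
        t = TwoByTwoTable.from_margins(n, m_a, m_b, sup.k_min + 1)
        assert finite_bound(t) <= math.log(2 * n**2) + 1e-12


def test_finite_bound_undefined_without_interior():
    with pytest.raises(UndefinedBoundError):
        finite_bound(TwoByTwoTable.from_margins(5, 4, 4, 3))
    with pytest.raises(UndefinedBoundError):
        finite_bound(TwoByTwoTable.from_margins(5, 0, 3, 0))


def test_interior_estimates_respect_bound_small():
    for n, m_a, m_b, k in interior_tables(15):
        alpha_hat, boundary = mle_alpha_value(n, m_a, m_b, k)
        assert not boundary
        t = TwoByTwoTable.from_margins(n, m_a, m_b, k)
        assert abs(alpha_hat) <= finite_bound(t) + 1e-8


def test_sign_coherence_and_monotonicity_in_k():
    """alpha_hat has the sign of k - E0(X) and increases with k, margins fixed."""
    for n in range(2, 16):
        for m_a in range(1, n):
            for m_b in range(m_a, n):
                sup = CooccurrenceModel(n, m_a, m_b).support
                if sup.is_single_point:
                    continue
                null_mean = m_a * m_b / n
                prev = None
                for k in range(sup.k_min + 1, sup.k_max):
                    alpha_hat, _ = mle_alpha_value(n, m_a, m_b, k)
                    if k > null_mean:
                        assert alpha_hat > 0
                    elif k < null_mean:
                        assert alpha_hat < 0
                    if prev is not None:
                        assert alpha_hat > prev
                    prev = alpha_hat


def test_role_symmetry_and_complement_antisymmetry():
    cases = [(40, 15, 20, 12), (60, 30, 25, 10), (100, 20, 80, 16), (33, 11, 17, 7)]
    for n, m_a, m_b, k in cases:
        a1, _ = mle_alpha_value(n, m_a, m_b, k)
        a2, _ = mle_alpha_value(n, m_b, m_a, k)
        assert a1 == pytest.approx(a2, abs=1e-10)
        # relabeling B-absence as presence flips the log odds ratio
        a3, b3 = mle_alpha_value(n, m_a, n - m_b, m_a - k)
        if not b3:
            assert a3 == pytest.approx(-a1, abs=1e-8)


def test_null_p_value_symmetric_mode_is_one():
    assert null_p_value(TwoByTwoTable.from_margins(100, 50, 50, 25)) == pytest.approx(
        1.0, abs=1e-12
    )


def test_null_p_value_matches_rational_enumeration():
    for n in range(2, 21):
        for m_a in range(1, n):
            for m_b in range(m_a, n):
                sup = CooccurrenceModel(n, m_a, m_b).support
                for k in sup:
                    t = TwoByTwoTable.from_margins(n, m_a, m_b, k)
                    exact = oracles.exact_minlike_p(n, m_a, m_b, k)
                    assert null_p_value(t) == pytest.approx(exact, abs=1e-10)


def test_null_p_value_extreme_tail():
    t = TwoByTwoTable.from_margins(50, 20, 15, 15)
    p = null_p_value(t)
    assert 0 < p < 0.01
    assert null_p_value(t, method="doubled") <= 1.0


def test_ci_contains_estimate_and_widens(rng):
    for _ in range(40):
        n = int(rng.integers(6, 120))
        m_a = int(rng.integers(1, n))
        m_b = int(rng.integers(1, n))
        sup = CooccurrenceModel(n, m_a, m_b).support
        if sup.k_max - sup.k_min < 2:
            continue
        k = int(rng.integers(sup.k_min + 1, sup.k_max))
        t = TwoByTwoTable.from_margins(n, m_a, m_b, k)
        alpha_hat, _ = mle_alpha_value(n, m_a, m_b, k)
        for method in ("midp", "tail", "lrt"):
            lo, hi = alpha_ci(t, 0.95, method=method)
            assert lo <= alpha_hat + 1e-8 and alpha_hat - 1e-8 <= hi
        lo90, hi90 = alpha_ci(t, 0.90)
        lo99, hi99 = alpha_ci(t, 0.99)
        assert lo99 <= lo90 and hi90 <= hi99


def test_ci_one_sided_at_boundary():
    t = TwoByTwoTable.from_margins(100, 50, 50, 50)
    lo, hi = alpha_ci(t, 0.95)
    assert hi == truncation_value(100)
    assert lo < hi
    t0 = TwoByTwoTable.from_margins(100, 50, 50, 0)
    lo0, hi0 = alpha_ci(t0, 0.95)
    assert lo0 == -truncation_value(100)


def test_estimate_record_fields():
    t = TwoByTwoTable.from_margins(40, 15, 20, 12)
    est = mle_alpha(t, ci_level=0.9)
    assert est.ci_level == 0.9
    assert est.truncation_value == truncation_value(40)
    assert est.finite_bound == pytest.approx(finite_bound(t))
    assert abs(est.alpha_hat) <= est.finite_bound
    assert est.ci_low <= est.alpha_hat <= est.ci_high
    assert est.method_info["solver"] == "brentq"
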