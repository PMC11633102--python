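"""Independent oracles used only by the test suite.

Exact-arithmetic references (integer binomials via fractions.Fraction,
high-precision exponentials via mpmath) recompute the distributions by
direct summation, independently of the package's log-space code path.
"""

from __future__ import annotations

import math
from fractions import Fraction

import mpmath
import numpy as np
from scipy.stats import chi2_contingency, chisquare


def support_range(n: int, m_a: int, m_b: int) -> range:
    return range(max(m_a + m_b - n, 0), min(m_a, m_b) + 1)


def exact_null_pmf(n: int, m_a: int, m_b: int):
    """Hypergeometric masses as exact rationals."""
    ks = list(support_range(n, m_a, m_b))
    w = [Fraction(math.comb(m_a, k) * math.comb(n - m_a, m_b - k)) for k in ks]
    tot = sum(w)
    return ks, [x / tot for x in w]


def exact_null_sd(n: int, m_a: int, m_b: int) -> float:
    ks, probs = exact_null_pmf(n, m_a, m_b)
    mean = sum(Fraction(k) * p for k, p in zip(ks, probs))
    var = sum((Fraction(k) - mean) ** 2 * p for k, p in zip(ks, probs))
    return math.sqrt(float(var))


def exact_affinity_pmf(n: int, m_a: int, m_b: int, alpha: float, dps: int = 60):
    """Tilted masses by direct high-precision summation."""
    with mpmath.workdps(dps):
        a = mpmath.mpf(alpha)
        ks = list(support_range(n, m_a, m_b))
        w = [
            mpmath.mpf(math.comb(m_a, k) * math.comb(n - m_a, m_b - k))
            * mpmath.e ** (a * k)
            for k in ks
        ]
        tot = mpmath.fsum(w)
        return ks, [float(x / tot) for x in w]


def exact_affinity_mean(n: int, m_a: int, m_b: int, alpha: float) -> float:
    ks, probs = exact_affinity_pmf(n, m_a, m_b, alpha)
    return float(sum(k * p for k, p in zip(ks, probs)))


def exact_minlike_p(n: int, m_a: int, m_b: int, k: int) -> float:
    """Two-sided minimum-likelihood p-value by exact rational enumeration."""
    ks, probs = exact_null_pmf(n, m_a, m_b)
    p_obs = probs[ks.index(k)]
    return float(sum(p for p in probs if p <= p_obs))


def _merge_bins(observed: np.ndarray, expected: np.ndarray, min_expected: float = 5.0):
    """Pool adjacent bins until every expected count reaches the floor."""
    obs_out, exp_out = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(observed, expected):
        o_acc += o
        e_acc += e
        if e_acc >= min_expected:
            obs_out.append(o_acc)
            exp_out.append(e_acc)
            o_acc = e_acc = 0.0
    if e_acc > 0:
        if exp_out:
            obs_out[-1] += o_acc
            exp_out[-1] += e_acc
        else:
            obs_out.append(o_acc)
            exp_out.append(e_acc)
    return np.asarray(obs_out), np.asarray(exp_out)


def gof_pvalue(draws: np.ndarray, ks: np.ndarray, probs: np.ndarray) -> float:
    """Chi-square goodness of fit of draws against an exact discrete pmf."""
    observed = np.array([(draws == k).sum() for k in ks], dtype=float)
    expected = probs * len(draws)
    obs, exp = _merge_bins(observed, expected)
    if len(obs) < 2:
        return 1.0
    return float(chisquare(obs, exp * obs.sum() / exp.sum()).pvalue)


def homogeneity_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Chi-square two-sample homogeneity test for discrete draws."""
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    ks = np.arange(lo, hi + 1)
    cx = np.array([(x == k).sum() for k in ks], dtype=float)
    cy = np.array([(y == k).sum() for k in ks], dtype=float)
    pooled = cx + cy
    keep_from = np.flatnonzero(pooled > 0)
    cx, cy, pooled = cx[keep_from], cy[keep_from], pooled[keep_from]
    # pool adjacent bins so pooled expected counts are not tiny
    merged_x, merged_y = [], []
    ax = ay = acc = 0.0
    for vx, vy, vp in zip(cx, cy, pooled):
        ax += vx
        ay += vy
        acc += vp
        if acc >= 10:
            merged_x.append(ax)
            merged_y.append(ay)
            ax = ay = acc = 0.0
    if acc > 0 and merged_x:
        merged_x[-1] += ax
        merged_y[-1] += ay
    table = np.array([merged_x, merged_y])
    if table.shape[1] < 2:
        return 1.0
    return float(chi2_contingency(table).pvalue)
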