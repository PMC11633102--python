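"""Exact null and affinity distributions of the co-occurrence count.

Under independent equiprobable placement with fixed margins the count of
jointly occupied sites is hypergeometric(N, m_A, m_B).  The one-parameter
alternative tilts each support point ``k`` by ``exp(alpha * k)``:

    P_alpha(X = k)  proportional to  C(m_A, k) C(N - m_A, m_B - k) e^{alpha k}

— the extended (Fisher noncentral) hypergeometric distribution, which
reduces to the null exactly at ``alpha = 0``.  All computation is done in
log space (log-binomials via log-gamma, normalisation by max-subtraction)
so that large ``N`` and large ``|alpha|`` do not overflow.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import hypergeom

from .tables import CooccurrenceModel, SupportRange

__all__ = [
    "support",
    "null_pmf",
    "null_mean_sd",
    "affinity_pmf",
    "affinity_cdf",
    "affinity_mean",
    "affinity_log_weights",
]


def support(model: CooccurrenceModel) -> SupportRange:
    """Inclusive range of attainable co-occurrence counts for the model's margins."""
    return model.support


def _log_binom(n: int, k: np.ndarray) -> np.ndarray:
    # log C(n, k); -inf outside 0 <= k <= n
    k = np.asarray(k, dtype=float)
    out = np.full(k.shape, -np.inf)
    ok = (k >= 0) & (k <= n)
    kk = k[ok]
    out[ok] = gammaln(n + 1) - gammaln(kk + 1) - gammaln(n - kk + 1)
    return out


def affinity_log_weights(model: CooccurrenceModel):
    """Support points and unnormalised log-weights ``log w_k + alpha*k``.

    Building block shared by the pmf/cdf/mean and by the estimator's
    bisection loop, where the margin-dependent part is computed once.
    """
    sup = model.support
    ks = np.arange(sup.k_min, sup.k_max + 1)
    # the family is role-symmetric; computing with margins in canonical order
    # makes that symmetry hold bit-for-bit, not just to rounding
    lo, hi = sorted((model.m_a, model.m_b))
    logw = _log_binom(lo, ks) + _log_binom(model.n - lo, hi - ks) + model.alpha * ks
    return ks, logw


def _pmf_table(model: CooccurrenceModel):
    ks, logw = affinity_log_weights(model)
    p = np.exp(logw - logsumexp(logw))
    return ks, p


def _at_k(ks: np.ndarray, values: np.ndarray, k, fill: float):
    k_arr = np.asarray(k)
    idx = np.clip(k_arr - ks[0], 0, len(ks) - 1)
    out = np.where((k_arr >= ks[0]) & (k_arr <= ks[-1]), values[idx], fill)
    return float(out) if np.isscalar(k) or k_arr.ndim == 0 else out


def null_pmf(model: CooccurrenceModel, k):
    """Hypergeometric null mass at ``k`` (0 outside the support).

    ``model.alpha`` must be 0: the null is the alpha = 0 member of the family.
    """
    if model.alpha != 0.0:
        raise ValueError("null_pmf requires alpha = 0; use affinity_pmf for tilted models")
    k_arr = np.asarray(k)
    p = hypergeom.pmf(k_arr, model.n, model.m_a, model.m_b)
    sup = model.support
    p = np.where((k_arr >= sup.k_min) & (k_arr <= sup.k_max), p, 0.0)
    return float(p) if np.isscalar(k) or k_arr.ndim == 0 else p


def null_mean_sd(model: CooccurrenceModel) -> tuple[float, float]:
    """Null mean ``m_A * m_B / N`` and the exact null standard deviation.

    The sd is obtained by direct summation over the support rather than a
    closed form, so it is convention-proof on degenerate margins.
    """
    mean = model.m_a * model.m_b / model.n
    ks, p = _pmf_table(model.with_alpha(0.0))
    sd = float(np.sqrt(np.sum((ks - mean) ** 2 * p)))
    return mean, sd


def affinity_pmf(model: CooccurrenceModel, k):
    """Extended hypergeometric mass at ``k`` (0 outside the support)."""
    ks, p = _pmf_table(model)
    return _at_k(ks, p, k, 0.0)


def affinity_cdf(model: CooccurrenceModel, k):
    """P(X <= k) under the extended hypergeometric model."""
    ks, p = _pmf_table(model)
    cum = np.minimum(np.cumsum(p), 1.0)
    k_arr = np.asarray(k)
    below = k_arr < ks[0]
    out = np.where(below, 0.0, _at_k(ks, cum, np.maximum(k_arr, ks[0]), 1.0))
    return float(out) if np.isscalar(k) or k_arr.ndim == 0 else out


def affinity_mean(model: CooccurrenceModel) -> float:
    """E_alpha(X), strictly increasing in alpha; equals m_A*m_B/N at alpha = 0."""
    ks, p = _pmf_table(model)
    return float(np.sum(ks * p))
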