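"""Classical similarity indices and their exact null distributions.

With margins fixed, every index of the 2x2 table is a function of the
co-occurrence count ``k`` alone, so its exact null distribution is the
image of the hypergeometric null under that function.  Tabulating it over
the support exposes the phenomenon these tools exist to quantify: the null
centre of Jaccard (and friends) drifts with prevalence, while the null
centre of the affinity estimate stays at 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .distributions import null_pmf
from .estimation import mle_alpha_value
from .exceptions import UndefinedIndexError
from .tables import CooccurrenceModel, TwoByTwoTable

__all__ = [
    "jaccard",
    "sorensen_dice",
    "simpson",
    "jaccard_from_count",
    "alpha_hat_index",
    "INDEX_FUNCTIONS",
    "IndexNullDistribution",
    "index_null_distribution",
    "standardized_index",
    "median_crossing",
    "median_crossing_bracket",
    "centering_pairs",
]


def _require_occurrence(table: TwoByTwoTable, k: int | None = None) -> None:
    if table.a + table.b + table.c == 0:
        raise UndefinedIndexError("neither entity occurs anywhere (a+b+c = 0)", k=k)


def jaccard(table: TwoByTwoTable) -> float:
    """Jaccard index a/(a+b+c): shared sites over sites occupied by either entity."""
    _require_occurrence(table)
    return table.a / (table.a + table.b + table.c)


def sorensen_dice(table: TwoByTwoTable) -> float:
    """Sorensen-Dice index 2a/(2a+b+c)."""
    _require_occurrence(table)
    return 2 * table.a / (2 * table.a + table.b + table.c)


def simpson(table: TwoByTwoTable) -> float:
    """Simpson overlap a/(a+min(b,c)): shared sites over the rarer entity's sites."""
    _require_occurrence(table)
    denom = table.a + min(table.b, table.c)
    if denom == 0:
        raise UndefinedIndexError(
            "Simpson overlap undefined: the rarer entity occurs nowhere"
        )
    return table.a / denom


def jaccard_from_count(m_a: int, m_b: int, a: float) -> float:
    """Jaccard written in margin form a/(m_A + m_B - a); accepts a real-valued a.

    Useful for evaluating the index at non-integer reference points such as
    the null mean m_A*m_B/N.
    """
    denom = m_a + m_b - a
    if denom <= 0:
        raise UndefinedIndexError("Jaccard undefined: m_A + m_B - a <= 0")
    return a / denom


def alpha_hat_index(table: TwoByTwoTable, tol: float = 1e-10) -> float:
    """The truncated affinity estimate used *as* an index of the table."""
    return mle_alpha_value(table.n, table.m_a, table.m_b, table.k, tol)[0]


INDEX_FUNCTIONS: dict[str, Callable[[TwoByTwoTable], float]] = {
    "jaccard": jaccard,
    "dice": sorensen_dice,
    "simpson": simpson,
    "alpha": alpha_hat_index,
}


def _resolve(index) -> tuple[str, Callable[[TwoByTwoTable], float]]:
    if callable(index):
        return getattr(index, "__name__", "custom"), index
    try:
        return index, INDEX_FUNCTIONS[index]
    except KeyError:
        raise KeyError(
            f"unknown index {index!r}; choose from {sorted(INDEX_FUNCTIONS)}"
        ) from None


@dataclass(frozen=True)
class IndexNullDistribution:
    """Exact distribution of an index over the null co-occurrence support."""

    index_name: str
    n: int
    m_a: int
    m_b: int
    k: np.ndarray            # support points
    value: np.ndarray        # index at each support point
    probability: np.ndarray  # hypergeometric null mass at each point
    e_null: float
    sd_null: float

    @property
    def attainable_min(self) -> float:
        return float(self.value.min())

    @property
    def attainable_max(self) -> float:
        return float(self.value.max())

    def cdf(self, t: float) -> float:
        """P(index <= t) under the null."""
        return float(self.probability[self.value <= t + 1e-12].sum())

    def median_crossing(self) -> float:
        """Smallest attained index value whose null CDF reaches 0.5."""
        order = np.argsort(self.value, kind="stable")
        cum = np.cumsum(self.probability[order])
        i = int(np.searchsorted(cum, 0.5 - 1e-12))
        return float(self.value[order][i])

    def median_crossing_bracket(self) -> tuple[float, float]:
        """Attained index values straddling the null CDF's crossing of 0.5.

        Returns ``(lo, hi)`` with ``hi`` the median-crossing value and ``lo``
        the largest attained value below it (``lo == hi`` when the crossing
        happens at the smallest attained value).
        """
        order = np.argsort(self.value, kind="stable")
        vals = self.value[order]
        cum = np.cumsum(self.probability[order])
        i = int(np.searchsorted(cum, 0.5 - 1e-12))
        return (float(vals[i - 1]) if i > 0 else float(vals[i]), float(vals[i]))


def index_null_distribution(index, n: int, m_a: int, m_b: int) -> IndexNullDistribution:
    """Tabulate an index and its exact null weights over the support.

    ``index`` is a name from :data:`INDEX_FUNCTIONS` or any callable mapping a
    :class:`TwoByTwoTable` to a real.  An index undefined at some support
    point raises :class:`UndefinedIndexError` identifying the offending k.
    """
    name, func = _resolve(index)
    model = CooccurrenceModel(n, m_a, m_b, 0.0)
    sup = model.support
    ks = np.arange(sup.k_min, sup.k_max + 1)
    values = np.empty(len(ks))
    for i, k in enumerate(ks):
        try:
            values[i] = func(TwoByTwoTable.from_margins(n, m_a, m_b, int(k)))
        except UndefinedIndexError as exc:
            raise UndefinedIndexError(
                f"index {name!r} undefined at support point k={int(k)}: {exc.reason}",
                k=int(k),
            ) from exc
    probs = null_pmf(model, ks)
    e = float(np.dot(values, probs))
    sd = float(np.sqrt(np.dot((values - e) ** 2, probs)))
    return IndexNullDistribution(name, n, m_a, m_b, ks, values, probs, e, sd)


def standardized_index(index, table: TwoByTwoTable) -> float:
    """(observed index - exact null mean) / exact null sd, margins fixed."""
    dist = index_null_distribution(index, table.n, table.m_a, table.m_b)
    if dist.sd_null == 0:
        raise UndefinedIndexError(
            "standardized index undefined: null sd is 0 (single-point support)"
        )
    _, func = _resolve(index)
    return (func(table) - dist.e_null) / dist.sd_null


def median_crossing(index, n: int, m_a: int, m_b: int) -> float:
    """Index value at which the null CDF first reaches 0.5 — the curve's centre."""
    return index_null_distribution(index, n, m_a, m_b).median_crossing()


def median_crossing_bracket(index, n: int, m_a: int, m_b: int) -> tuple[float, float]:
    """Pair of attained index values straddling the null CDF's 0.5 crossing."""
    return index_null_distribution(index, n, m_a, m_b).median_crossing_bracket()


def centering_pairs(
    n: int, h: float, tol: float
) -> Sequence[tuple[int, int]]:
    """Margin pairs whose null Jaccard distribution centres near ``h``.

    Because Jaccard increases in the count a, its null distribution centres
    near ``h`` when the null mean m_A*m_B/N plugged into a/(m_A+m_B-a) gives
    about ``h``, i.e. when ``N/m_A + N/m_B`` is close to ``(1+h)/h``.  Returns
    all pairs ``1 <= m_A <= m_B <= N-1`` within ``tol`` of that target, sorted
    by deviation.
    """
    if not 0.0 < h < 1.0:
        raise ValueError(f"h must be in (0, 1), got {h}")
    if n < 2:
        raise ValueError(f"N must be at least 2, got {n}")
    target = (1.0 + h) / h
    found: list[tuple[float, int, int]] = []
    for m_a in range(1, n):
        for m_b in range(m_a, n):
            dev = abs(n / m_a + n / m_b - target)
            if dev <= tol:
                found.append((dev, m_a, m_b))
    found.sort()
    return [(m_a, m_b) for _, m_a, m_b in found]
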