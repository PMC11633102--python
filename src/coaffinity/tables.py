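"""Core data types for 2x2 co-occurrence analysis.

The sampling frame is a set of ``N`` sites ("boxes"); entity A occupies
``m_A`` of them and entity B occupies ``m_B``.  The 2x2 table records

    a : sites with both entities        b : sites with only B
    c : sites with only A               d : sites with neither

so that ``N = a+b+c+d``, ``m_A = a+c``, ``m_B = a+b`` and the co-occurrence
count is ``k = a``.  With margins fixed, ``k`` ranges over the integer
interval ``max(m_A + m_B - N, 0) .. min(m_A, m_B)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import InvalidMarginsError

__all__ = ["TwoByTwoTable", "CooccurrenceModel", "SupportRange"]


@dataclass(frozen=True)
class SupportRange:
    """Inclusive range of attainable co-occurrence counts."""

    k_min: int
    k_max: int

    def __post_init__(self) -> None:
        if self.k_min > self.k_max:
            raise InvalidMarginsError(
                f"empty support: k_min={self.k_min} > k_max={self.k_max}"
            )

    @property
    def size(self) -> int:
        return self.k_max - self.k_min + 1

    @property
    def is_single_point(self) -> bool:
        return self.k_min == self.k_max

    def __contains__(self, k: int) -> bool:
        return self.k_min <= k <= self.k_max

    def __iter__(self):
        return iter(range(self.k_min, self.k_max + 1))


def _check_margins(n: int, m_a: int, m_b: int) -> None:
    for name, v in (("N", n), ("m_A", m_a), ("m_B", m_b)):
        if int(v) != v or v < 0:
            raise InvalidMarginsError(f"{name} must be a non-negative integer, got {v!r}")
    if max(m_a, m_b) > n:
        raise InvalidMarginsError(
            f"margins exceed the number of sites: m_A={m_a}, m_B={m_b}, N={n}"
        )


def _support(n: int, m_a: int, m_b: int) -> SupportRange:
    return SupportRange(max(m_a + m_b - n, 0), min(m_a, m_b))


@dataclass(frozen=True)
class TwoByTwoTable:
    """Observed 2x2 co-occurrence table with cells ``a, b, c, d``."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise InvalidMarginsError(
                    f"cell {name} must be a non-negative integer, got {v!r}"
                )

    @classmethod
    def from_margins(cls, n: int, m_a: int, m_b: int, k: int) -> "TwoByTwoTable":
        """Build the table from ``(N, m_A, m_B)`` and the co-occurrence count ``k``."""
        _check_margins(n, m_a, m_b)
        sup = _support(n, m_a, m_b)
        if k not in sup:
            raise InvalidMarginsError(
                f"k={k} outside the attainable range [{sup.k_min}, {sup.k_max}]"
            )
        return cls(a=k, b=m_b - k, c=m_a - k, d=n - m_a - m_b + k)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def m_a(self) -> int:
        return self.a + self.c

    @property
    def m_b(self) -> int:
        return self.a + self.b

    @property
    def k(self) -> int:
        return self.a

    @property
    def support(self) -> SupportRange:
        return _support(self.n, self.m_a, self.m_b)

    def model(self, alpha: float = 0.0) -> "CooccurrenceModel":
        """The co-occurrence model sharing this table's margins."""
        return CooccurrenceModel(self.n, self.m_a, self.m_b, alpha)

    def swap_roles(self) -> "TwoByTwoTable":
        """Exchange the roles of the two entities (transposes b and c)."""
        return TwoByTwoTable(self.a, self.c, self.b, self.d)


@dataclass(frozen=True)
class CooccurrenceModel:
    """Margins ``(N, m_A, m_B)`` plus the log-odds affinity parameter ``alpha``.

    ``alpha = 0`` is the independence null; positive values tilt the
    co-occurrence count upward, negative values downward.  ``alpha`` must be
    finite for all probability evaluations; infinite affinities correspond to
    point masses at the support endpoints and are handled explicitly by
    callers.
    """

    n: int
    m_a: int
    m_b: int
    alpha: float = 0.0

    def __post_init__(self) -> None:
        _check_margins(self.n, self.m_a, self.m_b)
        if not math.isfinite(self.alpha):
            raise InvalidMarginsError(
                f"alpha must be finite for model evaluation, got {self.alpha!r}"
            )

    @property
    def support(self) -> SupportRange:
        return _support(self.n, self.m_a, self.m_b)

    @property
    def is_degenerate(self) -> bool:
        """True when the support is a single point (a margin equals 0 or N)."""
        return self.support.is_single_point

    def with_alpha(self, alpha: float) -> "CooccurrenceModel":
        return CooccurrenceModel(self.n, self.m_a, self.m_b, alpha)
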