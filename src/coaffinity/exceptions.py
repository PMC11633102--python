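"""Typed errors raised across the package.

Degenerate configurations (an entity present everywhere or nowhere, a
single-point co-occurrence support) are represented by errors rather than
sentinel numbers so that downstream code cannot silently average an
undefined estimate into a summary.
"""


class CoaffinityError(Exception):
    """Base class for all package errors."""


class InvalidMarginsError(CoaffinityError, ValueError):
    """Margins violate 0 <= min(m_A, m_B) <= max(m_A, m_B) <= N, or counts are negative."""


class EstimateUndefinedError(CoaffinityError):
    """Affinity estimation is undefined (single-point co-occurrence support).

    Carries a human-readable ``reason``.
    """

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


class UndefinedBoundError(CoaffinityError):
    """The finite-estimate bound log(2(N - min(m_A,m_B) - 1) * min(m_A,m_B)) has a
    non-positive argument, which can only happen when the support has no interior point."""


class UndefinedIndexError(CoaffinityError):
    """A similarity index is undefined at the given table (0/0 form)."""

    def __init__(self, reason: str, k: int | None = None):
        self.reason = reason
        self.k = k
        super().__init__(reason)
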