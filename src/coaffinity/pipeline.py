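"""All-pairs affinity analysis over a binary presence-absence matrix.

The input is a sites x entities 0/1 matrix (sites in rows, entities in
columns; a ``transpose`` switch covers the other orientation, since what
counts as a "site" differs between applications).  Every unordered entity
pair yields one record carrying the 2x2 table, the affinity estimate and
the classical indices.  Degenerate entities (present everywhere or
nowhere) are reported with undefined estimates rather than dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .estimation import AffinityEstimate, mle_alpha
from .exceptions import CoaffinityError, EstimateUndefinedError, UndefinedIndexError
from .indices import jaccard, simpson, sorensen_dice, standardized_index
from .tables import TwoByTwoTable

__all__ = [
    "OccurrenceMatrix",
    "PairRecord",
    "table_from_columns",
    "pairwise_affinity",
    "records_to_frame",
    "write_pair_table",
    "read_occurrence_csv",
    "write_occurrence_csv",
    "PAIR_TABLE_COLUMNS",
    "PAIR_TABLE_VERSION",
]

#: schema version of the pair-table CSV written by :func:`write_pair_table`
PAIR_TABLE_VERSION = 1

#: column order of the pair table (version 1)
PAIR_TABLE_COLUMNS = [
    "entity_1", "entity_2", "N", "mA", "mB", "a", "b", "c", "d",
    "alpha_hat", "boundary_flag", "degenerate", "ci_low", "ci_high",
    "p_null", "jaccard", "dice", "simpson", "jaccard_std",
]


class MatrixValidationError(CoaffinityError, ValueError):
    """The occurrence matrix violates the binary/labels contract."""


@dataclass(frozen=True, eq=False)
class OccurrenceMatrix:
    """Binary sites x entities grid with unique row and column labels."""

    values: np.ndarray
    site_labels: tuple[str, ...]
    entity_labels: tuple[str, ...]

    def __eq__(self, other) -> bool:
        if not isinstance(other, OccurrenceMatrix):
            return NotImplemented
        return (
            self.site_labels == other.site_labels
            and self.entity_labels == other.entity_labels
            and np.array_equal(self.values, other.values)
        )

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise MatrixValidationError("occurrence matrix must be 2-dimensional")
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise MatrixValidationError(
                f"non-binary value {values[i, j]!r} at site "
                f"{self.site_labels[i]!r}, entity {self.entity_labels[j]!r}"
            )
        if values.shape != (len(self.site_labels), len(self.entity_labels)):
            raise MatrixValidationError("label lengths do not match matrix shape")
        for kind, labels in (("site", self.site_labels), ("entity", self.entity_labels)):
            if len(set(labels)) != len(labels):
                raise MatrixValidationError(f"duplicate {kind} labels")
        object.__setattr__(self, "values", values.astype(np.int8))
        object.__setattr__(self, "site_labels", tuple(map(str, self.site_labels)))
        object.__setattr__(self, "entity_labels", tuple(map(str, self.entity_labels)))

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_entities(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "OccurrenceMatrix":
        return cls(
            frame.to_numpy(),
            tuple(map(str, frame.index)),
            tuple(map(str, frame.columns)),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(),
            index=list(self.site_labels),
            columns=list(self.entity_labels),
        )

    def transpose(self) -> "OccurrenceMatrix":
        return OccurrenceMatrix(self.values.T, self.entity_labels, self.site_labels)


def read_occurrence_csv(
    source, transpose: bool = False, nonbinary: str = "error"
) -> OccurrenceMatrix:
    """Read a labelled binary matrix from CSV (header row, label column).

    ``nonbinary`` is either ``"error"`` (strict, names the offending cell) or
    ``"threshold"`` (values >= 0.5 become 1).
    """
    try:
        frame = pd.read_csv(source, index_col=0)
    except Exception as exc:  # pandas raises several parser error types
        raise MatrixValidationError(f"could not parse occurrence CSV: {exc}") from exc
    if nonbinary == "threshold":
        frame = (frame.astype(float) >= 0.5).astype(int)
    elif nonbinary != "error":
        raise ValueError(f"unknown nonbinary policy {nonbinary!r}")
    matrix = OccurrenceMatrix.from_dataframe(frame)
    return matrix.transpose() if transpose else matrix


def write_occurrence_csv(matrix: OccurrenceMatrix, destination) -> None:
    matrix.to_dataframe().to_csv(destination, index_label="site")


def table_from_columns(matrix: OccurrenceMatrix, i, j) -> TwoByTwoTable:
    """2x2 table for entity columns ``i`` and ``j`` (indices or labels)."""
    def _col(key):
        if isinstance(key, str):
            try:
                key = matrix.entity_labels.index(key)
            except ValueError:
                raise KeyError(f"unknown entity label {key!r}") from None
        return matrix.values[:, key], key

    x, i = _col(i)
    y, j = _col(j)
    if i == j:
        raise ValueError("need two distinct entities")
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 0) & (y == 1)))
    c = int(np.sum((x == 1) & (y == 0)))
    d = int(np.sum((x == 0) & (y == 0)))
    return TwoByTwoTable(a, b, c, d)


@dataclass(frozen=True)
class PairRecord:
    """Per-pair results: the table, the affinity estimate and the indices.

    ``estimate`` is None for degenerate pairs, with the reason preserved;
    indices undefined at the pair's table are NaN.
    """

    entity_1: str
    entity_2: str
    table: TwoByTwoTable
    estimate: AffinityEstimate | None
    degenerate_reason: str | None
    jaccard: float
    dice: float
    simpson: float
    jaccard_std: float


def _maybe(func, *args) -> float:
    try:
        return float(func(*args))
    except UndefinedIndexError:
        return math.nan


def pairwise_affinity(
    matrix: OccurrenceMatrix,
    ci_level: float = 0.95,
    tol: float = 1e-10,
    ci_method: str = "midp",
    p_method: str = "minlike",
) -> list[PairRecord]:
    """Affinity analysis of every unordered entity pair, in label-sorted order."""
    if matrix.n_entities < 2:
        raise MatrixValidationError("pairwise analysis needs at least 2 entities")
    order = sorted(range(matrix.n_entities), key=lambda i: matrix.entity_labels[i])
    records = []
    for i, j in combinations(order, 2):
        table = table_from_columns(matrix, i, j)
        try:
            estimate = mle_alpha(table, tol=tol, ci_level=ci_level,
                                 ci_method=ci_method, p_method=p_method)
            reason = None
        except EstimateUndefinedError as exc:
            estimate, reason = None, exc.reason
        records.append(
            PairRecord(
                entity_1=matrix.entity_labels[i],
                entity_2=matrix.entity_labels[j],
                table=table,
                estimate=estimate,
                degenerate_reason=reason,
                jaccard=_maybe(jaccard, table),
                dice=_maybe(sorensen_dice, table),
                simpson=_maybe(simpson, table),
                jaccard_std=_maybe(standardized_index, "jaccard", table),
            )
        )
    return records


def records_to_frame(
    records: list[PairRecord], adjust: str | None = None
) -> pd.DataFrame:
    """Tidy pair table (schema version 1); ``adjust="bh"`` appends p_null_bh."""
    rows = []
    for r in records:
        e = r.estimate
        rows.append({
            "entity_1": r.entity_1,
            "entity_2": r.entity_2,
            "N": r.table.n,
            "mA": r.table.m_a,
            "mB": r.table.m_b,
            "a": r.table.a,
            "b": r.table.b,
            "c": r.table.c,
            "d": r.table.d,
            "alpha_hat": e.alpha_hat if e else math.nan,
            "boundary_flag": bool(e.is_boundary) if e else False,
            "degenerate": e is None,
            "ci_low": e.ci_low if e else math.nan,
            "ci_high": e.ci_high if e else math.nan,
            "p_null": e.p_null if e else math.nan,
            "jaccard": r.jaccard,
            "dice": r.dice,
            "simpson": r.simpson,
            "jaccard_std": r.jaccard_std,
        })
    frame = pd.DataFrame(rows, columns=PAIR_TABLE_COLUMNS)
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        adjusted = np.full(len(frame), math.nan)
        mask = frame["p_null"].notna().to_numpy()
        if mask.any():
            adjusted[mask] = multipletests(
                frame.loc[mask, "p_null"], method="fdr_bh"
            )[1]
        frame["p_null_bh"] = adjusted
    elif adjust not in (None, "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    return frame


def write_pair_table(
    records: list[PairRecord], destination, adjust: str | None = None
) -> None:
    """Write the pair table as CSV (schema version 1)."""
    records_to_frame(records, adjust=adjust).to_csv(destination, index=False)


def affinity_dissimilarity(frame: pd.DataFrame) -> pd.DataFrame:
    """Affine transform max(alpha_hat) - alpha_hat, exported for downstream
    clustering tools that expect a dissimilarity; plumbing only, no new
    information beyond the truncated estimates (boundary flags still apply)."""
    out = frame.copy()
    out["dissimilarity"] = out["alpha_hat"].max() - out["alpha_hat"]
    return out
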