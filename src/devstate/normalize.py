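"""Opt-in expression transforms.

The projection arithmetic is unit-agnostic, so no transform is ever applied
implicitly; these are offered for callers whose raw data are linear-scale
intensities.  ``log2`` maps x -> log2(1 + x), defined for zeros and
monotone; ``log2+quantile`` additionally quantile-normalizes across samples
(each column's sorted values are replaced by the across-column mean of
values at the same rank), the standard microarray between-array transform.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .io import ExpressionTable

METHODS = ("none", "log2", "log2+quantile")


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Rank-mean quantile normalization of a genes x samples matrix.

    Ties within a column receive the value at their sorted slot (plain
    rank order, not mid-rank), which is adequate for continuous data.
    """
    order = np.argsort(values, axis=0)
    ranks = np.empty_like(order)
    rows = np.arange(values.shape[0])[:, None]
    np.put_along_axis(ranks, order, rows, axis=0)
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    return mean_sorted[ranks]


def normalize_expression(table: ExpressionTable, method: str) -> ExpressionTable:
    """Apply one of the named transforms; ``"none"`` returns the input."""
    if method not in METHODS:
        raise ValidationError(
            f"unknown normalization {method!r}; choose from {METHODS}"
        )
    if method == "none":
        return table
    if np.any(table.values < 0):
        raise ValidationError(
            "log2 normalization requires non-negative values "
            "(data may already be log-scale)"
        )
    values = np.log2(1.0 + table.values)
    if method == "log2+quantile":
        values = quantile_normalize(values)
    return ExpressionTable(
        gene_ids=list(table.gene_ids),
        sample_ids=list(table.sample_ids),
        values=values,
    )
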