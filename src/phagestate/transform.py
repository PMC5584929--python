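"""Count normalizations and variance-stabilizing transforms.

Every operation returns an ExpressionMatrix tagged with its transform
chain, so any downstream value can be traced back to the raw counts. All
transforms are elementwise monotone non-decreasing, preserving within-
sample rank order.
"""

from __future__ import annotations

import logging
from typing import Union

import numpy as np
import pandas as pd

from .containers import CountMatrix, DataError, ExpressionMatrix

logger = logging.getLogger(__name__)


def _as_expression(source: Union[CountMatrix, ExpressionMatrix]) -> ExpressionMatrix:
    if isinstance(source, CountMatrix):
        return ExpressionMatrix(
            values=source.counts.astype(float), transform_chain=[], source=source
        )
    return source


def libsize_normalize(
    counts: CountMatrix, scale: float = 1e6
) -> ExpressionMatrix:
    """Counts per ``scale`` retained pairs (default: per million).

    Samples with zero library size cannot be normalized and are dropped
    with a logged reason (they fall under the negligible-expression rule
    anyway).
    """
    lib = counts.library_size
    zero = list(lib.index[lib == 0])
    if zero:
        logger.warning("dropping samples with zero library size: %s", zero)
        counts = counts.drop_samples(zero)
        lib = counts.library_size
    values = counts.counts / lib.astype(float) * scale
    return ExpressionMatrix(
        values=values,
        transform_chain=[("libsize_normalize", {"scale": scale, "dropped": zero})],
        source=counts,
    )


def rpob_normalize(counts: CountMatrix, rpob_gene: str = "rpoB") -> ExpressionMatrix:
    """Per-sample division by the host rpoB count (host-density proxy).

    Samples where rpoB is zero are not normalizable; they are dropped with
    a logged reason rather than pseudocounted.
    """
    if rpob_gene not in counts.counts.index:
        raise DataError(f"rpoB gene {rpob_gene!r} not present in count matrix")
    rpob = counts.counts.loc[rpob_gene]
    zero = list(rpob.index[rpob == 0])
    if zero:
        logger.warning("samples not rpoB-normalizable (rpoB = 0): %s", zero)
        counts = counts.drop_samples(zero)
        rpob = counts.counts.loc[rpob_gene]
    values = counts.counts / rpob.astype(float)
    return ExpressionMatrix(
        values=values,
        transform_chain=[
            ("rpob_normalize", {"rpob_gene": rpob_gene, "dropped": zero})
        ],
        source=counts,
    )


def log2_shift(x):
    """log2(x + 10), the correlation-analysis transform; defined for x >= 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise DataError("log2_shift requires non-negative input")
    return np.log2(x + 10.0)


def log2_shift_matrix(
    m: Union[CountMatrix, ExpressionMatrix]
) -> ExpressionMatrix:
    """Elementwise log2(x + 10) over a count or expression matrix."""
    em = _as_expression(m)
    values = pd.DataFrame(
        log2_shift(em.values.to_numpy()), index=em.genes, columns=em.samples
    )
    return em.with_transform(values, "log2_shift", shift=10)


def sqrt_transform(m: Union[CountMatrix, ExpressionMatrix]) -> ExpressionMatrix:
    """Elementwise square root (the pre-resemblance transform)."""
    em = _as_expression(m)
    arr = em.values.to_numpy()
    if np.any(arr < 0):
        raise DataError("sqrt_transform requires non-negative input")
    values = pd.DataFrame(np.sqrt(arr), index=em.genes, columns=em.samples)
    return em.with_transform(values, "sqrt")
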