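"""Expression-table preparation: impute, filter, log2 transform, quantile normalize.

Missing values are imputed with the gene's mean within the sample's cancer
type (global gene mean as fallback); genes never reaching the expression
floor in any sample are removed; the table is then log2(x+1) transformed and
quantile normalized so every sample shares one common value distribution.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger("ipmg")


def impute_by_cancer_type(m: ExpressionMatrix, clin: pd.DataFrame) -> ExpressionMatrix:
    """Replace each NA with the gene's mean over same-cancer-type samples.

    If a gene is entirely missing within one cancer type, its global mean
    over all samples fills in; a gene missing everywhere is an error.
    """
    vals = m.values.copy()
    all_na = vals.isna().all(axis=1)
    if all_na.any():
        raise ValueError(f"gene {vals.index[all_na][0]!r} has no observed values")

    types = clin.set_index("sample_id")["cancer_type"].reindex(vals.columns)
    if types.isna().any():
        missing = types.index[types.isna()][0]
        raise ValueError(f"sample {missing!r} has no cancer_type in the clinical table")

    global_mean = vals.mean(axis=1)
    for _, cols in vals.columns.groupby(types).items():
        block = vals[cols]
        type_mean = block.mean(axis=1)
        fill = type_mean.fillna(global_mean)
        vals[cols] = block.apply(lambda c: c.fillna(fill))
    return m.with_values(vals, stage="imputed")


def filter_low_expression(m: ExpressionMatrix, threshold: float = 1.0) -> ExpressionMatrix:
    """Keep a gene iff at least one sample reaches ``threshold``."""
    keep = (m.values >= threshold).any(axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_low_expression: removed %d genes below %.3g everywhere",
                    n_drop, threshold)
    return m.with_values(m.values.loc[keep], stage="filtered")


def log2_quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x+1) then classic quantile normalization across samples.

    Each sample's values are replaced by the cross-sample mean of the sorted
    log values at the matching rank; within-sample ties receive the mean over
    their rank range (the standard mean-of-ranks convention).
    """
    if (m.values < 0).any(axis=None):
        raise ValueError("negative expression value; log2 transform undefined")
    logged = np.log2(m.values + 1.0)
    if logged.shape[1] == 1:
        return m.with_values(logged, stage="normalized")

    arr = logged.to_numpy(float)
    order = np.argsort(arr, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(arr, order, axis=0)
    ref = sorted_vals.mean(axis=1)  # mean of sorted values at each rank

    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        x = arr[:, j]
        ordinal = np.argsort(np.argsort(x, kind="stable"))
        ref_at = ref[ordinal]
        # ties receive the mean of ref over their whole rank block
        uniq, inv, counts = np.unique(x, return_inverse=True, return_counts=True)
        sums = np.zeros(len(uniq))
        np.add.at(sums, inv, ref_at)
        out[:, j] = sums[inv] / counts[inv]
    df = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return m.with_values(df, stage="normalized")
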