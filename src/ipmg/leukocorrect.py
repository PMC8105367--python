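"""Leukocyte-fraction correction of immune-gene expression.

Bulk tumor expression mixes tumor cells and infiltrating leukocytes, so the
measured level of an immune gene rises mechanically with the leukocyte
fraction of the sample. Genes whose expression correlates positively with
leukocyte fraction and negatively with tumor purity are treated as
immune-related; their per-cell activity is recovered by dividing the
expression value by the leukocyte fraction (floored to avoid unbounded
inflation at near-zero fractions).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger("ipmg")

FRACTION_FLOOR = 0.01


def select_immune_genes(expr: ExpressionMatrix, fractions: pd.DataFrame,
                        cutoff: float = 0.3) -> pd.DataFrame:
    """Genes with Pearson r >= cutoff vs leukocyte fraction and <= -cutoff vs purity.

    Returns a frame indexed by gene with columns r_fraction, r_purity and
    selected. Zero-variance genes are excluded (correlation undefined).
    """
    common = expr.sample_ids.intersection(fractions.index)
    if len(common) < 3:
        raise ValueError("need >= 3 samples with leukocyte fraction and purity")
    X = expr.values[common].to_numpy(float)
    f = fractions.loc[common, "leukocyte_fraction"].to_numpy(float)
    p = fractions.loc[common, "tumor_purity"].to_numpy(float)

    Xc = X - X.mean(axis=1, keepdims=True)
    sd = Xc.std(axis=1)
    ok = sd > 0

    def _corr(v: np.ndarray) -> np.ndarray:
        vc = v - v.mean()
        denom = sd * vc.std()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(ok, (Xc @ vc) / len(v) / np.where(denom > 0, denom, np.nan), np.nan)

    rf = _corr(f)
    rp = _corr(p)
    out = pd.DataFrame({"r_fraction": rf, "r_purity": rp}, index=expr.gene_ids)
    out["selected"] = ok & (rf >= cutoff) & (rp <= -cutoff)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.warning("select_immune_genes: %d zero-variance genes excluded", n_excluded)
    return out


def correct_by_fraction(expr: ExpressionMatrix, fractions: pd.DataFrame,
                        immune_genes: set[str] | list[str],
                        floor: float = FRACTION_FLOOR,
                        linear_scale: bool = False) -> ExpressionMatrix:
    """Divide immune-gene expression by max(leukocyte fraction, floor).

    Samples with no recorded fraction are dropped from the corrected table
    (with a warning); non-immune genes pass through unchanged. By default
    the division acts on the table as given (the normalized log scale);
    ``linear_scale`` instead divides 2^x - 1 and transforms back.
    """
    immune = pd.Index(immune_genes)
    unknown = immune.difference(expr.gene_ids)
    if len(unknown):
        raise ValueError(f"immune genes not in expression table: {list(unknown)[:5]}")

    have = expr.sample_ids.intersection(
        fractions.index[fractions["leukocyte_fraction"].notna()])
    dropped = expr.sample_ids.difference(have)
    if len(dropped):
        logger.warning("correct_by_fraction: %d samples lack a fraction; excluded", len(dropped))
    vals = expr.values[have].copy()
    f = np.maximum(fractions.loc[have, "leukocyte_fraction"].to_numpy(float), floor)
    if linear_scale:
        lin = np.exp2(vals.loc[immune].to_numpy()) - 1.0
        vals.loc[immune] = np.log2(lin / f + 1.0)
    else:
        vals.loc[immune] = vals.loc[immune].to_numpy() / f
    return expr.with_values(vals, stage="fraction_corrected")
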