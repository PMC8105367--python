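"""Genome-wide survival screen.

For every gene, samples are split per cancer type into the top and bottom
expression quantile (default 30%), pooled across types into a
high-expression and a low-expression group, and compared with a one-tailed
log-rank test after administratively censoring follow-up at a cap (default
3 years). Two ranked gene lists come out: one under the hypothesis that
high expression prolongs survival, one under the opposite hypothesis.

The log-rank statistic is computed by an in-package vectorized routine so a
whole genome (and the many cohort resamples of the specificity null) can be
screened in one pass; it matches lifelines' two-group test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

logger = logging.getLogger("ipmg")

DAYS_PER_YEAR = 365.0


@dataclass
class SurvivalSpec:
    """Settings of the survival screen."""

    cap_years: float = 3.0
    quantile: float = 0.30
    treatment_class: str = "immunotherapy"
    min_type_size: int = 4

    def __post_init__(self) -> None:
        if not (0.0 < self.quantile <= 0.5):
            raise ValueError("quantile must lie in (0, 0.5]")


@dataclass
class RankedGeneList:
    """Genes ordered by one-tailed log-rank significance.

    ``table`` columns: gene, p, stat (-log10 p); ascending p, ties broken by
    gene id. ``direction`` is "high_better" or "high_worse".
    """

    table: pd.DataFrame
    direction: str

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    def stats(self) -> pd.Series:
        return self.table.set_index("gene")["stat"]


def cap_survival(clin: pd.DataFrame, cap_years: float) -> pd.DataFrame:
    """Administratively censor follow-up beyond ``cap_years``.

    Times above the cap are set to the cap with event <- 0; all other rows
    are unchanged.
    """
    out = clin.copy()
    cap_days = cap_years * DAYS_PER_YEAR
    over = out["time_days"] > cap_days
    out.loc[over, "time_days"] = cap_days
    out.loc[over, "event"] = 0
    return out


def stratified_groups(expr_row: pd.Series, clin: pd.DataFrame,
                      quantile: float = 0.30, min_type_size: int = 4
                      ) -> tuple[list[str], list[str]]:
    """Top/bottom expression quantile per cancer type, pooled across types.

    Group size per type is floor(q * n) with a minimum of 1; expression ties
    are broken by sample id (ascending), making the split deterministic.
    Types with fewer than ``min_type_size`` samples are skipped.
    """
    high: list[str] = []
    low: list[str] = []
    clin = clin[clin["sample_id"].isin(expr_row.index)]
    for t, block in clin.groupby("cancer_type", observed=True):
        ids = sorted(block["sample_id"])
        if len(ids) < min_type_size:
            logger.warning("stratified_groups: cancer type %s has %d samples; skipped",
                           t, len(ids))
            continue
        m = max(1, int(np.floor(quantile * len(ids))))
        vals = expr_row[ids].to_numpy(float)
        order = np.argsort(vals, kind="stable")  # ids pre-sorted -> ties by sample id
        low.extend(ids[i] for i in order[:m])
        high.extend(ids[i] for i in order[-m:])
    return high, low


def _logrank_arrays(time: np.ndarray, event: np.ndarray, H: np.ndarray, L: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-group log-rank over G gene-specific group pairs.

    ``H``/``L`` are (n, G) boolean membership matrices of the high/low
    groups. Returns (chi2, OmE_high, valid) arrays of length G; ``valid``
    is False when a gene has an empty group or no events among its
    participants.
    """
    H = np.asarray(H, bool)
    L = np.asarray(L, bool)
    P = H | L
    order = np.argsort(time, kind="stable")
    t = np.asarray(time, float)[order]
    e = np.asarray(event, float)[order]
    Hs = H[order].astype(np.float64)
    Ps = P[order].astype(np.float64)

    _, starts = np.unique(t, return_index=True)
    G = H.shape[1]

    d = np.add.reduceat(e[:, None] * Ps, starts, axis=0)
    d1 = np.add.reduceat(e[:, None] * Hs, starts, axis=0)
    cumP = np.cumsum(Ps, axis=0)
    cumH = np.cumsum(Hs, axis=0)
    totP = cumP[-1]
    totH = cumH[-1]
    prevP = np.vstack([np.zeros(G), cumP[starts[1:] - 1]]) if len(starts) > 1 else \
        np.zeros((1, G))
    prevH = np.vstack([np.zeros(G), cumH[starts[1:] - 1]]) if len(starts) > 1 else \
        np.zeros((1, G))
    n_at = totP[None, :] - prevP
    n1_at = totH[None, :] - prevH

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n_at > 0, n1_at / n_at, 0.0)
        OmE = (d1 - d * frac).sum(axis=0)
        vterm = d * frac * (1.0 - frac) * np.where(n_at > 1, (n_at - d) / (n_at - 1), 0.0)
        V = vterm.sum(axis=0)
        chi2 = np.where(V > 0, OmE**2 / V, 0.0)

    valid = (totH > 0) & (totP - totH > 0) & (d.sum(axis=0) > 0)
    return chi2, OmE, valid


def one_tailed_logrank(high: pd.DataFrame, low: pd.DataFrame, direction: str) -> float:
    """One-tailed log-rank p for the hypothesized direction.

    The two-sided chi-square p is halved when the observed effect matches
    the hypothesis (``high_better``: fewer deaths than expected in the high
    group; ``high_worse``: more) and complemented otherwise. With zero
    events in both groups the test is uninformative and p = 1.
    """
    n_h, n_l = len(high), len(low)
    if n_h == 0 or n_l == 0:
        raise ValueError("both groups must be non-empty")
    time = np.concatenate([high["time_days"].to_numpy(float), low["time_days"].to_numpy(float)])
    event = np.concatenate([high["event"].to_numpy(float), low["event"].to_numpy(float)])
    if event.sum() == 0:
        logger.warning("one_tailed_logrank: zero events in both groups; p = 1")
        return 1.0
    H = np.zeros((n_h + n_l, 1), bool)
    H[:n_h, 0] = True
    L = ~H
    chi2, OmE, valid = _logrank_arrays(time, event, H, L)
    return float(_one_tailed_p(chi2, OmE, valid, direction)[0])


def _one_tailed_p(chi2: np.ndarray, OmE: np.ndarray, valid: np.ndarray,
                  direction: str) -> np.ndarray:
    if direction not in ("high_better", "high_worse"):
        raise ValueError(f"unknown direction {direction!r}")
    p2 = stats.chi2.sf(chi2, df=1)
    observed_better = OmE < 0  # fewer deaths than expected in the high group
    match = observed_better if direction == "high_better" else (OmE > 0)
    p = np.where(chi2 == 0, 0.5, np.where(match, p2 / 2.0, 1.0 - p2 / 2.0))
    return np.where(valid, p, 1.0)


def group_membership(values: np.ndarray, sample_ids: list[str], clin: pd.DataFrame,
                     quantile: float, min_type_size: int = 4
                     ) -> tuple[np.ndarray, np.ndarray]:
    """(n, G) high/low membership masks for all genes at once.

    ``values`` is genes x samples; columns must align with ``sample_ids``.
    Within each cancer type, samples are ordered by expression with stable
    ties on sample id.
    """
    n = len(sample_ids)
    G = values.shape[0]
    H = np.zeros((n, G), bool)
    L = np.zeros((n, G), bool)
    pos = {s: i for i, s in enumerate(sample_ids)}
    for t, block in clin.groupby("cancer_type", observed=True):
        ids = sorted(s for s in block["sample_id"] if s in pos)
        if len(ids) < min_type_size:
            continue
        m = max(1, int(np.floor(quantile * len(ids))))
        cols = np.array([pos[s] for s in ids])
        sub = values[:, cols]  # (G, n_t)
        order = np.argsort(sub, axis=1, kind="stable")
        low_idx = cols[order[:, :m]]    # (G, m)
        high_idx = cols[order[:, -m:]]
        rows = np.repeat(np.arange(G), m)
        L[low_idx.ravel(), rows] = True
        H[high_idx.ravel(), rows] = True
    return H, L


def screen_genome(expr: ExpressionMatrix, clin: pd.DataFrame, spec: SurvivalSpec
                  ) -> dict[str, RankedGeneList]:
    """Rank all genes by one-tailed log-rank p in both directions.

    The cohort is filtered to ``spec.treatment_class``, follow-up is capped,
    groups are formed per gene and the vectorized log-rank is applied once.
    Degenerate genes (empty group, no events) receive p = 1.
    """
    cohort = clin[clin["treatment_class"] == spec.treatment_class]
    cohort = cohort[cohort["sample_id"].isin(expr.sample_ids)]
    if cohort.empty:
        raise ValueError(f"no samples with treatment_class={spec.treatment_class!r}")
    cohort = cap_survival(cohort, spec.cap_years)

    sample_ids = list(cohort["sample_id"])
    values = expr.values[sample_ids].to_numpy(float)
    H, L = group_membership(values, sample_ids, cohort, spec.quantile, spec.min_type_size)
    time = cohort["time_days"].to_numpy(float)
    event = cohort["event"].to_numpy(float)
    chi2, OmE, valid = _logrank_arrays(time, event, H, L)

    out: dict[str, RankedGeneList] = {}
    for direction in ("high_better", "high_worse"):
        p = _one_tailed_p(chi2, OmE, valid, direction)
        tab = pd.DataFrame({"gene": expr.gene_ids, "p": p})
        tab["stat"] = -np.log10(np.clip(tab["p"], 1e-300, None))
        tab = tab.sort_values(["p", "gene"], kind="stable").reset_index(drop=True)
        out[direction] = RankedGeneList(tab, direction)
    return out
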