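"""Patient stratification by marker-panel ssGSEA score.

All patients are scored on the candidate marker panel with ssGSEA and cut
into k groups at boundaries that split the immunotherapy-treated patients
equally (sizes differ by at most 1). The survival contrast compares the
k-group log-rank among immunotherapy patients with a resampling control:
each resample draws the same number of non-immunotherapy patients from each
group and recomputes the k-group test, showing whether the grouping
captures response to immunotherapy rather than overall prognosis. The two
extreme groups are then characterized by a one-tailed Mann-Whitney
differential-expression ranking fed to pre-ranked GSEA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .gsea import EnrichmentResult, preranked_gsea, ssgsea_score
from .io import ExpressionMatrix, PathwayDB
from .survival import RankedGeneList, cap_survival

logger = logging.getLogger("ipmg")


@dataclass
class PatientGroups:
    """k score-ordered patient groups (0 = highest panel score)."""

    labels: pd.Series            # sample_id -> group in [0, k)
    k: int
    boundaries: list[float]      # descending score boundaries between groups
    immuno_counts: list[int]

    def members(self, group: int) -> list[str]:
        return list(self.labels.index[self.labels == group])


def group_by_panel_score(expr: ExpressionMatrix, panel: set[str] | list[str],
                         clin: pd.DataFrame, k: int = 3, alpha: float = 0.25
                         ) -> PatientGroups:
    """Assign every patient to one of k groups by panel ssGSEA score.

    Boundaries are placed so immunotherapy-treated patients split into k
    equal blocks (±1, larger blocks first); every other patient is assigned
    by comparing its score to those boundaries. Ties are resolved
    deterministically by (score, sample_id) ordering.
    """
    panel = [g for g in panel if g in expr.gene_ids]
    if len(panel) < 2:
        raise ValueError("panel intersects expression table in < 2 genes")
    scores = ssgsea_score(expr, set(panel), alpha=alpha)
    clin = clin[clin["sample_id"].isin(scores.index)]
    immuno = clin.loc[clin["treatment_class"] == "immunotherapy", "sample_id"]
    if len(immuno) < k:
        raise ValueError("fewer immunotherapy patients than groups")
    if k == 1:
        labels = pd.Series(0, index=scores.index)
        return PatientGroups(labels, 1, [], [len(immuno)])

    # order immunotherapy patients by descending score, ties by sample id
    order = sorted(immuno, key=lambda s: (-scores[s], s))
    sizes = [len(order) // k + (1 if i < len(order) % k else 0) for i in range(k)]
    blocks, at = [], 0
    for size in sizes:
        blocks.append(order[at:at + size])
        at += size
    boundaries = [scores[block[-1]] for block in blocks[:-1]]  # lowest score per block

    assign = {}
    for s in scores.index:
        g = 0
        while g < k - 1 and scores[s] < boundaries[g]:
            g += 1
        assign[s] = g
    for g, block in enumerate(blocks):  # immunotherapy equal split takes precedence
        for s in block:
            assign[s] = g
    labels = pd.Series(assign, dtype=int).reindex(scores.index)
    return PatientGroups(labels, k, [float(b) for b in boundaries], sizes)


@dataclass
class GroupContrast:
    immuno_p: float
    control_median_p: float
    frac_control_smaller: float
    control_p: np.ndarray


def group_survival_contrast(groups: PatientGroups, clin: pd.DataFrame,
                            cap_years: float = 3.0, n_resample: int = 5000,
                            seed: int | np.random.Generator = 0) -> GroupContrast:
    """k-group log-rank among immunotherapy patients vs resampled controls.

    Each control resample draws, within every group, as many
    non-immunotherapy patients as the group holds immunotherapy patients,
    and recomputes the k-group log-rank. Reports the immunotherapy p, the
    median control p and the fraction of controls with smaller p.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    clin = cap_survival(clin[clin["sample_id"].isin(groups.labels.index)], cap_years)
    lab = groups.labels
    clin = clin.assign(group=lab[clin["sample_id"]].to_numpy())

    imm = clin[clin["treatment_class"] == "immunotherapy"]
    res = multivariate_logrank_test(imm["time_days"], imm["group"], imm["event"])
    immuno_p = float(res.p_value)

    ctrl = clin[clin["treatment_class"] == "non_immunotherapy"]
    per_group_ids = {g: ctrl.loc[ctrl["group"] == g, "sample_id"].to_numpy()
                     for g in range(groups.k)}
    need = {g: int((imm["group"] == g).sum()) for g in range(groups.k)}
    for g in range(groups.k):
        if need[g] > len(per_group_ids[g]):
            raise ValueError(f"group {g} lacks non-immunotherapy patients "
                             f"({len(per_group_ids[g])} < {need[g]})")

    ctrl_idx = ctrl.set_index("sample_id")
    control_p = np.empty(n_resample)
    for b in range(n_resample):
        picks, glab = [], []
        for g in range(groups.k):
            chosen = rng.choice(per_group_ids[g], size=need[g], replace=False)
            picks.append(chosen)
            glab.append(np.full(need[g], g))
        sel = ctrl_idx.loc[np.concatenate(picks)]
        r = multivariate_logrank_test(sel["time_days"].to_numpy(),
                                      np.concatenate(glab),
                                      sel["event"].to_numpy())
        control_p[b] = r.p_value
    return GroupContrast(
        immuno_p=immuno_p,
        control_median_p=float(np.median(control_p)),
        frac_control_smaller=float((control_p < immuno_p).mean()),
        control_p=control_p,
    )


def _km_survival_at(times: np.ndarray, events: np.ndarray, horizon: float) -> float:
    """Kaplan-Meier survival probability at ``horizon``."""
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    at_risk = len(t)
    surv = 1.0
    for ti, ei in zip(t, e):
        if ti > horizon:
            break
        if ei:
            surv *= 1.0 - 1.0 / at_risk
        at_risk -= 1
    return surv


def best_worst_groups(groups: PatientGroups, clin: pd.DataFrame,
                      cap_years: float = 3.0) -> tuple[int, int]:
    """Groups with the highest / lowest 3-year KM survival among immunotherapy patients."""
    clin = cap_survival(clin[clin["sample_id"].isin(groups.labels.index)], cap_years)
    imm = clin[clin["treatment_class"] == "immunotherapy"]
    lab = groups.labels
    surv = {}
    horizon = cap_years * 365.0
    for g in range(groups.k):
        ids = set(groups.members(g))
        block = imm[imm["sample_id"].isin(ids)]
        surv[g] = _km_survival_at(block["time_days"].to_numpy(float),
                                  block["event"].to_numpy(int), horizon)
    best = max(surv, key=lambda g: (surv[g], -g))
    worst = min(surv, key=lambda g: (surv[g], g))
    return best, worst


def group_de_gsea(expr: ExpressionMatrix, groups: PatientGroups, clin: pd.DataFrame,
                  db: PathwayDB, cap_years: float = 3.0, n_perm: int = 1000,
                  seed: int = 0) -> tuple[RankedGeneList, EnrichmentResult]:
    """One-tailed Mann-Whitney DE (greater in the best-surviving group) + GSEA.

    All patients of the two extreme groups enter the test; genes are ranked
    by ascending one-tailed p and the ranking feeds pre-ranked GSEA.
    Zero-variance genes receive p = 1.
    """
    best, worst = best_worst_groups(groups, clin, cap_years)
    a = expr.values[groups.members(best)].to_numpy(float)
    b = expr.values[groups.members(worst)].to_numpy(float)
    p = np.ones(a.shape[0])
    varying = (np.concatenate([a, b], axis=1).std(axis=1) > 0)
    if varying.any():
        res = stats.mannwhitneyu(a[varying], b[varying], alternative="greater", axis=1)
        p[varying] = res.pvalue
    tab = pd.DataFrame({"gene": expr.gene_ids, "p": p})
    tab["stat"] = -np.log10(np.clip(tab["p"], 1e-300, None))
    tab = tab.sort_values(["p", "gene"], kind="stable").reset_index(drop=True)
    ranking = RankedGeneList(tab, direction="up_in_best_group")
    enrich = preranked_gsea(ranking, db, n_perm=n_perm, seed=seed)
    return ranking, enrich
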