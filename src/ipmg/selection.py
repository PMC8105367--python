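"""Pathway/gene prioritization and the survival-status classifier.

Pathways scored per patient by ssGSEA are ranked with a random survival
forest (log-rank splitting); feature relevance is permutation importance
(concordance drop) with an Altmann-style p-value from response-permuted
refits. Pathways surviving both correction branches are intersected, their
member genes filtered by the immunotherapy survival screen, and the
resulting candidate marker panel feeds an elastic-net logistic regression
of 1-year survival status, trained on SMOTE-balanced data and evaluated on
many balanced validation subsets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sksurv.ensemble import RandomSurvivalForest
from sksurv.util import Surv

from .io import ExpressionMatrix, PathwayDB
from .survival import DAYS_PER_YEAR, RankedGeneList, cap_survival

logger = logging.getLogger("ipmg")


# ---------------------------------------------------------------------------
# labels

def one_year_labels(clin: pd.DataFrame, days: float = 365.0) -> pd.Series:
    """1-year survival status: 1 deceased within a year, 0 alive at a year.

    Patients censored before one year carry no label and are excluded.
    """
    deceased = (clin["event"] == 1) & (clin["time_days"] <= days)
    alive = clin["time_days"] >= days
    labeled = clin[deceased | alive]
    return pd.Series(deceased[labeled.index].astype(int).to_numpy(),
                     index=labeled["sample_id"], name="deceased_1y")


# ---------------------------------------------------------------------------
# random survival forest importance

@dataclass
class ImportanceRanking:
    """Permutation importance per feature with response-permutation p-values."""

    table: pd.DataFrame  # feature, importance, p, selected — sorted by importance desc


def _fit_rsf(X: np.ndarray, y, n_trees: int, seed: int) -> RandomSurvivalForest:
    rsf = RandomSurvivalForest(
        n_estimators=n_trees, max_features="sqrt", min_samples_leaf=3,
        random_state=seed, n_jobs=1,
    )
    rsf.fit(X, y)
    return rsf


def _perm_importance(model, X: np.ndarray, y, rng: np.random.Generator,
                     n_repeats: int = 2) -> np.ndarray:
    base = model.score(X, y)
    imp = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        drops = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops.append(base - model.score(Xp, y))
        imp[j] = float(np.mean(drops))
    return imp


def rsf_rank(features: pd.DataFrame, clin: pd.DataFrame, cap_years: float = 1.0,
             n_null: int = 100, n_trees: int = 1000, alpha: float = 0.05,
             n_repeats: int = 2, seed: int = 0) -> ImportanceRanking:
    """Rank features by random-survival-forest permutation importance.

    ``features`` is features x patients (ssGSEA scores or gene expression).
    Survival is capped at ``cap_years``; the forest uses log-rank splitting.
    Each feature's p-value is (1 + #{null importance >= observed}) /
    (1 + n_null), the null importances coming from refits on
    response-permuted data; selected iff p < alpha.
    """
    if features.shape[0] < 2:
        raise ValueError("need >= 2 features")
    common = [s for s in features.columns if s in set(clin["sample_id"])]
    if len(common) < 20:
        raise ValueError("need >= 20 patients with features and survival")
    sub = cap_survival(clin.set_index("sample_id").loc[common].reset_index(), cap_years)
    if sub["event"].sum() < 3:
        raise ValueError("need >= 3 events after the cap")

    X = features[common].to_numpy(float).T
    y = Surv.from_arrays(sub["event"].astype(bool), sub["time_days"].astype(float))
    rng = np.random.default_rng(seed)

    model = _fit_rsf(X, y, n_trees, seed)
    imp = _perm_importance(model, X, y, rng, n_repeats=n_repeats)

    null_max = np.zeros((n_null, X.shape[1]))
    for b in range(n_null):
        perm = rng.permutation(len(y))
        y_perm = y[perm]
        m = _fit_rsf(X, y_perm, n_trees, seed + 1 + b)
        null_max[b] = _perm_importance(m, X, y_perm, rng, n_repeats=n_repeats)
    p = (1.0 + (null_max >= imp[None, :]).sum(axis=0)) / (1.0 + n_null)

    tab = pd.DataFrame({"feature": features.index, "importance": imp, "p": p})
    tab["selected"] = tab["p"] < alpha
    tab = tab.sort_values("importance", ascending=False, kind="stable").reset_index(drop=True)
    return ImportanceRanking(tab)


# ---------------------------------------------------------------------------
# intersection and candidate gene picking

def intersect_and_pick_genes(sel_mut: ImportanceRanking, sel_frac: ImportanceRanking,
                             rankings: dict[str, RankedGeneList], db: PathwayDB,
                             gene_p: float = 0.05, keep_top: int = 1) -> pd.DataFrame:
    """Candidate marker genes from pathways selected under both corrections.

    A pathway must be selected in the mutation-corrected AND the
    fraction-corrected branch; candidate genes are members of those pathways
    whose immunotherapy survival-screen p is below ``gene_p`` under either
    correction's ranking. Returns a frame with gene, pathway and the best p,
    ordered by that p (ascending). ``keep_top`` guarantees each branch
    contributes at least its top-ranked pathways by importance, so a noisy
    importance p-value cannot empty the intersection on its own.
    """
    chosen_mut = set(sel_mut.table.loc[sel_mut.table["selected"], "feature"])
    chosen_frac = set(sel_frac.table.loc[sel_frac.table["selected"], "feature"])
    chosen_mut |= set(sel_mut.table["feature"].head(keep_top))
    chosen_frac |= set(sel_frac.table["feature"].head(keep_top))
    shared = sorted(chosen_mut & chosen_frac)
    if not shared:
        logger.warning("intersect_and_pick_genes: no pathway selected under both corrections")
        return pd.DataFrame(columns=["gene", "pathway", "p"])

    pmaps = [rk.table.set_index("gene")["p"] for rk in rankings.values()]
    rows = []
    for pw in shared:
        for g in db.sets.get(pw, []):
            ps = [float(pm[g]) for pm in pmaps if g in pm.index]
            if ps and min(ps) < gene_p:
                rows.append((g, pw, min(ps)))
    out = pd.DataFrame(rows, columns=["gene", "pathway", "p"])
    out = out.sort_values(["p", "gene"], kind="stable").drop_duplicates("gene")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# SMOTE

def smote_oversample(X: np.ndarray, y: np.ndarray, k: int = 5,
                     seed: int | np.random.Generator = 0) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by synthesizing minority points between neighbors.

    Each synthetic point is x + u (x_nn - x) with u ~ U(0, 1), x a minority
    sample and x_nn one of its k nearest minority neighbors, so synthetic
    points lie on segments within the minority class. Already balanced
    input is returned unchanged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    counts = pd.Series(y).value_counts()
    if len(counts) != 2:
        raise ValueError("SMOTE requires exactly two classes")
    minority = counts.idxmin()
    n_needed = int(counts.max() - counts.min())
    if n_needed == 0:
        return X, y
    Xm = X[y == minority]
    if len(Xm) < 2:
        raise ValueError("minority class of 1 has no neighbor to interpolate with")
    k_eff = min(k, len(Xm) - 1)
    d2 = ((Xm[:, None, :] - Xm[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1)[:, :k_eff]

    base = rng.integers(0, len(Xm), size=n_needed)
    pick = nn[base, rng.integers(0, k_eff, size=n_needed)]
    u = rng.random((n_needed, 1))
    synth = Xm[base] + u * (Xm[pick] - Xm[base])
    return np.vstack([X, synth]), np.concatenate([y, np.full(n_needed, minority)])


# ---------------------------------------------------------------------------
# elastic-net classifier

@dataclass
class ModelMetrics:
    """Mean performance over the balanced validation subsets."""

    panel_size: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    n_validation_sets: int


def _fit_elastic_net(X: np.ndarray, y: np.ndarray, seed: int, cv: int = 5,
                     l1_ratio: float = 0.5) -> LogisticRegression:
    """Elastic-net logistic regression with the penalty chosen by CV AUC."""
    Cs = np.logspace(-2, 2, 7)
    best_C, best_auc = Cs[0], -np.inf
    n_splits = min(cv, int(np.bincount(y).min()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if n_splits >= 2:
            skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
            for C in Cs:
                aucs = []
                for tr, te in skf.split(X, y):
                    m = LogisticRegression(solver="saga", l1_ratio=l1_ratio, C=C,
                                           max_iter=2000)
                    m.fit(X[tr], y[tr])
                    score = m.decision_function(X[te])
                    if len(np.unique(y[te])) == 2:
                        aucs.append(roc_auc_score(y[te], score))
                mean_auc = np.mean(aucs) if aucs else -np.inf
                if mean_auc > best_auc:
                    best_auc, best_C = mean_auc, C
        model = LogisticRegression(solver="saga", l1_ratio=l1_ratio, C=best_C,
                                   max_iter=5000)
        model.fit(X, y)
    return model


def transfer_eval(train_expr: ExpressionMatrix, train_clin: pd.DataFrame,
                  test_expr: ExpressionMatrix, test_clin: pd.DataFrame,
                  gene_panel: list[str], n_val: int = 1000, seed: int = 0,
                  label_days: float = DAYS_PER_YEAR) -> ModelMetrics:
    """Train on one cohort, evaluate on an independent external cohort.

    The model is fit on the full labeled training cohort (SMOTE-balanced,
    per-feature standardization learned on training data) and evaluated on
    the external cohort's balanced validation subsets, exactly as in
    :func:`train_eval_elastic_net`.
    """
    rng = np.random.default_rng(seed)
    panel = [g for g in gene_panel
             if g in train_expr.gene_ids and g in test_expr.gene_ids]
    if len(panel) < 2:
        raise ValueError("panel shares < 2 genes between cohorts")

    def _xy(expr, clin):
        labels = one_year_labels(clin, days=label_days)
        samples = [s for s in labels.index if s in set(expr.sample_ids)]
        X = expr.values.loc[panel, samples].to_numpy(float).T
        return X, labels[samples].to_numpy()

    X_tr, y_tr = _xy(train_expr, train_clin)
    X_te, y_te = _xy(test_expr, test_clin)
    mu, sd = X_tr.mean(0), np.where(X_tr.std(0) > 0, X_tr.std(0), 1.0)
    X_bal, y_bal = smote_oversample((X_tr - mu) / sd, y_tr, seed=rng)
    model = _fit_elastic_net(X_bal, y_bal, seed=seed)

    X_te = (X_te - mu) / sd
    score = model.decision_function(X_te)
    pred = (score > 0).astype(int)
    dec = np.flatnonzero(y_te == 1)
    alive = np.flatnonzero(y_te == 0)
    if len(dec) < 1 or len(alive) < 1:
        raise ValueError("external cohort lacks both outcome classes")
    accs, sens, specs, aucs = [], [], [], []
    for _ in range(n_val):
        draw = rng.choice(alive, size=len(dec), replace=len(alive) < len(dec))
        idx = np.concatenate([dec, draw])
        accs.append((pred[idx] == y_te[idx]).mean())
        sens.append(pred[dec].mean())
        specs.append(1.0 - pred[draw].mean())
        aucs.append(roc_auc_score(y_te[idx], score[idx]))
    return ModelMetrics(len(panel), float(np.mean(accs)), float(np.mean(sens)),
                        float(np.mean(specs)), float(np.mean(aucs)), n_val)


def train_eval_elastic_net(expr: ExpressionMatrix, clin: pd.DataFrame,
                           gene_panel: list[str],
                           panel_sizes: tuple[int, ...] = (64, 50, 40, 30, 20, 10),
                           n_val: int = 1000, seed: int = 0,
                           label_days: float = DAYS_PER_YEAR) -> list[ModelMetrics]:
    """Train and evaluate the 1-year survival-status classifier per panel size.

    The labeled cohort splits 2/3 train : 1/3 validation (stratified);
    training data is SMOTE-balanced; evaluation draws ``n_val`` balanced
    validation subsets (all deceased plus an equal-size random draw of
    alive) and averages accuracy, sensitivity, specificity and AUC.
    """
    labels = one_year_labels(clin, days=label_days)
    samples = [s for s in labels.index if s in set(expr.sample_ids)]
    labels = labels[samples]
    rng = np.random.default_rng(seed)

    results = []
    for size in panel_sizes:
        panel = [g for g in gene_panel[:size] if g in expr.gene_ids]
        if len(panel) < 2:
            logger.warning("train_eval_elastic_net: panel size %d has < 2 usable genes", size)
            continue
        X = expr.values.loc[panel, samples].to_numpy(float).T
        y = labels.to_numpy()
        X_tr, X_va, y_tr, y_va = train_test_split(
            X, y, test_size=1 / 3, stratify=y, random_state=seed)
        if int(y_va.sum()) < 2:
            raise ValueError("fewer than 2 deceased patients in the validation split")
        mu, sd = X_tr.mean(0), np.where(X_tr.std(0) > 0, X_tr.std(0), 1.0)
        X_tr = (X_tr - mu) / sd
        X_va = (X_va - mu) / sd
        X_bal, y_bal = smote_oversample(X_tr, y_tr, seed=rng)
        model = _fit_elastic_net(X_bal, y_bal, seed=seed)

        dec_idx = np.flatnonzero(y_va == 1)
        alive_idx = np.flatnonzero(y_va == 0)
        accs, sens, specs, aucs = [], [], [], []
        score_all = model.decision_function(X_va)
        pred_all = (score_all > 0).astype(int)
        for _ in range(n_val):
            draw = rng.choice(alive_idx, size=len(dec_idx),
                              replace=len(alive_idx) < len(dec_idx))
            idx = np.concatenate([dec_idx, draw])
            yy, pp, ss = y_va[idx], pred_all[idx], score_all[idx]
            accs.append((pp == yy).mean())
            sens.append(pp[yy == 1].mean())
            specs.append(1.0 - pp[yy == 0].mean())
            aucs.append(roc_auc_score(yy, ss))
        results.append(ModelMetrics(
            panel_size=size,
            accuracy=float(np.mean(accs)),
            sensitivity=float(np.mean(sens)),
            specificity=float(np.mean(specs)),
            auc=float(np.mean(aucs)),
            n_validation_sets=n_val,
        ))
    return results
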