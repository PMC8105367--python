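"""Feature selection and the survival-status classifier: 1-year labels,
SMOTE, candidate-gene intersection, and elastic-net behavior."""

import numpy as np
import pandas as pd
import pytest

from ipmg import selection
from ipmg.io import ExpressionMatrix, PathwayDB
from ipmg.survival import RankedGeneList


def test_one_year_labels_rule():
    clin = pd.DataFrame({
        "sample_id": ["a", "b", "c", "d"],
        "cancer_type": ["T"] * 4,
        "treatment_class": ["immunotherapy"] * 4,
        "time_days": [100.0, 400.0, 200.0, 365.0],
        "event": [1, 1, 0, 0],
    })
    labels = selection.one_year_labels(clin)
    assert labels.to_dict() == {"a": 1, "b": 0, "d": 0}  # c censored early: excluded


def test_smote_points_lie_on_minority_segments():
    rng = np.random.default_rng(0)
    Xmin = rng.normal(size=(6, 3))
    Xmaj = rng.normal(5, 1, size=(20, 3))
    X = np.vstack([Xmin, Xmaj])
    y = np.array([1] * 6 + [0] * 20)
    Xb, yb = selection.smote_oversample(X, y, k=3, seed=1)
    assert (yb == 1).sum() == (yb == 0).sum() == 20
    synth = Xb[len(X):]
    for s in synth:
        on_segment = False
        for i in range(len(Xmin)):
            for j in range(len(Xmin)):
                if i == j:
                    continue
                d = Xmin[j] - Xmin[i]
                t = np.dot(s - Xmin[i], d) / np.dot(d, d)
                if -1e-9 <= t <= 1 + 1e-9 and \
                        np.linalg.norm(s - (Xmin[i] + t * d)) < 1e-9:
                    on_segment = True
        assert on_segment


def test_smote_1d_convexity_and_balance():
    X = np.array([[0.0], [1.0], [5.0], [5.1], [5.2], [4.9]])
    y = np.array([1, 1, 0, 0, 0, 0])
    Xb, yb = selection.smote_oversample(X, y, k=1, seed=0)
    synth = Xb[len(X):][yb[len(X):] == 1]
    assert ((synth >= 0.0) & (synth <= 1.0)).all()


def test_smote_balanced_input_unchanged_and_determinism():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(10, 2))
    y = np.array([0] * 5 + [1] * 5)
    Xb, yb = selection.smote_oversample(X, y, seed=9)
    assert Xb.shape == X.shape and (yb == y).all()
    y2 = np.array([0] * 7 + [1] * 3)
    a = selection.smote_oversample(X, y2, seed=9)
    b = selection.smote_oversample(X, y2, seed=9)
    assert np.array_equal(a[0], b[0])


def test_smote_minority_of_one_is_error():
    X = np.zeros((4, 2))
    y = np.array([0, 0, 0, 1])
    with pytest.raises(ValueError, match="minority"):
        selection.smote_oversample(X, y)


def _importance(features, selected):
    tab = pd.DataFrame({"feature": features,
                        "importance": np.linspace(1, 0, len(features)),
                        "p": [0.01 if s else 0.5 for s in selected]})
    tab["selected"] = tab["p"] < 0.05
    return selection.ImportanceRanking(tab)


def _ranking(pmap):
    tab = pd.DataFrame({"gene": list(pmap), "p": list(pmap.values())})
    tab["stat"] = -np.log10(tab["p"])
    return RankedGeneList(tab.sort_values("p"), "high_better")


def test_intersection_requires_both_corrections():
    db = PathwayDB({"P1": ["g1", "g2"], "P2": ["g3", "g4"]})
    rankings = {"mutation": _ranking({"g1": 0.04, "g2": 0.5, "g3": 0.01, "g4": 0.2}),
                "fraction": _ranking({"g1": 0.5, "g2": 0.5, "g3": 0.5, "g4": 0.5})}
    sel_mut = _importance(["P1", "P2"], [True, True])
    sel_frac = _importance(["P1", "P2"], [True, False])
    out = selection.intersect_and_pick_genes(sel_mut, sel_frac, rankings, db,
                                             keep_top=0)
    # P2 selected under one correction only -> excluded; g1 passes via mutation ranking
    assert list(out["gene"]) == ["g1"]
    assert out["p"].iloc[0] == pytest.approx(0.04)


def test_intersection_empty_when_nothing_shared():
    db = PathwayDB({"P1": ["g1"], "P2": ["g2"]})
    rankings = {"mutation": _ranking({"g1": 0.01, "g2": 0.01})}
    out = selection.intersect_and_pick_genes(
        _importance(["P1", "P2"], [True, False]),
        _importance(["P1", "P2"], [False, True]),
        rankings, db, keep_top=0)
    assert out.empty


def test_keep_top_floor_rescues_top_ranked_pathway():
    db = PathwayDB({"P1": ["g1", "g2"]})
    rankings = {"mutation": _ranking({"g1": 0.01, "g2": 0.6})}
    out = selection.intersect_and_pick_genes(
        _importance(["P1"], [False]), _importance(["P1"], [False]),
        rankings, db, keep_top=1)
    assert list(out["gene"]) == ["g1"]


def test_elastic_net_separable_toy_reaches_perfect_auc():
    rng = np.random.default_rng(0)
    n = 90
    x = np.concatenate([rng.uniform(0, 1, n // 3), rng.uniform(3, 4, n - n // 3)])
    genes = ["gA", "gB"]
    vals = pd.DataFrame([x, rng.normal(size=n)], index=genes,
                        columns=[f"s{i}" for i in range(n)])
    clin = pd.DataFrame({
        "sample_id": vals.columns,
        "cancer_type": ["T"] * n,
        "treatment_class": ["immunotherapy"] * n,
        "time_days": np.where(x < 2, 100.0, 400.0),
        "event": np.where(x < 2, 1, 0),
    })
    metrics = selection.train_eval_elastic_net(
        ExpressionMatrix(vals), clin, genes, panel_sizes=(2,), n_val=50, seed=0)
    assert metrics[0].auc == pytest.approx(1.0)
    assert metrics[0].accuracy > 0.95


def test_rsf_recovers_strongly_informative_feature(small_cohort, small_norm):
    clin = small_cohort.clinical
    immuno = clin[clin["treatment_class"] == "immunotherapy"]
    rng = np.random.default_rng(0)
    spec_genes = [g for g, c in small_cohort.truth.gene_class.items()
                  if c == "immuno_specific" and g in small_norm.gene_ids]
    signal = small_norm.values.loc[spec_genes, list(immuno["sample_id"])].mean(axis=0)
    feats = pd.DataFrame(
        rng.normal(size=(6, len(signal))), columns=signal.index,
        index=[f"noise{i}" for i in range(6)])
    feats.loc["signal"] = signal.to_numpy()
    rk = selection.rsf_rank(feats, immuno, n_null=19, n_trees=100, seed=0)
    assert rk.table.iloc[0]["feature"] == "signal"


def test_rsf_validates_inputs(small_cohort):
    clin = small_cohort.clinical.head(30)
    feats = pd.DataFrame(np.zeros((1, 30)), columns=clin["sample_id"])
    with pytest.raises(ValueError, match="2 features"):
        selection.rsf_rank(feats, clin)


def test_transfer_to_independent_cohort_retains_signal(small_cohort, small_norm):
    """A panel trained on one cohort stays predictive on an independently
    seeded cohort drawn from a shifted distribution."""
    from conftest import small_spec
    from ipmg import preprocess
    from ipmg.cohort import generate_cohort

    ext = generate_cohort(small_spec(seed=77, baseline_median_years=1.2))
    m = preprocess.impute_by_cancer_type(ext.expression, ext.clinical)
    ext_norm = preprocess.log2_quantile_normalize(preprocess.filter_low_expression(m))
    panel = [g for g, c in small_cohort.truth.gene_class.items()
             if c in ("immuno_specific", "general_prognostic")]
    tr = small_cohort.clinical
    te = ext.clinical[ext.clinical["treatment_class"] == "immunotherapy"]
    metrics = selection.transfer_eval(
        small_norm, tr[tr["treatment_class"] == "immunotherapy"],
        ext_norm, te, panel, n_val=100, seed=0)
    assert metrics.auc > 0.6  # transfers above chance on the external cohort
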