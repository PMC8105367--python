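"""Enrichment machinery: running-sum ES vs brute-force oracle, Monte-Carlo
p-values, ssGSEA invariances, and the QQ construction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ipmg.gsea import (
    QQSeries,
    build_qq,
    enrichment_score,
    preranked_gsea,
    ssgsea_score,
)
from ipmg.io import ExpressionMatrix, PathwayDB
from ipmg.survival import RankedGeneList


def brute_force_es(stats_ordered, hit_positions, weight=1.0):
    """Step through the running sum one gene at a time."""
    N = len(stats_ordered)
    hits = set(int(p) for p in hit_positions)
    K = len(hits)
    w = {p: abs(stats_ordered[p]) ** weight for p in hits}
    W = sum(w.values())
    if W == 0:
        w = {p: 1.0 for p in hits}
        W = float(K)
    run, hi, lo = 0.0, 0.0, 0.0
    for i in range(N):
        run += w[i] / W if i in hits else -1.0 / (N - K)
        hi = max(hi, run)
        lo = min(lo, run)
    # ties in magnitude resolve to the positive deviation (package convention)
    return hi if hi >= -lo else lo


def test_es_matches_brute_force_exhaustively():
    rng = np.random.default_rng(5)
    for N in range(3, 11):
        for stats_vec in (np.sort(rng.exponential(1, N))[::-1],
                          np.sort(rng.uniform(0, 3, N))[::-1]):
            for k in range(1, min(4, N - 1) + 1):
                for pos in itertools.combinations(range(N), k):
                    got = enrichment_score(stats_vec, np.array(pos))
                    want = brute_force_es(stats_vec, pos)
                    same = abs(got - want) < 1e-12
                    # a near-exact magnitude tie may resolve to opposite signs
                    # depending on float summation order; magnitudes must agree
                    tied = abs(got + want) < 1e-9 and abs(abs(got) - abs(want)) < 1e-12
                    assert same or tied, (N, pos, got, want)


def test_es_top_block_unweighted_is_one():
    stats_vec = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
    assert enrichment_score(stats_vec, [0, 1], weight=0.0) == pytest.approx(1.0)


def test_es_symmetry_between_top_and_bottom_sets():
    stats_vec = np.linspace(3, -3, 8)
    top = enrichment_score(np.abs(stats_vec), [0, 1], weight=0.0)
    bottom = enrichment_score(np.abs(stats_vec), [6, 7], weight=0.0)
    assert top == pytest.approx(-bottom)


def _ranking(stats_vec, genes=None):
    genes = genes or [f"g{i}" for i in range(len(stats_vec))]
    tab = pd.DataFrame({"gene": genes, "p": 10.0 ** (-np.asarray(stats_vec)),
                        "stat": stats_vec})
    return RankedGeneList(tab, "high_better")


def test_preranked_gsea_p_in_open_unit_interval_and_shares_null():
    rng = np.random.default_rng(0)
    ranking = _ranking(np.sort(rng.exponential(1, 100))[::-1])
    db = PathwayDB({"A": [f"g{i}" for i in range(5)],
                    "B": [f"g{i}" for i in range(50, 55)],
                    "tiny": ["g1", "g2"]})
    res = preranked_gsea(ranking, db, n_perm=200, seed=1)
    assert set(res.table["pathway"]) == {"A", "B"}  # tiny skipped
    assert ((res.table["p"] > 0) & (res.table["p"] <= 1)).all()
    assert res.table.set_index("pathway").loc["A", "p"] < \
        res.table.set_index("pathway").loc["B", "p"]


def test_preranked_null_p_uniform():
    rng = np.random.default_rng(9)
    ps = []
    for _ in range(200):
        stats_vec = np.sort(rng.exponential(1, 60))[::-1]
        genes = [f"g{i}" for i in range(60)]
        members = list(rng.choice(genes, size=5, replace=False))
        res = preranked_gsea(_ranking(stats_vec, genes), PathwayDB({"S": members}),
                             n_perm=500, seed=rng)
        ps.append(float(res.table["p"].iloc[0]))
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_ssgsea_invariant_to_monotone_transform():
    rng = np.random.default_rng(2)
    X = pd.DataFrame(rng.uniform(1, 9, size=(30, 4)),
                     index=[f"g{i}" for i in range(30)],
                     columns=list("abcd"))
    gene_set = {f"g{i}" for i in range(5)}
    base = ssgsea_score(ExpressionMatrix(X), gene_set)
    warped = ssgsea_score(ExpressionMatrix(np.exp(X / 3.0)), gene_set)
    pd.testing.assert_series_equal(base, warped, atol=1e-12)


def test_ssgsea_top_set_beats_bottom_set():
    vals = pd.DataFrame({"s": np.arange(20.0, 0.0, -1.0)},
                        index=[f"g{i}" for i in range(20)])
    m = ExpressionMatrix(vals)
    top = ssgsea_score(m, {"g0", "g1", "g2"})["s"]
    bottom = ssgsea_score(m, {"g17", "g18", "g19"})["s"]
    assert top > bottom


def test_ssgsea_identical_rank_order_identical_scores():
    vals = pd.DataFrame({"a": [9.0, 5.0, 1.0], "b": [100.0, 50.0, 10.0]},
                        index=["g0", "g1", "g2"])
    s = ssgsea_score(ExpressionMatrix(vals), {"g0"})
    assert s["a"] == pytest.approx(s["b"])


def test_ssgsea_hand_enumerated_three_gene_case():
    # one sample, genes ranked g0 > g1 > g2, set = {g0}, alpha = 0
    vals = pd.DataFrame({"s": [3.0, 2.0, 1.0]}, index=["g0", "g1", "g2"])
    s = ssgsea_score(ExpressionMatrix(vals), {"g0"}, alpha=0.0)["s"]
    # running terms: (1 - 0) + (1 - 1/2) + (1 - 1) = 1.5
    assert s == pytest.approx(1.5)


def test_ssgsea_full_universe_set_rejected():
    vals = pd.DataFrame({"s": [1.0, 2.0]}, index=["g0", "g1"])
    with pytest.raises(ValueError):
        ssgsea_score(ExpressionMatrix(vals), {"g0", "g1"})


def test_build_qq_null_pathway_tracks_genome_control():
    rng = np.random.default_rng(4)
    genes = [f"g{i}" for i in range(200)]
    ranking = _ranking(-np.log10(np.sort(rng.uniform(size=200))), genes)
    nulls = [_ranking(-np.log10(np.sort(rng.uniform(size=200))), genes)
             for _ in range(50)]
    pathway = list(rng.choice(genes, size=20, replace=False))
    qq = build_qq(ranking, nulls, pathway, n_draws=200, seed=1)
    assert isinstance(qq, QQSeries)
    assert len(qq.observed) == len(qq.genome_control) == 20
    assert (np.diff(qq.observed) >= 0).all()
    # random pathway: roughly half the positions below the 95th-quantile control
    assert 0.3 < qq.frac_below_genome <= 1.0


def test_build_qq_validates_draw_count_and_size():
    ranking = _ranking(np.arange(10.0, 0.0, -1.0))
    with pytest.raises(ValueError, match="n_draws"):
        build_qq(ranking, [], ["g0", "g1", "g2"], n_draws=1)
    with pytest.raises(ValueError, match="3 genes"):
        build_qq(ranking, [], ["g0"], n_draws=10)
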