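"""Pre-ranked GSEA, single-sample GSEA, and the immunotherapy-specificity test.

Pre-ranked GSEA scores a pathway against a ranked gene list with the
weighted Kolmogorov-Smirnov running sum (hits add |stat|^w / sum, misses
subtract 1/(N-K)); significance comes from random same-size gene sets. The
specificity test asks whether a pathway's enrichment in the
immunotherapy-treated cohort exceeds what equally sized random cohorts of
non-immunotherapy patients produce: B cohort resamples each rerun the
genome survival screen and GSEA, and a pathway is specific when its observed
p falls below the 5th percentile of its own B-sized null. A quantile-
quantile construction compares the pathway's gene-level p-values against
size-matched random gene draws and against the non-immunotherapy resamples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .io import ExpressionMatrix, PathwayDB
from .survival import RankedGeneList, SurvivalSpec, screen_genome

logger = logging.getLogger("ipmg")

MIN_SET_SIZE = 3


# ---------------------------------------------------------------------------
# enrichment score

def enrichment_score(stats_ordered: np.ndarray, hit_positions: np.ndarray,
                     weight: float = 1.0) -> float:
    """Signed ES of one gene set on one ranking (genes in rank order).

    ``hit_positions`` are 0-based positions of the set members in the
    ranking. The running sum increments by |stat|^weight / (total hit
    weight) at hits and decrements by 1/(N-K) at misses; the ES is the
    deviation of maximum magnitude (a tie resolves to the positive side).
    """
    pos = np.sort(np.asarray(hit_positions, dtype=np.int64))[None, :]
    return float(_es_batch(np.asarray(stats_ordered, float), pos, weight)[0])


def _es_batch(stats_ordered: np.ndarray, pos: np.ndarray, weight: float) -> np.ndarray:
    """ES for many same-size sets at once; ``pos`` is (R, K) sorted ascending."""
    N = len(stats_ordered)
    R, K = pos.shape
    if not (0 < K < N):
        raise ValueError("set size must be in (0, N)")
    w_all = np.abs(stats_ordered) ** weight
    w = w_all[pos]
    W = w.sum(axis=1, keepdims=True)
    uniform = (W[:, 0] == 0)
    if uniform.any():  # all hit stats zero: fall back to unweighted hits
        w[uniform] = 1.0
        W = w.sum(axis=1, keepdims=True)
    cw = np.cumsum(w, axis=1) / W
    miss = 1.0 / (N - K)
    i = np.arange(K)[None, :]
    misses_before = (pos - i) * miss
    after = cw - misses_before            # running sum just after each hit
    before = cw - w / W - misses_before   # just before each hit
    max_pos = after.max(axis=1)
    min_neg = np.minimum(before.min(axis=1), 0.0)
    return np.where(max_pos >= -min_neg, max_pos, min_neg)


def _null_positions(rng: np.random.Generator, n_perm: int, N: int, K: int) -> np.ndarray:
    """(n_perm, K) sorted random hit positions (sampling without replacement)."""
    u = rng.random((n_perm, N))
    part = np.argpartition(u, K, axis=1)[:, :K]
    return np.sort(part, axis=1)


@dataclass
class EnrichmentResult:
    """Per-pathway enrichment on one ranking."""

    table: pd.DataFrame  # columns pathway, size, es, p
    direction: str


def preranked_gsea(ranking: RankedGeneList, db: PathwayDB, n_perm: int = 1000,
                   weight: float = 1.0, seed: int | np.random.Generator = 0
                   ) -> EnrichmentResult:
    """Weighted running-sum GSEA with gene-permutation p-values.

    p = (1 + #{null ES >= observed ES}) / (1 + n_perm), from random gene
    sets of the pathway's effective size; the null for each size is built
    once and shared by all pathways of that size. Pathways intersecting the
    ranking in fewer than 3 genes are skipped with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = ranking.table["gene"].to_numpy()
    stats_ordered = ranking.table["stat"].to_numpy(float)
    pos_of = {g: i for i, g in enumerate(order)}
    N = len(order)

    sizes_needed: dict[int, list[str]] = {}
    hit_pos: dict[str, np.ndarray] = {}
    for name, genes in db.sets.items():
        pos = np.sort([pos_of[g] for g in genes if g in pos_of])
        if len(pos) < MIN_SET_SIZE:
            logger.warning("preranked_gsea: pathway %s intersects ranking in %d genes; skipped",
                           name, len(pos))
            continue
        hit_pos[name] = pos
        sizes_needed.setdefault(len(pos), []).append(name)

    null_es: dict[int, np.ndarray] = {
        K: _es_batch(stats_ordered, _null_positions(rng, n_perm, N, K), weight)
        for K in sizes_needed
    }
    rows = []
    for name, pos in hit_pos.items():
        es = float(_es_batch(stats_ordered, pos[None, :], weight)[0])
        null = null_es[len(pos)]
        p = (1.0 + np.count_nonzero(null >= es)) / (1.0 + n_perm)
        # continuous normal-tail approximation; resolves ties below the
        # Monte-Carlo floor when p-values from different rankings are compared
        sd = float(null.std())
        z = (es - float(null.mean())) / sd if sd > 0 else 0.0
        p_norm = float(sp_stats.norm.sf(z))
        rows.append((name, len(pos), es, p, p_norm))
    table = pd.DataFrame(rows, columns=["pathway", "size", "es", "p", "p_norm"])
    return EnrichmentResult(table, ranking.direction)


# ---------------------------------------------------------------------------
# single-sample GSEA

def ssgsea_score(expr: ExpressionMatrix, gene_set: set[str] | list[str],
                 alpha: float = 0.25, normalize: bool = False) -> pd.Series:
    """Barbie-style single-sample enrichment score per patient.

    Genes are ranked per sample by expression (descending; ties broken by
    gene id); the score is the sum over ranks of the difference between the
    rank^alpha-weighted in-set ECDF and the uniform out-set ECDF. The score
    depends on ranks only, so any strictly monotone transform of a sample's
    expression leaves it unchanged.
    """
    vals = expr.values.sort_index()  # rows in gene-id order so stable sorts tie-break by id
    genes = vals.index
    in_set = np.asarray(genes.isin(list(gene_set)), dtype=float)
    K = int(in_set.sum())
    if K == 0:
        raise ValueError("gene set does not intersect the expression table")
    if K == len(genes):
        raise ValueError("gene set covers all genes; out-set ECDF undefined")

    X = vals.to_numpy(float)
    N = len(genes)
    order = np.argsort(-X, axis=0, kind="stable")
    hits = in_set[order]  # (N, S)
    ranks = (N - np.arange(N, dtype=float))[:, None] ** alpha
    w = hits * ranks
    cum_in = np.cumsum(w, axis=0) / w.sum(axis=0, keepdims=True)
    cum_out = np.cumsum(1.0 - hits, axis=0) / float(N - K)
    scores = (cum_in - cum_out).sum(axis=0)
    if normalize:
        rng_span = scores.max() - scores.min()
        if rng_span > 0:
            scores = scores / rng_span
    return pd.Series(scores, index=expr.sample_ids, name="ssgsea")


def ssgsea_matrix(expr: ExpressionMatrix, db: PathwayDB, alpha: float = 0.25) -> pd.DataFrame:
    """Pathways x patients ssGSEA score grid."""
    rows = {}
    for name, genes in db.sets.items():
        inter = expr.gene_ids.intersection(genes)
        if len(inter) == 0 or len(inter) == len(expr.gene_ids):
            logger.warning("ssgsea_matrix: pathway %s skipped (degenerate intersection)", name)
            continue
        rows[name] = ssgsea_score(expr, set(genes), alpha=alpha)
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# immunotherapy-specificity permutation test

@dataclass
class SpecificityResult:
    """Observed vs resampled-cohort enrichment per pathway."""

    table: pd.DataFrame       # pathway, size, es, p_observed, null_p05, percentile, specific
    null_p: pd.DataFrame      # pathways x B null p-values
    n_resamples: int


def specificity_test(expr: ExpressionMatrix, clin: pd.DataFrame, db: PathwayDB,
                     spec: SurvivalSpec, B: int = 1000, n_perm_gsea: int = 200,
                     weight: float = 1.0, seed: int | np.random.Generator = 0
                     ) -> SpecificityResult:
    """Permutation test of pathway specificity to the immunotherapy cohort.

    The observed statistic is each pathway's GSEA p on the immunotherapy
    survival ranking. The null draws B equally sized cohorts of
    non-immunotherapy patients (without replacement), reruns the genome
    screen once per resample, and re-scores every pathway on that ranking.
    ``specific`` requires the observed p below the 5th percentile of the
    pathway's null p distribution.
    """
    if B < 20:
        raise ValueError("B < 20 makes the 5th-percentile cutoff meaningless")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    obs_ranking = screen_genome(expr, clin, spec)[_obs_direction(spec)]
    obs = preranked_gsea(obs_ranking, db, n_perm=n_perm_gsea, weight=weight, seed=rng)
    pathways = list(obs.table["pathway"])

    immuno_n = int((clin["treatment_class"] == "immunotherapy").sum())
    ctrl = clin[clin["treatment_class"] == "non_immunotherapy"]
    if len(ctrl) < immuno_n:
        raise ValueError("non-immunotherapy cohort smaller than immunotherapy cohort")
    ctrl_ids = ctrl["sample_id"].to_numpy()
    ctrl_spec = SurvivalSpec(cap_years=spec.cap_years, quantile=spec.quantile,
                             treatment_class="non_immunotherapy",
                             min_type_size=spec.min_type_size)

    null_p = np.ones((len(pathways), B))
    for b in range(B):
        draw = rng.choice(ctrl_ids, size=immuno_n, replace=False)
        sub = clin[clin["sample_id"].isin(draw)]
        sub_expr = expr.with_values(expr.values[list(sub["sample_id"])], expr.stage)
        ranking = screen_genome(sub_expr, sub, ctrl_spec)[_obs_direction(spec)]
        res = preranked_gsea(ranking, db, n_perm=n_perm_gsea, weight=weight, seed=rng)
        pmap = res.table.set_index("pathway")["p_norm"]
        null_p[:, b] = pmap.reindex(pathways).fillna(1.0).to_numpy()

    null_df = pd.DataFrame(null_p, index=pathways)
    tab = obs.table.rename(columns={"p": "p_observed"}).copy()
    obs_cmp = tab["p_norm"].to_numpy()
    tab["null_p05"] = np.quantile(null_p, 0.05, axis=1)
    tab["percentile"] = (null_p < obs_cmp[:, None]).mean(axis=1)
    tab["specific"] = obs_cmp < tab["null_p05"]
    return SpecificityResult(tab, null_df, B)


def _obs_direction(spec: SurvivalSpec) -> str:
    return getattr(spec, "direction", "high_better")


# ---------------------------------------------------------------------------
# quantile-quantile construction

@dataclass
class QQSeries:
    """Three sorted p-value series for one pathway.

    observed: the pathway genes' p on the immunotherapy ranking;
    genome_control: per-position 95th quantile of size-matched random gene
    draws from the same ranking; cohort_control: per-position 95th quantile
    of the pathway genes' p across the non-immunotherapy cohort resamples.
    """

    observed: np.ndarray
    genome_control: np.ndarray
    cohort_control: np.ndarray
    frac_below_genome: float
    frac_below_cohort: float


def build_qq(ranking_immuno: RankedGeneList, null_screens: list[RankedGeneList],
             pathway: set[str] | list[str], n_draws: int = 1000,
             seed: int | np.random.Generator = 0) -> QQSeries:
    """QQ comparison of a pathway's survival p-values against two controls."""
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2 for a quantile to be meaningful")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pmap = ranking_immuno.table.set_index("gene")["p"]
    genes = [g for g in pathway if g in pmap.index]
    if len(genes) < MIN_SET_SIZE:
        raise ValueError("pathway intersects the ranking in fewer than 3 genes")
    K = len(genes)

    observed = np.sort(pmap[genes].to_numpy(float))

    all_p = pmap.to_numpy(float)
    draws = np.sort(all_p[_null_positions(rng, n_draws, len(all_p), K)], axis=1)
    genome_control = np.quantile(draws, 0.95, axis=0)

    ctrl = np.ones((len(null_screens), K))
    for i, screen in enumerate(null_screens):
        cmap = screen.table.set_index("gene")["p"]
        ctrl[i] = np.sort(cmap.reindex(genes).fillna(1.0).to_numpy(float))
    cohort_control = np.quantile(ctrl, 0.95, axis=0)

    return QQSeries(
        observed=observed,
        genome_control=genome_control,
        cohort_control=cohort_control,
        frac_below_genome=float((observed <= genome_control).mean()),
        frac_below_cohort=float((observed <= cohort_control).mean()),
    )
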