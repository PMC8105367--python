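"""SNP association with 1-year survival status and with gene expression.

SNPs are restricted to the gene body ± a window (default 100 kb) of the
candidate genes and to minor allele frequency >= 5%. Association uses a
single-marker score test of the binary 1-year status on additive dosage;
per SNP, shuffling the genotype builds a null p distribution whose 5th
percentile is the significance cutoff (a SNP must beat both the nominal
0.05 and its own permutation cutoff). The expression step applies the same
logic to the Pearson correlation between dosage and the nearby candidate
gene's expression (eQTL rule: r > 0.2, p < 0.05, below the cutoff).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger("ipmg")


def filter_snps(geno: GenotypeMatrix, window_kb: float = 100.0,
                maf_min: float = 0.05) -> GenotypeMatrix:
    """Keep SNPs within gene body ± window of any listed gene and MAF >= maf_min."""
    w = window_kb * 1000.0
    snps = geno.snp_coords
    usable = geno.dosages.columns.intersection(snps.index)
    dropped_coords = geno.dosages.columns.difference(snps.index)
    if len(dropped_coords):
        logger.warning("filter_snps: %d SNPs without coordinates dropped", len(dropped_coords))

    keep = []
    genes = geno.gene_coords
    for snp in usable:
        chrom, pos = snps.loc[snp, "chrom"], snps.loc[snp, "start"]
        same = genes[genes["chrom"] == chrom]
        near = ((same["start"] - w <= pos) & (pos <= same["end"] + w)).any()
        if near:
            keep.append(snp)
    maf = geno.maf()
    keep = [s for s in keep if maf[s] >= maf_min]
    return GenotypeMatrix(geno.dosages[keep], snps.loc[keep], genes)


@dataclass
class SnpResult:
    """Per-SNP association with its permutation cutoff."""

    table: pd.DataFrame


def _score_test_p(g: np.ndarray, y: np.ndarray) -> float:
    """Score test of logistic regression of y on g (additive dosage)."""
    ybar = y.mean()
    gc = g - g.mean()
    denom = ybar * (1.0 - ybar) * (gc**2).sum()
    if denom <= 0:
        return 1.0
    U = float(gc @ (y - ybar))
    return float(stats.chi2.sf(U * U / denom, df=1))


def _score_test_p_batch(G: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized score test over columns of G."""
    ybar = y.mean()
    Gc = G - G.mean(axis=0, keepdims=True)
    denom = ybar * (1.0 - ybar) * (Gc**2).sum(axis=0)
    U = Gc.T @ (y - ybar)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, U * U / denom, 0.0)
    p = stats.chi2.sf(chi2, df=1)
    return np.where(denom > 0, p, 1.0)


def associate_snps(geno: GenotypeMatrix, labels: pd.Series, n_shuffle: int = 1000,
                   alpha: float = 0.05, seed: int | np.random.Generator = 0) -> SnpResult:
    """Score-test association of each SNP with 1-year status + permutation cutoff.

    ``labels``: sample_id -> {0 alive, 1 deceased}. Per SNP the genotype is
    shuffled ``n_shuffle`` times; the cutoff is the 5th percentile of the
    null p distribution, and significance requires p < alpha AND
    p < cutoff.
    """
    common = [s for s in geno.dosages.index if s in labels.index]
    y = labels[common].to_numpy(float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are constant; association undefined")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    G = geno.dosages.loc[common].to_numpy(float)

    rows = []
    for j, snp in enumerate(geno.dosages.columns):
        g = G[:, j]
        p_obs = _score_test_p(g, y)
        perms = np.argsort(rng.random((n_shuffle, len(g))), axis=1)
        null_p = _score_test_p_batch(g[perms].T, y)
        cutoff = float(np.quantile(null_p, 0.05))
        rows.append((snp, p_obs, cutoff, p_obs < alpha and p_obs < cutoff))
    tab = pd.DataFrame(rows, columns=["snp", "p", "cutoff", "significant"])
    return SnpResult(tab)


def snp_gene_pairs(geno: GenotypeMatrix, candidate_genes: list[str],
                   window_kb: float = 100.0) -> dict[str, str]:
    """Map each SNP to the nearest candidate gene within the window."""
    w = window_kb * 1000.0
    genes = geno.gene_coords.loc[[g for g in candidate_genes
                                  if g in geno.gene_coords.index]]
    pairs: dict[str, str] = {}
    for snp in geno.dosages.columns:
        chrom, pos = geno.snp_coords.loc[snp, "chrom"], geno.snp_coords.loc[snp, "start"]
        same = genes[genes["chrom"] == chrom]
        near = same[(same["start"] - w <= pos) & (pos <= same["end"] + w)]
        if len(near):
            dist = np.minimum(np.abs(near["start"] - pos), np.abs(near["end"] - pos))
            pairs[snp] = str(dist.idxmin())
    return pairs


def _pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a Pearson correlation at sample size n."""
    r = np.clip(r, -0.999999, 0.999999)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def snp_expression_correlation(geno: GenotypeMatrix, expr: ExpressionMatrix,
                               pairs: dict[str, str], n_perm: int = 1000,
                               r_min: float = 0.2, alpha: float = 0.05,
                               seed: int | np.random.Generator = 0) -> SnpResult:
    """Pearson dosage-expression correlation with a per-pair permutation cutoff.

    eQTL flag requires r > r_min, correlation p < alpha and p below the 5th
    percentile of the p-values from ``n_perm`` genotype permutations.
    Zero-variance genotypes are skipped.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    common = [s for s in geno.dosages.index if s in set(expr.sample_ids)]
    if len(common) < 10:
        raise ValueError("need >= 10 samples shared between genotypes and expression")
    n = len(common)

    rows = []
    for snp, gene in pairs.items():
        if gene not in expr.gene_ids or snp not in geno.dosages.columns:
            continue
        g = geno.dosages.loc[common, snp].to_numpy(float)
        if g.std() == 0:
            logger.warning("snp_expression_correlation: %s has zero variance; skipped", snp)
            continue
        x = expr.values.loc[gene, common].to_numpy(float)
        if x.std() == 0:
            continue
        r = float(np.corrcoef(g, x)[0, 1])
        p = float(_pearson_p(np.array([r]), n)[0])

        perms = np.argsort(rng.random((n_perm, n)), axis=1)
        gp = g[perms]
        gc = gp - gp.mean(axis=1, keepdims=True)
        xc = x - x.mean()
        null_r = (gc @ xc) / (n * gp.std(axis=1) * x.std())
        null_p = _pearson_p(null_r, n)
        cutoff = float(np.quantile(null_p, 0.05))
        flagged = (r > r_min) and (p < alpha) and (p < cutoff)
        rows.append((snp, gene, r, p, cutoff, flagged))
    tab = pd.DataFrame(rows, columns=["snp", "gene", "r", "p", "cutoff", "eqtl"])
    return SnpResult(tab)
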