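"""Mutation correction of tumor expression profiles.

Expression alone overstates the functional activity of a gene whose protein
is disrupted by somatic mutation. This module derives, per cancer type, the
background frequency of each trinucleotide substitution category from the
observed somatic SNVs, converts those frequencies into per-codon and
per-gene expectations of non-synonymous (N_j) and synonymous (S_j) burden by
enumerating every single-base change of every codon, computes a regularized
dN/dS = (C_j/N_j + 1) / (C'_j/S_j + 1) per gene and cancer type, calls
significantly mutated genes (dN/dS > 1 plus a one-sided binomial test),
assigns each mutated codon of those genes a rarity index I = r/T (the
sample-weighted pan-cancer category frequency over the codon's recurrence),
and collapses the min-max-scaled indexes into a per-sample protein-activity
score in [0, 1] that multiplies the normalized expression value. Frameshift
and splice-site events zero the score; unmutated genes keep score 1.

The default category scheme keys substitutions by (5' base, ref, alt,
3' base) over all 12 ref->alt pairs and 16 flanking contexts — 192 keys; a
strand-collapsed 96-key view (pyrimidine reference) is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Data.CodonTable import standard_dna_table

from .io import ExpressionMatrix, LOSS_OF_FUNCTION_CLASSES, MutationTable

logger = logging.getLogger("ipmg")

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

STOP_CODONS = set(standard_dna_table.stop_codons)
_CODON_AA = dict(standard_dna_table.forward_table)
for _stop in STOP_CODONS:
    _CODON_AA[_stop] = "*"

#: classes counted as non-synonymous SNVs (nonsense alters the protein)
NONSYNONYMOUS_CLASSES = frozenset({"missense", "nonsense"})
SYNONYMOUS_CLASSES = frozenset({"silent"})


# ---------------------------------------------------------------------------
# substitution categories

def category_key(five: str, ref: str, alt: str, three: str) -> str:
    return f"{five}[{ref}>{alt}]{three}"


def enumerate_categories(collapse_strands: bool = False) -> list[str]:
    """All substitution-category keys: 192 by default, 96 strand-collapsed."""
    keys = []
    for ref in BASES:
        for alt in BASES:
            if alt == ref:
                continue
            for five in BASES:
                for three in BASES:
                    keys.append(category_key(five, ref, alt, three))
    if collapse_strands:
        keys = sorted({collapse_category(k) for k in keys})
    return keys


def collapse_category(key: str) -> str:
    """Map a category to its pyrimidine-reference strand representative."""
    five, ref, alt, three = key[0], key[2], key[4], key[6]
    if ref in "CT":
        return key
    return category_key(_COMPLEMENT[three], _COMPLEMENT[ref], _COMPLEMENT[alt],
                        _COMPLEMENT[five])


_CAT_KEYS = enumerate_categories()
_CAT_INDEX = {k: i for i, k in enumerate(_CAT_KEYS)}

# integer lookup table: cat_idx = _CAT_LUT[five, ref, alt, three] (-1 when ref==alt)
_CAT_LUT = np.full((4, 4, 4, 4), -1, dtype=np.int32)
for _k, _i in _CAT_INDEX.items():
    _CAT_LUT[_BASE_IDX[_k[0]], _BASE_IDX[_k[2]], _BASE_IDX[_k[4]], _BASE_IDX[_k[6]]] = _i


def _codon_syn_table() -> np.ndarray:
    """SYN[codon, pos_in_codon, alt_base] = substitution is synonymous.

    Substitutions producing a stop codon are non-synonymous; entries where
    alt equals the reference base are marked False (never used).
    """
    syn = np.zeros((64, 3, 4), dtype=bool)
    for c in range(64):
        codon = BASES[c >> 4] + BASES[(c >> 2) & 3] + BASES[c & 3]
        aa = _CODON_AA[codon]
        for pos in range(3):
            for alt in range(4):
                if BASES[alt] == codon[pos]:
                    continue
                mutated = codon[:pos] + BASES[alt] + codon[pos + 1:]
                syn[c, pos, alt] = _CODON_AA[mutated] == aa
    return syn


_SYN = _codon_syn_table()


# ---------------------------------------------------------------------------
# data containers

@dataclass
class CategoryFrequencyTable:
    """Per-cancer-type substitution-category frequencies (summing to 1)."""

    freqs: dict[str, pd.Series]        # cancer_type -> Series over category keys
    n_samples: dict[str, int]          # cancer_type -> number of samples
    collapse_strands: bool = False

    def pan_cancer_weighted(self) -> pd.Series:
        """Sample-weighted pan-cancer category frequency sum: sum_t freq_t * n_t."""
        keys = enumerate_categories(self.collapse_strands)
        total = pd.Series(0.0, index=keys)
        for t, fr in self.freqs.items():
            total = total.add(fr * self.n_samples.get(t, 0), fill_value=0.0)
        return total


@dataclass
class CodonBackground:
    """Expected non-synonymous / synonymous burden per codon and per gene."""

    cancer_type: str
    per_codon: dict[str, tuple[np.ndarray, np.ndarray]]  # gene -> (n_i, s_i)
    N: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    S: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


@dataclass
class DnDsResult:
    """dN/dS and binomial significance per (gene, cancer_type)."""

    table: pd.DataFrame  # columns gene, cancer_type, C, C_syn, N, S, dnds, p, significant


@dataclass
class CodonIndexTable:
    """Per mutated codon of significant genes: rarity index and its scaling."""

    table: pd.DataFrame  # columns gene, codon, r, T, raw_index, scaled_index


# ---------------------------------------------------------------------------
# step 1: category frequencies

def _snv_mask(rec: pd.DataFrame) -> pd.Series:
    return (rec["ref"].str.len() == 1) & (rec["alt"].str.len() == 1) & \
        rec["ref"].isin(list(BASES)) & rec["alt"].isin(list(BASES)) & \
        (~rec["variant_class"].isin(LOSS_OF_FUNCTION_CLASSES))


def build_category_frequencies(muts: MutationTable, clin: pd.DataFrame,
                               collapse_strands: bool = False) -> CategoryFrequencyTable:
    """Per cancer type, the fraction of SNVs falling in each category.

    Only SNV records with a resolvable trinucleotide context contribute;
    cancer types contributing zero SNVs are excluded with a warning.
    """
    keys = enumerate_categories(collapse_strands)
    sample_type = clin.set_index("sample_id")["cancer_type"]
    rec = muts.records
    ok = _snv_mask(rec) & (rec["context"].str.len() == 3)
    rec = rec[ok]
    cats = rec["context"].str[0] + "[" + rec["ref"] + ">" + rec["alt"] + "]" + \
        rec["context"].str[2]
    if collapse_strands:
        cats = cats.map(collapse_category)
    types = rec["sample"].map(sample_type)

    freqs: dict[str, pd.Series] = {}
    n_samples: dict[str, int] = {}
    for t in sorted(sample_type.unique()):
        counts = cats[types == t].value_counts()
        total = int(counts.sum())
        if total == 0:
            logger.warning("build_category_frequencies: cancer type %s has no SNVs; excluded", t)
            continue
        freqs[t] = counts.reindex(keys).fillna(0.0) / total
        n_samples[t] = int((sample_type == t).sum())
    return CategoryFrequencyTable(freqs, n_samples, collapse_strands)


# ---------------------------------------------------------------------------
# step 2: codon backgrounds and dN/dS

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


_ENC_LUT = np.full(256, -1, dtype=np.int8)
for _b, _i in _BASE_IDX.items():
    _ENC_LUT[ord(_b)] = _i


def _freq_vector(freqs: pd.Series) -> np.ndarray:
    """Frequencies as a dense vector indexed by _CAT_LUT (192-key layout)."""
    v = np.zeros(len(_CAT_KEYS))
    for key, val in freqs.items():
        v[_CAT_INDEX[key]] = val
    return v


def compute_codon_background(cds: dict[str, str], freqs: CategoryFrequencyTable,
                             cancer_type: str) -> CodonBackground:
    """Enumerate the 9 single-base changes of every codon of every gene.

    Each change is classified synonymous / non-synonymous by the standard
    codon table (changes creating a stop are non-synonymous) and weighted by
    the frequency of its substitution category in ``cancer_type``; the
    per-codon sums n_i, s_i accumulate into the gene backgrounds N_j, S_j.
    A trailing stop codon is excluded; an internal stop is an error.
    """
    if freqs.collapse_strands:
        raise ValueError("codon background requires the 192-key (uncollapsed) scheme")
    fvec = _freq_vector(freqs.freqs[cancer_type])

    per_codon: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    N: dict[str, float] = {}
    S: dict[str, float] = {}
    for gene, flanked in cds.items():
        body = flanked[1:-1]
        if len(body) % 3 != 0:
            raise ValueError(f"CDS length for {gene} not divisible by 3")
        codons = [body[i:i + 3] for i in range(0, len(body), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        if any(c in STOP_CODONS for c in codons):
            raise ValueError(f"internal stop codon in {gene}")
        k = len(codons)
        enc = _ENC_LUT[_encode(flanked)].astype(np.int64)
        if (enc[: 3 * k + 2] < 0).any():
            raise ValueError(f"non-ACGT base in CDS of {gene}")

        # positions 1..3k in CDS coordinates = indexes 1..3k of the flanked string
        pos = np.arange(1, 3 * k + 1)
        ref = enc[pos]
        five = enc[pos - 1]
        three = enc[pos + 1]
        codon_of = (pos - 1) // 3
        pos_in_codon = (pos - 1) % 3
        codon_code = (enc[1::3][:k] << 4) | (enc[2::3][:k] << 2) | enc[3::3][:k]

        n_i = np.zeros(k)
        s_i = np.zeros(k)
        for alt in range(4):
            valid = ref != alt
            cat = _CAT_LUT[five, ref, np.full_like(ref, alt), three]
            w = np.where(valid, fvec[np.clip(cat, 0, None)], 0.0)
            syn = _SYN[codon_code[codon_of], pos_in_codon, alt] & valid
            np.add.at(s_i, codon_of[syn], w[syn])
            nonsyn = valid & ~syn
            np.add.at(n_i, codon_of[nonsyn], w[nonsyn])
        per_codon[gene] = (n_i, s_i)
        N[gene] = float(n_i.sum())
        S[gene] = float(s_i.sum())
    return CodonBackground(cancer_type, per_codon, pd.Series(N), pd.Series(S))


def count_mutations(muts: MutationTable, clin: pd.DataFrame) -> pd.DataFrame:
    """Observed non-synonymous (C) and synonymous (C_syn) SNVs per gene and type."""
    sample_type = clin.set_index("sample_id")["cancer_type"]
    rec = muts.records.copy()
    rec["cancer_type"] = rec["sample"].map(sample_type)
    snv = rec[_snv_mask(rec)]
    grp = snv.groupby(["gene", "cancer_type"], observed=True)["variant_class"]
    C = grp.apply(lambda s: int(s.isin(NONSYNONYMOUS_CLASSES).sum()))
    Cs = grp.apply(lambda s: int(s.isin(SYNONYMOUS_CLASSES).sum()))
    out = pd.DataFrame({"C": C, "C_syn": Cs}).reset_index()
    return out


def compute_dnds(counts: pd.DataFrame, backgrounds: dict[str, CodonBackground]) -> DnDsResult:
    """Regularized dN/dS = (C/N + 1) / (C'/S + 1) per gene and cancer type.

    Genes whose synonymous background S_j is zero (no synonymous change is
    possible) are excluded with a warning. A gene with no observed SNVs has
    dN/dS = 1 by the regularizers.
    """
    rows = []
    for _, row in counts.iterrows():
        bg = backgrounds.get(row["cancer_type"])
        if bg is None or row["gene"] not in bg.N.index:
            continue
        N = bg.N[row["gene"]]
        S = bg.S[row["gene"]]
        if S <= 0 or N <= 0:
            logger.warning("compute_dnds: gene %s has zero background (N=%g, S=%g); excluded",
                           row["gene"], N, S)
            continue
        dnds = (row["C"] / N + 1.0) / (row["C_syn"] / S + 1.0)
        rows.append((row["gene"], row["cancer_type"], int(row["C"]), int(row["C_syn"]),
                     N, S, dnds))
    table = pd.DataFrame(rows, columns=["gene", "cancer_type", "C", "C_syn", "N", "S", "dnds"])
    return DnDsResult(table)


def binomial_p(C: int, C_syn: int, N: float, S: float) -> float:
    """One-sided binomial tail: P(X >= C) for X ~ Bin(C + C', N/(N+S))."""
    n = C + C_syn
    if n == 0:
        return 1.0
    p0 = N / (N + S)
    return float(stats.binom.sf(C - 1, n, p0))


def call_significant_genes(dnds: DnDsResult, alpha: float = 0.05) -> set[str]:
    """Union over cancer types of genes with dN/dS > 1 and binomial p < alpha."""
    tab = dnds.table.copy()
    tab = tab[(tab["C"] + tab["C_syn"]) > 0]
    tab["p"] = [binomial_p(c, cs, n, s)
                for c, cs, n, s in zip(tab["C"], tab["C_syn"], tab["N"], tab["S"])]
    flagged = tab[(tab["p"] < alpha) & (tab["dnds"] > 1.0)]
    return set(flagged["gene"])


# ---------------------------------------------------------------------------
# steps 3-4: codon indexes and protein-activity scores

def compute_codon_indexes(muts: MutationTable, freqs: CategoryFrequencyTable,
                          sig_genes: set[str], scale_per_gene: bool = False) -> CodonIndexTable:
    """Rarity index I = r/T for every non-synonymously mutated codon.

    r is the sample-weighted pan-cancer frequency of the observed category
    (sum over cancer types of frequency x sample count; event-weighted mean
    when several categories hit one codon); T is the pan-cancer count of
    non-synonymous events at the codon. Indexes are min-max scaled to [0, 1]
    across all tabulated codons (per gene when ``scale_per_gene``); if all
    raw indexes are equal every scaled index is 1.
    """
    weighted = freqs.pan_cancer_weighted()
    rec = muts.records
    snv = rec[_snv_mask(rec) & rec["variant_class"].isin(NONSYNONYMOUS_CLASSES) &
              rec["gene"].isin(sig_genes) & (rec["cds_pos"] > 0) &
              (rec["context"].str.len() == 3)].copy()
    if snv.empty:
        return CodonIndexTable(pd.DataFrame(
            columns=["gene", "codon", "r", "T", "raw_index", "scaled_index"]))
    snv["codon"] = (snv["cds_pos"] - 1) // 3
    cats = snv["context"].str[0] + "[" + snv["ref"] + ">" + snv["alt"] + "]" + \
        snv["context"].str[2]
    if freqs.collapse_strands:
        cats = cats.map(collapse_category)
    snv["r_event"] = cats.map(weighted)

    grp = snv.groupby(["gene", "codon"])
    out = grp.agg(r=("r_event", "mean"), T=("r_event", "size")).reset_index()
    out["raw_index"] = out["r"] / out["T"]

    def _scale(raw: pd.Series) -> pd.Series:
        lo, hi = raw.min(), raw.max()
        if hi - lo <= 0:
            return pd.Series(1.0, index=raw.index)
        return (raw - lo) / (hi - lo)

    if scale_per_gene:
        out["scaled_index"] = out.groupby("gene")["raw_index"].transform(_scale)
    else:
        out["scaled_index"] = _scale(out["raw_index"])
    return CodonIndexTable(out)


def score_and_correct(expr: ExpressionMatrix, idx: CodonIndexTable, muts: MutationTable,
                      sig_genes: set[str]) -> tuple[pd.DataFrame, ExpressionMatrix]:
    """Protein-activity scores S in [0, 1] and the corrected expression table.

    Per (significant gene, sample): no mutation -> 1; any frameshift or
    splice-site event -> 0; otherwise the product of the scaled indexes of
    the sample's non-synonymously mutated codons. Genes outside the
    significant set pass through with score 1. Corrected expression is
    score x normalized expression.
    """
    scores = pd.DataFrame(1.0, index=expr.gene_ids, columns=expr.sample_ids)
    scaled = idx.table.set_index(["gene", "codon"])["scaled_index"] if len(idx.table) else \
        pd.Series(dtype=float)

    rec = muts.records
    known = rec["gene"].isin(expr.gene_ids) & rec["sample"].isin(expr.sample_ids)
    n_skip = int((~known).sum())
    if n_skip:
        logger.warning("score_and_correct: %d mutation records with unknown gene/sample skipped",
                       n_skip)
    rec = rec[known & rec["gene"].isin(sig_genes)]

    lof = rec[rec["variant_class"].isin(LOSS_OF_FUNCTION_CLASSES)]
    nonsyn = rec[_snv_mask(rec) & rec["variant_class"].isin(NONSYNONYMOUS_CLASSES) &
                 (rec["cds_pos"] > 0)].copy()
    if len(nonsyn):
        nonsyn["codon"] = (nonsyn["cds_pos"] - 1) // 3
        nonsyn = nonsyn.drop_duplicates(["gene", "sample", "codon"])
        key = pd.MultiIndex.from_frame(nonsyn[["gene", "codon"]])
        nonsyn["idx"] = scaled.reindex(key).to_numpy()
        nonsyn = nonsyn.dropna(subset=["idx"])
        prod = nonsyn.groupby(["gene", "sample"])["idx"].prod()
        for (g, s), v in prod.items():
            scores.at[g, s] = v
    for g, s in zip(lof["gene"], lof["sample"]):
        scores.at[g, s] = 0.0

    corrected = expr.values * scores
    return scores, expr.with_values(corrected, stage="mutation_corrected")
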