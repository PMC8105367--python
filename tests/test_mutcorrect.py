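"""Mutation-correction: substitution categories, codon backgrounds (with a
brute-force oracle), dN/dS, the binomial significance test, codon indexes
and protein-activity scores."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ipmg import mutcorrect as mc
from ipmg.io import ExpressionMatrix, MutationTable

BASES = "ACGT"
CODON_AA = mc._CODON_AA


def uniform_freq_table(u: float = 1.0 / 192, cancer_type: str = "TX",
                       n_samples: int = 4) -> mc.CategoryFrequencyTable:
    keys = mc.enumerate_categories()
    return mc.CategoryFrequencyTable(
        {cancer_type: pd.Series(u, index=keys)}, {cancer_type: n_samples})


# ---------------------------------------------------------------------------
# categories

def test_category_space_has_192_keys_and_96_collapsed():
    keys = mc.enumerate_categories()
    assert len(keys) == len(set(keys)) == 192
    collapsed = mc.enumerate_categories(collapse_strands=True)
    assert len(collapsed) == 96


def test_collapsed_frequency_is_sum_of_strand_pair(small_cohort):
    full = mc.build_category_frequencies(small_cohort.mutations, small_cohort.clinical)
    coll = mc.build_category_frequencies(small_cohort.mutations, small_cohort.clinical,
                                         collapse_strands=True)
    for t in full.freqs:
        pair_sum = full.freqs[t].groupby(mc.collapse_category).sum()
        merged = coll.freqs[t].add(-pair_sum.reindex(coll.freqs[t].index), fill_value=0.0)
        assert np.abs(merged).max() < 1e-12


def test_frequencies_sum_to_one_and_hand_counts():
    muts = MutationTable(pd.DataFrame({
        "gene": ["g"] * 10, "sample": ["s1"] * 10,
        "variant_class": ["missense"] * 10,
        "ref": ["C"] * 5 + ["T"] * 3 + ["A"] * 2,
        "alt": ["T"] * 5 + ["G"] * 3 + ["G"] * 2,
        "cds_pos": [1] * 10,
        "context": ["ACG"] * 5 + ["TTA"] * 3 + ["GAC"] * 2,
    }))
    clin = pd.DataFrame({"sample_id": ["s1"], "cancer_type": ["TX"],
                         "treatment_class": ["immunotherapy"],
                         "time_days": [10.0], "event": [1]})
    fr = mc.build_category_frequencies(muts, clin).freqs["TX"]
    assert fr.sum() == pytest.approx(1.0)
    assert fr["A[C>T]G"] == pytest.approx(0.5)
    assert fr["T[T>G]A"] == pytest.approx(0.3)
    assert fr["G[A>G]C"] == pytest.approx(0.2)


def test_degenerate_single_category():
    muts = MutationTable(pd.DataFrame({
        "gene": ["g"] * 4, "sample": ["s1"] * 4, "variant_class": ["missense"] * 4,
        "ref": ["C"] * 4, "alt": ["A"] * 4, "cds_pos": [1] * 4, "context": ["ACA"] * 4,
    }))
    clin = pd.DataFrame({"sample_id": ["s1"], "cancer_type": ["TX"],
                         "treatment_class": ["immunotherapy"],
                         "time_days": [1.0], "event": [0]})
    fr = mc.build_category_frequencies(muts, clin).freqs["TX"]
    assert fr["A[C>A]A"] == 1.0
    assert (fr.drop("A[C>A]A") == 0).all()


# ---------------------------------------------------------------------------
# codon backgrounds: brute-force oracle

def brute_force_background(flanked: str, freqs: pd.Series):
    """Independent enumeration of all (codon, substitution) pairs."""
    body = flanked[1:-1]
    codons = [body[i:i + 3] for i in range(0, len(body), 3)]
    if codons[-1] in mc.STOP_CODONS:
        codons = codons[:-1]
    n = np.zeros(len(codons))
    s = np.zeros(len(codons))
    for ci, codon in enumerate(codons):
        for pos in range(3):
            cds_pos = 3 * ci + pos + 1
            ref = flanked[cds_pos]
            five, three = flanked[cds_pos - 1], flanked[cds_pos + 1]
            for alt in BASES:
                if alt == ref:
                    continue
                mutated = codon[:pos] + alt + codon[pos + 1:]
                f = freqs[f"{five}[{ref}>{alt}]{three}"]
                if CODON_AA[mutated] == CODON_AA[codon]:
                    s[ci] += f
                else:
                    n[ci] += f
    return n, s


def test_background_matches_brute_force_on_fixture(codon_fixture):
    cds, muts, clin = codon_fixture
    freqs = mc.build_category_frequencies(muts, clin)
    bg = mc.compute_codon_background(cds, freqs, "TX")
    for gene, flanked in cds.items():
        n_o, s_o = brute_force_background(flanked, freqs.freqs["TX"])
        n_i, s_i = bg.per_codon[gene]
        assert np.max(np.abs(n_i - n_o)) < 1e-12
        assert np.max(np.abs(s_i - s_o)) < 1e-12
        assert bg.N[gene] == pytest.approx(n_o.sum(), abs=1e-12)
        assert bg.S[gene] == pytest.approx(s_o.sum(), abs=1e-12)


def test_background_random_genes_match_brute_force():
    rng = np.random.default_rng(3)
    keys = mc.enumerate_categories()
    freqs = pd.Series(rng.dirichlet(np.ones(192)), index=keys)
    table = mc.CategoryFrequencyTable({"TX": freqs}, {"TX": 5})
    pool = sorted(set(CODON_AA) - mc.STOP_CODONS)
    for trial in range(5):
        body = "".join(rng.choice(pool, size=6))
        flanked = rng.choice(list(BASES)) + body + rng.choice(list(BASES))
        bg = mc.compute_codon_background({"g": flanked}, table, "TX")
        n_o, s_o = brute_force_background(flanked, freqs)
        assert np.allclose(bg.per_codon["g"][0], n_o, atol=1e-12)
        assert np.allclose(bg.per_codon["g"][1], s_o, atol=1e-12)


def test_codon_enumeration_conservation_property():
    """n_i + s_i equals the sum of the frequencies of the codon's 9 changes."""
    rng = np.random.default_rng(4)
    keys = mc.enumerate_categories()
    freqs = pd.Series(rng.dirichlet(np.ones(192)), index=keys)
    table = mc.CategoryFrequencyTable({"TX": freqs}, {"TX": 1})
    flanked = "T" + "ATGCTGAAA" + "G"
    bg = mc.compute_codon_background({"g": flanked}, table, "TX")
    n_i, s_i = bg.per_codon["g"]
    for ci in range(3):
        total = 0.0
        for pos in range(3):
            p = 3 * ci + pos + 1
            for alt in BASES:
                if alt != flanked[p]:
                    total += freqs[f"{flanked[p-1]}[{flanked[p]}>{alt}]{flanked[p+1]}"]
        assert n_i[ci] + s_i[ci] == pytest.approx(total, abs=1e-12)


def test_met_and_leu_codon_backgrounds_under_uniform_frequencies():
    u = 1.0 / 192
    table = uniform_freq_table(u)
    bg = mc.compute_codon_background({"m": "TATGTAAG", "l": "ACTGTAAC"}, table, "TX")
    n_m, s_m = bg.per_codon["m"]
    assert s_m[0] == pytest.approx(0.0, abs=1e-15)      # ATG: all 9 non-synonymous
    assert n_m[0] == pytest.approx(9 * u, abs=1e-15)
    n_l, s_l = bg.per_codon["l"]
    assert s_l[0] == pytest.approx(4 * u, abs=1e-15)    # CTG: CTA/CTC/CTT/TTG
    assert n_l[0] == pytest.approx(5 * u, abs=1e-15)


def test_background_rejects_internal_stop_and_bad_length():
    table = uniform_freq_table()
    with pytest.raises(ValueError, match="stop"):
        mc.compute_codon_background({"g": "ATAAATGC"}, table, "TX")  # TAA internal
    with pytest.raises(ValueError, match="divisible"):
        mc.compute_codon_background({"g": "AATGCA"}, table, "TX")


# ---------------------------------------------------------------------------
# dN/dS and the binomial test

def _dnds_of(C, C_syn, N, S):
    counts = pd.DataFrame({"gene": ["g"], "cancer_type": ["TX"],
                           "C": [C], "C_syn": [C_syn]})
    bg = mc.CodonBackground("TX", {}, pd.Series({"g": N}), pd.Series({"g": S}))
    res = mc.compute_dnds(counts, {"TX": bg})
    return float(res.table["dnds"].iloc[0])


@pytest.mark.parametrize("C, Cs, N, S, expected", [
    (0, 0, 0.5, 0.5, 1.0),                      # regularizer identity
    (2, 1, 0.6, 0.3, (2 / 0.6 + 1) / (1 / 0.3 + 1)),
    (3, 0, 0.5, 0.5, 7.0),
])
def test_dnds_hand_values(C, Cs, N, S, expected):
    assert _dnds_of(C, Cs, N, S) == pytest.approx(expected, abs=1e-12)


def test_dnds_monotone_in_counts():
    base = _dnds_of(2, 2, 0.5, 0.5)
    assert _dnds_of(3, 2, 0.5, 0.5) > base > _dnds_of(2, 3, 0.5, 0.5)


def test_dnds_zero_synonymous_background_excluded():
    counts = pd.DataFrame({"gene": ["g"], "cancer_type": ["TX"], "C": [1], "C_syn": [0]})
    bg = mc.CodonBackground("TX", {}, pd.Series({"g": 1.0}), pd.Series({"g": 0.0}))
    res = mc.compute_dnds(counts, {"TX": bg})
    assert len(res.table) == 0


def exact_binomial_tail(k: int, n: int, p: float) -> float:
    """Independent oracle: sum of exact pmf terms for P(X >= k)."""
    return sum(math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


@pytest.mark.parametrize("C, Cs, p0", [
    (10, 0, 0.75), (0, 5, 0.5), (7, 3, 0.6), (12, 1, 0.9), (3, 9, 0.25),
])
def test_binomial_p_matches_exact_tail(C, Cs, p0):
    N, S = p0, 1.0 - p0
    assert mc.binomial_p(C, Cs, N, S) == pytest.approx(
        exact_binomial_tail(C, C + Cs, p0), abs=1e-12)


def test_significant_gene_union_rule():
    # flagged in type A only (p < 0.05 and dnds > 1), null in type B
    tab = pd.DataFrame({
        "gene": ["g", "g", "h"],
        "cancer_type": ["A", "B", "A"],
        "C": [20, 1, 0], "C_syn": [0, 1, 0],
        "N": [0.5, 0.5, 0.5], "S": [0.5, 0.5, 0.5],
        "dnds": [3.0, 1.0, 1.0],
    })
    flagged = mc.call_significant_genes(mc.DnDsResult(tab))
    assert flagged == {"g"}


def test_ten_nonsyn_at_expected_three_quarters_is_not_significant():
    tab = pd.DataFrame({"gene": ["g"], "cancer_type": ["A"], "C": [10], "C_syn": [0],
                        "N": [0.75], "S": [0.25], "dnds": [2.0]})
    assert mc.call_significant_genes(mc.DnDsResult(tab)) == set()
    assert mc.binomial_p(10, 0, 0.75, 0.25) == pytest.approx(0.75**10, abs=1e-12)


# ---------------------------------------------------------------------------
# codon indexes and activity scores

def test_codon_index_scaling_rules():
    tab = uniform_freq_table(u=1.0 / 192, n_samples=10)
    # two codons in one gene: codon 0 hit twice (same category), codon 1 once
    muts = MutationTable(pd.DataFrame({
        "gene": ["g"] * 3, "sample": ["s1", "s2", "s3"],
        "variant_class": ["missense"] * 3,
        "ref": ["A", "A", "C"], "alt": ["G", "G", "T"],
        "cds_pos": [1, 1, 4], "context": ["TAG", "TAG", "GCA"],
    }))
    idx = mc.compute_codon_indexes(muts, tab, {"g"})
    t = idx.table.set_index("codon")
    # equal r (uniform frequencies): the twice-hit codon has half the raw index
    assert t.loc[0, "raw_index"] == pytest.approx(t.loc[1, "raw_index"] / 2)
    assert sorted(t["scaled_index"]) == [0.0, 1.0]


def test_single_tabulated_codon_scales_to_one():
    tab = uniform_freq_table()
    muts = MutationTable(pd.DataFrame({
        "gene": ["g"], "sample": ["s1"], "variant_class": ["missense"],
        "ref": ["A"], "alt": ["G"], "cds_pos": [1], "context": ["TAG"],
    }))
    idx = mc.compute_codon_indexes(muts, tab, {"g"})
    assert list(idx.table["scaled_index"]) == [1.0]


def test_synonymous_only_codon_not_tabulated():
    tab = uniform_freq_table()
    muts = MutationTable(pd.DataFrame({
        "gene": ["g"], "sample": ["s1"], "variant_class": ["silent"],
        "ref": ["A"], "alt": ["G"], "cds_pos": [3], "context": ["AAG"],
    }))
    idx = mc.compute_codon_indexes(muts, tab, {"g"})
    assert len(idx.table) == 0


def _expr(genes, samples):
    rng = np.random.default_rng(0)
    return ExpressionMatrix(pd.DataFrame(
        rng.uniform(1, 5, size=(len(genes), len(samples))),
        index=genes, columns=samples), stage="normalized")


def test_activity_score_contract():
    expr = _expr(["g", "h"], ["m1", "m2", "m3"])
    idx = mc.CodonIndexTable(pd.DataFrame({
        "gene": ["g", "g"], "codon": [0, 1], "r": [1, 1], "T": [1, 1],
        "raw_index": [0.1, 0.2], "scaled_index": [0.5, 0.8],
    }))
    muts = MutationTable(pd.DataFrame({
        "gene": ["g", "g", "g"], "sample": ["m1", "m1", "m2"],
        "variant_class": ["missense", "missense", "frameshift"],
        "ref": ["A", "C", "T"], "alt": ["G", "T", "A"],
        "cds_pos": [1, 4, 2], "context": ["AAA", "CCC", "TTT"],
    }))
    scores, corrected = mc.score_and_correct(expr, idx, muts, {"g"})
    assert scores.loc["g", "m1"] == pytest.approx(0.5 * 0.8)   # product of indexes
    assert scores.loc["g", "m2"] == 0.0                        # frameshift zeroes
    assert scores.loc["g", "m3"] == 1.0                        # unmutated
    assert corrected.values.loc["g", "m2"] == 0.0
    # unmutated gene passes through exactly
    pd.testing.assert_series_equal(corrected.values.loc["h"], expr.values.loc["h"])
    assert corrected.values.loc["g", "m1"] == pytest.approx(
        0.4 * expr.values.loc["g", "m1"])


def test_unknown_gene_or_sample_mutation_skipped():
    expr = _expr(["g"], ["m1"])
    idx = mc.CodonIndexTable(pd.DataFrame(
        columns=["gene", "codon", "r", "T", "raw_index", "scaled_index"]))
    muts = MutationTable(pd.DataFrame({
        "gene": ["nope"], "sample": ["m1"], "variant_class": ["frameshift"],
        "ref": ["A"], "alt": ["G"], "cds_pos": [1], "context": ["AAA"],
    }))
    scores, corrected = mc.score_and_correct(expr, idx, muts, {"nope"})
    assert (scores.to_numpy() == 1.0).all()
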