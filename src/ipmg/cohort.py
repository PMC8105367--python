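"""Synthetic TCGA-shaped cohort with known planted structure.

The generator emulates the multi-modal inputs of a pan-cancer
immunotherapy study — expression, somatic mutations with trinucleotide
context, clinical follow-up with treatment class, leukocyte fraction and
tumor purity, pathways, coding sequences, and genotypes — with planted
ground truth so every pipeline stage has an acceptance surface:

* immunotherapy-specific pathway genes load on a latent per-sample
  "responsiveness" factor that lowers the hazard of immunotherapy-treated
  samples only;
* general-prognostic pathway genes load on a second factor affecting all
  samples' hazard;
* immune genes track the leukocyte fraction (and hence anti-track purity);
* hyper-mutated genes receive excess non-synonymous events;
* one causal SNP shifts the hazard (and, as an eQTL, the expression of its
  neighboring gene).

Survival times are exponential with multiplicative effects and uniform
censoring on [0, 5] years, so marginal distributions have a closed form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GenotypeMatrix,
    MutationTable,
    PathwayDB,
    write_cds,
    write_clinical,
    write_expression,
    write_fractions,
    write_genotypes,
    write_gmt,
    write_maf,
)
from .mutcorrect import BASES, STOP_CODONS, _CODON_AA
from .survival import DAYS_PER_YEAR

_NONSTOP_CODONS = sorted(set(_CODON_AA) - STOP_CODONS)

# mean of a standard normal above its top tertile boundary; the top-vs-bottom
# tertile contrast of a unit normal latent spans twice this
_TERTILE_MEAN = 1.0911


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort; defaults are the desk-scale study."""

    n_cancer_types: int = 6
    samples_per_type: int = 100
    n_genes: int = 1500
    n_pathways: int = 60
    genes_per_pathway: int = 25
    frac_immunotherapy: float = 0.15
    seed: int = 0

    # planted structure
    n_specific_pathways: int = 1
    n_general_pathways: int = 1
    n_immune_genes: int = 40
    n_hypermutated_genes: int = 20
    hazard_ratio_immuno: float = 12.0    # bottom-vs-top tertile hazard of planted genes
    hazard_ratio_all: float = 12.0
    corr_leuko: float = 0.6              # target Pearson r of immune genes with fraction
    snp_log_odds: float = 1.75           # per-allele hazard effect of the causal SNP
    gene_latent_corr: float = 0.85       # loading of planted genes on their latent factor

    # nuisance structure
    baseline_median_years: float = 1.5
    censor_horizon_years: float = 5.0
    type_frailty_sd: float = 0.2
    mutation_rate_range: tuple[float, float] = (40.0, 60.0)
    hyper_factor: float = 12.0
    hyper_nonsyn_prob: float = 0.95
    lof_fraction: float = 0.03
    na_fraction: float = 0.002
    n_low_genes: int = 5
    n_snps: int = 80

    def __post_init__(self) -> None:
        if not (0.0 < self.frac_immunotherapy < 1.0):
            raise ValueError("frac_immunotherapy must lie in (0, 1)")
        if self.hazard_ratio_immuno <= 0 or self.hazard_ratio_all <= 0:
            raise ValueError("hazard ratios must be positive")
        n_planted = (
            (self.n_specific_pathways + self.n_general_pathways) * self.genes_per_pathway
            + self.n_immune_genes + self.n_hypermutated_genes + self.n_low_genes
        )
        if n_planted > self.n_genes:
            raise ValueError(f"planted genes ({n_planted}) exceed n_genes ({self.n_genes})")
        if self.n_pathways < self.n_specific_pathways + self.n_general_pathways:
            raise ValueError("n_pathways smaller than the planted pathways")


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator, serialized with the data."""

    gene_class: dict[str, str]           # immuno_specific / general_prognostic / immune / null
    pathway_class: dict[str, str]        # specific / general / null
    immune_genes: list[str]
    hypermutated_genes: list[str]
    specific_pathways: list[str]
    general_pathways: list[str]
    causal_snp: str
    causal_snp_target_gene: str
    snp_log_odds: float
    hazard_ratio_immuno: float
    hazard_ratio_all: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class CohortData:
    """The generated multi-modal bundle."""

    expression: ExpressionMatrix
    mutations: MutationTable
    clinical: pd.DataFrame
    fractions: pd.DataFrame
    pathways: PathwayDB
    cds: dict[str, str]
    genotypes: GenotypeMatrix
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": outdir / "expression.tsv",
            "mutations": outdir / "mutations.maf",
            "clinical": outdir / "clinical.tsv",
            "fractions": outdir / "fractions.tsv",
            "pathways": outdir / "pathways.gmt",
            "cds": outdir / "cds.fa",
            "dosages": outdir / "genotypes.tsv",
            "snp_bed": outdir / "snps.bed",
            "gene_bed": outdir / "genes.bed",
            "truth": outdir / "truth.json",
        }
        write_expression(self.expression, paths["expression"])
        write_maf(self.mutations, paths["mutations"])
        write_clinical(self.clinical, paths["clinical"])
        write_fractions(self.fractions, paths["fractions"])
        write_gmt(self.pathways, paths["pathways"])
        write_cds(self.cds, paths["cds"])
        write_genotypes(self.genotypes, paths["dosages"], paths["snp_bed"], paths["gene_bed"])
        self.truth.to_json(paths["truth"])
        return {k: str(v) for k, v in paths.items()}


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def _latent_loading(rho: float) -> tuple[float, float]:
    """(signal loading, noise sd) giving Pearson r = rho at unit total variance."""
    return rho, float(np.sqrt(1.0 - rho**2))


def generate_cohort(spec: CohortSpec) -> CohortData:
    """Generate the full synthetic bundle; all randomness flows from spec.seed."""
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)

    # ----- samples and clinical skeleton -------------------------------------
    types = [f"T{t + 1}" for t in range(spec.n_cancer_types)]
    sample_ids, sample_type = [], []
    for t in types:
        for i in range(spec.samples_per_type):
            sample_ids.append(f"S_{t}_{i + 1:04d}")
            sample_type.append(t)
    n = len(sample_ids)
    treatment = np.full(n, "non_immunotherapy", dtype=object)
    for t in types:
        idx = [i for i, ty in enumerate(sample_type) if ty == t]
        n_imm = max(1, int(round(spec.frac_immunotherapy * len(idx))))
        chosen = rng.choice(idx, size=n_imm, replace=False)
        treatment[chosen] = "immunotherapy"
    is_immuno = treatment == "immunotherapy"

    # ----- latent factors and fractions --------------------------------------
    # the causal SNP (drawn below) shifts the responsiveness factor, so its
    # survival effect is mediated by — and observable through — the planted genes
    z_base = rng.normal(size=n)       # immunotherapy responsiveness (pre-genotype)
    w_general = rng.normal(size=n)    # overall prognosis
    frac = np.clip(rng.beta(2.0, 5.0, size=n), 0.01, 0.95)
    stroma = rng.uniform(0.0, 0.1, size=n)
    purity = np.clip(1.0 - frac - stroma, 0.01, None)

    # ----- planted gene assignment -------------------------------------------
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = genes[cursor:cursor + k]
        cursor += k
        return out

    specific_sets = [take(spec.genes_per_pathway) for _ in range(spec.n_specific_pathways)]
    general_sets = [take(spec.genes_per_pathway) for _ in range(spec.n_general_pathways)]
    immune_genes = take(spec.n_immune_genes)
    hyper_genes = take(spec.n_hypermutated_genes)
    low_genes = take(spec.n_low_genes)
    null_pool = genes[cursor:]

    specific_genes = [g for s in specific_sets for g in s]
    general_genes = [g for s in general_sets for g in s]

    # ----- pathways -----------------------------------------------------------
    pw_names = [f"PW_{i + 1:03d}" for i in range(spec.n_pathways)]
    sets: dict[str, list[str]] = {}
    k_planted = spec.n_specific_pathways + spec.n_general_pathways
    for i, name in enumerate(pw_names):
        if i < spec.n_specific_pathways:
            sets[name] = list(specific_sets[i])
        elif i < k_planted:
            sets[name] = list(general_sets[i - spec.n_specific_pathways])
        else:
            sets[name] = sorted(rng.choice(null_pool, size=spec.genes_per_pathway,
                                           replace=False))
    pathways = PathwayDB(sets)

    # ----- genotypes ----------------------------------------------------------
    gene_coords = pd.DataFrame({
        "chrom": "chr1",
        "start": [i * 500_000 for i in range(spec.n_genes)],
        "end": [i * 500_000 + 2_000 for i in range(spec.n_genes)],
    }, index=pd.Index(genes, name="name"))

    snp_ids = [f"SNP_{i + 1:04d}" for i in range(spec.n_snps)]
    target_gene = specific_genes[0]
    gi_panel = specific_genes + general_genes
    tstart = int(gene_coords.loc[target_gene, "start"])
    snp_pos, snp_maf = [], []
    for i in range(spec.n_snps):
        if i == 0:  # causal SNP inside the window of its target gene
            snp_pos.append(tstart + 10_000)
            snp_maf.append(0.3)
        elif i < spec.n_snps // 3:  # near planted panel genes
            g = gi_panel[int(rng.integers(0, len(gi_panel)))]
            snp_pos.append(int(gene_coords.loc[g, "start"]) + int(rng.integers(-80_000, 80_000)))
            snp_maf.append(float(rng.uniform(0.1, 0.4)))
        elif i < spec.n_snps - 10:
            g = rng.integers(0, spec.n_genes)
            snp_pos.append(int(gene_coords.iloc[g]["start"]) + int(rng.integers(-80_000, 80_000)))
            snp_maf.append(float(rng.uniform(0.1, 0.4)))
        elif i < spec.n_snps - 5:  # intergenic, beyond any 100 kb window
            snp_pos.append(int(gene_coords.iloc[rng.integers(0, spec.n_genes)]["start"])
                           + 250_000)
            snp_maf.append(float(rng.uniform(0.1, 0.4)))
        else:  # rare: below the 5% MAF filter
            g = rng.integers(0, spec.n_genes)
            snp_pos.append(int(gene_coords.iloc[g]["start"]) + int(rng.integers(0, 2_000)))
            snp_maf.append(float(rng.uniform(0.005, 0.04)))
    dosages = rng.binomial(2, np.array(snp_maf)[None, :], size=(n, spec.n_snps)).astype(np.int8)
    snp_coords = pd.DataFrame({
        "chrom": "chr1",
        "start": snp_pos,
        "end": [p + 1 for p in snp_pos],
    }, index=pd.Index(snp_ids, name="name"))
    genotypes = GenotypeMatrix(
        pd.DataFrame(dosages, index=pd.Index(sample_ids, name="sample_id"), columns=snp_ids),
        snp_coords, gene_coords,
    )
    causal_dos = dosages[:, 0].astype(float)

    # ----- expression ---------------------------------------------------------
    rho = spec.gene_latent_corr
    beta_spec = np.log(spec.hazard_ratio_immuno) / (2.0 * _TERTILE_MEAN * rho)
    beta_gen = np.log(spec.hazard_ratio_all) / (2.0 * _TERTILE_MEAN * rho)
    # per-allele shift of the responsiveness factor giving the stated
    # per-allele log-hazard once multiplied by beta_spec
    delta = spec.snp_log_odds / beta_spec if beta_spec > 0 else 0.0
    z_immuno = z_base + delta * (causal_dos - causal_dos.mean())
    a_sig, sd_sig = _latent_loading(rho)
    r_imm = spec.corr_leuko
    a_imm, sd_imm = _latent_loading(r_imm)
    f_std = (frac - frac.mean()) / frac.std()
    type_offsets = {t: rng.normal(0.0, 0.5, size=spec.n_genes) for t in types}
    type_idx = np.array([types.index(t) for t in sample_type])
    offsets = np.stack([type_offsets[t] for t in types])  # (T, G)

    mu = rng.uniform(3.0, 8.0, size=spec.n_genes)
    L = mu[:, None] + offsets[type_idx].T + rng.normal(0.0, 1.0, size=(spec.n_genes, n))
    gi = {g: i for i, g in enumerate(genes)}
    for g in specific_genes:
        L[gi[g]] = mu[gi[g]] + offsets[type_idx].T[gi[g]] + a_sig * z_immuno + \
            rng.normal(0.0, sd_sig, size=n)
    for g in general_genes:
        L[gi[g]] = mu[gi[g]] + offsets[type_idx].T[gi[g]] + a_sig * w_general + \
            rng.normal(0.0, sd_sig, size=n)
    for g in immune_genes:
        L[gi[g]] = mu[gi[g]] + a_imm * f_std + rng.normal(0.0, sd_imm, size=n)

    raw = np.exp2(L) - 1.0
    raw = np.clip(raw, 0.0, None)
    for g in low_genes:
        raw[gi[g]] = rng.uniform(0.0, 0.5, size=n)
    values = pd.DataFrame(raw, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    if spec.na_fraction > 0:
        mask = rng.random(values.shape) < spec.na_fraction
        # never blank a whole gene within a cancer type beyond repair
        values = values.mask(mask & (values.rank(axis=1) > 2))
    expression = ExpressionMatrix(values, stage="raw")

    # ----- survival -----------------------------------------------------------
    lam0 = np.log(2.0) / (spec.baseline_median_years * DAYS_PER_YEAR)
    frailty = {t: rng.normal(0.0, spec.type_frailty_sd) for t in types}
    eta = np.array([frailty[t] for t in sample_type])
    eta = eta - beta_gen * w_general
    eta = eta - beta_spec * z_immuno * is_immuno
    lam = lam0 * np.exp(eta)
    t_event = rng.exponential(1.0 / lam)
    censor = rng.uniform(0.0, spec.censor_horizon_years * DAYS_PER_YEAR, size=n)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)

    clinical = pd.DataFrame({
        "sample_id": sample_ids,
        "cancer_type": sample_type,
        "treatment_class": treatment,
        "time_days": np.round(time, 3),
        "event": event,
    })
    fractions = pd.DataFrame({
        "leukocyte_fraction": np.round(frac, 6),
        "tumor_purity": np.round(purity, 6),
    }, index=pd.Index(sample_ids, name="sample_id"))

    # ----- coding sequences and mutations ------------------------------------
    cds = _generate_cds(rng, genes)
    mutations = _generate_mutations(rng, spec, cds, genes, hyper_genes,
                                    sample_ids, sample_type, types)

    gene_class = {g: "null" for g in genes}
    for g in specific_genes:
        gene_class[g] = "immuno_specific"
    for g in general_genes:
        gene_class[g] = "general_prognostic"
    for g in immune_genes:
        gene_class[g] = "immune"
    pathway_class = {name: "null" for name in pw_names}
    for i in range(spec.n_specific_pathways):
        pathway_class[pw_names[i]] = "specific"
    for i in range(spec.n_specific_pathways, k_planted):
        pathway_class[pw_names[i]] = "general"

    truth = SyntheticTruth(
        gene_class=gene_class,
        pathway_class=pathway_class,
        immune_genes=list(immune_genes),
        hypermutated_genes=list(hyper_genes),
        specific_pathways=pw_names[:spec.n_specific_pathways],
        general_pathways=pw_names[spec.n_specific_pathways:k_planted],
        causal_snp=snp_ids[0],
        causal_snp_target_gene=target_gene,
        snp_log_odds=spec.snp_log_odds,
        hazard_ratio_immuno=spec.hazard_ratio_immuno,
        hazard_ratio_all=spec.hazard_ratio_all,
    )
    return CohortData(expression, mutations, clinical, fractions, pathways, cds,
                      genotypes, truth)


def _generate_cds(rng: np.random.Generator, genes: list[str]) -> dict[str, str]:
    """Random stop-free CDS (20-40 codons) per gene, with 1-nt flanks and a stop."""
    cds: dict[str, str] = {}
    codon_pool = np.array(_NONSTOP_CODONS)
    for g in genes:
        k = int(rng.integers(20, 41))
        body = "ATG" + "".join(rng.choice(codon_pool, size=k - 1)) + "TAA"
        flank5, flank3 = rng.choice(list(BASES)), rng.choice(list(BASES))
        cds[g] = flank5 + body + flank3
    return cds


def _classify(codon: str, pos_in_codon: int, alt: str) -> str:
    mutated = codon[:pos_in_codon] + alt + codon[pos_in_codon + 1:]
    if _CODON_AA[mutated] == "*":
        return "nonsense"
    return "silent" if _CODON_AA[mutated] == _CODON_AA[codon] else "missense"


def _generate_mutations(rng: np.random.Generator, spec: CohortSpec, cds: dict[str, str],
                        genes: list[str], hyper_genes: list[str], sample_ids: list[str],
                        sample_type: list[str], types: list[str]) -> MutationTable:
    """Somatic SNVs with per-type substitution preferences; hypermutated genes
    receive extra, non-synonymous-biased events; a small fraction of events
    are frameshifts."""
    # per cancer type: Dirichlet alt preferences per reference base
    alt_choices = {b: [x for x in BASES if x != b] for b in BASES}
    pref = {t: {b: rng.dirichlet(np.ones(3)) for b in BASES} for t in types}
    mu_rate = {t: rng.uniform(*spec.mutation_rate_range) for t in types}

    lengths = np.array([len(cds[g]) - 5 for g in genes], float)  # coding, minus stop
    weights = lengths.copy()
    hyper_set = set(hyper_genes)
    for i, g in enumerate(genes):
        if g in hyper_set:
            weights[i] *= spec.hyper_factor
    weights /= weights.sum()

    rows = []
    for s, t in zip(sample_ids, sample_type):
        n_mut = rng.poisson(mu_rate[t])
        gene_idx = rng.choice(len(genes), size=n_mut, p=weights)
        for g_i in gene_idx:
            g = genes[g_i]
            flanked = cds[g]
            n_coding = len(flanked) - 5  # exclude flanks and the stop codon
            if rng.random() < spec.lof_fraction:
                pos = int(rng.integers(1, n_coding + 1))
                ref = flanked[pos]
                alt = rng.choice(alt_choices[ref])
                cls = "frameshift" if rng.random() < 0.7 else "splice_site"
                rows.append((g, s, cls, ref, alt, pos, flanked[pos - 1:pos + 2]))
                continue
            force_nonsyn = g in hyper_set and rng.random() < spec.hyper_nonsyn_prob
            for _ in range(12):
                pos = int(rng.integers(1, n_coding + 1))
                ref = flanked[pos]
                alt = rng.choice(alt_choices[ref], p=pref[t][ref])
                codon_i = (pos - 1) // 3
                codon = flanked[1 + 3 * codon_i: 4 + 3 * codon_i]
                cls = _classify(codon, (pos - 1) % 3, alt)
                if not force_nonsyn or cls in ("missense", "nonsense"):
                    break
            rows.append((g, s, cls, ref, alt, pos, flanked[pos - 1:pos + 2]))

    records = pd.DataFrame(
        rows, columns=["gene", "sample", "variant_class", "ref", "alt", "cds_pos", "context"])
    return MutationTable(records)


# ---------------------------------------------------------------------------
# hand-enumerable codon fixture

def generate_codon_fixture() -> tuple[dict[str, str], MutationTable]:
    """A 3-gene toy CDS plus a mutation list covering every variant class.

    FIX1 holds a lone ATG codon (every single-base change is
    non-synonymous); FIX2 a lone CTG leucine codon (4 synonymous / 5
    non-synonymous changes); FIX3 two codons hit by missense, silent,
    nonsense and frameshift events across four samples.
    """
    cds = {
        "FIX1": "T" + "ATG" + "TAA" + "G",
        "FIX2": "A" + "CTG" + "TAA" + "C",
        "FIX3": "G" + "AAA" + "TTA" + "TAA" + "T",
    }
    rows = [
        # gene, sample, class, ref, alt, cds_pos, context
        ("FIX3", "X1", "missense", "A", "C", 1, "GAA"),   # AAA -> CAA (K -> Q)
        ("FIX3", "X2", "silent", "A", "G", 3, "AAT"),     # AAA -> AAG (K)
        ("FIX3", "X3", "nonsense", "T", "G", 5, "TTA"),   # TTA -> TGA (stop)
        ("FIX3", "X4", "frameshift", "T", "A", 4, "ATT"),
        ("FIX1", "X1", "missense", "A", "G", 1, "TAT"),   # ATG -> GTG (M -> V)
        ("FIX2", "X2", "silent", "G", "A", 3, "TGT"),     # CTG -> CTA (L)
    ]
    records = pd.DataFrame(
        rows, columns=["gene", "sample", "variant_class", "ref", "alt", "cds_pos", "context"])
    return cds, MutationTable(records)
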