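"""End-to-end orchestration of the marker-discovery pipeline.

Stages run in dependency order: simulate (or load) -> preprocess -> mutation
correction -> leukocyte-fraction correction -> genome survival screens ->
pathway specificity -> RSF prioritization and candidate-gene intersection ->
survival-status classifier -> patient stratification -> SNP association.
Every stage records row counts and outputs into a manifest; a fixed seed
makes the run reproducible end to end (the per-stage seeds derive from the
run seed by name, so stages can be rerun in isolation).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import gsea, leukocorrect, mutcorrect, preprocess, selection, snps, stratify
from .cohort import CohortData, CohortSpec, generate_cohort
from .config import RunConfig, child_seed
from .io import GenotypeMatrix
from .survival import SurvivalSpec, screen_genome


@dataclass
class PipelineScale:
    """Computation sizes of the expensive stages.

    Defaults are the full study settings; tests and desk runs shrink them.
    """

    n_perm_gsea: int = 1000
    rsf_trees: int = 1000
    rsf_null: int = 100
    panel_sizes: tuple[int, ...] = (64, 50, 40, 30, 20, 10)
    k_groups: int = 3
    n_shuffle_snp: int = 1000
    max_panel: int = 64


@dataclass
class RunManifest:
    seed: int
    stages: dict = field(default_factory=dict)
    timing: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def record(self, stage: str, elapsed: float, **info) -> None:
        self.stages[stage] = info
        self.timing[stage] = round(elapsed, 3)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True, default=str)


@dataclass
class PipelineResult:
    manifest: RunManifest
    data: CohortData
    normalized: object
    corrected: dict
    rankings: dict
    specificity: dict
    candidates: pd.DataFrame
    panel: list[str]
    metrics: list
    contrast: object
    snp_results: dict


def run_pipeline(config: RunConfig, cohort_spec: CohortSpec | None = None,
                 data: CohortData | None = None, scale: PipelineScale | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Execute the full pipeline on simulated or provided data."""
    scale = scale or PipelineScale()
    manifest = RunManifest(seed=config.seed)

    # ---- data ---------------------------------------------------------------
    t0 = time.perf_counter()
    if data is None:
        if cohort_spec is None:
            raise ValueError("provide either a CohortSpec or a CohortData bundle")
        cohort_spec.seed = child_seed(config.seed, "simulate")
        data = generate_cohort(cohort_spec)
    manifest.record("simulate", time.perf_counter() - t0,
                    n_samples=int(len(data.clinical)),
                    n_genes=int(len(data.expression.gene_ids)),
                    n_mutations=int(len(data.mutations)))

    # ---- preprocess ---------------------------------------------------------
    t0 = time.perf_counter()
    m = preprocess.impute_by_cancer_type(data.expression, data.clinical)
    m = preprocess.filter_low_expression(m)
    norm = preprocess.log2_quantile_normalize(m)
    manifest.record("preprocess", time.perf_counter() - t0,
                    n_genes_retained=int(len(norm.gene_ids)))

    # ---- mutation correction ------------------------------------------------
    t0 = time.perf_counter()
    freqs = mutcorrect.build_category_frequencies(data.mutations, data.clinical)
    cds = {g: s for g, s in data.cds.items() if g in set(norm.gene_ids)}
    backgrounds = {t: mutcorrect.compute_codon_background(cds, freqs, t)
                   for t in freqs.freqs}
    counts = mutcorrect.count_mutations(data.mutations, data.clinical)
    dnds = mutcorrect.compute_dnds(counts, backgrounds)
    sig_genes = mutcorrect.call_significant_genes(dnds)
    idx = mutcorrect.compute_codon_indexes(data.mutations, freqs, sig_genes)
    scores, corrected_mut = mutcorrect.score_and_correct(norm, idx, data.mutations, sig_genes)
    manifest.record("mutation_correction", time.perf_counter() - t0,
                    n_significant_genes=int(len(sig_genes)),
                    n_indexed_codons=int(len(idx.table)))

    # ---- leukocyte-fraction correction --------------------------------------
    t0 = time.perf_counter()
    sel = leukocorrect.select_immune_genes(norm, data.fractions,
                                           cutoff=config.thresholds["corr_cutoff"])
    immune = set(sel.index[sel["selected"]])
    corrected_frac = leukocorrect.correct_by_fraction(norm, data.fractions, immune)
    manifest.record("fraction_correction", time.perf_counter() - t0,
                    n_immune_genes=int(len(immune)))

    # ---- genome survival screens --------------------------------------------
    t0 = time.perf_counter()
    sspec = SurvivalSpec(cap_years=config.survival_cap_years_screen)
    corrected = {"mutation": corrected_mut, "fraction": corrected_frac}
    rankings = {name: screen_genome(c, data.clinical, sspec)
                for name, c in corrected.items()}
    manifest.record("survival_screen", time.perf_counter() - t0,
                    n_genes_ranked=int(len(rankings["mutation"]["high_better"].table)))

    # ---- pathway specificity -------------------------------------------------
    t0 = time.perf_counter()
    specificity = {}
    for name, c in corrected.items():
        specificity[name] = gsea.specificity_test(
            c, data.clinical, data.pathways, sspec,
            B=config.n_specificity_resamples, n_perm_gsea=scale.n_perm_gsea,
            seed=np.random.default_rng(child_seed(config.seed, f"specificity_{name}")),
        )
    manifest.record("specificity", time.perf_counter() - t0,
                    n_specific={k: int(v.table["specific"].sum())
                                for k, v in specificity.items()})

    # ---- RSF prioritization and candidate genes ------------------------------
    t0 = time.perf_counter()
    immuno_clin = data.clinical[data.clinical["treatment_class"] == "immunotherapy"]
    importances = {}
    for name, c in corrected.items():
        tab = specificity[name].table
        chosen = list(tab.loc[tab["specific"], "pathway"])
        if len(chosen) < 2:  # pad with the most immunotherapy-specific pathways
            extra = tab.sort_values(["percentile", "p_observed"])["pathway"]
            chosen = list(dict.fromkeys(chosen + list(extra[:5])))
        sub_db = type(data.pathways)({p: data.pathways.sets[p] for p in chosen})
        imm_expr = c.with_values(
            c.values[[s for s in immuno_clin["sample_id"] if s in c.sample_ids]], c.stage)
        feats = gsea.ssgsea_matrix(imm_expr, sub_db)
        importances[name] = selection.rsf_rank(
            feats, immuno_clin, cap_years=config.survival_cap_years_model,
            n_null=scale.rsf_null, n_trees=scale.rsf_trees,
            alpha=config.thresholds["rsf_p"],
            seed=child_seed(config.seed, f"rsf_{name}"))
    both = {name: rankings[name]["high_better"] for name in corrected}
    candidates = selection.intersect_and_pick_genes(
        importances["mutation"], importances["fraction"], both, data.pathways,
        gene_p=config.thresholds["gene_p"], keep_top=2)
    panel = list(candidates["gene"][:scale.max_panel])
    manifest.record("selection", time.perf_counter() - t0,
                    n_candidates=int(len(candidates)), panel=panel)

    # ---- classifier ----------------------------------------------------------
    t0 = time.perf_counter()
    metrics = []
    if len(panel) >= 2:
        sizes = tuple(s for s in scale.panel_sizes if s <= len(panel))
        if len(panel) not in sizes:
            sizes = (len(panel),) + sizes
        metrics = selection.train_eval_elastic_net(
            norm, immuno_clin, panel, panel_sizes=sizes,
            n_val=config.n_validation_sets,
            seed=child_seed(config.seed, "model"))
    manifest.record("model", time.perf_counter() - t0,
                    metrics=[asdict(m) for m in metrics])

    # ---- stratification -------------------------------------------------------
    t0 = time.perf_counter()
    contrast = None
    if len(panel) >= 2:
        groups = stratify.group_by_panel_score(norm, panel, data.clinical,
                                               k=scale.k_groups)
        contrast = stratify.group_survival_contrast(
            groups, data.clinical, cap_years=config.survival_cap_years_screen,
            n_resample=config.n_cluster_resamples,
            seed=np.random.default_rng(child_seed(config.seed, "stratify")))
        manifest.record("stratification", time.perf_counter() - t0,
                        immuno_p=contrast.immuno_p,
                        control_median_p=contrast.control_median_p)
    else:
        manifest.record("stratification", time.perf_counter() - t0, skipped=True)

    # ---- SNP association -------------------------------------------------------
    t0 = time.perf_counter()
    snp_results = {}
    if panel:
        panel_coords = data.genotypes.gene_coords.loc[
            [g for g in panel if g in data.genotypes.gene_coords.index]]
        geno_panel = GenotypeMatrix(data.genotypes.dosages, data.genotypes.snp_coords,
                                    panel_coords)
        filtered = snps.filter_snps(geno_panel, maf_min=config.thresholds["maf"])
        labels = selection.one_year_labels(immuno_clin)
        if len(filtered.dosages.columns) and labels.nunique() == 2:
            assoc = snps.associate_snps(
                filtered, labels, n_shuffle=scale.n_shuffle_snp,
                seed=np.random.default_rng(child_seed(config.seed, "snp")))
            pairs = snps.snp_gene_pairs(filtered, panel)
            eqtl = snps.snp_expression_correlation(
                filtered, norm, pairs, n_perm=scale.n_shuffle_snp,
                seed=np.random.default_rng(child_seed(config.seed, "eqtl")))
            snp_results = {"association": assoc, "eqtl": eqtl}
            manifest.record("snp_association", time.perf_counter() - t0,
                            n_snps_tested=int(len(assoc.table)),
                            n_significant=int(assoc.table["significant"].sum()),
                            n_eqtl=int(eqtl.table["eqtl"].sum()))
        else:
            manifest.record("snp_association", time.perf_counter() - t0, skipped=True)
    else:
        manifest.record("snp_association", time.perf_counter() - t0, skipped=True)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest.to_json(outdir / "manifest.json")
        candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    return PipelineResult(manifest, data, norm, corrected, rankings, specificity,
                          candidates, panel, metrics, contrast, snp_results)
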