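# Methods

This note documents the models, conventions and parameter choices behind
`ipmg`, in the order the pipeline runs them, together with what the synthetic
cohort does and does not emulate.

## Expression preparation

Missing values are imputed with the gene's mean within the sample's cancer
type (global gene mean when a type is entirely missing; a gene with no
observed value anywhere is an error). Genes below an expression floor of 1 in
every sample are removed. The table is then transformed as log2(x + 1) — the
+1 offset avoids −∞ at zero counts — and quantile normalized: each sample's
values are replaced by the cross-sample mean of sorted values at the matching
rank, ties receiving the mean of their whole rank block (the dominant
convention). After normalization every sample shares one value distribution
to ≈1e-12.

## Mutation correction

Substitution categories are keyed by (5′ base, ref, alt, 3′ base) over all 12
ref→alt pairs × 16 contexts — 192 keys. A strand-collapsed 96-key view
(pyrimidine reference) is available behind a flag but is not the default; the
collapsed frequency of a key equals the sum of its two strand orientations.
Per cancer type, category frequencies are the observed SNV counts per
category over total SNVs; SNV records without a resolvable trinucleotide
context are excluded from frequency counting but still count toward the
per-gene mutation totals.

For each codon the 9 single-base changes are classified
synonymous/non-synonymous with the standard codon table; changes creating a
stop codon count as non-synonymous, and a trailing stop codon is excluded
from the codon list. Frequencies accumulate into per-codon n_i, s_i and
per-gene N_j, S_j. The regularized ratio dN/dS = (C/N + 1)/(C′/S + 1) is
computed per gene and cancer type; genes whose synonymous background is zero
(e.g. a CDS of only Met/Trp codons) are excluded. Significance is a one-sided
binomial test of C non-synonymous events in C + C′ trials against
p₀ = N/(N + S), per cancer type; the significant set is the union over types
of genes with p < 0.05 **and** dN/dS > 1.

Codon rarity indexes I = r/T use the sample-weighted pan-cancer frequency of
the observed category (event-weighted mean when several categories hit one
codon) over the codon's pan-cancer non-synonymous recurrence. Scaling to
[0, 1] is min–max over **all** tabulated codons (per-gene scaling available
behind a flag); if all raw indexes are equal every scaled index is 1, and a
single tabulated codon maps to 1. Activity scores multiply the scaled indexes
of a sample's non-synonymously mutated codons; frameshift and splice-site
events force 0; nonsense SNVs count as non-synonymous but do not force 0.
Scores multiply the log-scale normalized expression — a literal reading of
"score × expression value", documented as a modeling choice. Only
significantly mutated genes are corrected; all others pass through with
score 1.

## Leukocyte-fraction correction

Immune-related genes satisfy Pearson r ≥ 0.3 against leukocyte fraction and
r ≤ −0.3 against tumor purity across all samples (one symmetric cutoff;
zero-variance genes are excluded). Their normalized expression is divided by
max(fraction, 0.01); the floor prevents unbounded inflation at near-zero
fractions. Division acts on the normalized (log-scale) table by default.

## Survival screen

Follow-up is administratively censored at 3 years (365-day years). Per gene,
the top and bottom floor(0.3·n) samples of each cancer type (minimum 1;
expression ties broken by sample id; types with fewer than 4 samples skipped)
are pooled into high/low groups and compared by the log-rank test, computed
by an in-package vectorized routine that handles per-gene group membership
for the whole genome in one pass; it agrees with lifelines to 1e-6. The
one-tailed p halves the chi-square p when the observed direction (sign of
observed − expected deaths in the high group) matches the hypothesis and
complements it otherwise, so p(high_better) + p(high_worse) = 1 for
informative genes; degenerate genes (empty group, no events) receive p = 1 in
both directions. Two ranked lists (ascending p, ties by gene id) are emitted.

## Pathway enrichment and immunotherapy specificity

Pre-ranked GSEA uses the weighted Kolmogorov–Smirnov running sum on the
statistic −log10(p), weight exponent 1: hits add |stat|/Σ|stat|, misses
subtract 1/(N−K); the ES is the deviation of maximum magnitude (ties resolve
to the positive side). Significance comes from random same-size gene sets:
p = (1 + #{null ES ≥ obs})/(1 + n_perm), never 0; the null for each set size
is computed once per ranking and shared across pathways of that size. A
continuous refinement `p_norm` — the normal upper-tail of the ES z-scored
against the random-set null — accompanies the Monte-Carlo p; it exists
because the specificity test compares p-values *across different rankings*,
where strong enrichments saturate the Monte-Carlo floor and become
incomparable.

The specificity test draws B cohorts of non-immunotherapy patients of the
same size as the immunotherapy cohort (without replacement,
cancer-type-unconstrained), reruns the genome screen once per resample (not
per pathway), and re-scores every pathway; a pathway is specific when its
observed `p_norm` lies below the 5th percentile of its own B-sized null.
Because all resamples are drawn from one fixed control cohort, the null
p-values are correlated across resamples; the realized false-flag rate on
null pathways runs slightly above the nominal 5% (≈6–8% at desk scale),
which is inherent to the resampling design rather than to the implementation.
The study setting is B = 1000; the test suite uses B = 200.

The quantile–quantile construction compares, per pathway, (1) the sorted
survival p-values of its genes on the immunotherapy ranking against (2) the
per-position 95th quantile of size-matched random gene draws from the same
ranking and (3) the per-position 95th quantile of the pathway's p-values
across the non-immunotherapy resample screens.

## Prioritization, classification, stratification, SNPs

ssGSEA scores each patient with the rank-weighted ECDF difference, exponent
α = 0.25, no per-sample range normalization by default; the score depends on
within-sample ranks only (ties broken by gene id), so it is invariant to
monotone transforms. Pathway features feed a random survival forest
(log-rank splitting, √p features per split, 1000 trees at study scale;
survival capped at 1 year) whose permutation importance (mean concordance
drop over feature shuffles) gets an Altmann-style p-value from
response-permuted refits; p < 0.05 selects. Pathways selected under both
corrections are intersected — each branch always contributes at least its
top-ranked pathway so a single noisy importance p cannot empty the
intersection — and member genes with screen p < 0.05 under either correction
become candidate IPMGs, ordered by their best p.

The classifier predicts 1-year status (deceased = event ≤ 365 d; alive =
followed ≥ 365 d; earlier-censored patients carry no label) from the
normalized, uncorrected expression of the top panel genes: a 2/3–1/3
stratified split, per-feature standardization, SMOTE balancing of the
training set (synthetic minority points x + u·(x_nn − x), u ~ U(0,1), k = 5
neighbors), and elastic-net logistic regression (l1_ratio 0.5, penalty by
internal 5-fold CV maximizing AUC). Evaluation averages accuracy,
sensitivity, specificity and AUC over balanced validation subsets (all
deceased plus equal-size random draws of alive patients; 1000 at study
scale).

Stratification ranks all patients by panel ssGSEA score and cuts at the
scores that split immunotherapy patients into k equal blocks (±1, larger
blocks first; k = 3 default). The contrast compares the k-group log-rank
among immunotherapy patients (lifelines) with resamples drawing, per group,
as many non-immunotherapy patients as the group holds immunotherapy patients.
The two extreme groups (highest/lowest 3-year Kaplan–Meier survival among
immunotherapy patients) are contrasted by a one-tailed Mann–Whitney test per
gene (zero-variance genes p = 1) and the ranking fed to pre-ranked GSEA.

SNPs are restricted to gene body ± 100 kb of the candidate genes and minor
allele frequency ≥ 5% (allele count over 2n, folded). Association is the
single-marker score test of the binary label on additive dosage — equivalent
to the trend test, and within 10% of the logistic likelihood-ratio p at
n ≥ 100 — with a per-SNP cutoff at the 5th percentile of the p-values from
1000 genotype shuffles; significance requires p < 0.05 and p < cutoff. The
expression step applies the same logic to the Pearson correlation between
dosage and the nearby candidate gene (eQTL: r > 0.2, p < 0.05, below the
cutoff). No kinship or population-structure correction is applied: the
synthetic cohort has none, and the permutation cutoff is the operative
control.

## The synthetic cohort

Defaults: 6 cancer types × 100 samples, 15% immunotherapy-treated (90 vs 510
— the screen runs at the study's ~100-patient immunotherapy scale while the
control pool stays several times larger, which the resampling null needs),
1500 genes, 60 pathways of 25 genes, 20–40-codon stop-free CDS per gene,
per-sample SNV burden Poisson(40–60), 80 SNPs.

Survival is exponential with multiplicative effects and uniform censoring on
[0, 5] years (baseline median 1.5 y; per-type frailty sd 0.2), so marginals
have closed forms. Two latent factors drive the planted structure: a
responsiveness factor z lowers the hazard of immunotherapy-treated samples
only, and a general-prognosis factor w lowers everyone's hazard. The 25 genes
of the planted specific pathway load on z (correlation 0.85), the general
pathway's genes on w; the per-latent hazard coefficient is
ln(HR)/(2·1.0911·ρ), calibrated so a planted gene's top-vs-bottom expression
tertile shows approximately the stated hazard ratio (default 12 — the
strong-biomarker regime the method is designed to detect, and the smallest
round value at which the 1-year outcome retains enough signal above its
intrinsic Bernoulli noise for a ~0.85-AUC panel at 90 immunotherapy
patients). The causal SNP acts **through** z (per-allele shift
snp_log_odds/β, default log-hazard 1.75/allele): its survival effect is
therefore observable via the panel genes, and its eQTL correlation with the
neighboring planted gene (r ≈ 0.5) emerges from the same channel rather than
being painted on. Immune genes track the leukocyte fraction (target r 0.6;
fraction ~ Beta(2,5), purity = 1 − fraction − stroma). Hypermutated genes
receive 12× the background mutation rate with 95% of events forced
non-synonymous — large enough that the per-type binomial test can see them at
desk scale; mutation alt-alleles follow per-type Dirichlet preferences so
per-type category backgrounds genuinely differ; 3% of events are
frameshift/splice. Variant classes are derived from the actual codon change,
so the dN/dS machinery sees internally consistent data.

What the generator does **not** emulate: gene–gene co-expression beyond the
planted one-factor blocks, copy-number/methylation layers, population
structure in genotypes, batch effects, and realistic mutational-signature
mixtures (categories are Dirichlet-random, not COSMIC-like). Passing tests
demonstrate that the machinery recovers planted effects under the stated
generative model — not that the biological findings of any real cohort would
replicate.

## Numerical and engineering choices

All randomness flows from one seed; pipeline stages derive child seeds from
the run seed via named SeedSequence spawn keys, so stages can be rerun in
isolation and a rerun is byte-identical. Monte-Carlo p-values use the +1/+1
estimator everywhere. Desk-scale problem sizes used by the test suite and the
acceptance script (B = 100–200 specificity resamples, 300–500 stratification
resamples, 200 validation draws, 50–150 trees, 59 response-permutation
refits — with 59 nulls the p < 0.05 selection rate is exactly 3/60 = 0.05
under exchangeability) are the package's chosen desk defaults; the
corresponding study-scale constants (1000/5000/1000) remain the `RunConfig`
defaults.

Known limitations: the external-cohort transfer of the classifier is
exercised only against a second synthetic cohort; the RSF importance p-value
is granular at small null counts; and the specificity test inherits the
correlated-resample inflation described above.
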