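# Methods

This note documents the statistical model behind `reversal-scan`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter.

## Problem setting

Two GWAS summary-statistics tables describe the same phenotype (low bone
mineral density) in two strata of one population — premenopausal and
postmenopausal women — optionally on two genotyping platforms with
different variant coverage. Only summary data are handled: per variant, the
SNP id, chromosome, position, effect and other allele, β, SE, minor allele
frequency, sample size, association p-value, and optionally a
Hardy–Weinberg p. The question is which variant-level signals keep their
direction of effect across the menopausal transition (stable), which invert
it (reversal), and whether those classes converge on reproducible pathways.

## Variant QC

Per stratum, variants are removed in a fixed order (first failing rule is
the one reported): MAF < 0.01; HWE p < 1e-6 (a missing HWE column passes);
SE > 1; |β| > 2. On the shared-id set, variants with p ≥ 0.05 in *both*
strata are removed once — this joint screen cannot be evaluated per
stratum, so it lives in QC and is not re-applied later. The QC report
partitions every removal by rule, and retained + removed reconciles with
the input count.

## Allele harmonization

The premenopausal table is the coding reference. For each shared id:

* identical allele pair → copied through;
* swapped pair (post effect allele = pre other allele) → β_post := −β_post,
  SE and p kept, and the post effect-allele frequency re-oriented as
  maf := 1 − maf so downstream LD orientation stays coherent. The input
  `maf` column is a minor-allele frequency (coding-invariant, ≤ 0.5); the
  harmonized `maf_post` is an aligned effect-allele frequency and may
  exceed 0.5;
* palindromic pairs (A/T, C/G) are strand-ambiguous: dropped under the
  default `drop` policy. Under `maf_rescue` they are retained only when
  both strata report MAF < 0.4 (the conventional palindromic-rescue cutoff,
  at which allele frequency identifies the minor allele in both strata),
  and non-palindromic pairs are additionally compared after strand
  complementation;
* anything else is an allele mismatch and is dropped.

Only ids present in both strata are emitted. Harmonization is an involution
fixed point: artificially swapping the coding of every post record and
re-running reproduces the same pairs (only the `flipped` bookkeeping bit
inverts), and re-harmonizing already-harmonized data changes nothing.

## Heterogeneity test and classification

For each harmonized pair, Z = (β_pre − β_post)/√(SE_pre² + SE_post²) and
P_het = 2(1 − Φ(|Z|)), computed through the normal survival function so the
far tail keeps relative precision. The classifier then applies, in order:

1. no nominal association (p ≥ α_nom in both strata) → excluded;
2. P_het < α_het, β_pre·β_post < 0, max(|β|) ≥ b_min → **reversal**;
3. p < α_nom in both and P_het ≥ α_het → **stable**;
4. otherwise excluded with a reason code: `negligible_beta` (discordant,
   heterogeneous, but both |β| < b_min), `het_but_same_sign`,
   `discordant_no_het`, or `concordant_one_nominal` (concordant, nominal in
   exactly one stratum, no heterogeneity). The last code covers a case the
   classification rules do not otherwise assign; making it explicit keeps
   the label partition auditable.

Defaults α_het = α_nom = 0.05 and b_min = 0.1 (all configurable). The |β|
floor is enforced only for the reversal call. These are screening
thresholds, not genome-wide significance levels.

Two properties worth knowing:

* **Scale consistency.** Z and P_het are invariant under a common positive
  rescaling of all β and SE; only the |β| ≥ b_min clause is scale-dependent.
* **Selection inflation.** Among true-null variants that reach nominal
  association in one stratum, the conditional probability of P_het < 0.05
  is far above 0.05: selecting on |β̂_pre| > 1.96·SE inflates
  |β̂_pre − β̂_post|. With SE ≈ 0.05 (where 1.96·SE ≈ b_min) roughly 15–20%
  of such selected nulls satisfy the full reversal rule. The reversal class
  should therefore be read as enriched for, not equal to, true
  direction-reversing effects — a property of the classification rule
  itself that the synthetic truth tables make measurable.

## Gene-stage input

Each reversal or stable variant contributes p = min(p_pre, p_post), with
the sample size taken from the stratum contributing the minimum (ties go to
the pre stratum, the harmonization reference). The same rule drives the
MAGMA-compatible exports (SNP-location and p-value files), so the gene
stage can also be reproduced with external gene-based tools.

## Gene-level test

SNPs map to genes positionally (1-based inclusive gene bodies, optional
symmetric window, default 0 bp — the windowless convention of gene-based
association tools; a SNP may map to several overlapping genes). For a gene
with m SNPs the statistic is T = (1/m)·Σ Q_χ²₁(1 − pᵢ), with p floored at
1e-300 before the quantile transform as an overflow guard.

Under the null, m·T ~ Σ λᵢ·χ²₁ where λᵢ are the eigenvalues of the SNPs' LD
correlation matrix R. R is the pairwise-complete Pearson correlation of
panel dosages, symmetrized, regularized to the nearest positive
semidefinite matrix by clipping negative eigenvalues at zero and restoring
the unit diagonal. SNPs absent from the panel (or monomorphic in it) are
kept and treated as independent (r = 0, unit eigenvalue) with a logged
count — dropping them would silently change m.

The tail probability P(m·T_null ≥ m·T) is evaluated by Imhof's inversion
integral. The integrand oscillates as sin(φ(u) − qu/2) with φ saturating at
mπ/4, so the head of the integral is computed by adaptive quadrature and
the tail as two QUADPACK Fourier (QAWF) integrals; this reaches ~1e-10
absolute accuracy (verified to 1e-12 against the no-LD closed form, where
the mean of m independent χ²₁ is Gamma(m/2, 2/m)). Below p ≈ 1e-8 —
beyond the quadrature's absolute resolution — a Lugannani–Rice saddlepoint
tail takes over (relative error a few percent arbitrarily far into the
tail, and strictly monotone in T). If the quadrature reports an
untrustworthy error estimate, a seeded Monte Carlo fallback with
`mc_draws` (default 100,000) multivariate-normal draws z ~ N(0, R) is used
and reported as `method=montecarlo`. Single-SNP genes short-circuit to the
SNP's own p-value. Genes with p < 0.05 are flagged retained for enrichment,
mirroring the nominal retention rule of the gene stage.

## Enrichment and cross-platform convergence

Over-representation is the one-sided hypergeometric upper tail (one-sided
Fisher exact test) of the overlap between the retained gene list and each
GMT set, restricted to a stated universe. The default universe is
platform-aware: all genes with at least one mapped SNP on that platform.
Exome arrays cover a restricted gene space, and an all-genome background
would overstate enrichment. Sets are kept when their universe-restricted
size lies in [3, 500]; Benjamini–Hochberg adjustment runs across the tested
sets. Rows sort by raw p, ties by set id, so output is order-deterministic.

The cross-platform step intersects pathways significant on both platforms.
The default criterion is the raw p-value at α = 0.05 — an exploratory
choice appropriate for small retained-gene lists — with the BH-adjusted
criterion available. Output carries both platforms' p-values and overlap
gene lists. A user-supplied gene→category mapping produces functional
category counts (unmapped genes fall to "Other"; the first mapping wins on
conflict).

## Synthetic-data generator

The generator is the package's stand-in for restricted cohort data and
defines the conditions all statistical tests run under.

* **Variant layout**: `n_genes` genes (default 400) with 3–7 SNPs each at
  1 kb spacing, cycled over chromosomes 1–22; MAF ~ U(0.05, 0.5).
* **Effects**: a variant is reversal (default 15%: β_pre = ±0.5,
  β_post = ∓0.5), stable (15%: shared β = ±0.5), null (60%), or one-sided
  (remainder: effect in a single stratum). Cohort sizes default to 1,500
  (pre) and 2,200 (post); SE = se_scale/√(2·maf·(1−maf)·N) ≈ 0.04–0.08, so
  planted single-variant power is essentially complete.
* **Internal consistency**: β̂ = β + N(0, SE) and p is the two-sided Wald
  p of β̂/SE — the QC filters implicitly assume β, SE, p cohere.
* **Coding noise**: 30% of post records have swapped allele coding (with
  β̂ negated) that harmonization must undo; 10% of variants carry
  palindromic allele pairs.
* **LD**: per gene, a latent Gaussian AR(1) process (ρ = 0.5 by default)
  thresholded at Hardy–Weinberg genotype-frequency quantiles yields the
  0/1/2 reference panel; genes are independent. On the genotype scale the
  adjacent-variant correlation attenuates to roughly ρ² of the latent
  value.
* **Two platforms**: platform 2 draws a 70% variant subset with freshly
  sampled noise over the same true effects — limited SNP-level overlap with
  preserved gene/pathway signal.
* **Gene sets**: ten random sets plus one planted set composed of the
  reversal-hosting genes (plus two decoys), so end-to-end pathway recovery
  is checkable.

Fixed seed ⇒ byte-identical output files; all substreams derive from the
single config seed.

What the generator does **not** emulate: genome-realistic allele-frequency
spectra or array manifests, cross-gene LD, population stratification,
sample overlap between strata (effects are drawn independently, as the
heterogeneity test assumes), imputation uncertainty, or indels. Passing
tests therefore validate the statistical machinery under the model's own
assumptions — not robustness to confounding present in real cohort data.

## Numerical and design choices

* Positions are 1-based inclusive throughout; no half-open intervals.
* Alleles are upper-cased on read; multi-character (indel) alleles are
  dropped rows — the strand-ambiguity logic is defined only for single
  nucleotides.
* Quadrature tolerance 1e-8 absolute on the tail; Monte Carlo p-values use
  the add-one estimator (k+1)/(n+1) so they are never exactly zero.
* min-p ties between strata resolve to the pre stratum, matching the
  harmonization reference.
* The pipeline is deterministic given (inputs, config, seed): result
  tables from two identical runs are byte-identical.

## Known limitations

* The mean-of-chi-squared model is the only gene model (no top-SNP
  variant, no conditional analysis); the annotation window defaults to 0.
* Gene Ontology-style term redundancy is not trimmed; closely related sets
  will co-appear in enrichment output.
* The reversal class inherits the selection-inflation property described
  above; interpreting reversal calls at a single variant requires caution.
* The enrichment universe is the mapped-gene background, not a
  whole-genome one; with very few retained genes the hypergeometric test
  is exploratory at best.
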