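# Methods

`cistrans` integrates somatic copy-number alterations (SCNAs, or any other
binary (epi-)DNA event) with paired gene-expression profiles to prioritize
candidate driver genes.  This note documents the statistical model, the
defaults and the numerical choices, in the package's own terms.

## Model and procedure

For each alteration the samples split into an altered (status = 1) and an
unaltered (status = 0) group.  Genes inside the alteration's wide-peak
boundaries are *cis* genes; all other expressed genes are *trans* genes.
The pipeline has four stages.

**1. Binarization.** GISTIC-style continuous amplitudes `t` are binarized at
a threshold θ (default 0.1): amplifications are altered iff `t > θ`,
deletions iff `t < −θ`.  The boundary value is *not* altered (strict
inequality).  A sample changed in the opposite direction of the peak (e.g.
deleted at an amplification peak) falls into the 0 group.  Alterations whose
status is constant, or leaves fewer than two samples in a group, are
excluded from all statistical steps and listed in the run log.

**2. Differential expression.** Every gene is tested with a pooled-variance
two-sample t-test on log2 expression; `log2fc` is the altered-minus-unaltered
mean difference and `fold_change = 2^|log2fc|`.  With moderation on (the
default) the gene-wise variances within one (alteration, role) family are
shrunk toward an empirical-Bayes prior: sample variances are modelled as
scaled-F deviates around a prior variance s₀² with prior degrees of freedom
d₀, both estimated by moment matching on log-variances (the trigamma-based
fit used by the standard moderated-t methodology); the posterior variance
`(d₀·s₀² + d·s²)/(d₀ + d)` replaces `s²` and the residual degrees of freedom
increase by d₀.  One test cross-checks this implementation against the
Bioconductor `limma` reference via `Rscript`.

Cis genes use a one-sided p in the direction expected from gene dosage (up
for amplifications, down for deletions); trans genes use the two-sided p,
since downstream effects can be activating or repressive.  Benjamini–
Hochberg FDR is computed within each (alteration, role) family.  Defaults:
cis significance requires fold change > 1.2 and FDR < 0.25; trans requires
fold change > 1.5 and FDR < 0.01.  The trans FDR ceiling is exposed as
`trans_fdr_max` for analyses preferring a more lenient 0.1.

**3. Mediation.** For each (alteration, significant cis gene i, significant
trans gene j) triplet, three OLS fits are made on the n samples:

    trans ~ 1 + status            →  τ   (total effect)
    trans ~ 1 + status + cis      →  τ′  (direct effect), b̂ (cis coefficient)
    cis   ~ 1 + status            →  â

The indirect (mediated) effect is Δτ = τ − τ′, which for nested OLS equals
â·b̂ exactly — this identity is asserted to 1e-9 in the tests and doubles as
an internal consistency check of all three regressions.  Its first-order
(Sobel) standard error is `SE = sqrt(b̂²·SE(â)² + â²·SE(b̂)²)` and
`z = Δτ/SE` is referred to a standard normal to obtain a two-sided p.
Triplet FDR is BH within one alteration.

Each trans gene is assigned to at most one mediator: the cis gene with the
smallest triplet FDR, ties broken by larger |Δτ| and then lexicographically
by gene id, and only if that FDR is below `assign_fdr_max` (default 0.25,
mirroring the lenient cis DE family; the choice is configurable because no
canonical value exists).  The mediation weight of an assigned pair is

    w_ij = Δτ_ij / τ_ij   clipped into [0, 1],

i.e. the fraction of the total effect that is mediated.  The ratio is signed
relative to the total effect so that full mediation yields 1 for deletions
(τ < 0, Δτ < 0) exactly as for amplifications, while indirect effects
opposing the total effect clip to 0.  A cis gene's score is the *weighted
fraction of trans mediation*

    WFTM_i = Σ_j w_ij·I_ij / m,

where I_ij marks the assignment and m counts all significant trans genes of
the alteration — including unassigned ones, so Σ_i WFTM_i ≤ 1.  The cis
gene with maximal WFTM (ties: more trans genes mediated, then gene id) is
the **Rank-1** candidate driver.  A restriction set (e.g. one pathway from a
GMT collection, `trans_restrict`) limits both the tested trans genes and the
denominator m, for targeted analyses.

**4. Annotation and validation.** Cis/trans signatures (by default their
union per alteration) are tested against GMT gene-set collections with the
hypergeometric upper tail over the expressed-gene universe (configurable;
whether to condition on expressed or all annotated genes is a judgment call
the package leaves to the user).  Subtype over-representation of alterations
and subtype concentration of pathway enrichments use one-sided Fisher tests
(FDR < 0.05).  Rank-1 calls are validated against reference driver lists
with direction-aware one-sided Fisher tests (amplification Rank-1 genes vs
oncogenes, deletion vs tumor suppressors, or combined; per database or
pooled), where a gene that is Rank-1 in any alteration counts as Rank-1 and
the universe is every significant cis gene of the run.  Dependency screens
are modelled per gene as `score = α·copy_number + β` with a one-sided test
for α < 0 (amplification-driven essentiality); enrichment of dependent genes
among Rank-1 calls is again one-sided Fisher.  Cross-cohort recurrence
orders genes by the number of cohorts in which they appear (Rank-1 list,
top-DE-cis list, or all significant cis genes); the top-DE comparator ranks
by smallest cis FDR, then largest |log2fc| — an assumption, since no
canonical ranking statistic exists for that comparator.  Per-cohort
enrichment p-values are aggregated with a one-sample Kolmogorov–Smirnov test
against Uniform[0, 1].

## Sobel-test benchmark

True-positive replicates follow the chain `Y = α₁ + β₁X + N(0, σ₁²)`,
`Z = α₂ + β₂Y + N(0, σ₂²)`; true negatives share the common cause:
`Z = α₂ + β₂X + N(0, σ₂²)`, so Y ⟂ Z | X.  Both coefficients default to
β = 0.7.  X is a balanced binary vector (the altered fraction is
configurable, default 0.5, which maximizes power).  These replicates
represent total, not partial, mediation; a partial-mediation variant can be
emulated by mixing the two systems but is not a supported configuration.

Noise levels are reported as the implied population correlation
`r = β₁·sd(X)/sqrt(β₁²·Var(X) + σ₁²)` — an exact closed form for binary X
(equivalent in expectation to smoothing empirical correlations, but
deterministic).  Performance over 1000+1000 replicates is summarized as
sensitivity (positives with p < 0.05), specificity (negatives not called)
and AUC, estimated as the Mann–Whitney probability that a positive's p-value
is smaller than a negative's, with ties credited ½ (exact, no ROC
interpolation).  Expected behavior, reproduced by the acceptance script:
AUC ≈ 1 and sensitivity ≈ 1 for r ≈ 0.7 at n = 1000; sensitivity decays with
smaller n and larger σ; specificity stays at or above the nominal 95% across
the grid, because the Sobel z is conservative when both path coefficients
are weak and asymptotically standard normal otherwise.

## Synthetic studies

`generate_synthetic_study` plants known structure so recovery can be scored
exactly.  Defaults, chosen once as a realistic desk-scale cohort: 300
samples; 2 alterations (one amplification, one deletion, altered fraction
0.5); 5 cis genes each, of which 1 is the true driver and 4 are decoys; 20
significant trans genes of which 80% are mediated through the driver
(`Z = 0.7·Y + noise`) and the rest respond to status directly; baseline
expression N(7, 1) in log2 units, cis dosage effect ±1 (two-fold), noise sd
0.5; 200 pure-noise background genes filling the universe.  Decoys carry the
same marginal association with status as the driver but independent noise,
so they are significant cis genes yet mediate nothing — the hard case for
the ranking.  With two drivers (`n_drivers=2`) the mediated trans genes are
split between them, producing the near-tied, high-entropy regime.

What the generator does *not* emulate: gene–gene correlation beyond the
planted chain, overlapping alterations on the same samples, arm-level
events, expression heteroscedasticity, batch effects and missing data.
Passing recovery tests therefore demonstrates correctness of the machinery
under the stated model, not robustness to every property of tumor cohorts.

## Bootstrap reproducibility

`bootstrap_rank1` redraws samples with replacement (size of the original
cohort; alteration definitions fixed, only sample membership resampled),
reruns differential expression and mediation, and scores each originally
predicted Rank-1 gene by its inclusion fraction — the share of resamples in
which it is Rank-1 again *for the same alteration*.  Resamples that leave an
alteration untestable reduce that alteration's denominator and are counted.
Genes that become Rank-1 only in resamples are listed separately, not
scored.  Alteration-level ambiguity is quantified by the Shannon entropy
(base 2; the base only shifts the scale) of the WFTM vector across the
alteration's significant cis genes.  Inclusion is regressed on WFTM
(expected positive slope) and on entropy (expected negative slope) with
two-sided t-tests on the slope.

## Numerical and determinism choices

* OLS uses pseudo-inverse Gram matrices; coefficient SEs from residual
  variance with the exact residual degrees of freedom (n−2 / n−3).
* `SE = 0` with `Δτ = 0` gives z = 0, p = 1; perfect separation in a
  two-group test is flagged `degenerate` (p → 0 when means differ, p = 1
  otherwise).  A cis vector collinear with status (zero residual) makes the
  full model unidentifiable; such triplets are flagged and excluded from the
  FDR family.
* Every ranking and tie-break is deterministic (stable sorts, lexicographic
  final keys), so reruns with the same configuration and seed are
  byte-identical; wall-clock timings are printed to stderr only and never
  written into output files.
* All randomness flows from a single root seed (`numpy.random.default_rng`).
* Floats in TSV outputs are written with `%.10g`.

## Problem sizes used by the test suite and acceptance script

Benchmarks run at 1000+1000 replicates (n up to 1000); planted-driver
recovery uses 20 replicate studies of the default spec; the bootstrap uses
B = 25 resamples.  These sizes give binomial standard errors well below the
margins being asserted while keeping a full run in the order of seconds.

## Known limitations

* Single-mediator assignment: a trans gene influenced by several cis genes
  is credited to one mediator only.
* The Sobel SE is first order; bootstrap or product-distribution confidence
  intervals for indirect effects are out of scope.
* Trans genes on the same chromosome arm as the alteration are not excluded;
  cis membership is consumed as given, with no coordinate arithmetic.
* Dependency validation covers amplification-driven essentiality only
  (knockdown screens cannot reveal deletion-driven dependencies).
* The moderated t assumes exchangeable gene variances within a family; no
  mean–variance trend or robust down-weighting of outlier variances.
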