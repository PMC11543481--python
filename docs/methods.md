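# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical choices that matter for reproducibility.

## Summary-statistic model and harmonization

The atom of every computation is a per-variant marginal association
(β, SE, p, effect/other allele, effect-allele frequency f, sample size n)
for one trait, for a standardized (unit-variance) trait so that
SE ≈ 1/√(2nf(1−f)).  Positions are 1-based and all windows are closed
intervals, matching GWAS-catalogue convention.  p-values are floored at
1e-300 to keep log-domain arithmetic finite, and a record whose stated
p-value disagrees with the two-sided normal tail of β/SE by more than 10%
(relative) is treated as corrupt and dropped on read.

Harmonization aligns the outcome's effect allele to the exposure's per
SNP: identical orientation is kept, swapped alleles negate the outcome β
and reflect its frequency, and a non-palindromic mismatch is retried
after complementing the outcome alleles (strand flip) before being
declared incompatible.  Palindromic SNPs (A/T, C/G) cannot be resolved by
labels; they are oriented by which side of 0.5 the two frequencies fall
on, and dropped as ambiguous when either minor-allele frequency is within
0.08 of 0.5 (window configurable) or when a frequency is missing.  The
0.08 window is standard two-sample-MR practice; the source analyses
report only that ambiguous-allele SNPs were dropped, not the rule, so the
conventional rule was adopted.  Drops are recorded with a status, never
raised.

LD matrices are read as square labelled tables, symmetrized as
(M+Mᵀ)/2, given a unit diagonal, and repaired to positive semi-definite
by flooring eigenvalues at zero (then rescaling to a correlation matrix)
whenever the smallest eigenvalue is below −1e-8.

## Instrument selection

A valid cis instrument must satisfy, in order: exposure p < 5×10⁻⁸; lie
within 1 Mb of the protein-coding gene body (closed interval around
[gene_start, gene_end] — the window is anchored on the gene body rather
than the TSS or midpoint, a choice the source description leaves open);
fall outside the MHC (chr 6, 26–34 Mb, excluded for its extreme LD);
survive harmonization; survive greedy LD clumping at r² < 0.001 (visit
order: ascending p, ties broken lexically by SNP id, so results are
deterministic and invariant to input row order); and have a single-SNP
F > 10.  Strength statistics use the standard two-sample approximation
PVE = z²/(z²+n) (equivalently 2f(1−f)β²/(2f(1−f)β² + 2f(1−f)·SE²·n)) and
F = (n−1−k)/k · r²/(1−r²) with k = 1, since instruments are filtered
per-SNP.  No PVE formula is given in the source; this is the standard
choice and reproduces the qualitative PVE–F relationship of the
application's headline table.  Regions without gene coordinates (the
role-reversed runs) skip the cis filter, with a log message.

## Causal estimation

One instrument: Wald ratio β_GY/β_GX with the first-order Delta SE
SE_GY/|β_GX| (the dominant convention; a second-order variant adding the
exposure-uncertainty term is behind a flag).  Two or more: fixed-effect
IVW with weights 1/SE_GY², algebraically identical to weighted least
squares through the origin; fixed effects are the default because
cis-only instrument sets are small, and a multiplicative random-effects
option scales the SE by max(1, residual SD).  95% CIs use the multiplier
1.959964.  The proteome-wide Bonferroni threshold divides α = 0.05 by the
total number of retained instruments across proteins (the application
divided by its 1,869 cis-pQTLs), recomputed per run; the SMR threshold
divides α by the number of MR-significant proteins, also recomputed
rather than hard-coded.

## SMR and HEIDI

SMR uses the single top cis-SNP (smallest exposure p among those with
p < 5×10⁻⁸): T_SMR = z_X²z_Y²/(z_X²+z_Y²) referred to χ²(1), with
SE_SMR = |β_SMR|/√T_SMR.  In the strong-instrument limit (SE_GX → 0) the
SMR p-value converges to the Wald-ratio p-value, which the tests assert.

HEIDI asks whether surrounding cis SNPs' Wald ratios agree with the top
SNP's.  Candidates need exposure p < 1.57×10⁻³ (χ²(1) > 10), LD with the
top SNP in 0.05 ≤ r² ≤ 0.9 — tight LD makes the ratio difference
degenerate, weak LD uninformative — capped at the 20 strongest; these
knobs follow common SMR-software defaults because the source names the
tool but not its settings.  With fewer than 3 usable candidates no
p-value is reported.  For each candidate, d_i = β_SMR(i) − β_SMR(top);
its covariance follows from the first-order Delta method under the
two-sample design (exposure and outcome estimates independent between
GWAS, correlated across SNPs through the LD correlation r_ij):

    cov(b_i, b_j) = r_ij·SE_Yi·SE_Yj/(β_Xi·β_Xj)
                  + r_ij·β_Yi·β_Yj·SE_Xi·SE_Xj/(β_Xi²·β_Xj²).

The statistic Q = Σ(d_i/SD(d_i))² is a quadratic form whose null
distribution is the eigenvalue-weighted χ² of the correlation matrix of
the standardized d.  Its tail is computed by Imhof's inversion integral,
evaluated half-period by half-period (the integrand oscillates with
asymptotic half-period 2π/q) with repeated averaging of partial sums to
accelerate the alternating tail; against exact χ² cases this is accurate
to better than 1e-9, well inside the 1e-8 design tolerance.  A plain
moment-matched χ² would misstate small HEIDI p-values and was not used.
Since every Wald ratio is invariant to that SNP's allele orientation, the
HEIDI p-value is invariant under candidate relabeling (asserted in
tests).  Following the application's convention, the pipeline treats
heidi_p ≥ 0.05 as "no evidence the signal is linkage"; absence of a
HEIDI p-value (too few candidates) does not block a protein.

## Colocalization

Per variant and trait, Wakefield's log approximate Bayes factor
labf = ½[ln(V/(V+W)) + z²W/(V+W)] with V = SE², W = prior effect
variance.  The prior effect SD is 0.15 for both (standardized,
quantitative) traits — the reference default for quantitative traits;
the source states only the configuration priors p1 = p2 = 10⁻⁴,
p12 = 10⁻⁵.  Assuming at most one causal variant per trait, the
unnormalized hypothesis weights are (1, p1·S1, p2·S2, p1·p2·(S1·S2−S12),
p12·S12) with S1 = Σbf1, S2 = Σbf2, S12 = Σbf1·bf2; the H3 subtraction
removes same-variant configurations, so a single-SNP region has exactly
zero H3 mass.  All sums run in log space via log-sum-exp, so |z| beyond
35 cannot overflow.  Variants enter by snp_id intersection after
harmonization; orientation cannot affect the posterior because labf is
even in z (asserted, not assumed).  PP.H4 ≥ 0.80 is tiered strong,
0.50–0.80 weak.

## Directionality, mediation, subgroups

The Steiger test compares instrument-explained variance on the two sides
via Fisher's z: z = (atanh|r_X| − atanh|r_Y|)/√(1/(n_X−3) + 1/(n_Y−3));
for an instrument set, the per-instrument R² are summed (clumped
instruments are nearly independent) before the comparison.  Reverse MR
reuses the forward machinery with roles exchanged.  One caveat: within a
single cis region, a truly shared causal variant instruments both traits,
so region-restricted reverse MR is structurally non-null under
colocalization; the evidence tier therefore relies on Steiger
directionality, and the reverse estimate is reported as a diagnostic.

Mediation uses the coefficient product: indirect = β₁β₂ with first-order
Delta SE √(β₁²SE₂² + β₂²SE₁²); no cross-step covariance term is needed
because the two steps come from non-overlapping two-sample fits.  The
proportion mediated is indirect/total using the pipeline's own
total-effect estimate and is reported as-is, flagged when the total is
zero or signs disagree.  The sex comparison is a bilateral Z-test,
z = (β_f − β_m)/√(SE_f² + SE_m²).

## The simulator

`simulate_region` draws marginal z-scores from the standard
summary-statistic model z ~ N(R·z_joint, R), where R is an AR(1) LD
matrix (r_ij = ρ^|i−j|), z_joint holds the joint causal z-scores
β√(2nf(1−f)), per-SNP SE = 1/√(2nf(1−f)), β = z·SE, and MAFs are uniform
on [0.05, 0.5].  Scenario defaults mirror the study setting: protein GWAS
of 33,000 effective samples (the per-protein size implied by the
application's instrument-strength table, rather than its headline cohort
size), an outcome GWAS of 426,824, a BMI-like mediator GWAS of 461,460,
50 SNPs per region, ρ = 0.8, one causal cis variant of effect 0.15 SD.
Scenarios: null (cis signal, zero outcome effect), shared causal (outcome
effect θ·β at the same variant), linkage (distinct causal variants),
reverse (signal originates in the outcome), mediation chain (mediator
effect a·β_x, outcome (ab + c′)·β_x, plus the mediator's own region for
step 2), and sex-specific strata with independent draws.  A single study
seed fans out through numpy SeedSequence spawn keys per protein and per
trait, so adding a protein never perturbs another protein's draws and
identical seeds give byte-identical files.

What the simulator does **not** emulate: sample overlap between exposure
and outcome GWAS, non-AR(1) LD, allele-frequency mismatch between
panels, strand errors, population stratification, case-control traits,
or trans effects.  Passing operating-characteristic tests therefore
demonstrates internal statistical correctness under the stated model,
not robustness to those real-data pathologies.

## Problem sizes and numerical choices

Simulation-based checks use 500 replicates for IVW coverage, 100 per
colocalization scenario, 200 per HEIDI scenario, 20 seeds × 50 proteins
for the all-null family-wise error, and 200 replicates of the mediation
chain — sizes at which Monte-Carlo error is small relative to each
acceptance band while the whole suite stays interactive.  The IVW
coverage and mediation scenarios use three causal variants in weak LD
(ρ = 0.3) so that clumping retains a multi-SNP instrument set, and the
mediation chain uses strong exposure effects (0.7 SD) so the two-step
product's Monte-Carlo error stays well inside the 10% recovery band; the
colocalization scenarios use causal z ≈ 8 and MAFs near 0.3.  Degenerate
inputs are defined errors, not silent results: zero exposure β in a Wald
ratio, monomorphic variants in PVE, r² = 1 in F, empty regions, and
non-square LD tables all raise; empty instrument sets are valid results
reported with an explicit no-instrument status.

## Known limitations

Single-causal-variant assumptions throughout (coloc, SMR top-SNP);
no MR-Egger or median/mode estimators (cis instrument counts are too
small for them to be informative); no multivariable or multi-mediator
decomposition; LD matrices must be supplied (no reference-panel
download); and the external-validation command checks replication, not
heterogeneity, between cohorts.
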