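# Methods

## Model and procedure

The package implements two-sample Mendelian randomization (MR) with a
two-step mediation extension. The causal diagram has an exposure X, a
mediator M and an outcome Y: X affects M with effect α, M affects Y with
effect b, and X affects Y directly with effect θ. The total effect is
τ = θ + αb, the indirect (mediated) effect αb, and the proportion mediated
αb/τ. For a binary outcome every effect is a log odds ratio; odds ratios are
a display transform only.

Each pairwise effect is estimated by univariable two-sample MR:

1. **Instrument selection.** Retain SNPs with p strictly below the
   threshold (5×10⁻⁶ for the discovery exposure screen — chosen to leave
   enough instruments for many candidate exposures — 5×10⁻⁸ for mediators
   and later steps) and minor-allele frequency strictly above 0.01, then
   greedily clump: promote the smallest-p remaining SNP to index (ties by
   chromosome, then position), discard remaining SNPs on the same
   chromosome within 10,000 kb whose r² with the index is ≥ 0.001, repeat.
   Distance is measured to the index SNP, not interval-based. For QTL
   exposures an optional cis filter keeps SNPs within the gene body ± 10 kb
   (closed interval). No instrument-strength (F) filter is applied; per-SNP
   F = (γ/σ)² is reported for information.

2. **Harmonization.** Outcome effects are aligned to the exposure's
   effect-allele frame by direct match, allele swap (sign flip, frequency
   complement) and/or strand complement. Palindromic SNPs (A/T, C/G) cannot
   be strand-resolved from alleles; the default policy infers orientation
   from allele frequencies but drops SNPs whose frequency on either side
   falls in [0.42, 0.58] (conventional ambiguity window) or is missing.
   `drop_all` and `infer_by_freq` variants are available. The exposure beta
   is never modified.

3. **Estimation.** IVW with multiplicative random effects is the primary
   estimate (the random-effects scale factor √(Q/(J−1)) is floored at 1, so
   the reported SE is never smaller than fixed-effects); fixed-effects IVW,
   MR-Egger (slope + intercept, γ oriented non-negative before the fit,
   t(J−2) inference, residual scale floored at 1) and the weighted median
   (parametric-bootstrap SE, default 1000 resamples, seed mandatory) are
   reported alongside. IVW and Wald p-values are normal-based. The Wald
   ratio SE is first-order (exposure-side noise ignored); a second-order
   variant is available behind a flag.

4. **Sensitivity.** Cochran's Q with χ²_{J−1} reference; MR-Egger intercept
   test; MR-PRESSO global and outlier tests with empirical p-values from
   the add-one estimator (1 + #{sim ≥ obs})/(n_sim + 1) so p is never zero,
   per-SNP outlier p-values Bonferroni-adjusted, flagged SNPs removed once
   (no iteration) and IVW re-run; the distortion test is not implemented.
   Leave-one-out IVW completes the battery. MR-PRESSO processes SNPs in
   sorted-id order, so results are invariant to input row order at a given
   seed.

5. **Mediation.** Step 1 (X→M) uses the exposure's instruments; step 2
   (M→Y) is *univariable* MR with the mediator's own instruments —
   multivariable MR adjusting for the exposure is deliberately out of
   scope. The pipeline feeds the **outlier-corrected** primary estimates
   into the decomposition (outliers eliminated before further causal
   estimation). The delta method gives SE(ab) = √(a²σ_b² + b²σ_a²) and, for
   P = ab/τ, SE(P) = |P|·√(σ_a²/a² + σ_b²/b² + σ_τ²/τ²) assuming a, b, τ
   come from non-overlapping samples; when a or b is ~0 the relative form
   is singular and the product form divided by |τ| is used instead. The
   mediation Z and p test the indirect effect by default (a flag switches
   to the proportion); the CI on the proportion is delta-based, with a
   seeded Monte-Carlo CI available as a cross-check. Mediators are retained
   only if the indirect effect shares the total effect's sign and step-1,
   step-2 and mediation p-values are all below α = 0.05; BH-FDR q-values
   are reported within each screen family (never pooled across stages),
   with the family size recorded on every row.

## Synthetic data generator

`synthetic_data.simulate_sumstats` emits three summary-statistics tables
with known truth, directly from the asymptotic sampling distribution of
GWAS estimates — no individual-level genotypes. J exposure instruments get
true effects γⱼ (scaled so block leads explain h2_x of X's variance) and
j_mediator mediator-specific instruments get effects δⱼ (h2_m of M). True
marginal effects: X gets γⱼ; M gets αγⱼ + δⱼ (+ optional SNP→M pleiotropy);
Y gets τγⱼ + bδⱼ (+ optional SNP→Y pleiotropy on the exposure instruments).
Observed effects add normal noise with SE = 1/√(2·maf·(1−maf)·n), with
independent noise across the three GWAS samples — matching the two-sample
independence the delta method assumes.

Mediator-specific instruments are structurally necessary: with only X's
SNPs, the step-2 ratio at an X instrument is b + θ/α, so a univariable M→Y
analysis could not recover b and the recovery targets would be
unattainable by design.

Defaults are the study conditions used throughout the tests: J = 30
exposure and 30 mediator instruments, maf ∈ (0.05, 0.5), h2 = 0.05 per
trait, α = b = 0.11, θ = 0.088 (τ = 0.1001, proportion mediated 12.088%,
printed as 12.1%), n = 300,000 per GWAS — effect and sample sizes of the
order seen in biobank-scale GWAS of quantitative traits, giving per-SNP
instrument strength around z ≈ 20.

Optional hazards: (i) horizontal pleiotropy on Y with mean/SD
(pleio_mean, pleio_sd), applied in the frame of the exposure-increasing
allele so a non-zero mean is directional in the orientation MR-Egger fits
in; an InSIDE-violating switch correlates the pleiotropic effects with
instrument strength (correlation 0.7); (ii) AR(1) LD blocks — neighbour
correlation ld_rho within blocks of ld_block_size SNPs, reflected in the
true marginal effects (lead effect attenuated by the correlation), in the
sampling noise, and in the emitted r² matrix; blocks are placed 50 Mb apart
so only within-block pruning can occur; (iii) allele-encoding corruption
(swap / strand-flip / palindromic conversion) on a seeded subset, with a
ledger, to exercise harmonization. `resample_outcome` draws an independent
outcome GWAS from the same truth, emulating a validation dataset.

What the generator does **not** emulate: real LD maps, liability-scale
binary traits (Y is generated on the log-odds scale directly; liability
conversion and non-collapsibility are documented, not corrected), sample
overlap between GWAS, winner's-curse-free replication panels, population
stratification. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated sampling model, not robustness to
those real-data phenomena.

## Numerical choices

- Exact normal quantile (≈1.959964) everywhere a 95% level is used;
  printed-CI inversion examples quoted with 1.96 arithmetic agree to ~1e-3.
- Strict inequalities exactly as stated: p < threshold, MAF > 0.01, prune
  at r² ≥ threshold; cis window closed.
- Clumping ties (equal p) break by chromosome then position, for
  determinism.
- Weighted-median interpolation uses cumulative-midpoint positions
  pⱼ = Sⱼ − wⱼ/2; an exact midpoint hit (within 1e-12) returns that ratio,
  so equal weights with odd J give the sample median exactly.
- Empirical p-values never reach zero (add-one estimator); computed normal
  tail p-values are floored at the smallest positive double.
- Degenerate inputs: a zero exposure effect is a hard error for ratios; the
  delta product SE at a = b = 0 returns 0 with a warning; proportion
  mediated at τ = 0 is reported as undefined while the indirect effect is
  still returned.
- Every stochastic operation (weighted-median bootstrap, MR-PRESSO,
  Monte-Carlo CI) requires an explicit seed, which is recorded in outputs;
  pipeline sub-seeds are derived from the run seed by CRC-hashing the
  trait-pair identifiers, so (config, seed) determine every output byte.

## Problem sizes

Test-suite simulations use the study conditions at desk scale: Cochran's Q
type-I error over 2,000 null replicates at J = 20; IVW CI coverage over
1,000 replicates at J = 50; MR-PRESSO null behaviour over 200 replicates at
J = 10 (n_sim = 1,000); mediated-proportion recovery over 500 replicates of
the default three-trait world (MR-PRESSO at n_sim = 600 inside the loop).
The acceptance script uses 60–150 replicates per reported quantity.

## Known limitations

- Step 2 is univariable; when exposure instruments leak into the mediator's
  instrument set (their SNP→M effects reaching genome-wide significance)
  the step-2 estimate picks up a b + θ/α contamination. MR-PRESSO outlier
  elimination removes most of it at the default conditions; multivariable
  MR, the principled fix, is out of scope.
- Proportion mediated is interpreted on the log-odds scale; with a binary
  outcome this is approximate because the odds ratio is non-collapsible.
- The delta CI on the proportion assumes independence of a, b and τ;
  shared exposure-GWAS noise between a and τ induces a small positive
  correlation, negligible with strong instruments (NOME), slightly
  conservative otherwise.
- The LD model is block-AR(1) with one causal signal per block — adequate
  for exercising clumping semantics, not a model of real haplotype
  structure.
- No MR-RAPS, mode-based estimators, Steiger filtering, multivariable or
  reverse-direction MR; no funnel/radial plots; no liftover, VCF parsing or
  download clients.
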