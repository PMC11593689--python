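# medimr

Two-sample and two-step **mediation Mendelian randomization** (MR) from
GWAS/pQTL/eQTL summary statistics, for epidemiologists and statistical
geneticists who want the full pipeline — instrument selection,
harmonization, causal estimation, sensitivity analysis and mediation
decomposition — as a tested, scriptable Python library rather than a chain
of R packages.

The motivating use case is a dietary-supplement → circulating-biomolecule →
hypertension study design: screen many candidate exposures against a binary
outcome, then ask how much of a protective effect runs through a plasma
protein or metabolite mediator, and confirm it in an independent outcome
GWAS. Because the real datasets behind such studies (UK Biobank, deCODE,
eQTLGen) are access-controlled downloads, the package ships a synthetic
three-trait generator with known causal structure so every stage is testable
on a desk.

## The statistics

For instrument *j* with exposure effect γⱼ (SE σ_xⱼ) and outcome effect Γⱼ
(SE σ_yⱼ), aligned to a common effect-allele frame:

- **Wald ratio** β̂ⱼ = Γⱼ/γⱼ, SE σ_yⱼ/|γⱼ| (first-order delta).
- **IVW**: β̂ = Σwⱼβ̂ⱼ / Σwⱼ with wⱼ = γⱼ²/σ_yⱼ² — weighted least squares of
  Γ on γ through the origin. Fixed-effects SE (Σwⱼ)^(−1/2); multiplicative
  random effects inflate it by max(1, √(Q/(J−1))).
- **MR-Egger**: WLS with intercept after orienting γⱼ ≥ 0; a non-null
  intercept indicates directional horizontal pleiotropy (valid under
  InSIDE); t(J−2) inference.
- **Weighted median**: interpolated median of the β̂ⱼ under inverse-variance
  weights, parametric-bootstrap SE; consistent when ≥ 50% of weight comes
  from valid instruments.
- **Sensitivity**: Cochran's Q (χ²_{J−1}), MR-PRESSO global/outlier tests
  (simulated null of the leave-one-out residual sum of squares; flagged
  outliers removed once and IVW re-run), leave-one-out.
- **Two-step mediation**: a = X→M (exposure instruments), b = M→Y
  (mediator's own instruments), τ = X→Y. Indirect effect ab with delta SE
  √(a²σ_b² + b²σ_a²); direct effect τ − ab; proportion mediated ab/τ with
  delta CI; Z = ab/SE(ab); direction-consistency filter and
  Benjamini–Hochberg FDR across families.

Instrument selection follows common practice: p < 5×10⁻⁶ (discovery screen)
or p < 5×10⁻⁸ (mediators and later steps), greedy LD clumping at r² < 0.001
within 10,000 kb, MAF > 0.01, and an optional cis window (gene body ± 10 kb)
for QTL exposures.

## Worked example

The numbered scripts under `analysis/` run the whole design on synthetic
data with true effects α = 0.11 (X→M), b = 0.11 (M→Y) and direct effect
0.088, so the true total effect is 0.1001 and the true mediated proportion
0.0121/0.1001 = 12.1%:

```sh
python analysis/01_simulate_study.py    # writes results/data/
python analysis/02_exposure_screen.py
python analysis/03_mediation_screen.py
python analysis/04_validation.py
```

prints (abridged):

```
screened 1 exposure(s); skipped: NULL_A (no instruments pass selection), ...
  X -> Y: OR 1.105 [1.087-1.122], p 1.15e-34, q 1.15e-34 (significant, 23 SNPs)
  X -> M -> Y:
    a = 0.1048 (se 0.0081), b = 0.1018 (se 0.0091), tau = 0.0996 (se 0.0081)
    indirect = 0.01067, direct = 0.08897
    proportion mediated = 10.7% [7.7%-13.7%], p = 3.40e-17
simulated truth: 12.1%
  discovery: proportion mediated 10.7% [7.7%-13.7%], p = 3.40e-17 (outcome Y)
  validation: proportion mediated 11.5% [8.8%-14.2%], p = 4.60e-24 (outcome Y_validation)
validation estimate falls inside the discovery CI
```

Read: the causal exposure is picked up by the screen (null exposures are
skipped for lack of instruments), the two-step decomposition recovers the
mediated share of the total effect with a CI covering the 12.1% truth, and
an independent validation outcome reproduces it.

The same stages are available as a CLI over TSV/YAML files:
`medimr simulate|screen|mediate|validate --config cfg.yaml --out dir/`.

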