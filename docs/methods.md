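# Methods

## Estimating model and assumptions

All estimators operate on harmonized per-SNP pairs: exposure effect
γ̂ⱼ with standard error se_γⱼ and outcome effect Γ̂ⱼ with se_Γⱼ, both
on additive (log-odds for binary traits) scales, from non-overlapping
samples. The working model is

    γ̂ⱼ ~ N(gⱼ, se_γⱼ²),   Γ̂ⱼ ~ N(β·gⱼ + αⱼ, se_Γⱼ²),

independent across SNPs, with gⱼ the true instrument effect, β the
causal effect and αⱼ a horizontal-pleiotropy effect (zero for valid
instruments). Standard errors are treated as known. IVW and maximum
likelihood assume all αⱼ = 0; MR-Egger allows a common directional α
(InSIDE: α independent of g); the weighted median tolerates arbitrary
αⱼ on instruments carrying under half the total weight.

Inference conventions: 95% intervals use the fixed constant
z = 1.959964; IVW, ML and weighted-median p-values use the normal
reference (a t reference is a documented alternative; the choice is
visible in the code, not a config knob, since the difference is
negligible at the instrument counts involved); MR-Egger uses t on J−2
df. P-values are clamped into (0, 1] so downstream consumers never see
an exact zero.

## Per-method numerical choices

* **Wald ratio** — first-order delta SE se_Γ/|γ̂| by default; the
  second-order variant √(se_Γ²/γ̂² + Γ̂²se_γ²/γ̂⁴) is available via a
  flag. Cochran's Q and the weighted median use first-order weights
  (γ̂²/se_Γ²) for consistency.
* **IVW** — fixed-effect variance 1/Σwγ̂²; the random-effects variant
  is multiplicative overdispersion, inflating by √(max(Q/(J−1), 1)).
  `mode="auto"` applies the conventional gate: random effects when
  Cochran's Q has p < 0.05, fixed otherwise. With one SNP the estimate
  is the Wald ratio and the gate is moot.
* **MR-Egger** — SNPs are oriented γ̂ⱼ > 0 before fitting (the
  estimate is invariant to allele encoding only in this frame). The
  default residual scaling is classical multiplicative WLS: SEs scale
  by √(Q_egger/(J−2)), under which the intercept test has exact t(J−2)
  type-I calibration when instruments are valid — verified by the
  acceptance suite's null simulation. The floored variant
  (`overdispersion="floored"`, scaling by √(max(Q_egger/(J−2), 1)), as
  the widespread R implementations do) is deliberately conservative
  under the null (≈3% rejection at nominal 5%) and never deflates SEs
  under underdispersion; choose it when parity with those tools
  matters more than exact test size.
* **Weighted median** — the weighted empirical CDF of the sorted
  ratios is interpolated at standardized cumulative weight 0.5 using
  midpoint positions (cumⱼ − wⱼ/2)/Σw. The SE is a parametric
  bootstrap (default 1000 draws) redrawing γ̂, Γ̂ from normals at the
  observed values; the RNG seed is a required pipeline input and is
  recorded in the report, so reports are bit-reproducible.
* **Maximum likelihood** — the per-SNP nuisance effects gⱼ profile
  out in closed form, leaving the profile deviance
  Σ (Γ̂ⱼ − βγ̂ⱼ)²/(se_Γⱼ² + β²se_γⱼ²). Because this flattens to a
  constant as |β| → ∞ it need not be convex, so the optimiser scans a
  coarse grid (±10·(|β_IVW|+1), widening ×10 up to twice) for an
  interior minimum before bounded refinement; absence of an interior
  minimum raises an estimation error rather than returning a boundary
  value. The SE comes from the numerical curvature (central
  differences) of the profile deviance at the optimum; in the
  precise-exposure limit this reproduces IVW.

## Selection, harmonization, degenerate inputs

The instrument funnel runs p-threshold → clumping → F ≥ 10 (boundary
inclusive) → exclusion of SNPs strongly associated with the outcome →
harmonization, with every removal attributed to exactly one stage in
an audit whose counts reconcile with the input size. Clumping is
greedy on ascending p-value with ties broken by (chromosome, position,
SNP id), making the retained set independent of input row order; the
window is intra-chromosomal. The outcome-association exclusion cutoff
is configurable (default 5×10⁻⁸) because no standard value exists; it
is echoed in the report.

Harmonization matches by SNP id (position disagreements warn, since
genome builds may differ), tries literal then strand-complemented
alleles, flips the outcome beta and EAF for swapped encodings, and
handles palindromic SNPs by frequency: both EAFs must be known and
outside 0.5 ± 0.08 (configurable), otherwise the SNP is dropped as
ambiguous; a missing EAF on a palindromic SNP drops it (conservative).
Irreconcilable allele sets are dropped with an explicit action tag,
never silently. Runs surviving with fewer than three instruments
degrade to IVW/ML only, with a warning in the audit.

Mediation: the total effect is the univariable exposure→outcome IVW
(not an MVMR direct effect); the mediator→outcome step is unadjusted
for the exposure — genuine two-step MR, matching the screening use
case. The proportion SE treats the indirect and total estimates as
independent; they share the exposure dataset in reality, so the CI is
approximate — simulation puts its coverage near 94–95% at the effect
scales of interest. The screen applies no multiplicity correction
across a mediator panel by default (raw p < 0.05 on both steps plus
sign concordance); apply Benjamini–Hochberg on the returned columns if
the panel is large. MVMR assembles instruments as the union of the
per-exposure selections, re-clumped jointly, complete-case on every
exposure's effects.

## What the synthetic generator emulates — and what it does not

`synthetic_data` realises exactly the estimating model above, plus the
practical nuisances the pipeline must survive: palindromic alleles (a
configurable fraction, default 0.2), missing-by-construction overlap,
and block-constant LD at the r² summary level (clumping consumes r²
directly, so no haplotype simulation is attempted). Standard errors
follow 1/√(2·maf(1−maf)·n). Defaults mirror the motivating study's
conditions: β = 0.077 (OR 1.08), exposure GWAS n = 72,500
(psychiatric-consortium scale), outcome GWAS n = 486,500
(biobank scale), MAF uniform on (0.05, 0.5), instrument effects
g ~ N(0, 0.05²) so selected SNPs are strong (typical F ≈ 70).
Directional pleiotropy is defined on the exposure-increasing allele
(α multiplied by sign(g)), which is the violation that biases IVW and
that the Egger intercept detects; balanced pleiotropy is zero-mean.

Passing tests on these data show the statistics are computed correctly
under the model's assumptions. They do not show robustness to what the
generator omits: case-control ascertainment, sample overlap between
the two GWAS, weak-instrument winner's curse beyond the mild selection
effect the tests incur, realistic MAF spectra, or LD mis-specification
relative to the analysed population.

Fixed simulation scales keep the suite fast while leaving Monte-Carlo
error well below the tolerances tested: 2000 replicates for null
calibration (J = 20) and mediation coverage, 500 for parameter
recovery (J = 50). The pleiotropy-hierarchy scenario uses 30% invalid
instruments with α ~ sign(g)·N(0.01, 0.004²) and g ~ N(0, 0.2²):
strong pleiotropy relative to instrument noise (so IVW's drift is
unambiguous, ≈ +0.012) yet weak enough that the weighted median's
residual contamination shift (≈ +0.004, a known finite-J property of
the estimator, shrinking with instrument strength) stays well inside
its tolerance. The mediation scenario uses effect sizes at the
motivating study's own scale (a = 0.113, b = 0.131, direct effect
0.0592, true proportion 0.20) — at much larger effects the first-order
SEs ignore exposure-side uncertainty ("no measurement error"
assumption) and the delta CI visibly undercovers, which is a genuine
limitation of the method, not of the implementation.

## Known limitations

* First-order weights throughout; "exact" Q weights and conditional
  F-statistics for MVMR are not implemented.
* No Steiger direction filtering, MR-PRESSO outlier correction, or
  mode-based estimators.
* The LD matrix is an explicit input; there is no reference-panel
  clumping or proxy-SNP search.
* Positions are opaque within a dataset: no liftover, no build checks
  beyond a warning on id/position disagreement.
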