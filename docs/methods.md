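# Methods

## The problem

Two-sample Mendelian randomization (MR) estimates the causal effect of
an exposure (here, the motivating use case is serum liver-enzyme levels
— ALP, ALT, GGT) on an outcome (bone and joint diseases: osteoporosis
measured as bone mineral density, rheumatoid arthritis, osteoarthritis,
ankylosing spondylitis, psoriatic arthritis, gout) using genetic
variants as instrumental variables, with the exposure and outcome
associations taken from two non-overlapping GWAS at the
summary-statistic level. Per SNP *j* the inputs are the estimated
additive effects β̂_xj (per SD of exposure) and β̂_yj (log odds for
binary outcomes), their standard errors, allele labels, and
effect-allele frequencies (EAF).

The instrumental-variable assumptions are: relevance (the SNP is
associated with the exposure), exchangeability (no confounding of the
SNP–outcome relationship), and exclusion restriction (no effect on the
outcome except through the exposure). The package's diagnostics target
violations of the third assumption (horizontal pleiotropy).

## Instrument selection

Applied in order, each SNP logged with its first failing reason:

1. **Genome-wide significance** p < 5×10⁻⁸ (`p_threshold`).
2. **LD clumping** at r² < 0.001 (`clump_r2`): a greedy sweep in
   ascending p-value order (ties broken by rsid so the result is
   order-independent) accepting a SNP only if its r² with every
   accepted SNP is below the threshold. LD is supplied as a sparse
   pairwise r² table; an absent pair is treated as independence.
3. **Strength filtering.** The variance in the exposure explained by a
   SNP is R² = 2β²p(1−p) / [2β²p(1−p) + 2SE²·N·p(1−p)], which reduces
   to β²/(β² + SE²N); its F statistic is F = R²(N−k−1)/[k(1−R²)]. The
   weak-instrument filter removes SNPs with per-SNP F < 10 (k = 1); the
   set-level F with k equal to the retained count is reported
   alongside. SNPs with missing EAF cannot enter the R² formula and
   are excluded here with reason `missing_eaf`.

Instruments absent from the outcome table may be replaced by a **proxy**
in LD at r² strictly greater than 0.8 (the best available candidate;
ties to the lexicographically smallest rsid). The proxy must have its
own exposure row; allele-phase alignment between a proxy and its
original is not modeled.

## Harmonization

Both records of a pair are aligned to the exposure's effect allele.
Allele-pair comparison permits strand complements (A↔T, C↔G): identical
or complement-identical codings pass through; swapped (or
complement-swapped) codings flip the outcome record (β negated, EAF
complemented). Palindromic SNPs (A/T, C/G) are flagged before any
same/flipped verdict because the strand cannot be read off the labels;
they are resolved by EAF concordance when both frequencies fall outside
the ambiguity window and dropped as `palindromic_ambiguous` otherwise
(including when either EAF is missing). All other combinations are
dropped as `incompatible`.

The ambiguity window defaults to [0.42, 0.58]. A symmetric ±0.08 band
around 0.5 is a common operating point for "intermediate" allele
frequency; it is a config key (`ambiguous_eaf_window`) precisely
because the choice is conventional rather than principled, and
sensitivity to it can be tested directly.

## Estimators

With aligned effects (β̂_xj, β̂_yj) and weights w_j = 1/SE²_yj:

* **Wald ratio** per SNP: β̂_yj/β̂_xj, SE = SE_yj/|β̂_xj| (first order).
* **IVW**: β̂ = Σw β̂_x β̂_y / Σw β̂_x², the weighted through-origin
  regression of outcome on exposure betas. Fixed-effect SE is
  √(1/Σw β̂_x²); the default multiplicative random-effects mode
  multiplies it by max(1, √(Q/(n−1))) with Q the Cochran statistic.
  The floor at 1 means the random-effects SE never undercuts the
  fixed-effect SE; the headline estimator stays coherent when
  heterogeneity is substantial, which is the regime these analyses
  usually occupy. Inference is normal.
* **MR-Egger**: weighted least squares of β̂_y on β̂_x with an
  unconstrained intercept, each SNP first re-signed so β̂_x ≥ 0 (the
  conventional orientation; a config flag). The intercept estimates
  the average directional pleiotropic effect; its two-sided test is
  the pleiotropy diagnostic. Coefficient variances are scaled by
  φ = max(1, RSS_w/(n−2)) and inference uses t(n−2).
* **Weighted median**: ratio estimates weighted by their inverse
  first-order variances β̂_x²/SE_y², sorted; the estimate interpolates
  the ratio at standardized cumulative weight 0.5. Consistent when
  valid instruments carry ≥ 50% of the weight. The SE comes from a
  seeded parametric bootstrap (default 1000 draws) redrawing both
  betas from normals at their observed means/SEs.

Estimates are reported as OR = exp(β̂) with 95% CI
exp(β̂ ∓ z₀.₉₇₅·SE). The t vs normal reference choices and the
bootstrap size are implementation conventions, not inherited facts.

## Sensitivity battery

* **Cochran's Q** over Wald ratios (weights β̂_x²/SE_y²), df = n−1,
  upper-tail χ² p-value, and I² = max(0, (Q−df)/Q). This identity
  with df = n−1 exactly reproduces the reverse-analysis heterogeneity
  rows used as acceptance checks.
* **Leave-one-out**: IVW with each SNP removed; a SNP is flagged
  influential if its removal changes the sign of β̂ or moves the
  p-value across α.
* **Residual-sum outlier test** (MR-PRESSO style): the observed
  weighted RSS about leave-one-out IVW slopes is compared with a
  parametric simulation null; per-SNP tail probabilities are
  Bonferroni-multiplied by n. Detected outliers are removed in a
  single pass (no iteration) and IVW is refit; the global empirical
  p-value has resolution 1/(n_sim+1). Defaults: 1000 simulations,
  outlier α = 0.05.
* **Power** for a binary outcome uses the normal non-centrality
  approximation power = Φ(|β|·√(n·R²·cf·(1−cf)) − z₁₋α/₂). The method
  behind the motivating study's power claim is unstated; this
  approximation is the package's choice.

## Pipeline

`run_pair` chains selection → proxy lookup → merge → harmonization →
outlier test (single detect-and-remove pass) → optional
confounder-rsid exclusion (a user-supplied list standing in for a
Phenoscanner-style lookup, applied after harmonization with all
estimators rerun) → IVW + weighted median + MR-Egger → Q and
leave-one-out. Conservation is asserted per run: every selected
instrument is either harmonized, dropped in harmonization, or missing
without proxy. All stochastic stages draw from per-stage substreams
spawned from the run seed, so stage order cannot perturb results and a
replay is byte-identical. Multiple testing across an outcome panel
uses α/n_tests with n_tests defaulting to the number of outcome traits
(10 in the motivating design, giving 0.005).

## Synthetic data generator

The generator emulates the statistical structure of public GWAS
summary tables so the whole pipeline can be exercised with known
ground truth: instrument effects γ_j ~ N(0, γ_sd²) (others zero), true
outcome effects Γ_j = β·γ_j + α_j, observed effects drawn with the
standardized-scale SE 1/√(2np(1−p)) (binary outcomes rescaled by
1/√(cf(1−cf))), EAFs observed with binomial noise, exchangeable LD
blocks (noise correlation √r² within a block), a fraction of
palindromic allele pairs, and a fraction of outcome records emitted
under swapped allele coding.

Pleiotropy modes: `balanced` draws α_j ~ N(0, σ²); `directional` draws
α_j = sign(γ_j)·μ + N(0, σ²). The sign alignment is deliberate: with
effects symmetric about zero, a constant-sign α averages out of the
IVW numerator and produces no bias, whereas pleiotropy acting in the
exposure-raising direction — the phenomenon the Egger intercept and
weighted median exist for — requires the direct effect to be oriented
by each SNP's exposure-increasing allele.

Default scales mirror the motivating data: exposure GWAS n = 753,010
(the liver-enzyme meta-analysis size), outcome n = 400,000 with 25%
cases (biobank disease scale), ~150 instruments, MAF ~ U(0.05, 0.5),
15% palindromic SNPs, 10% flipped codings, LD blocks of 5 at r² = 0.2.

What it does **not** model: winner's curse (instrument effects are not
conditioned on discovery), sample overlap, population stratification,
realistic genome-wide LD, liability-scale binary traits (binary
effects are generated directly on a log-odds-like scale, since the
pipeline consumes betas/SEs only). Passing tests therefore demonstrate
correctness of the estimators and plumbing under clean two-sample
assumptions, not robustness to those real-data pathologies.

## Evaluation studies and their problem sizes

The replicated studies (`mrkit.evaluation`) use a reference scenario of
100 instrument SNPs and 10⁵ samples per side with continuous traits:
parameter recovery and CI coverage at β = 0.3 (200/500 replicates),
null calibration with balanced pleiotropy σ = 0.005 (500 replicates),
weighted-median vs IVW bias with 40% directionally pleiotropic
instruments at μ = 0.03 (200 replicates), planted-outlier detection
(100 constructions; ratio 10× the causal effect at small SE among 20
clean instruments), and harmonization invariance (50 mis-coded
fixtures). Study instruments are the generator's ground-truth
instruments passing the per-SNP F ≥ 10 filter — the pipeline never
estimates with weak instruments, and including near-null draws would
measure weak-instrument attenuation rather than estimator behaviour on
the sets it actually receives.

## Numerical choices and degenerate inputs

Zero p-values on input are clamped to the smallest positive float (a
total order is needed for thresholding); estimator p-values are
likewise floored. A zero exposure beta makes the Wald ratio undefined
and raises. Q = 0 maps to I² = 0 and p = 1. Clumping and proxy ties
break lexicographically. The weighted-median interpolation clamps at
the extreme ratios when 0.5 falls outside the standardized-weight
range (possible only with ≤ 2 SNPs, below the estimator's minimum).
The bootstrap guards exact-zero redraws of β̂_x with the smallest
positive float.

## Known limitations

* IVW retains the first-order attenuation from measurement error in
  the exposure betas (no NOME correction): the estimate shrinks by
  roughly the weighted ratio Σw·SE²_x / Σw(γ² + SE²_x), i.e. on the
  order of 1/F̄ relative — about 0.2% in the reference scenario. The
  recovery study measures the combined effect.
* The outlier test implements the global and per-SNP residual-sum
  tests with single-pass removal; the distortion test and iterated
  removal are out of scope, as are mode-based estimators, MR-RAPS,
  multivariable MR, and Steiger direction filtering. Consequently a
  strong forward effect whose downstream associations reach
  genome-wide significance will, by design, be "detected" in the
  reverse direction at 1/β — the package reports both directions and
  leaves the directionality judgment to the analyst.
* Clumping is purely r²-based; genomic positions and distance windows
  are not in the data model.
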