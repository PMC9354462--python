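# Methods

This note records the models implemented in `cardiopls`, the defaults
and the reasoning behind the choices that were genuinely open.

## Data model and preprocessing

Expression input is a samples × genes matrix of TPM. TPM rows are
compositions: each row carries only relative information and sums to a
constant (10⁶). Euclidean operations — Pearson correlation, distances,
least squares — are not meaningful on the simplex, so all analyses run
on centred log-ratio (CLR) values,

    clr(x)_i = log10( x_i / gmean(x_basis) ),

with the geometric mean computed in log space. Base 10 is used
throughout. Two preprocessing decisions were open:

* **CLR basis.** The geometric mean may run over the whole matrix or
  over the analysed gene panel. The default basis is the 62-gene panel
  union: it is reproducible from the panel configuration alone,
  independent of how many unrelated genes a matrix happens to contain.
  `clr_transform(..., basis=None)` uses all genes instead; the
  synthetic generator includes 200 filler genes precisely so the two
  choices differ measurably in sensitivity checks.
* **Zeros.** CLR is undefined at zero. The default policy replaces
  zeros per gene with half that gene's smallest positive value across
  samples (logged standard practice for compositional data);
  `zero_policy="error"` refuses instead.

Sample filtering happens in a fixed order: (1) keep samples whose
reference-gene (GAPDH) TPM lies in the **closed** interval
[500, 2,500] — GAPDH level is a dilution/quality proxy, and boundary
inclusion is a documented convention here; (2) CLR-transform; (3) fit a
preliminary PLS model (modifiers → ion channels) and drop samples whose
score on any of the first 2 latent variables exceeds 4 SD of that
component's scores. The 4-SD / 2-component default removes only gross
outliers (on synthetic cohorts at default rates, ~2 of 242) and is
configurable.

## PLS regression

Both classic algorithms are implemented from first principles and
cross-checked against each other and against an external reference in
the test suite:

* **NIPALS**: inner power iteration on the cross-covariance, data
  deflation `X ← X − t pᵀ`, `Y ← Y − t qᵀ`. Convergence is declared
  when the squared relative change of the score vector falls below
  1e-10; the iteration cap is 10,000, because the iteration converges
  linearly at rate (σ₂/σ₁)² of the cross-covariance and near-degenerate
  leading pairs (ratios above 0.99) occur routinely on realistic
  blocks. Iterations cost O(n·p·q), so the high cap is cheap.
* **SIMPLS**: dominant singular vector of the cross-covariance,
  deflated through an orthonormal loading basis; scores are unit-norm
  (de Jong's convention).

Both centre X and Y; by default columns are scaled to unit variance
(`scale=False` disables). Each weight vector's largest-magnitude
element is made positive — components have arbitrary sign, and a fixed
convention makes runs comparable. The coefficient matrix is assembled
as `B = R Qᵀ` with `R = W (PᵀW)⁻¹` (NIPALS) or the SIMPLS rotations
directly, then de-scaled so that `Ŷ = (X − x̄) B + ȳ` in original
units. Orientation: **B is predictors × responses and multiplies X on
the right**; training predictions reproduce the component-wise
reconstruction to 1e-10, and at full rank with no scaling B equals the
least-squares solution.

**Component count.** Leave-one-out cross-validation with PRESS
(`‖Y − Ỹ‖²F`). One model at the maximal component count per left-out
sample yields nested predictions for every smaller count. The chosen
count is the smallest whose mean LOOCV squared error is within one
standard error of the minimum; a verbal "most variance while keeping
the model simple" criterion is not operational, the one-SE rule is.
The pipeline's default model uses 4 components.

## Monte-Carlo cross-validation and biplots

Ensembles of fits over repeated random splits (default 1,000 runs, 10%
holdout drawn without replacement; run *i* uses the independent stream
`default_rng([seed, i])`, so any run is reproducible in isolation).
Before averaging, every run's components are sign-aligned to the first
run by the inner product of concatenated X- and Y-loading vectors:
without this, runs with flipped components cancel in the mean — the
test suite carries a constructed counterexample. The coefficient
matrix is sign-invariant and is averaged directly. Biplots place each
variable at its averaged loadings on latent variables 1–2; angular
proximity indicates co-regulation, vector length the variable's weight
in that plane.

## Transfer audit

Three designs quantify whether a model trained on one sex transfers to
the other (modifiers → ion channels, 4 components):

* **original** — per run, 84 random training-stratum (male) samples,
  10% held out (train 76); predict the within-stratum holdout and the
  *entire* female set.
* **reduced** — as original, but the male pool is first down-sampled by
  histogram matching on total ischemic time so its confounder
  distribution matches the female one. Matching removes samples
  uniformly at random within bins; the default bin width is the
  Freedman–Diaconis width of the smaller stratum (objective and
  documented; overridable). Bins where the large stratum is already
  smaller keep everything, with a warning.
* **mixed** — per run, equal numbers from both sexes are pooled and
  split into equal-composition train/test halves. A null design: the
  model has seen both strata, so errors should centre on zero.

Errors are **prediction − actual** in CLR units (underestimation is
negative), pooled per output gene and tested stratum across runs.
Ashman's D between the two strata's error populations,
`√2 |μ₁ − μ₂| / √(σ₁² + σ₂²)` with n−1 sample variances, quantifies
separability; D > 2 is the separability criterion and D > 1 a weaker
signal. Errors are kept on the raw CLR scale (no per-gene
standardisation), matching the formula as written.

Two reporting choices deserve note. First, MC runs reuse the same
cohort samples, so per-run error means are pseudoreplicates; the
standard error reported by `error_summary()` therefore treats
*samples* as the independent unit (SD over per-sample mean errors /
√n_samples). Per-run means are retained on the result for users who
want them. Second, the stratum holdout applies only to the training
stratum; the other stratum is tested wholesale each run.

In place of an embedding-based confounder visualisation the package
provides `confounder_score_correlation`, a table of Pearson
correlations between PLS sample scores and the metadata covariates
(age, BMI, RIN, ischemic time).

## Group effects and flow export

Beta coefficients are averaged over ion-channel groupings:
Depolarization (SCN5A, CACNA1C, SLC8A1), Repolarization (KCNH2, KCNQ1,
KCNJ2, ATP1A1), Net = Depolarization − Repolarization (exactly, by
construction), Resting (KCNJ2, ATP1A1), Calcium handling (ATP2A2,
RYR2, SLC8A1, CACNA1C) and Coupling (GJA1). SLC8A1 and CACNA1C belong
to two groupings by design. Group tables use **raw** coefficients from
models fitted on all samples of a stratum (no MC holdout); max-abs
scaling — each target gene's incoming coefficients divided by their
largest magnitude, preserving signs — is applied only to the two-stage
modifier → TF → ion-channel flow export, where links with scaled
magnitude below 0.01 are pruned (line-width pruning made explicit). A
negative link into a negative link reads as a positive net relation;
no product is computed — the stages stay separate.

## Synthetic cohorts

The generator emulates the statistical structure of left-ventricle
bulk RNA-seq — not any real gene's expression level. Defaults mirror
the study conditions of the targeted cohort: 84 female and 158 male
samples, four latent factors with a dominant first pair (scales 1.0,
0.7, 0.35, 0.25), ~1,000-minute-scale ischemic times with a male-only
exponential tail (female ≈ N(300, 120²) minutes clipped positive; male
adds Exp(250)), GAPDH centred at 1,300 ± 300 TPM inside the filter
window, 3% planted out-of-window reference values, 0.8% gross
outliers planted at 10 SD along factor 1, 200 filler genes, and log10
residual noise of 0.1.

Structure: modifier log-abundances load directly on the factors; the
TF block is a linear map of the modifier *factor signal* plus noise;
the ion-channel block realises per-gene factor exposures through the
cascade (the TF → IC map is the pseudo-inverse solution, so the
cascade is exact). Exposures place all ion channels on a shared
co-regulation axis (factor 1) with per-gene strengths and a small
spread — the tight co-regulated cluster seen in biplots — except the
Na/K-pump analogue ATP1A1, which is driven by factor 2 alone and is
therefore regulated by the modifiers *orthogonally* to the rest, as in
the data this emulates. Transmitting the factor signal rather than the
modifier genes' own noise keeps the modifier → IC relation at exactly
the configured latent rank; with equal noise everywhere, cross-
validation genuinely detects extra predictable directions (a property
of PLS, reproduced by the reference implementation as well), so rank-
recovery checks use a cleaner modifier block (`modifier_noise_sd`
below `noise_sd`) — also the biologically sensible regime, since
transcriptional noise accumulates downstream of the drive.

Sex effects: for selected ion-channel genes (default SLC8A1, delta
−0.5), the *female* coupling onto a repressive drive (baseline −1 plus
a small factor-1 loading) differs additively. A negative delta weakens
the repression, so female expression is higher on average and
co-varies differently with the factors; a male-trained model then
under-predicts the gene in females (left-shifted error histogram) and
its Ashman's D rises — the mechanism needs a non-zero-mean drive,
because a coupling change on a zero-mean drive shifts error variance
but not the error mean. The ischemic-time confounder acts additively
on the log scale (default 5 × 10⁻⁴ log10 units/minute on the KCNJ2 and
GJA1 analogues), making histogram matching consequential by default.

TPM assembly: signals are exponentiated (base 10); filler genes and
the reference gene are appended; all non-reference genes are rescaled
per sample so the row totals 10⁶ exactly with the reference gene at
its drawn TPM — the rescaling is a per-sample constant and CLR is
invariant to it, which is also why post-subsetting renormalisation
questions are moot downstream.

What the generator does **not** emulate: real marginal expression
levels, count noise at low expression (values are lognormal-ish,
never zero), batch structure, or age/BMI/RIN effects (those covariates
are drawn independently). Passing tests therefore demonstrate the
pipeline's statistical machinery on data with the right *structure*,
not performance on any real cohort.

## Problem sizes and numerics

Tests and examples run desk-scale configurations chosen to keep the
statistical content intact: cohorts of ~200–242 samples, Monte-Carlo
ensembles of 60–200 runs (the CLI defaults to 1,000), 50 replicates
for rank-recovery rates. Degenerate inputs are rejected loudly:
constant columns under scaling, zero combined variance in Ashman's D,
holdouts leaving fewer than n_components + 2 training samples,
non-overlapping confounder ranges in histogram matching. Ties in the
TF ranking break alphabetically. File round-trips preserve full float
precision (`%.17g` on write, correctly-rounded parse on read).

## Known limitations

* CLR only; no isometric or additive log-ratio variants.
* No sparse, orthogonal or kernel PLS; predictors must number fewer
  than samples for the standard algorithms to be sensible.
* Ashman's D is used descriptively, as a separability index — no
  hypothesis test or multiplicity control is attached to it, and none
  is attached to the correlation analyses.
* The mixed design assumes the two strata are of comparable size;
  with very unbalanced strata its equal-composition halves shrink to
  the smaller stratum.
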