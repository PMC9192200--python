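# Methods

## The analysis

The package implements a three-way serum discrimination workflow for
advanced endometriosis (E) versus other benign gynecological disorders
(NE) versus healthy controls (C). Three classifier families share one
modelling core:

* **biochem** — the 29-parameter serum panel is autoscaled, forward
  interval-PLS with singleton windows selects parameters, and a PLS-DA
  model with 4 latent variables (LVs) classifies;
* **spectral** — ATR-FTIR absorbance spectra are differentiated twice
  (Savitzky–Golay, 15-point window, cubic polynomial), the
  700–1450 cm⁻¹ fingerprint block is extracted and mean-centred,
  forward iPLS with 10-variable windows selects spectral regions, and a
  5-LV PLS-DA model classifies;
* **fused** — the fingerprint second-derivative block is reduced
  tenfold by quadrant selection in a transposed-PCA score plane, both
  blocks are range-scaled to [0, 1] and concatenated, singleton-window
  iPLS selects fused variables, and a 2-LV PLS-DA model classifies.

Classification is one-vs-rest argmax over the predicted class-indicator
columns (order E, NE, C; ties resolve to the earlier class). Models are
evaluated by calibration (training-set) and leave-one-out
cross-validation (LOO-CV) confusion statistics — per-class sensitivity,
specificity, accuracy, precision, F1, plus overall accuracy — and
one-vs-rest ROC curves with trapezoidal AUC.

## PLS-DA

PLS regression of the one-hot indicator matrix Y (n × 3) on the data
block X uses the SIMPLS algorithm: at each step the dominant right
singular vector of the current cross-product matrix S = XᵀY yields an
X-weight, scores are orthonormalized, and S is deflated against the
orthonormalized loading basis. SIMPLS is deterministic and reproduces
the multivariate least-squares fit at full rank. A NIPALS
implementation is kept as an independent cross-check; the two are
algebraically identical for a single response column and at full rank
(for multi-column Y at intermediate ranks they are distinct algorithms
and agreement is approximate, so the tests pin down agreement exactly
where theory guarantees it).

Variable importance in projection follows the standard normalization
VIPⱼ = √( m · Σₐ SSYₐ (wⱼₐ/‖wₐ‖)² / Σₐ SSYₐ ), so Σⱼ VIPⱼ² = m for any
fitted model.

All LOO machinery is vectorized: the n leave-one-out training sets are
stacked into an (n, n−1, m) tensor, scaling statistics are refit inside
every fold (no held-out leakage into the pretreatment), and SIMPLS runs
on all folds in one batched pass. Interval selection scores thousands of
column subsets against the same block, so the scaled fold tensor is
cached column-major and subsets are gathered from it. Double precision
is kept throughout: second-derivative spectra mix dominant directions
with directions ~300× weaker, and the SIMPLS deflation cancellations on
such data exceed single-precision headroom (verified during
development: a single-precision variant corrupted components beyond the
second). The cached block is normalized to unit RMS — predictions are
invariant to a common rescale of X — so blocks living at ~10⁻⁴
absorbance units stay clear of rank tolerances.

## Forward interval-PLS and its stopping rule

Variables are partitioned into contiguous windows (width 1 for the
panel and fused blocks, width 10 for spectra, the last window shorter
when the width does not divide the column count). A greedy loop scores
every unaccepted window by LOO-CV of a PLS-DA model on
(accepted ∪ candidate) columns, yielding the pair (indicator RMSECV,
misclassification count). Candidates are ranked by RMSECV, then miss
count, then window index: the continuous criterion ranks; an integer
error count is too coarse to order ~150 candidates at n ≈ 71 and can
trap the greedy loop on a plateau where no single window lowers the
count even though one clearly improves the fit (observed on the fused
block: a marker cutting RMSECV by 7% was unreachable because its miss
count ticked up by one). The LV count during selection equals the
final model's, capped by the current column count.

The ranked-best candidate is accepted when it strictly lowers the
misclassification count, or lowers the cross-validated RMSE by at
least a relative margin (`ipls_min_improvement`). The margin is
essential, not cosmetic: each acceptance test is a *minimum over up to
~150 candidates*, and the minimum of that many near-zero chance
fluctuations is almost surely a small spurious improvement. Adding
white-noise windows can also genuinely lower LOO RMSE slightly through
coefficient shrinkage (an implicit-ridge effect), so a margin-free rule
keeps absorbing noise windows indefinitely.

Two defaults serve two purposes. Predictive pipelines use a 1% margin:
marginal windows still improve held-out prediction slightly, and
admitting them costs nothing but parsimony. Support-recovery studies
(`endospec.experiments`) use a 3% margin: claims about *which* windows
carry signal need the margin to sit above the chance/shrinkage
improvements (typically 0.5–2% in these designs) and below the genuine
implanted-window improvements (3–45%). The two distributions brush
against each other at the weakest true windows, which is why the
recovery studies report a replicate-mean count rather than a single
draw.

Selection is performed once on the full dataset; LOO-CV then evaluates
the fixed selection. This mirrors standard chemometric practice but is
optimistically biased — on label-permuted data the pipeline's CV
accuracy stays visibly above the 1/3 chance level even though a model
on fixed columns drops to chance. Every run manifest carries this
caveat, and the test suite demonstrates the bias explicitly.

## Synthetic cohorts

No patient-level data are distributed, so analyses run on synthetic
cohorts engineered to have the statistical structure the models assume.

**Biochemical panel.** Twelve markers (PRL, CA 125, IgG, hsCRP,
albumin, calcium, magnesium, hsIL-1β, IL-6, FRAP, AOPP, YKL-40) follow
group-specific published mean ± SD values; each entry is drawn from a
lognormal moment-matched to (m, s) via σ² = ln(1 + s²/m²),
μ = ln m − σ²/2, so the population mean and SD equal the targets
exactly while all concentrations stay positive. The lognormal choice is
forced by the data: several markers (CA 125, YKL-40, IL-6) have
SD > mean, which a normal model cannot represent without impossible
negative concentrations. The remaining 17 parameters receive clinically
plausible values identical across groups and act as nuisance variables.

**Spectra.** Serum-like spectra are sums of Gaussian bands (amide I/II
at 1645/1545 cm⁻¹ dominate; OH/NH and CH stretches above 2900 cm⁻¹;
weak fingerprint bands at 731–1306 cm⁻¹) on the instrument axis
400–4000 cm⁻¹ with 7,469 points (≈0.482 cm⁻¹ spacing). Class structure
enters as multiplicative band-amplitude effects: an inflammation effect
shared by both patient groups (factors 1.08–1.12 on the nucleic-acid /
phosphate bands 1056, 1080, 1213, 1241 cm⁻¹) and a subtler
endometriosis-vs-other-disorder effect (factors 1.08 vs 0.92 on ten
fingerprint bands, 731–1243 cm⁻¹). Instrument artefacts are a
per-sample multiplicative gain ~ N(1, 0.05²) truncated positive
(film-thickness scatter), a random quadratic baseline with coefficient
SD 4·10⁻³ absorbance units, and white noise with SD 10⁻⁴ absorbance
units (typical of a 128-scan DTGS measurement).

What the generator does **not** emulate: interferogram-level processing
(apodization, zero-filling), water-vapour lines, drying kinetics,
Lorentzian/Voigt line shapes, per-band biological variability beyond
the global gain, and any biochemistry↔spectrum coupling. Passing tests
therefore show that the pipeline recovers the structure this generator
encodes — they do not certify performance on real serum spectra, where
within-class variability is richer.

## Known-support recovery experiments

Two canonical experiments probe whether forward iPLS finds an implanted
signal support (`endospec.experiments`).

**Eight spectral windows.** One narrow Gaussian band (σ = 1 cm⁻¹,
amplitude 0.02) is placed at the centre of each of eight disjoint
10-point windows spread across the fingerprint block, each window
carrying a distinct class-amplitude pattern so that every window
contributes an independent contrast. Gain scatter and baseline drift
are off in this design — they contaminate every column with a shared
per-sample latent, which turns band-free windows into genuinely useful
clutter references for PLS and defeats the purpose of a known-support
experiment — leaving white noise (SD 5·10⁻⁴) as the only nuisance.
Group sizes are scaled up (2× the 29/24/18 study sizes, 142 samples):
the selection criterion is a minimum over ~150 candidates and its
chance fluctuations, the enemy of support recovery, shrink with sample
size. Two facts shape what "recovery" can mean here: the 15-point SG
filter smears each band's derivative response into the adjacent
windows, so accepted windows are counted as hits within ±1 window; and
the greedy stopping step carries irreducible ±1-window variability, so
the headline statistic is the retained-variable count averaged over a
small set of replicate cohorts rather than a single draw.

**Six panel parameters.** Six markers receive distinct class-contrast
mean shifts of ≥1.5 SD while the other 23 parameters are identical
across groups; singleton-window iPLS should retain approximately those
six. Exact support recovery by greedy CV-driven selection is known to
be unstable at n≈71, and the tests assert the realistic contract
(5–7 retained, majority implanted) rather than an idealized exact-six.

## Data fusion

The second-derivative fingerprint block is reduced tenfold before
fusion: PCA on the transposed block gives every variable a (PC1, PC2)
score; variables are partitioned into the four quadrants of the score
plane (zero scores fall in quadrant I); per-quadrant quotas are
apportioned by largest remainder on quadrant sizes (an empty quadrant's
quota redistributes proportionally); and within each quadrant picks sit
at evenly spaced ranks of the atan2(PC2, PC1) ordering, spreading the
retained variables around the scores cloud. The retained count is
round(m/10) — 156 of the 1,556 fingerprint columns on the default grid
— and the procedure is a deterministic function of the block. Both
blocks are then range-scaled to [0, 1] on the training rows (held-out
data clipped; constant columns flagged and set to 0) and concatenated,
panel first. The reduction PCA and range scaling are fit on all samples
before cross-validation, mirroring the low-level fusion practice this
package models; the same selection-bias caveat applies.

## Numerical choices

* PCA sign convention: each loading column is flipped so its
  largest-magnitude entry is positive; PCA always centres internally.
* SG derivatives are computed on the full grid and regions extracted
  afterwards, so no valid points are lost inside 700–1450 cm⁻¹; the 7
  filter-edge points at each end of the full grid are treated as
  invalid.
* GLSW uses the within-class deviation covariance C = DᵀD/(n−1) and the
  filter W = V diag(1/√(1+s/α))Vᵀ, default α = 0.02; W → I as α → ∞.
* Scalers refit inside every CV fold; zero-variance columns are flagged
  (autoscale divides by 1, range01 maps to 0).
* Argmax ties in prediction resolve to the earliest declared class.
* LV counts requested above the usable rank are capped at
  min(A, columns, n−2) with a log notice.

## Problem sizes

The shipped validation studies use the 71-sample default cohort on the
full 7,469-point grid for the three model families (fused-vs-single
comparisons aggregate six replicate seeds), 142-sample cohorts for the
eight-window recovery study (five replicate seeds), and 71-sample
cohorts for the six-parameter study. These sizes are the package's
standard study conditions; the generators accept any group sizes.

## Known limitations

* The stopping point of greedy forward selection has irreducible
  ±1-window variability near the end of the informative set; support
  recovery is reported with that granularity.
* PLS-DA argmax classification has no probability calibration; scores
  are indicator predictions, not posteriors.
* The synthetic generator's within-class spectral variability (gain +
  baseline + white noise) is simpler than real serum film replicates;
  absolute accuracy figures on synthetic cohorts are not comparable to
  clinical performance.
* Variable selection on the full dataset biases CV metrics upward; the
  bias is documented rather than removed because the modelled published
  procedure carries it too.
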