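# Methods

This package implements a zone-referenced analysis chain for single-cell
calcium imaging and fiber photometry of freely behaving mice, together with
a synthetic-session generator that makes every stage verifiable without
animal data.  This note documents the models, the defaults and the design
choices made where the underlying procedure left room.

## Synthetic sessions (`calzone.synthgen`)

**Behavior.** Zone occupancy is a semi-Markov process: dwell times in each
zone are exponential with a per-zone mean, and the next zone is drawn with
probability proportional to configured weights (excluding the current
zone).  Between visits the animal spends an exponential *transit* interval
(mean `transit_s`, default 1 s) assigned to no zone.  The transit interval
reflects the physical traversal between zone boundaries; it also keeps the
binary zone design linearly independent of the regression intercept, which
zone sets tiling the whole arena would not be.  Occupancy is emitted one-hot
at the 30 Hz tracking rate; traces run at 10 Hz and the two clocks are
reconciled by taking the tracking sample nearest each frame midpoint.

**Calcium traces.** Each cell fires a Poisson train of unit-amplitude
transients convolved with a single-exponential decay kernel (tau = 1 s),
plus white noise.  Zone modulation multiplies the event rate while the
animal occupies the zone.  Requested effect sizes are stated in s.d. units
of the cell's null trace and converted to a rate change through Campbell's
theorem: for per-frame rate lambda and kernel k, the trace mean is
lambda * sum(k) and its shot-noise variance lambda * sum(k^2), so the rate
offset achieving a given mean shift is known in closed form.  Rates are
clipped at zero (with the achieved effect recorded), so strong inhibition
saturates at silencing — as it does in real neurons.

**Reference study conditions.** Validation studies use baseline rate
0.5 events/s, noise s.d. 0.5 (signal-to-noise ~2 against unit transients,
typical of extracted miniscope traces), zone dwells of 10–15 s with 2-s
transits, and 15-min sessions.  These were fixed once, at design time, from
what published recordings of this kind look like, and all tests and the
reproduction script run at exactly these conditions.

**Photometry.** Channels are double-exponential bleach curves
(a1 e^{-b1 t} + a2 e^{-b2 t}) plus, on the primary channel, a transient
signal train; both channels share a motion series (random-sign exponential
bumps at a configurable rate) scaled by per-channel coefficients, plus
independent white noise.  Packet-loss samples (Bernoulli per sample) are
replaced by spikes of 10x the running 20-s IQR, which guarantees the 4xIQR
detection fence sees them.  Every planted component is returned as ground
truth.

**Cohort metrics.** A latent anxiety trait (standard normal per animal)
loads negatively on EPM open-arm time and OF center time and positively on
NSFT latency, each with unit test-specific noise; `trait_effect` scales the
loading.  Raw metrics are placed on realistic scales (e.g. 300-s EPM, 600-s
NSFT cutoff) and clipped to their physical ranges.

**What the generator does not emulate:** spatially continuous trajectories
(occupancy jumps between zones), calcium indicator nonlinearity and
saturation, cross-cell noise correlations, slow drift in event rates, and
cell-registration errors across sessions.  Passing tests therefore establish
correctness of the *analysis* under the stated generative model, not
robustness to every artifact of real recordings.

## Photometry correction (`calzone.photometry`)

Stages run in a fixed order: 5-s startup trim; artifact interpolation;
1-s moving-average smoothing; per-channel double-exponential baseline fit
and subtraction; motion correction; dF/F; whole-session z-score.

Numerical choices:

* **IQR fence.** A sample is flagged when outside
  [Q1 − k·IQR, Q3 + k·IQR] of a centered 20-s window (k = 4, stride one
  sample, truncated windows at the edges).  The fence is symmetric around
  the quartiles; only the multiplier is inherited from the procedure being
  implemented, the centering is our convention.  Flagged runs are linearly
  interpolated between nearest unflagged neighbors.  Note the fence can
  never flag a majority of a window (the middle 50% is inside it by
  construction); the >50%-flagged error is a defensive guard.
* **Moving average** uses truncated centered windows (no padding invents
  data at the edges).
* **Double-exponential fit**: nonlinear least squares with all four
  parameters bounded at zero; a b ≈ 0 term plays the role of an additive
  constant.  Initialization splits the series mean between a fast (5/T) and
  a slow (0.5/T) decay, with one fixed alternative start; the better
  residual wins, making the fit deterministic.
* **Motion correction** regresses the (baseline-subtracted) isobestic
  channel onto the primary by OLS and subtracts the fitted series.  dF/F
  divides by the *primary* channel's fitted baseline only.
* **z-scoring** uses the sample standard deviation (n − 1).

Every stage except the curve fit is checked against an independently coded
naive-loop reference (`calzone.naive`) to 1e-8; the curve fit is checked by
planted-curve recovery (RMSE well under 1% of the curve's amplitude at
noise s.d. 0.01).

## Peri-event quantification (`calzone.perievent`)

Traces are averaged in non-overlapping 1-s bins (final partial bin
dropped).  Entries/exits are 0→1/1→0 transitions of the one-hot occupancy;
gaps shorter than `min_visit_s` (default 1 s) are merged and remaining
visits shorter than the floor are dropped — tracking flicker otherwise
inflates entry counts.  Epochs span −5 s to +15 s around entries on the
trace clock; samples outside the session are NaN and the epoch is flagged
truncated, never zero-filled.  Named analysis windows are half-open
[start, end) so adjacent windows share no sample: pre (−3, 0), post (0, 3),
peri-entry (−1, 1), post (2, 4), late post (4, 6), approach (−6, −3)
relative to food contact.  Window summaries are epoch means first, then the
mean across epochs.  Food-contact events arrive as an explicit event
channel (they are manually scored in practice), not inferred from
proximity.

The peri-event curve is a local quadratic regression (tricube weights,
span = fraction of the time range, default 0.3) over all epoch samples
pooled, with a pointwise s.e.m. band from the raw per-epoch values.  A
span ≥ 1 degenerates, by our convention, to the unweighted global quadratic
fit.  One smoother serves all dataset sizes; the alternative spline-based
smoothers used elsewhere for large data differ only visually.

## Responsive-cell classification (`calzone.cellclass`)

Per cell: OLS of the session-z-scored, 1-s-binned trace on binary zone
predictors plus an intercept.  Predictors are bin occupancy fractions
binarized at 0.5.  Two-sided t-tests per predictor are Benjamini-Hochberg
adjusted *within each predictor across the cells of a session* — the family
matching "proportion of responsive cells" summaries.  Labels: excited if
q < alpha and the coefficient is positive (and, when the effect gate is
active, exceeds the threshold in magnitude), inhibited symmetrically,
nonresponsive otherwise.  Since traces are z-scored, coefficients are
already in s.d. units, so the gate (default 0.1 for small-enclosure
recordings, off otherwise) applies directly to the coefficient.  Traces are
z-scored for every task; the in-vivo procedure states this explicitly only
for the stimulation analysis, and we adopt it uniformly — it changes only
the units of coefficients, not p-values.

Rank-deficient designs (e.g. zones that tile the session exactly) raise an
error naming the collinear columns rather than silently dropping one.

Plain OLS inference is used deliberately — no autocorrelation correction —
so p-values are mildly anticonservative under the kernel-induced bin
autocorrelation; the validation studies quantify the realized error rate
(~5–6% of null cells modulated at alpha = 0.05 under the reference
conditions).

Proportions of responsive cells are compared within a condition by the
pooled two-sample z test (no continuity correction; the pooled form
satisfies z² = Pearson chi-squared on the 2x2 table, used as a
cross-check) and across conditions by the Pearson chi-squared test.  The
sidedness of the proportion z test is two-sided.

## Anxiety scores (`calzone.anxiety`)

Per test, scores are cohort z-scores with the sample s.d.; EPM and OF
scores are multiplied by −1 so higher always means more anxious.  The
overall score averages available test scores.  Animals are split at the
cohort *median* (robust to non-normal score distributions); ties at the
median are assigned "low" — deterministic and conservative in the number of
high-anxiety calls.

## Population structure (`calzone.population`)

The overlap coefficient is the integral of the pointwise minimum of two
Gaussian KDEs (Silverman bandwidth by default) on a shared grid extended 4
bandwidths past the data; it is 1 for identical distributions and decreases
monotonically as distributions separate.  A two-sample Kolmogorov-Smirnov
test accompanies it.  The per-cell interval-overlap alternative reading of
"proportion of cells with overlapping responses" is not implemented.

PCA eigendecomposes the *correlation* matrix of the registered
cell x condition response matrix (columns z-normalized across cells).
Components are ordered by decreasing eigenvalue and each loading vector is
sign-fixed so its largest-magnitude entry is positive, making results
deterministic.  Biplot arrow coordinates are loadings scaled by
sqrt(eigenvalue); plotting itself is out of scope.

## Decoding (`calzone.decoding`)

Cells are samples, pooled across animals (splits do not respect animal
identity, matching the original analysis; a grouped mode is a possible
extension).  Features are column-z-scored per-zone or per-time-bin means.
The classifier is a soft-margin SVC with RBF kernel
K = exp(−sigma·||x−y||²); sigma and cost are taken as fixed
hyperparameters (defaults sigma = 0.87, C = 1 for stage decoding at a 70%
training fraction; sigma = 0.43, C = 32 at 80% for anxiety-category
decoding), with stratified k-fold cross-validation on the training split as
confirmation and an optional 8-point power-of-2 cost grid.  Splitting is
stratified to avoid degenerate single-class test sets at small n.  The
no-information rate is the majority-class fraction of the *held-out*
labels, and the exact binomial test of accuracy > NIR is one-sided.  A
label-permutation control with empirical
p = (1 + #{perm ≥ observed})/(n_perm + 1) accompanies the parametric test.

## Statistics (`calzone.statcore`)

Benjamini-Hochberg is the standard step-up with enforced monotonicity
(cross-checked against statsmodels in tests).  The two-proportion z test
uses the pooled standard error by default.  The exact binomial test's
two-sided p sums all outcomes with point mass at most that of the observed
count.  Fisher's z comparison of two correlations uses
(atanh r1 − atanh r2)/sqrt(1/(n1−3) + 1/(n2−3)).  Routine tests
(Shapiro-Wilk, t, Wilcoxon, Mann-Whitney, ANOVA, log-rank) are left to
established libraries and are not wrapped here.

## Problem sizes in the validation studies

The seeded studies in `calzone.studies` use 15-min sessions (9000 frames),
300 cells x 10 seeds for the null error-rate study, 100 cells for planted
label recovery, 10-min photometry traces, 200 synthetic cells for decoder
calibration and 16-animal cohorts — sizes comparable to one experimental
cohort of the kind this pipeline targets, at which every study completes in
seconds to tens of seconds on one CPU.

## Known limitations

* OLS p-values ignore temporal autocorrelation (see above); error control
  is empirical, not exact.
* The generator's occupancy has no spatial continuity, so zone-boundary
  phenomena (partial occupancy bins) are milder than in real tracking.
* Effect sizes are defined against the *null* trace s.d.; after session
  z-scoring of a strongly modulated cell the realized coefficient shrinks
  slightly (the modulation itself inflates the session s.d.).
* Decoding pools cells across animals; per-animal generalization is a
  different, harder question the pipeline does not answer.
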