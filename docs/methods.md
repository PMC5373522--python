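# Methods

This note documents the models and procedures implemented in `aecg`, the
parameter defaults and why they were chosen, the design of the synthetic
generators, and what the test suite does and does not establish about real
data.

## Signal path

**Beat detection.** The QRS detection function is the spatial magnitude of
the band-passed (5-25 Hz, 2nd-order zero-phase Butterworth) Kors-derived
VCG. One peak per complex is taken above half the global maximum with a
250 ms refractory interval. This is deliberately simple: inputs are 10-s
resting recordings screened to exclude paced rhythms and gross noise, so no
arrhythmia logic is attempted.

**Signal averaging.** Beat windows span R−300 ms to R+450 ms. The running
template is seeded with the element-wise *median* across beats (robust to a
single corrupted complex), each beat is aligned at the lag (±50 ms)
maximising the QRS-window cross-correlation with the template, and beats
whose aligned QRS Pearson correlation falls below **0.97** are rejected;
the template is the *mean* of accepted aligned beats (one refinement pass).
0.97 on the QRS window is conventional signal-averaged-ECG practice; it is
a configurable argument, not a constant. The template is baseline-corrected
by the mean of its first 40 ms (before the P wave).

**Fiducials.** All windows are half-open `[onset, offset)` in 0-based
sample indices. QRS onset/offset are threshold crossings of the spatial
velocity `|d(X,Y,Z)/dt|` of the Kors-derived template at **20 % of the peak
QRS velocity**, sustained for a 10 ms hysteresis run; the landmark search
runs on a 40 Hz low-passed copy of the template so residual template noise
does not dominate the velocity signal (features are still computed on the
unfiltered template). The T offset uses the tangent method on the spatial
T magnitude: the steepest descending tangent after the T peak is
intersected with the zero baseline. P bounds come from a local-maximum
search before the QRS with a 10 %-of-peak span rule. A flat T (below 5 %
of the R magnitude) or absent P raises a fiducial error naming the
landmark; the pipeline logs and skips such records.

## Vectorcardiography

The VCG is derived with the Kors regression matrix (shipped as a
plain-text 3×8 config, columns I, II, V1-V6). Axis convention: X positive
leftward, Y positive inferior, Z positive **posterior** — anterior
precordial leads carry negative Z weights, which is what makes the
posterior-to-leftward QRS loop ratio read directly off positive Z and X
excursions. Data digitised with anterior-positive Z can set
`z_anterior_positive=True`.

Mean QRS and T vectors are time averages over `[qrs_onset, qrs_offset)`
and `[qrs_offset, t_offset)` respectively; the T window starts at the J
point because mean-vector conventions use the full JT segment (no separate
T onset is detected). The *peaks* angle uses the sample of maximal spatial
magnitude in each window; whether per-axis peaks should be used instead is
a known ambiguity in the field — the maximal-magnitude reading is
implemented and exposed.

All integrals are trapezoidal in mV·ms. Azimuth is measured in the
horizontal (X-Z) plane with 0° leftward and +90° posterior; elevation is
positive toward +Y (inferior).

## SVD complexity

Singular values are taken of the `[window × 8]` matrix of the independent
leads; any other column count is rejected, because appending a linearly
dependent lead (III, aVR…) silently distorts the spectrum. Dipolar and
nondipolar voltages are RMS equivalents `√(Σ₁³σᵢ²/n)` and `√(Σ₄⁸σᵢ²/n)`;
this normalisation is self-validating through the Parseval identity
(dipolar² + nondipolar² equals the mean-square signal power of the
window), which the tests assert. The literature is not unanimous on the
`1/n` factor, so `normalize_by_n=False` exposes the raw root-power sums.
The PCA ratio `100·σ₂²/σ₁²` is computed for both the QRS and T windows.

## Risk scores

The 5-parameter LVSD score is a fixed published logistic model over the
spatial mean QRS-T angle, Frank Z-lead QRS integral, total 12-lead QRS
voltage, QRS nondipolar voltage and T dipolar voltage. Its coefficients
are **not bundled**: the packaged file `lvsd_coefficients_synthetic.txt`
is a clearly labelled synthetic example for tests and demos only, and real
analyses must supply the published coefficient file. The score's
orientation (more negative = more diseased, consistent with a cutoff of
≤ −2.04 and a protective per-unit hazard ratio) is recorded on the
coefficients object rather than hard-coded.

ELI is `(AVA·Aa)/(Aa − AVA)` (cm², optionally indexed to BSA), defined
only for `Aa > AVA > 0`; it decreases monotonically toward AVA as the
aorta widens. The therapy-response rule uses absolute LVEF percentage
points: Δ > 10 responder, Δ < −10 deteriorator, otherwise nonresponder —
a change of exactly −10 points is nonresponse, because the "≤ 10 % change"
clause takes precedence.

## Cohort statistics

- Screening: Welch's unequal-variance t-test per numeric variable
  (pooled-variance optional); constant variables are flagged untestable
  rather than raising. Bonferroni control uses α/m with m defaulting to
  the number of testable variables: α = 0.05 and m = 291 gives 1.7×10⁻⁴,
  and m = 291·290/2 = 42 195 pairs gives 1.2×10⁻⁶.
- ROC: rank (Mann-Whitney) AUC with tie correction; DeLong variance for
  the 95 % CI; the optimal cutoff maximises Youden's J over midpoints
  between observed values, with ties broken toward higher sensitivity
  (matching the sensitivity-favouring published operating points).
- Survival: Kaplan-Meier product-limit curves with the log-rank test, and
  Cox proportional hazards by maximum partial likelihood with Efron tie
  handling (lifelines) — Efron because day-granularity times tie often.
  Wald 95 % CIs; non-convergence or separation raises a fit error.

## Networks and similarity

Pairwise-complete Pearson correlations (missingness is pervasive in echo
metadata, so listwise deletion would be wasteful); p-values via the
t-transform of r with n−2 degrees of freedom. Edges require |r| > 0.45;
an edge is *significant* when it has more than 82 paired observations and
p < 1.2×10⁻⁶. The ">82 instances" rule is implemented as a significance
gate, not as a variable pre-filter. The certainty index is the percentage
of variables participating in at least one significant correlation.
Metrics (degree, normalised betweenness, shortest-path lengths) run on the
unweighted graph; disconnected pairs are counted separately rather than
given infinite length. The rewiring score of a node between two networks
on the same variables is 1 − cosine similarity of its edge-weight vectors
(absent edges weigh 0); nodes isolated in both networks score 0.

Patient similarity is the cosine similarity of z-scored feature vectors,
with missing entries imputed to the column mean (0 after z-scoring). Raw
dot products are scale-dominated, which is why normalisation is the
default (`raw_dot_product=True` restores them). The within-event versus
event-vs-nonevent median difference is tested by label permutation.

## Synthetic generators

**ECG.** The dipole model builds the VCG directly: QRS and T are loops
with raised-cosine envelopes of *compact support* (so onset/offset ground
truth is exact) around configured spatial mean vectors, plus a
zero-time-integral quadrature component scaled by the loop eccentricity
(default 0.2) that widens each loop. The loop normal is chosen
perpendicular to **both** mean vectors, so truncating an integration
window (e.g. a tangent-method T offset that lands slightly early) perturbs
only vector magnitudes, never the QRS-T angle — this is what makes ±2°
noiseless and ±5° noisy end-to-end recovery achievable and honest. A
small P wave precedes each QRS. The 8 leads are produced by projecting
through the minimum-norm right inverse of the Kors matrix (so derivation
is exact on noiseless data), limb leads completed by Einthoven identities,
and white Gaussian noise added per lead. Defaults: 500 Hz, 10 beats at
60 bpm, QRS 100 ms, T 200 ms, QRS|T mean-vector magnitudes 1.5|0.4 mV,
2 ms beat jitter.

**Cohort.** Defaults emulate the two-group study table: 246 non-event vs
49 event patients; spatial QRS-T angle Normal(112, 38) vs Normal(134, 33)
degrees; diabetes prevalence 21 % vs 37 %; age 60 ± 12 vs 64 ± 9; LVEF
36 ± 2.9 vs 35 ± 2.9 %; P/L ratio means 1.15 vs 2.15. A shared latent
severity factor (loading 0.7 for the repolarisation family, weaker for
structural/echo variables) induces the strong intercorrelations real
A-ECG/echo metadata show, giving the correlation network edges above the
0.45 threshold. Survival columns use an exponential hazard
(10⁻⁴ events/day below the 110° cutoff) over a 1 814-day horizon with
uniform censoring — chosen to give ≈17 % primary events; heart-failure
admissions use a smaller baseline hazard (4×10⁻⁵) with a true hazard
ratio of 4.1. Two designs: `case_control` fixes group sizes (group-mean
emulation), `prospective` draws angles from the mixture and events from
the hazard with true HR 3.4 (estimator-recovery studies).

**What the generators do not emulate.** Realistic PQRST morphology beyond
what fiducial detection needs (no notching, no U waves, no baseline
wander or muscle artefact); respiratory modulation; the full 291-variable
covariance of real metadata (the synthetic cohort has ~14 variables, so
absolute similarity medians and network sizes are smaller than a real
cohort's, and the tests assert orderings and recoveries, not those
absolute magnitudes). Passing tests therefore demonstrate correctness of
the computations and recoverability under the stated conditions, not
clinical performance.

## Numerical choices and degenerate inputs

- Trapezoidal integration throughout; at 500 Hz it differs from a Riemann
  sum by < 0.5 % on simulated beats.
- Angle computations clip cosines to [−1, 1]; zero-magnitude vectors raise
  a domain error rather than returning NaN.
- The P/L ratio is 0 for loops with no posterior excursion and undefined
  (error) without a leftward excursion.
- Problem sizes in the test suite are desk-scale by design: 200 cohort
  replicates for AUC and Cox coverage, 100 seeded records for end-to-end
  angle recovery, 20-60-sample matrices for oracle equivalence.

## Known limitations

- WFDB input requires the optional `wfdb` dependency; CSV is the
  first-class path.
- The tangent T-offset lands slightly before the true end of a
  compact-support T wave; by the loop-normal construction this does not
  bias the angle, but SVG and SAI are measured a few percent low relative
  to the analytic full-support values (tests allow 2-3 %).
- The LVSD score ships without published coefficients (see above).
- Fiducial location assumes the largest spatial-magnitude deflection is
  the QRS; extreme T-dominant morphologies would need a configured R
  position.
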