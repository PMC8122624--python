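# Methods

This note documents the models, conventions and parameter choices behind
`fatiguemark`, what the synthetic-data generator does and does not
emulate, and the problem sizes used by the verification studies.

## Data model and epoching

A session is a 10 × n float64 matrix (µV) at 508.6 Hz with the fixed
electrode order LO, RO, LT, RT, LFL, LFM, RFL, RFM, FZ, CZ.  Event times
are seconds from session start; sample indices are `round(t·fs)` and all
windows are half-open `[start, start+n)`, 0-based — one convention
everywhere, so epoch extraction is a pure slice and every epoch sample
equals the corresponding session sample exactly.

Three evaluation periods are defined per trial: `delay` starts at the
delay-cue onset (the main analysis window), `target` at target onset,
and `pre_target` ends at target onset.  The pre-target interval of the
task is variable in length, so the package uses a fixed-length window
ending at target onset; this keeps all epochs the same length and lets
one feature path serve all periods.  Trials whose window falls outside
the recording, and event rows without an outcome, are dropped and
counted in the log.

Signals travel as a lossless HDF5 container (`/data`, `/fs`,
`/channels`) or as 16-bit EDF.  The EDF encoder picks the smallest
record duration (0.5-s steps) holding an integer number of samples —
5 s at 508.6 Hz — and zero-pads the final record; EDF is quantized to
the per-channel amplitude range by construction, and the round trip is
validated in the tests against the independent MNE reader.

## ICA artifact removal

FastICA with as many components as channels, whitening on, fixed seed.
The contrast function is `cube` (kurtosis): the generator's sources are
distinguished by their amplitude burstiness, and the kurtosis contrast
converges quickly there while `logcosh` stalls.  Component time courses
are correlated with the *raw* LFL and RFL traces over the whole session
(this is a session-level stage; epoching comes later).  A component is
ocular when |r| exceeds the threshold (default 0.1) against **both**
references: ocular potentials are picked up by both lateral-frontal
electrodes, and requiring both keeps genuinely frontal neural components
— which correlate strongly with one reference only — out of the removal
set.  The either-reference rule is available as
`reference_mode="any"`.  |r| is used because component signs are
arbitrary.  Back-projection with nothing removed reconstructs the input
to round-off; cleaning never changes shape, rate or channel order.
Re-running ICA on a cleaned session may decompose differently, so
idempotence is deliberately not claimed.  For long sessions the unmixing
matrix can be estimated on every k-th sample (`fit_stride`); component
time courses and back-projection always use the full recording.  The
pipeline uses stride 4 on ~30-minute sessions.

## Biomarkers

* **Band powers** — Hann-windowed Welch periodogram over the full epoch
  (a 1-s epoch gives ~1 Hz resolution), integrated over the half-open
  band interval.  Bands: delta 1–4, theta 4–8, alpha 8–13, low-beta
  13–20, high-beta 20–30, low-gamma 30–45, gamma 60–90, high-gamma
  100–200 Hz.
* **Wavelet entropy** — `db4`, 4 decomposition levels; the Shannon
  entropy is taken over all K = 5 relative subband energies (4 details
  plus the approximation), which conserves energy; a details-only K = 4
  variant is available via `FeatureConfig(entropy_include_approx=False)`.
  Zero-energy subbands contribute 0 (p·ln p → 0); an all-zero epoch is
  an error.
* **Hjorth** — activity var(y); mobility √(var(Δy)/var(y)) with Δ the
  first difference; complexity mobility(Δy)/mobility(y).  A constant
  epoch returns activity 0 and NaN mobility/complexity; NaNs are treated
  as missing downstream.
* **PAC modulation index** — phase from the analytic signal of the
  3–7 Hz trace, amplitude envelope from the 70–130 Hz trace, N = 18
  phase bins (20°), MI = (ln N − H(P))/ln N of the normalized mean
  envelope per bin, clamped to [0, 1].
* **IA/IF** — instantaneous amplitude |analytic(δ-filtered)| and
  instantaneous frequency (1/2π)·d(unwrapped phase)/dt of the 4–14 Hz
  analytic signal, both averaged over the interior 80% of the epoch;
  the IA/IF ratio is missing when the mean IF is non-positive.
* **PDC** — MVAR fitted by least squares at order p = 5: a 1-s epoch
  (509 samples, 10 channels) supports the ~500 coefficients of p = 5
  with a safety factor of two, and an AIC scan utility
  (`mvar_order_scan`) is provided for other data.  With
  B̄(f) = I − Σₖ Aₖ e^{−i2πfk/fs}, the feature is the squared PDC
  |B̄ᵢⱼ|²/(b̄ⱼ*b̄ⱼ) averaged over the band's 1-Hz frequency grid; columns
  (sources) are normalized so Σᵢ PDC²ᵢⱼ(f) = 1 exactly.  Column names
  read `pdc.SRC→DST.band`.  ICA-cleaned sessions are rank-reduced (one
  rank per removed component), so the feature path accepts the
  minimum-norm least-squares MVAR solution there; direct `fit_mvar`
  calls still reject singular regressions.  "Beta" for connectivity maps to low-beta
  (13–20 Hz); the connectivity bands are delta, theta, alpha, low-beta.
* **PLI** — |T⁻¹ Σₜ e^{iΔθₜ}| from Hilbert phases of the band-filtered
  pair, edge-trimmed.  The formula is the classical phase-locking value;
  the package keeps the name PLI used in this literature.  Note that a
  1-s delta-band epoch holds 1–4 cycles, so delta PLI/PDC values on
  short epochs are intrinsically noisy — the null expectation for
  independent signals is E|PLI| ≈ (√π/2)·√(Σ_τ|ρ(τ)|²/T) with ρ the
  band phasor autocorrelation, which the tests verify.
* **Global coherence** — DPSS multitaper (3 tapers, NW = 2) on
  50%-overlapping ~1-s segments; GC(f) = λ_max/Σλ of the averaged
  cross-spectral matrix, band-averaged; bounded in [1/C, 1].  With a 1-s
  epoch only 3 outer products are averaged, so the single-epoch null
  level is well above 1/C; it decays toward it on longer windows.
* Band filters everywhere are 4th-order zero-phase Butterworth
  (`sosfiltfilt`, reflective padding).

`extract_features` produces 708 named columns for 10 channels (80 band
powers, 10 entropy, 30 Hjorth, 10 PAC, 30 IA/IF, 360 PDC, 180 PLI, 8
GC), each registered to exactly one of the 17 families.  Degenerate
values stay NaN in the table; imputation happens inside the classifier
with training-fold medians only, so no test-fold statistic ever reaches
training.  Feature-set conditions: `spectral` = the 8 band-power
families, `HOST` = the other 9, `combined` = all.

## Classifier and evaluation

XGBoost, 30 trees, maximum depth 4, learning rate 0.3, L2 regularization
1.0, histogram tree method, single thread; the intercept (`base_score`)
is left to the library's estimate from the training class prior, and can
be fixed explicitly.  The positive class is the incorrect trial.

Wrapper forward selection: per step, every candidate column is scored by
the pooled F1 of a stratified inner 5-fold CV of the ensemble on the
current set plus that candidate; the best is added (ties break to the
lower column index, making selection deterministic and duplicate-proof).
Selection stops at `k_max` (default 15) or after 2 consecutive steps
without a ≥ 1e-3 improvement — the training curve saturates within
5–10 features on this problem, which motivates the budget.  For very
wide tables a training-fold point-biserial R² screen
(`screen_top_m`) can restrict the candidate pool before the greedy scan;
cohort-scale runs use m = 20-30, and `screen_top_m=None` scans everything.

Nested evaluation: outer stratified 5-fold split; wrapper selection,
median imputation and model fitting see only the outer-training folds;
metrics are computed on the held-out fold, then pooled by summing
confusion counts (per-fold means are reported alongside, since both
views are informative when sessions are averaged).  Each report carries
hashes of the fold index sets as an audit trail.  Metrics: precision,
sensitivity, specificity, accuracy, F1 (0 when precision + sensitivity
is 0, NaN when undefined), balanced accuracy = (sensitivity +
specificity)/2.  The all-positive baseline F1 = 2P/(2P + N) is attached
to every report.  Models are session-specific; cross-session pooling
sums confusion counts.

Single-electrode models use only that channel's 16 single-channel
columns; period/window comparisons rerun the full pipeline per period.

## Synthetic sessions

What the generator emulates, and why:

* **Fatigue and outcomes.**  A latent state follows a positive-drift
  random walk squashed through a logistic (slope 0.012/trial, walk SD
  0.05), and P(incorrect) = logistic(a + 4f).  Over ~300 trials the
  error rate climbs from roughly 20% to 70%, reproducing the
  within-session performance decline.  The intercept can be re-solved
  per session to hit a target incorrect fraction; cohort regimes
  `balanced` (≈ 0.52) and `unbalanced` (≈ 0.72) mirror the two animals'
  mean per-session correct/incorrect counts (254/270 and 202/518).
  Trial delays are N(2500 ms, 250 ms) truncated at 500 ms; the fixation
  interval between target and delay cue is 1 s.
* **Background.**  Per channel: 1/f^1.5 noise (20 µV RMS), waxing-waning
  10 and 20 Hz narrowband rhythms, a bursty channel-specific oscillation
  (7–24 Hz across the array, 20 µV RMS, strongly super-Gaussian
  envelope), a ~50 Hz mid-gamma component (8 µV RMS), a slow log-normal
  amplitude envelope (log-SD 0.15–0.35 by channel, 30-s timescale), and
  a 0.5 Hz acquisition high-pass.  Three of these choices are
  load-bearing: the distinct bursty rhythms make the channels separable
  by ICA (near-Gaussian backgrounds are provably not), the slow
  amplitude envelopes give raw power features the trial-to-trial
  instability that makes scale-invariant HOST features comparatively
  reliable — the phenomenon the real analysis reports — and the
  high-pass removes sub-delta drift whose tiny effective sample count
  would otherwise produce spurious component–reference correlations.
* **Class effects**, injected only into the delay window of incorrect
  trials: (i) additive 1–10 Hz noise (10 µV RMS per unit gain) on FZ and
  CZ — the low-frequency power elevation, which also moves broadband
  variance, entropy and mobility on those channels, and the ground-truth
  record attributes all of these honestly; (ii) suppression of the
  ~50 Hz component on LT and RT — wavelet energy concentrates in the
  slow subbands, so entropy and mobility drop, while every band-power
  feature is blind to 45–60 Hz (the gap between the low-gamma and gamma
  bands), making this a HOST-only effect; (iii) a power-preserving
  alpha-band substitution on the FZ→CZ pair (part of CZ's alpha replaced
  by FZ's 6-ms-lagged alpha) — directed coherence and phase locking rise
  with no power signature; alpha is used because a 1-s window holds ~10
  alpha cycles but only 1–4 delta cycles, so delta-band phase coupling
  is not estimable at this window length; (iv) saccade-like artifacts:
  a 50-ms biphasic transient plus a 300-ms 2 Hz drift burst, mixed
  through a frontal-dominant vector (LFL 1.0, RFL 0.9, midline ≤ 0.2),
  in storms on incorrect trials and sparsely on correct ones.  A
  separate AR(2) construction with one-way coupling
  (`coupling_ar_coefficients` + `simulate_var`) provides the analytic
  PDC oracle used in testing.
* **What is not emulated:** volume conduction and realistic cortical
  geometry, reaction-time structure, eye position, non-stationarity of
  the effect sizes themselves, inter-subject variability beyond class
  balance, and any stimulation-related activity.  Passing tests
  therefore demonstrate that the pipeline recovers the *kinds* of
  structure the analysis assumes at realistic SNR — not performance on
  real recordings.

Effect gains default to 1, calibrated once so that the full pipeline
separates classes clearly above the all-positive baseline at realistic
trial counts; gain 0 disables an effect, and with all gains 0 and
outcome gain 0 labels are independent of the signal (the null model).

## Verification-study problem sizes

Chosen to make the studies reproducible on one CPU in minutes, and fixed
in `fatiguemark.study`:

* strong-effect cohort: 10 balanced sessions, ~300 trials each, nested
  CV with k_max 4 and screen m = 20; pooled F1 is compared with the
  pooled all-positive baseline and wrapper picks with the ground truth;
* label-shuffled null: 2 unbalanced sessions at the 720-trial count the
  unbalanced regime's mean counts imply (202 + 518); at a few hundred
  trials the honest null sits several F1 points below the baseline
  because the fixed-size ensemble overfits label noise and predicts the
  minority class too often, while at the regime's own session length it
  sits within a couple of points — the null is therefore evaluated at
  that length;
* HOST-versus-spectral: 3 balanced sessions, ~220 trials, with only the
  HOST-side effects (ii) and (iii) injected;
* ICA study: one 60-trial session with 150 µV artifacts; reported are
  removed-component count, LFL/CZ delta-power changes, and the
  single-electrode F1 spread before/after cleaning;
* PDC oracle: the embedded AR(2) pair at n = 5000 samples;
* delay distribution: 100 000 draws.

## Known limitations

* Wrapper selection over all 708 columns inside nested CV is expensive
  (hours per session on one CPU); the R² pre-screen is the supported
  desk-scale path and is honest (computed on training folds only), but
  it can in principle discard a feature whose value is purely
  multivariate.
* Delta-band connectivity features on 1-s epochs are close to their
  noise floor by construction (1–4 cycles); they are retained because
  the feature contract requires them, not because they are individually
  informative at this window length.
* EDF output is 16-bit and record-padded; use the HDF5 container when
  lossless round trips matter.
* The ICA stage assumes the ocular component is separable and reaches
  both lateral-frontal references; an artifact confined to one electrode
  would evade the both-reference rule (switch to `reference_mode="any"`
  for that case at the cost of occasionally removing genuine frontal
  components).
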