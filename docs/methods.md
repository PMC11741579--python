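# Methods

`actloc` simulates active sound localisation as recursive Bayesian
inference over a discrete set of candidate source directions.  This note
describes the model, the synthetic world it runs in, the numerical choices,
and what the shipped simulations do and do not demonstrate.

## The observer model

**Acoustic features.** Each direction on a quasi-uniform template grid
(default 2042 Fibonacci-spiral points) is summarised by a 65-dimensional
feature vector `[T_itd, T_L, T_R]`: the interaural time difference (ITD)
expressed in just-noticeable-difference (JND) units, plus two 32-channel
excitation spectra in dB.  The spectra come from a gammatone filterbank on
the ERB scale (300 Hz–15 kHz) followed by a simplified inner-hair-cell
stage: half-wave rectification, five cascaded first-order 2-kHz low-pass
filters, and a dB transform.  The TOA underlying the ITD is the first
crossing of max − 10 dB on the 3-kHz-low-passed impulse response;
`TOA(left) − TOA(right)` is positive for sources on the right.

**ITD scale.** The JND map is an odd, strictly monotone cumulative-JND
count with a linearly growing local JND width, `w(t) = w0 + g·t` with
`w0 = 20 µs` and `g = 0.114`, so one JND is 20 µs at the midline and about
100 µs near the 700-µs limit.  The closed form
`f(t) = log(1 + g·t/w0)/g` is tabulated at configurable knots and
interpolated piecewise-linearly.  On this scale, additive observation noise
corresponds to the multiplicative precision loss of large ITDs.

**Generative observation model.** A look is
`y = [y_itd, y_L, y_R]` with `y_itd = T_itd(ψ_rel) + δ_itd`,
`y_{L,R} = T_{L,R}(ψ_rel) + S + δ_{L,R}`, where `ψ_rel` is the source
direction in the current head frame, `S` the true source spectrum (the
white-noise stimulus through the same front end, plus per-trial ±2.5 dB
level roving), and the δ terms are zero-mean Gaussian with SDs `σ_itd`
(default 0.6 JND) and `σ_I` (default 3.5 dB per channel).  The observer
does not know `S`; it subtracts its expected spectrum `Ŝ` and carries the
residual uncertainty as a covariance `Σ_S`.  The full 65×65 feature
covariance is block-structured: the ITD variance is uncoupled, each ear
block is `σ_I²I + Σ_S`, and the ear-cross blocks equal `Σ_S` (the source is
common to both ears).  The first look of a trial is full; every later look
(one per `Δt = 100 ms`, plus the end of the rotation in active trials)
carries the ITD alone, entering as an independent absolute-ITD likelihood
term.  The alternative reading (first-differenced ITDs) is noted as an open
modelling choice; the independent-terms form matches the recursive
i.i.d. assumption of the update rule.

**Head-orientation belief.** The yaw belief is a scalar Kalman filter:
gain `K = (σ² + σ_u²)/(σ² + σ_u² + σ_H²)`, mean
`(1−K)(μ + uΔt) + K·y_H`, variance `(1−K)(σ² + σ_u²)`, initialised at the
first orientation reading with SD `σ_H`.  The motor input `u` is the
executed rotation increment as a head tracker would log it, so with
`σ_H = σ_u = 0` the observer knows the true orientation exactly.  Pitch and
roll contamination is a per-trial constant the observer reads with the same
sensor SD.  At each look the orientation integral is discretised over
`n_candidates = 9` evenly spaced yaws spanning ±2 posterior SDs (≈95% of
the belief mass; a dense-quadrature oracle test shows ≤1% total-variation
error at ±4 SDs), weighted by their proper Gaussian density and
renormalised.

**Posterior and decision.** The direction posterior is updated
multiplicatively, `p_t ∝ p_{t−1} · Σ_c w_c L_A(y_t | θ_c, ψ)`, entirely in
log space with max-subtraction; Gaussian normalisation constants that
cancel in the posterior are dropped.  The initial prior is Gaussian in
elevation with SD `σ_p` (default 30°; `∞` gives uniform).  The response is
drawn by posterior matching (PM, a weighted sample — the default) or MAP
(argmax, ties to the lowest index).

## The synthetic world

The generator replaces everything a behavioural study would measure.

**HRIRs** come from a rigid spherical head (radius 8.75 cm, Woodworth
delays, head-shadow low-pass on the far ear) with ears at ±100° azimuth and
−10° elevation, plus a parametric pinna: a deep, broad primary notch whose
frequency rises from ~3.6 to ~10 kHz over −90°…+90° elevation, a second
notch at 1.4× that frequency, a fixed 10.5-kHz notch deepening with
rearness, and a rear high-frequency tilt.  Two structural choices matter
and were made deliberately:

* Ears off the equator give the ITD a weak elevation dependence.  With
  ears exactly on the interaural axis, up/down mirror directions share
  *identical* ITDs both statically and throughout a yaw rotation, so no
  amount of ITD precision could resolve elevation sign; real heads are not
  so degenerate.
* The front/back cue is a localized notch rather than only a broad tilt,
  because a broad tilt is statistically confounded with the observer's
  smooth source-spectrum uncertainty.

Magnitude responses are realised minimum-phase (via the real cepstrum) and
delayed per ear, so onset-based TOA estimation stays causal.  Impulse
responses are 256 samples at 48 kHz.  The notch parameters were fixed at
design time so that static spectral cues are informative but imperfect:
passive polar errors remain well above active ones, head rotation removes
quadrant errors, and elevation remains decodable without a prior.  They
were not revisited against any acceptance threshold.

**Source spectra.** The corpus generator emulates natural recordings as a
per-clip broad tilt (SD 2 dB/octave) plus smooth correlated channel
deviations (SD 6 dB) plus a clip gain (SD 5 dB); segments within a clip add
an AR(1) deviation (SD 3.8 dB, coefficient 0.3) so adjacent 100-ms segments
correlate at ρ ≈ 0.8, the value reported for natural-sound corpora.  The
observer's `(Ŝ, Σ_S)` is the pooled mean and ridge-regularised covariance
(ridge 1e-6) of 200 clips × 10 segments.

**Trajectories.** Passive trials hold the head still for the 500-ms
stimulus with 0.3° per-sample yaw jitter and constant pitch/roll offsets
(SD 0.8°/0.5°).  Active trials ramp the yaw at a log-normal speed (median
15.75 deg/s, log-SD 0.5 — making the median 10° rotation last ~635 ms)
until the 10° gate, the last sample landing exactly on the gate.  Left and
right rotations with the same seed are exact mirrors.  Movement gates
follow the behavioural protocol: passive trials are excluded above 2° of
any-axis movement, active trials outside 7–13° total yaw or above 6° pitch
(boundaries kept); with the default jitter ≥95% of generated trials pass.

**What the world does not contain.** Torso/room acoustics, moving sources,
measured pinna fine structure, listener-specific spectral idiosyncrasies,
closed-loop movement strategies, pointing/response errors, and
multiplicative motor noise.  Passing tests therefore show that the
inference machinery behaves as specified on a world satisfying the model's
assumptions — not that the generator's error *magnitudes* match human data.
Qualitative orderings (error growth with each noise SD, QE removal by
rotation, prior-strength effects on elevation gain) are the intended
transferable content.

## Numerical choices

* Σ_A is Cholesky-factorised once per configuration; full-look
  log-likelihoods use the expanded quadratic form with per-template cached
  `Σ⁻¹Tᵀ`, which matches the direct Mahalanobis evaluation to 1e-9 and
  makes a 2042-direction look cost one 65×2042 product.
* The ITD variance is floored at `(0.05 JND)²` so Σ_A stays invertible in
  `σ_itd = 0` sweeps; 0.05 JND (≈1 µs) is below the template's own
  quantisation scale.
* Head-relative template lookups are nearest-neighbour through index maps
  cached per 0.05°-quantised orientation and shared between the generative
  world and the observer, so a hypothesis at the true direction and
  orientation reproduces the noiseless features exactly.  Nominal targets
  are rendered at their nearest grid direction for the same reason.
* dB aggregation: the default is dB of the envelope RMS.  The alternative
  sentence-order reading (aggregate in the dB domain) is exposed as
  `db_domain_average=True` and implemented as a dB-domain mean, since an
  RMS of signed dB values is not order-preserving and would break level
  equivariance.
* Silence floor −120 dB; polar errors wrapped to [0, 180]; responses
  exactly on the frontal/horizontal plane count as non-crossing; polar RMSE
  covers only |lateral| ≤ 30° targets without reversal flags (quadrant,
  front/back and up/down all excluded).
* Per-trial random substreams derive from
  `(master seed, subject, condition, direction, repetition)`, so trial
  tables are bit-identical across runs and independent of schedule order.

## Problem sizes of the shipped simulations

The packaged experiment runs 8 synthetic listeners × 33 directions × 5
repetitions × 3 conditions (3,960 trials) per configuration on the
2042-direction template, which a single core completes in about a minute;
parameter sweeps reuse one world (templates, prior, stimulus) across
values.  These sizes are the package defaults for reproducible desk-scale
study; the 20-repetition protocol of the full design is available by
setting `repetitions=20`.

## Known limitations

* The Kent summary is a tangent-plane moment fit (centroid + 2-SD axes),
  not a maximum-likelihood Kent estimate; it is intended for descriptive
  response-ellipse maps.
* ITD-only follow-up looks use absolute ITD values; a first-difference
  variant would change how orientation errors propagate and is not
  implemented.
* The lateral-pole target makes the default 33-direction layout minimally
  left-asymmetric; metrics that average over directions are insensitive to
  this, and the layout is a documented constant.
* The SOFA reader assigns equal quadrature weights; strongly non-uniform
  measured grids should be re-weighted before quadrature-sensitive use.
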