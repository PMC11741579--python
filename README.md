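# actloc

Bayesian ideal-observer simulation of **active sound localisation** — how
well a listener *could* localise a broadband sound on the full sphere,
given noisy acoustic cues, uncertain knowledge of their own head
orientation, and small voluntary head rotations.

## The problem and the model

Head-centred acoustic cues are ambiguous: all directions on a "cone of
confusion" share nearly the same interaural time difference (ITD), so
front/back and up/down errors are common when the head is still.  Rotating
the head changes the cues in a direction-dependent way, and an observer who
integrates those changes with knowledge of its own rotation can resolve the
ambiguity — and even extract elevation from the *rate* of ITD change (the
Wallach cue).

`actloc` implements this as recursive Bayesian estimation over a discrete
direction grid ψ:

* **Template matching.** Per direction the observer stores
  `T_A = [T_itd, T_L, T_R]`: the ITD in JND units and two 32-channel
  ERB-scale excitation spectra (gammatone filterbank, rectify + 2-kHz
  low-pass inner-hair-cell stage, dB).
* **Acoustic likelihood.** A look `y_A` is scored by the Mahalanobis
  distance to the template of each candidate direction under a structured
  covariance Σ_A built from the ITD noise σ_itd, the spectral sensor noise
  σ_I, and the observer's source-spectrum uncertainty Σ_S (shared between
  the ears).  The first look carries all 65 features; later looks (every
  Δt = 100 ms) carry the ITD alone.
* **Sensorimotor integration.** The head-yaw belief is a scalar Kalman
  filter over motor commands and orientation readings (noise SDs σ_u,
  σ_H); the acoustic likelihood is marginalised over candidate orientations
  spanning ±2 posterior SDs.
* **Recursive posterior and decision.**
  `p_t(ψ) ∝ p_{t−1}(ψ) · Σ_θ L_H(θ) L_A(y_t | θ, ψ)`, starting from a
  Gaussian elevation prior (SD σ_p); the response is a posterior-matching
  draw or the MAP direction.

Because measured HRTFs and human trajectories are not shipped, the package
includes a first-class synthetic world: spherical-head HRIRs with
parametric pinna notches (elevation and front/back cues that are
informative but imperfect), a natural-like source-spectrum corpus
(adjacent-segment correlation ρ ≈ 0.8) from which the observer's spectral
prior is fitted, and jittered passive/active head trajectories.  The full
study design is reproduced in simulation: 33 source directions over the
sphere, passive (500-ms stimulus) and active (10° left/right rotation)
conditions, level roving, movement-gate exclusions, and the standard
metrics — lateral/polar RMSE, quadrant / front-back / up-down reversal
rates, elevation gain, and Kent-style response ellipses.

## Worked example

```python
from actloc import NoiseConfig, make_design, build_world, run_experiment, summarize

design = make_design(repetitions=2, n_subjects=2)     # scaled-down study
world = build_world(design, master_seed=0)            # templates, prior, stimulus
trials = run_experiment(design, NoiseConfig(), rule="PM", master_seed=0, world=world)
kept = trials[~trials.excluded]
print(f"{len(kept)} of {len(trials)} trials kept")
print(summarize(kept).groupby("condition")[
    ["lateral_rmse", "polar_rmse", "qe_pct", "fbc_pct", "udc_pct"]
].mean().round(1))
```

prints

```
394 of 396 trials kept
              lateral_rmse  polar_rmse  qe_pct  fbc_pct  udc_pct
condition
active-left            4.3        10.6     5.3     17.4     11.4
active-right           4.0        11.0     3.8     12.1     14.4
passive                3.9        18.2     8.5     32.3     14.6
```

Reading the numbers: lateral RMSE (degrees) is small and condition-
independent — the ITD pins the left/right angle with or without movement.
The polar RMSE drops from 18.2° (passive) to ~11° (active): the rotation
supplies the dynamic cue that sharpens polar estimates.  The quadrant-error
rate (polar error > 90°) falls by roughly half in the active conditions;
with larger trial counts and the default noise it settles near 13% passive
vs 2% active — head rotation resolves the cone-of-confusion reversals that
spectral cues alone leave behind.  FBC/UDC are the coarse plane-crossing
rates, inflated by targets lying on the reference planes.

Two lines swap in the research questions: `NoiseConfig(sigma_itd=3.0)`
degrades the ITD, `NoiseConfig(sigma_H=8.0)` degrades head-orientation
knowledge, `parameter_sweep("sigma_p", [10, 30, 90], ...)` sweeps the
spatial prior, and `rule="MAP"` switches the decision strategy.

A thin CLI wraps the same calls:

```bash
actloc run  --config cfg.yaml --seed 1 --out trials.csv --metrics-out metrics.csv
actloc sweep --param sigma_itd --values 0,0.6,1.2,3 --seed 1 --out sweep.csv
```

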