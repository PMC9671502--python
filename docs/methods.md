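# Methods

This note records the models, parameter choices and numerical decisions
behind `premove`, and what the synthetic-data studies do and do not
demonstrate about real recordings.

## Data model and time conventions

A session is an (areas × frames) matrix at `fps_neural` (default 30 Hz) with
behavioral events in float seconds and optional body-part tracks at
`fps_video` (default 15 Hz). One convention is used everywhere: frame *i*
corresponds to time *i*/fps, peri-event time t = 0 is the event, and windows
are half-open `[t_start, t_end)` in frames. Events detected on video are
stored in seconds and mapped to the nearest neural frame at use time; the
session container never rescales or reorders times. Trial extraction places
t = 0 exactly on frame `round(t_event * fps)`, so peri-event alignment is an
identity, not an interpolation.

## Synthetic sessions

`SynthConfig`/`generate_session` produce sessions with the structure the
analyses assume, with every implanted parameter recorded in
`meta["ground_truth"]`:

- **Background.** Per area: a sinusoid at a fixed per-session frequency
  (drawn uniformly in 0.2–0.6 Hz) plus mean-reverting Ornstein–Uhlenbeck
  noise (τ = 0.3 s). Oscillation amplitudes follow the area hierarchy of the
  phenomenon being modeled: limb 1.0, motor 0.8, barrel 0.5, retrosplenial
  0.4, visual 0.1 (limb ≈ 10× visual). The OU noise sd defaults to 0.3: with
  markedly larger in-band noise the single-trial sine fits have a phase-error
  floor above 0.4 rad, and the narrow (<90°) phase windows that motivate the
  phase analysis could not be observed even under perfect implanted locking;
  sd 0.3 puts the fit floor near 0.28 rad, the regime in which narrow windows
  are observable. White noise is not used because the traces being emulated
  are smooth and oscillatory.
- **Events.** Rewarded pulls are a homogeneous Poisson stream thinned to
  enforce inter-event gaps ≥ `lockout_s` (3 s), kept ≥ 30 s from the session
  edges so deep peri-event windows always fit. Unrewarded pulls, licks and
  independent paw bouts are additional Poisson streams; right-paw bouts
  co-occur with every rewarded pull (the pulling paw).
- **Ramp.** From `signal_onset_s` (default −5 s) to the event, a half-cosine
  additive ramp reaches `ramp_depth` at t = 0 (motor/limb −1.5,
  retrosplenial/barrel −0.5, visual 0 — a single inhibitory pre-movement
  phase, absent in visual cortex) and relaxes back over 1 s after the event.
  `signal_onset_s` is the ground-truth decodability onset: depths are set so
  that, at the default noise level and ~200 trials/class, decoding becomes
  significant shortly after the onset — that is the semantics the recovery
  studies test.
- **Phase steering.** Each rewarded event draws a target phase from
  von Mises(`phase_mu` = π/2, `phase_kappa` = 8 by default). The oscillation's
  phase offset is pulled continuously (half-cosine) from the later of
  (previous event, event + `signal_onset_s`) so that the phase at t = 0
  equals the target; the pull completes at `steer_hold_s` (default onset/2)
  and is held, so the final pre-event stretch is a stationary sinusoid — a
  pull that kept drifting to t = 0 would be a chirp that a sine fit cannot
  summarize, whereas the modeled trials are phase-aligned well before the
  action. If the window opens too late (short gaps), the pull completes over
  the first quarter of the gap instead. With κ = 0 no steering is applied.
- **Variance change.** The noise-sd envelope is scaled by
  √`var_change_factor` from `var_change_onset_s` (default: factor 0.5 from
  −3 s) to the event, in every area.
- **Null sessions** keep the event trains and background but implant no
  ramp, steering or variance change — the "random periods of activity"
  control.

Everything is a pure function of (config, seed); identical inputs give
byte-identical sessions.

**What the generator does not emulate:** pixel-level images, hemodynamic
artifacts, indicator bleaching and other longitudinal drift, lick
microstructure, correlated inter-area noise, non-sinusoidal oscillation
waveforms, and the area-specific *profile* of the variance change (the
implanted change is uniform across areas). Recovery results therefore show
the estimators are correct and calibrated under the assumed structure — not
that real recordings satisfy those assumptions.

## Preprocessing

Band-pass (0.1–6 Hz) and zero-phase low-pass filtering use 4th-order
Butterworth with forward–backward passes. The **causal** low-pass instead
uses a linear-phase FIR (2·round(fps/fc)+1 taps, Hamming window) whose group
delay is exactly round(fps/fc) samples — 100 at fc = 0.3 Hz and 30 fps — so
advancing the output by that amount aligns it with the zero-phase result and
the tail is padded with the last value. A one-pass IIR filter was rejected
here because its DC group delay (~42 samples for Butterworth-4 at this
cutoff) cannot be corrected exactly by the stated shift. Filters are
initialized at their DC steady state so constants pass unchanged.

ΔF/F₀ uses F₀ = mean of the window immediately preceding the analysis
window, with baseline length equal to the pre-event part of the analysis
window (a ±3 s window takes F₀ from −6…−3 s). Band-pass preprocessing is the
default; ΔF/F₀ is available explicitly.

Control triggers are sampled uniformly, rejected within `min_gap_s` (3 s) of
any lever event, and matched in count to the behavior trials — controls may
contain licks or paw movements, which is the conservative choice. PCA
denoising arranges frames as samples and areas as features, keeps the
smallest k reaching 95% explained variance, and one basis is shared between
the behavior and control sets of a session. Concatenated sessions are first
denoised per-session, then projected onto a multi-session basis fit on a
seeded 3% frame sample with a fixed 20 components (capped at the feature
dimensionality — synthetic sessions carry 10 area traces).

## Decoding and EDT

One SVC (sigmoid kernel, C = 1, gamma = 'scale') per 1-s window position per
fold; all positions share one seeded stratified fold partition so fold
accuracies are paired across time. Window positions run over starts
0…n_frames−w−1 (870 for a (−15, +15) s window at 30 fps) and the accuracy is
assigned to the window's last frame. Curves are smoothed per fold with a
centered 30-step moving average (shrinking at the edges), tested per time
point with a one-sample t-test against 0.5 — one-sided (greater), since only
above-chance decoding is evidence of prediction; a zero-variance time point
gets p = 0 if its mean beats chance, else 1 — and corrected with
Benjamini–Hochberg across the whole curve (pre- and post-event). The EDT
backward walk starts at the evaluated point closest to t = 0 and extends the
contiguous significant run; isolated earlier islands are ignored and a
non-significant t = 0 yields EDT = 0.

## Phase, spectra, trends

Sine fits scan frequency on a 0.01-Hz grid with closed-form amplitude/phase/
offset per candidate (the model is linear at fixed f), then refine by bounded
nonlinear least squares (f ∈ [0.05, 2] Hz); a failed refinement falls back to
the grid solution and is flagged. The phase at t = 0 is φ wrapped to
(−π, π]. Rayleigh p-values use the standard finite-n corrected series, with
an optional Monte-Carlo uniform-null p for very small n. Inter-area phase
coupling is the Fisher–Lee pairwise circular correlation (plain Pearson on
wrapped angles breaks at the ±π seam). Welch spectra use Hann windows,
segment length min(n, 512), 50% overlap; the peak is the band-restricted
argmax. Longitudinal trends are Pearson correlations against session index
after dropping a 7-session habituation burn-in.

## State space and variance

Hulls are compared only within a shared per-session 3-D PCA embedding
(volumes are basis-dependent; full-dimensional hulls are combinatorially
infeasible; the embedding dimension is configurable 2–6). A 10% k-NN triage
(k = 10, mean distance to neighbors) precedes every hull. Ratio curves use
1-s segments ending at offsets −10…0 s over the triaged session hull and are
clipped to [0, 1] (independent triage can leave sub-ulp excursions). Hull
overlap samples uniformly inside one hull via its Delaunay simplices
(volume-weighted simplex choice, Dirichlet barycentric coordinates) and
tests membership in the other.

The EVDT baseline (mean, sd of the variance trace over −30…−15 s) is always
computed on the raw trace; optional Savitzky–Golay smoothing (31 samples,
order 3) applies to the detection trace only, and is used in the recovery
study because threshold crossings on raw variance traces are inconsistent —
the detection-side smoothing stabilizes them. Detection requires every
sample in a 1-s left-closed window to satisfy the criterion; `decrease` mode
tests v < μ_b − kσ_b (k = 2), `absolute` mode |v − μ_b| > kσ_b for subjects
whose variance rises. An exactly constant trace is reported undetected; a
non-constant trace with zero baseline sd is a degenerate-baseline error.
EVDT is intended for non-pooled trial sets; pooled lockout sets carry much
higher intra-session variance.

## Study conditions used by tests and `scripts/acceptance.py`

Chosen as this package's own simulation design and fixed up front:

- **EDT recovery:** 1800-s sessions at 0.3 Hz event rate, onset −4 s,
  200 trials/class (first 200 events), decoding window (−8, +2) s with an
  every-2nd-frame evaluation grid (15 Hz; the smoothing span stays 1 s);
  median recovered EDT over 10 seeds ∈ [−5, −3]. Nulls use 100 trials/class;
  EDT = 0 in ≥ 85% of runs.
- **Phase recovery:** 2000-s sessions at 0.12 Hz event rate, ramp off,
  steering complete by −8 s; fits on pulls with no lever event in the
  preceding 8 s (`apply_lockout`), ~60–80 trials; fitted-phase resultant
  strictly increasing over κ ∈ {0, 2, 10, 50}, R(κ=50) > 0.9. The lockout
  mirrors how pre-movement phase analyses must exclude trials whose
  pre-window contains another pull.
- **EVDT recovery:** steering and ramp disabled to isolate the implanted
  variance change (steering itself reduces across-trial variance from the
  signal onset and would confound the −3 s target); drop factor 0.5 at −3 s,
  200 trials, per-seed median over detecting areas ∈ [−4, −2] in ≥ 80% of
  10 seeds.
- **Hull suite:** 600-s sessions, κ = 20; normalized AUC < 1 for structured
  sessions, 1 ± 0.15 (mean over seeds) for nulls; geometric identities
  (unit square, identical/shifted-cube overlaps) checked exactly or at
  Monte-Carlo precision.

## Known limitations

- SVC hyperparameters beyond the kernel family (C, gamma) are conventional
  defaults recorded in curve provenance, not tuned.
- The sine-fit phase error grows with in-band background power; under heavy
  noise the resultant length underestimates the implanted concentration.
- EVDT detection depends on the noise share of across-trial variance; in
  oscillation-dominated areas a pure noise-sd change can be undetectable at
  k = 2, which is why the recovery reads out the median over detecting areas.
- `hull_ratio_curve` needs enough trials per offset (≥ 20 points after
  triage) and returns missing values otherwise.
- Movement-initiation detection uses a whole-session speed sd threshold; it
  is not robust to nonstationary tracking noise.
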