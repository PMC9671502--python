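# premove

Analysis of multi-second pre-movement neural dynamics in area-level widefield
calcium imaging: can an upcoming self-initiated action (a water-rewarded lever
pull in a head-fixed mouse) be read out from cortical activity seconds before
the movement happens?

The package is aimed at systems neuroscientists working with mesoscale
cortical recordings (e.g. locaNMF area components at 30 Hz) and behavioral
event streams. It implements the full analysis chain as a library plus a thin
`premove` command line, and ships a synthetic-session generator that implants
known structure (decodability onset, phase locking, variance change) so every
statistic can be validated by parameter recovery — no real recordings needed.

## What it computes

**Earliest decoding time (EDT).** For every 1-s sliding window position, a
two-class SVM (sigmoid kernel, 10-fold stratified CV) separates peri-event
neural activity from random control segments placed ≥ 3 s from any lever
event. Fold accuracies are assigned to the window's last frame, smoothed with
a 30-step moving average, tested per time point against chance (one-sample
t-test) and corrected across the curve with Benjamini–Hochberg. The EDT is

> EDT = min { t* ≤ 0 : p_adj(t) < α for every evaluated t ∈ [t*, 0] },

i.e. the most negative time from which decoding stays significant all the way
to the action; EDT = 0 means the action was not predicted. Isolated earlier
islands of significance are ignored.

**Phase-of-action statistics.** Per trial, A·sin(2πf·t + φ) + c is fit to the
last 5 s before the pull; the phase at t = 0 summarizes where in the slow
oscillation (0.2–0.6 Hz) the action lands. Circular mean, resultant length
R = |⟨e^{iφ}⟩| and the Rayleigh uniformity test quantify the phase bias;
inter-area phase coupling uses the Fisher–Lee circular correlation.

**Convex-hull state-space structure.** Session state vectors are embedded in
a shared 3-D PCA basis; for each 1-s segment ending at offsets −10…0 s the
ratio hull(segment)/hull(session) (after a 10% k-NN outlier triage) traces
how the pre-movement state space contracts toward the action. The area under
the ratio curve is normalized by the same curve at random triggers; hull
intersections are estimated by Monte-Carlo sampling inside the hulls.

**Earliest variance-decrease time (EVDT).** The across-trial variance trace
is compared with a baseline (−30…−15 s): the EVDT is the earliest time at
which the variance stays beyond mean ± 2 sd of the baseline for a full 1-s
window, restricted to −6…+0.5 s.

Supporting steps: Butterworth band-pass (0.1–6 Hz) and low-pass filtering
with an exactly corrected causal mode, ΔF/F₀ against a pre-window baseline,
velocity-threshold movement-initiation detection from body tracks,
lockout/quiescence trial selection on a 0.250-s grid, sliding-group pooling
of locked-out trials, PCA denoising (≥95% variance per session, fixed 20
components across concatenated sessions) and Welch power spectra.

## Worked example

Generate a synthetic session (1330 s at 30 Hz, 10 bilateral areas, rewarded
pulls under a 3-s lockout, decodability onset −5 s) and run the analyses:

```bash
premove simulate --seed 3 --out demo.h5
# wrote demo.h5: 10 areas x 39900 frames, 179 rewarded pulls

premove decode demo.h5 --seed 3 --out edt.json --window -6 1 --stride 5 --folds 5
# EDT = -5.03 s (synth-3)

premove phases demo.h5 --seed 3 --out phases.json
# limb_L: R = 0.745, circular mean = +1.011 rad, Rayleigh p = 5.42e-42

premove evdt demo.h5 --seed 3 --out evdt.json --area visual_L
# visual_L: EVDT = -3.0

premove hull demo.h5 --seed 3 --out hull.json
# normalized hull AUC = 0.875
```

Reading the numbers: the decoder recovers the implanted −5 s decodability
onset (EDT ≈ −5.0 s); fitted phases at pull time are strongly concentrated
(R = 0.75 under the default von Mises κ = 8, Rayleigh p ≪ 10⁻⁵) near the
implanted crest phase π/2; the implanted variance drop at −3 s is detected at
−3.0 s; and the pre-movement hull is smaller than at random triggers
(normalized AUC 0.88 < 1), the state-space signature of stereotyped
pre-movement dynamics. The same calls work on any session container that
follows the HDF5 layout in `premove.io` (or an `neural.npy` + `events.csv`
directory).

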