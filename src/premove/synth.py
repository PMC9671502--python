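"""Synthetic session generator.

Emulates the statistical structure of area-level widefield calcium recordings
during a self-initiated lever-pull task:

* per-area slow oscillations (0.2-0.6 Hz) of area-dependent amplitude
  (limb cortex ~10x visual cortex);
* smooth mean-reverting (Ornstein-Uhlenbeck) background noise;
* a rewarded-lever event train with a refractory lockout (>= 3 s between
  rewarded pulls);
* a pre-event additive ramp (inhibitory for motor/limb) starting at a
  configurable onset — the ground-truth decodability onset;
* steering of the oscillation phase over the pre-event window so that the
  phase at movement time follows a von Mises law;
* an across-trial variance change: the noise sd envelope is scaled from a
  configurable pre-event onset;
* paw-position tracks at video rate whose movement bouts co-occur with lever
  events, plus independent bouts.

Every implanted parameter is stored in ``session.meta["ground_truth"]`` so
downstream recovery tests need no side channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .session import DEFAULT_AREA_LABELS, BodyTrack, EventTable, Session

__all__ = ["SynthConfig", "generate_session", "generate_null_session"]


def _default_amp(label: str) -> float:
    # limb-cortex oscillations dominate; visual cortex is ~10x weaker
    base = {"limb": 1.0, "motor": 0.8, "barrel": 0.5, "retrosplenial": 0.4, "visual": 0.1}
    return base.get(label.rsplit("_", 1)[0], 0.5)


def _default_ramp(label: str) -> float:
    # single inhibitory (negative) pre-movement phase in motor/limb cortex
    base = {"limb": -1.5, "motor": -1.5, "barrel": -0.5, "retrosplenial": -0.5, "visual": 0.0}
    return base.get(label.rsplit("_", 1)[0], -0.5)


@dataclass
class SynthConfig:
    """Ground-truth parameters for one synthetic session.

    Per-area parameters (``osc_freq_hz``, ``osc_amp``, ``ramp_depth``) may be
    ``None`` to use defaults: frequencies drawn uniformly in [0.2, 0.6] Hz,
    amplitudes and ramp depths assigned by area identity.
    """

    duration_s: float = 1330.0
    fps_neural: float = 30.0
    fps_video: float = 15.0
    area_labels: tuple[str, ...] = DEFAULT_AREA_LABELS
    osc_freq_hz: tuple[float, ...] | None = None
    osc_amp: tuple[float, ...] | None = None
    noise_sd: float = 0.3
    noise_tau_s: float = 0.3
    event_rate_hz: float = 0.25
    unrewarded_rate_hz: float = 0.05
    lick_rate_hz: float = 0.2
    lockout_s: float = 3.0
    signal_onset_s: float = -5.0
    steer_hold_s: float | None = None   # steering completes here; default onset/2
    ramp_depth: tuple[float, ...] | None = None
    phase_mu: float = np.pi / 2
    phase_kappa: float = 8.0
    var_change_onset_s: float = -3.0
    var_change_factor: float = 0.5
    bout_rate_hz: float = 0.05
    bout_duration_s: float = 0.5
    bout_amp_px: float = 20.0
    track_noise_px: float = 1.0

    def __post_init__(self):
        if self.signal_onset_s > 0:
            raise ValidationError("signal_onset_s must be <= 0")
        if self.lockout_s <= 0:
            raise ValidationError("lockout_s must be > 0")
        if self.phase_kappa < 0:
            raise ValidationError("phase_kappa must be >= 0")
        if self.var_change_factor <= 0:
            raise ValidationError("var_change_factor must be > 0")
        if self.var_change_onset_s > 0:
            raise ValidationError("var_change_onset_s must be <= 0")
        if self.duration_s <= 0 or self.fps_neural <= 0 or self.fps_video <= 0:
            raise ValidationError("duration and sampling rates must be positive")

    @property
    def n_areas(self) -> int:
        return len(self.area_labels)


def _wrap(phi):
    """Wrap angle(s) to (-pi, pi]."""
    return -(np.mod(-np.asarray(phi) + np.pi, 2 * np.pi) - np.pi)


def _thinned_poisson(rng, rate, lo, hi, min_gap):
    """Homogeneous Poisson arrivals on [lo, hi) thinned to inter-event gaps >= min_gap."""
    n_cand = rng.poisson(rate * (hi - lo))
    cand = np.sort(rng.uniform(lo, hi, size=n_cand))
    kept = []
    last = -np.inf
    for t in cand:
        if t - last >= min_gap:
            kept.append(t)
            last = t
    return np.asarray(kept)


def _ou_noise(rng, n, dt, tau):
    """Unit-variance stationary Ornstein-Uhlenbeck samples (AR(1) recursion)."""
    from scipy.signal import lfilter

    a = np.exp(-dt / tau)
    b = np.sqrt(1.0 - a * a)
    eps = rng.standard_normal(n)
    drive = b * eps
    drive[0] = eps[0]  # start from the stationary law
    return lfilter([1.0], [1.0, -a], drive)


def _half_cosine(u):
    """Smooth 0 -> 1 transition for u in [0, 1]."""
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(u, 0.0, 1.0)))


def _paw_track(rng, n, fps, bout_times, cfg: SynthConfig, base_xy):
    """Position trace with smooth displacement bouts at the given times."""
    t = np.arange(n) / fps
    xy = np.tile(np.asarray(base_xy, dtype=float), (n, 1))
    xy += rng.normal(0.0, cfg.track_noise_px, size=(n, 2))
    for tb in bout_times:
        direction = rng.normal(size=2)
        direction /= np.linalg.norm(direction) + 1e-12
        # Gaussian-shaped displacement pulse centred shortly after bout onset
        w = cfg.bout_duration_s / 2.355  # FWHM -> sd
        pulse = np.exp(-0.5 * ((t - tb - cfg.bout_duration_s / 2) / w) ** 2)
        xy += cfg.bout_amp_px * pulse[:, None] * direction[None, :]
    return xy.astype(np.float32)


def generate_session(cfg: SynthConfig, seed: int, *, structured: bool = True,
                     session_id: str | None = None, session_index: int = 0) -> Session:
    """Generate one synthetic session; deterministic in ``(cfg, seed)``.

    With ``structured=False`` no pre-event structure is implanted (no ramp, no
    phase steering, no variance change) while the event trains and background
    statistics are unchanged — the "random periods of neural activity" control.
    """
    rng = np.random.default_rng(seed)
    fps = cfg.fps_neural
    n = int(round(cfg.duration_s * fps))
    t = np.arange(n) / fps
    n_areas = cfg.n_areas

    freqs = (np.asarray(cfg.osc_freq_hz, dtype=float) if cfg.osc_freq_hz is not None
             else rng.uniform(0.2, 0.6, size=n_areas))
    amps = (np.asarray(cfg.osc_amp, dtype=float) if cfg.osc_amp is not None
            else np.array([_default_amp(a) for a in cfg.area_labels]))
    depths = (np.asarray(cfg.ramp_depth, dtype=float) if cfg.ramp_depth is not None
              else np.array([_default_ramp(a) for a in cfg.area_labels]))
    for name, arr in (("osc_freq_hz", freqs), ("osc_amp", amps), ("ramp_depth", depths)):
        if arr.shape != (n_areas,):
            raise ValidationError(f"{name} must have one entry per area")

    # --- event trains -----------------------------------------------------
    margin = max(30.0, -cfg.signal_onset_s)  # keep full peri-windows inside the session
    rewarded = _thinned_poisson(rng, cfg.event_rate_hz, margin,
                                cfg.duration_s - margin, cfg.lockout_s)
    unrewarded = _thinned_poisson(rng, cfg.unrewarded_rate_hz, 1.0,
                                  cfg.duration_s - 1.0, 0.5)
    licks = np.sort(rng.uniform(0.0, cfg.duration_s, size=rng.poisson(
        cfg.lick_rate_hz * cfg.duration_s)))

    # --- per-event phase targets -----------------------------------------
    if structured and cfg.phase_kappa > 0:
        targets = _wrap(rng.vonmises(cfg.phase_mu, cfg.phase_kappa, size=rewarded.size))
    else:
        targets = np.full(rewarded.size, np.nan)

    onset = cfg.signal_onset_s
    neural = np.empty((n_areas, n), dtype=np.float32)

    # --- variance envelope (shared across areas) --------------------------
    sd_env = np.ones(n)
    if structured:
        sf = np.sqrt(cfg.var_change_factor)
        for te in rewarded:
            i0 = int(round((te + cfg.var_change_onset_s) * fps))
            i1 = int(round(te * fps))
            sd_env[max(i0, 0):max(i1, 0)] = sf

    phi0s = []
    for a in range(n_areas):
        phi0 = rng.uniform(-np.pi, np.pi)
        phi0s.append(float(phi0))
        # cumulative phase offset from steering, piecewise-smooth in time
        delta = np.zeros(n)
        if structured and cfg.phase_kappa > 0:
            hold = cfg.steer_hold_s if cfg.steer_hold_s is not None else onset / 2
            d_prev = 0.0
            prev_event = -np.inf
            for te, psi in zip(rewarded, targets):
                natural = 2 * np.pi * freqs[a] * te + phi0 + d_prev
                d_new = d_prev + float(_wrap(psi - natural))
                t_start = max(te + onset, prev_event)
                # phase adjustment completes at te + hold and is held constant
                # afterwards, so the oscillation is stationary (and on target)
                # over the final pre-event stretch; if the window opens too
                # late for that, complete over the first quarter of the gap
                desired = te + hold
                t_end = desired if desired > t_start else t_start + 0.25 * (te - t_start)
                i0 = max(int(round(t_start * fps)), 0)
                i1 = int(round(t_end * fps))
                if i1 > i0:
                    u = (t[i0:i1] - t_start) / (t_end - t_start)
                    delta[i0:i1] = d_prev + (d_new - d_prev) * _half_cosine(u)
                delta[i1:] = d_new
                d_prev = d_new
                prev_event = te
        osc = amps[a] * np.sin(2 * np.pi * freqs[a] * t + phi0 + delta)

        ramp = np.zeros(n)
        if structured and depths[a] != 0.0 and onset < 0:
            for te in rewarded:
                i0 = max(int(round((te + onset) * fps)), 0)
                i1 = int(round(te * fps))
                if i1 > i0:
                    u = (t[i0:i1] - (te + onset)) / (-onset)
                    ramp[i0:i1] += depths[a] * _half_cosine(u)
                # return to baseline over 1 s to avoid a step discontinuity
                i2 = min(int(round((te + 1.0) * fps)), n)
                if i2 > i1:
                    u = (t[i1:i2] - te) / 1.0
                    ramp[i1:i2] += depths[a] * (1.0 - _half_cosine(u))

        noise = cfg.noise_sd * sd_env * _ou_noise(rng, n, 1.0 / fps, cfg.noise_tau_s)
        neural[a] = osc + ramp + noise

    # --- body tracks ------------------------------------------------------
    n_video = int(round(cfg.duration_s * cfg.fps_video))
    indep_left = np.sort(rng.uniform(1.0, cfg.duration_s - 1.0, size=rng.poisson(
        cfg.bout_rate_hz * cfg.duration_s)))
    indep_right = np.sort(rng.uniform(1.0, cfg.duration_s - 1.0, size=rng.poisson(
        cfg.bout_rate_hz * cfg.duration_s)))
    right_bouts = np.sort(np.concatenate([rewarded, indep_right]))  # lever pulled with right paw
    tracks = BodyTrack(
        features={
            "left_paw": _paw_track(rng, n_video, cfg.fps_video, indep_left, cfg, (100.0, 200.0)),
            "right_paw": _paw_track(rng, n_video, cfg.fps_video, right_bouts, cfg, (300.0, 200.0)),
            "lever": _paw_track(rng, n_video, cfg.fps_video, rewarded, cfg, (350.0, 250.0)),
            "jaw": _paw_track(rng, n_video, cfg.fps_video, licks, cfg, (200.0, 100.0)),
        },
        fps_video=cfg.fps_video,
    )

    events = EventTable({
        "lever_rewarded": rewarded,
        "lever_unrewarded": unrewarded,
        "lick": licks,
        "left_paw": indep_left,
        "right_paw": right_bouts,
    })

    ground_truth = {
        "structured": bool(structured),
        "signal_onset_s": float(onset) if structured else None,
        "var_change_onset_s": float(cfg.var_change_onset_s) if structured else None,
        "var_change_factor": float(cfg.var_change_factor) if structured else None,
        "phase_mu": float(cfg.phase_mu),
        "phase_kappa": float(cfg.phase_kappa) if structured else 0.0,
        "phase_targets": [float(x) for x in targets] if structured else [],
        "osc_freq_hz": [float(x) for x in freqs],
        "osc_phi0": phi0s,
        "osc_amp": [float(x) for x in amps],
        "ramp_depth": [float(x) for x in depths] if structured else [0.0] * n_areas,
        "noise_sd": float(cfg.noise_sd),
        "event_times": [float(x) for x in rewarded],
        "seed": int(seed),
    }

    return Session(
        neural=neural,
        fps_neural=fps,
        area_labels=cfg.area_labels,
        events=events,
        tracks=tracks,
        session_id=session_id or f"synth-{seed}",
        session_index=session_index,
        meta={"ground_truth": ground_truth},
    )


def generate_null_session(cfg: SynthConfig, seed: int, **kwargs) -> Session:
    """Session with identical event trains and background but no pre-event
    structure (no ramp, no phase steering, no variance change)."""
    return generate_session(cfg, seed, structured=False, **kwargs)
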