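"""Synthetic visual-awareness sessions: task schedule, staircase observer,
gaze traces and multichannel LFP epochs with programmable awareness effects.

The generator emulates a near-threshold detection task: on each trial a
fixation period is followed by a briefly flashed grating whose contrast is
controlled by a 1-up/1-down staircase on near-threshold trials, and 650 ms
after grating onset a color cue instructs a saccade that reports the
awareness state.  The simulated LFP is pink noise plus a stimulus-evoked
transient, and on designated channels three awareness-dependent components
with programmable onsets: an extra evoked deflection (ERP effect), a
60-150 Hz burst (high-gamma effect), and a 4 Hz oscillation with a
trial-consistent inter-channel phase lag (connectivity effect).
"""
from __future__ import annotations

import string

import numpy as np
import pandas as pd

from .config import TaskConfig, ObserverSpec
from .containers import EpochArray, SessionData, default_times

__all__ = [
    "schedule_session", "respond", "run_staircase", "synth_eye_trace",
    "synth_epochs", "synth_montage", "simulate_trials", "simulate_session",
    "session_rng", "gaze_times",
]


def session_rng(seed: int, session_index: int = 0) -> np.random.Generator:
    """One independent RNG stream per session, keyed by (seed, session index)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(session_index)]))


# ---------------------------------------------------------------------------
# Trial schedule and observer
# ---------------------------------------------------------------------------

def schedule_session(cfg: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Randomly ordered trial classes with exact per-class counts.

    Class counts are enforced exactly (``round(prop * session_trials)`` each
    for near/high/catch), not drawn multinomially; a configuration whose
    proportions do not yield integral counts is rejected.
    """
    counts = cfg.class_counts
    classes = np.array(
        ["near"] * counts["near"] + ["high"] * counts["high"]
        + ["catch"] * counts["catch"])
    return rng.permutation(classes)


def respond(obs: ObserverSpec, contrast: float, rng: np.random.Generator) -> bool:
    """Draw one awareness report from the logistic observer at ``contrast`` %."""
    if contrast < 0:
        raise ValueError("contrast must be non-negative")
    p = obs.p_aware(contrast)
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"observer yields p={p} outside [0, 1]")
    return bool(rng.random() < p)


def high_contrast_value(obs: ObserverSpec) -> float:
    """Contrast used on high-class trials: 6 logistic widths above threshold,
    i.e. P(aware) ~ psy_a + 0.998 * psy_b."""
    return obs.psy_c + 6.0 / obs.psy_d


def run_staircase(obs: ObserverSpec, cfg: TaskConfig, n_near: int,
                  rng: np.random.Generator,
                  start_contrast: float | None = None):
    """Run the 1-up/1-down staircase over ``n_near`` near-class trials.

    An aware report lowers the next contrast by ``cfg.staircase_step``, an
    unaware report raises it; contrast is floored at 0.  The rule converges
    to the 50% point of the observer's psychometric function.

    Returns ``(contrasts, aware)`` arrays of length ``n_near``.
    """
    if start_contrast is None:
        start_contrast = obs.psy_c + 5.0 * cfg.staircase_step
    if start_contrast <= 0:
        raise ValueError("starting contrast must be positive")
    contrasts = np.empty(n_near)
    aware = np.empty(n_near, dtype=bool)
    c = float(start_contrast)
    for i in range(n_near):
        contrasts[i] = c
        aware[i] = respond(obs, c, rng)
        c = c - cfg.staircase_step if aware[i] else c + cfg.staircase_step
        c = max(c, 0.0)
    return contrasts, aware


# ---------------------------------------------------------------------------
# Gaze traces
# ---------------------------------------------------------------------------

def gaze_times(cfg: TaskConfig) -> np.ndarray:
    """Gaze time axis: fixation start to end of response window, ms rel. to
    grating onset."""
    t0 = -cfg.fixation_dur
    t1 = cfg.stim_to_cue + cfg.max_response
    n = int(round((t1 - t0) * cfg.fs / 1000.0)) + 1
    return t0 + np.arange(n) * 1000.0 / cfg.fs


def _smooth_jitter(n: int, rng: np.random.Generator, sd: float = 0.3,
                   tau_samples: float = 50.0) -> np.ndarray:
    """Temporally correlated fixational jitter (Gaussian-smoothed noise,
    rescaled to standard deviation ``sd`` degrees)."""
    from scipy.ndimage import gaussian_filter1d
    w = gaussian_filter1d(rng.standard_normal(n), tau_samples, mode="wrap")
    s = w.std()
    return w * (sd / s) if s > 0 else w


def _saccade_pulse(amplitude: float, saccade_dur: float, fs: float) -> np.ndarray:
    """Cumulative displacement of a raised-cosine velocity pulse."""
    ns = int(round(saccade_dur * fs / 1000.0))
    ph = np.linspace(0, 2 * np.pi, ns, endpoint=False)
    vel = 1 - np.cos(ph)
    return np.cumsum(vel) / vel.sum() * amplitude


def _detector_onset_offset(amplitude: float, saccade_dur: float,
                           fs: float) -> int:
    """Samples between pulse start and the velocity-criterion onset.

    The saccade latency parameter is defined operationally — the time at
    which the standard smoothed-velocity 30 deg/s criterion fires — so the
    pulse is placed such that the criterion (applied to the noise-free
    profile) fires exactly at the requested latency.
    """
    key = (round(amplitude, 6), round(saccade_dur, 6), round(fs, 6))
    cached = _detector_onset_offset._cache.get(key)
    if cached is not None:
        return cached
    from .behavior import detect_saccade_latency
    from .config import TaskConfig as _TC
    cfg = _TC(fs=fs)
    pad = int(round(0.3 * fs))
    disp = _saccade_pulse(amplitude, saccade_dur, fs)
    x = np.zeros(2 * pad + disp.size)
    x[pad:pad + disp.size] = disp
    x[pad + disp.size:] = disp[-1]
    tt = (np.arange(x.size) - pad) * 1000.0 / fs
    det = detect_saccade_latency(np.stack([x, np.zeros_like(x)], axis=1),
                                 tt, float(tt[0]), cfg)
    # det is relative to the trace start; the pulse starts at t = 0
    t_cross = None if det is None else tt[0] + det
    offset = 0 if t_cross is None else -int(round(t_cross * fs / 1000.0))
    _detector_onset_offset._cache[key] = offset
    return offset


_detector_onset_offset._cache = {}


def synth_eye_trace(latency: float, direction: int, cfg: TaskConfig,
                    rng: np.random.Generator,
                    saccade_dur: float = 40.0,
                    fixation_break: tuple[float, float, float] | None = None):
    """One 2-D gaze trace with a saccade ``latency`` ms after the cue.

    The saccade follows a raised-cosine velocity profile of duration
    ``saccade_dur`` ms landing at ``direction * target_ecc`` degrees
    horizontally (peak velocity 2*amplitude/duration, 500 deg/s at defaults).
    ``latency`` is defined by the standard velocity-threshold criterion: the
    pulse is placed so that the smoothed-speed 30 deg/s crossing of the
    noise-free profile occurs ``latency`` ms after the cue.
    ``fixation_break``, if given, is ``(offset_deg, start_ms, dur_ms)``: a
    square horizontal excursion injected during the fixation period.

    Pass ``latency=None`` to omit the saccade entirely.

    Returns ``(times_ms, xy)`` with ``xy`` of shape ``(n_times, 2)`` degrees.
    """
    t = gaze_times(cfg)
    n = t.size
    xy = np.empty((n, 2))
    xy[:, 0] = _smooth_jitter(n, rng)
    xy[:, 1] = _smooth_jitter(n, rng)

    if latency is not None:
        if not (0 < latency <= cfg.max_response):
            raise ValueError("latency outside (0, max_response]")
        onset_ms = cfg.stim_to_cue + latency
        i0 = int(round((onset_ms - t[0]) * cfg.fs / 1000.0))
        i0 += _detector_onset_offset(cfg.target_ecc, saccade_dur, cfg.fs)
        ns = int(round(saccade_dur * cfg.fs / 1000.0))
        if i0 + ns >= n:
            raise ValueError("saccade extends beyond the gaze trace")
        disp = direction * _saccade_pulse(cfg.target_ecc, saccade_dur, cfg.fs)
        xy[i0:i0 + ns, 0] += disp
        xy[i0 + ns:, 0] += direction * cfg.target_ecc

    if fixation_break is not None:
        off, start_ms, dur_ms = fixation_break
        j0 = int(round((start_ms - t[0]) * cfg.fs / 1000.0))
        j1 = j0 + int(round(dur_ms * cfg.fs / 1000.0))
        xy[max(j0, 0):min(j1, n), 0] += off
    return t, xy


# ---------------------------------------------------------------------------
# Electrode montage
# ---------------------------------------------------------------------------

_DEFAULT_REGIONS = (
    "rostralmiddlefrontal", "caudalmiddlefrontal", "parsopercularis",
    "superiorfrontal", "lateralorbitofrontal", "precentral",
    "superiortemporal", "supramarginal", "insula", "fusiform",
)

CONTACT_SPACING_MM = 3.5   # center-to-center along a shaft (2 mm contact + 1.5 mm gap)
SEGMENT_GAP_MM = 10.0      # extra gap between segments of a segmented shaft


def synth_montage(n_shafts: int, contacts_per_shaft: int,
                  regions: tuple[str, ...] | None = None,
                  rng: np.random.Generator | None = None,
                  segmented: dict[int, int] | None = None) -> pd.DataFrame:
    """Generate a depth-electrode table with MNI-like coordinates.

    Contacts are placed 3.5 mm apart along each shaft (index 1 deepest);
    ``segmented`` maps shaft number to the contact count of its first
    segment, splitting the shaft into two segments separated by an extra
    10 mm.  ``regions`` supplies one atlas label per shaft (cycled).
    """
    if n_shafts < 1 or contacts_per_shaft < 1:
        raise ValueError("counts must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(0)
    regions = tuple(regions) if regions else _DEFAULT_REGIONS
    segmented = segmented or {}
    letters = [string.ascii_uppercase[i % 26] * (i // 26 + 1)
               for i in range(n_shafts)]
    rows = []
    for s in range(n_shafts):
        # entry point on a rough head sphere, shaft pointing inward
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        entry = u * 70.0
        direction = -u
        split = segmented.get(s, None)
        for k in range(contacts_per_shaft):
            depth = k * CONTACT_SPACING_MM
            segment = 0
            if split is not None and k >= split:
                depth += SEGMENT_GAP_MM
                segment = 1
            pos = entry + direction * depth
            rows.append({
                "name": f"{letters[s]}{k + 1}",
                "x": pos[0], "y": pos[1], "z": pos[2],
                "shaft": letters[s], "segment": segment, "index": k + 1,
                "region": regions[s % len(regions)],
                "hemisphere": "R" if pos[0] >= 0 else "L",
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LFP epochs
# ---------------------------------------------------------------------------

def _pink_shape(n: int, fs: float) -> tuple[np.ndarray, float]:
    """One-sided 1/f amplitude shape (flat below 1 Hz, zero DC) and the
    scale factor mapping unit-variance white noise to unit-variance output."""
    f = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.ones_like(f)
    amp[0] = 0.0
    high = f >= 1.0
    amp[high] = 1.0 / f[high]
    w = np.full(f.size, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    unit_var = (w * amp ** 2).sum() / n
    return amp, unit_var


def _shaped_noise(shape: tuple, amp: np.ndarray, rng: np.random.Generator,
                  dtype=np.float32) -> np.ndarray:
    """Gaussian noise with the given one-sided amplitude spectrum along the
    last axis; white input has unit variance per sample before shaping.

    Generated in float32 by default: epoch arrays are large and microvolt
    signals need nowhere near double precision.
    """
    n = shape[-1]
    white = rng.standard_normal(shape, dtype=dtype)
    spec = np.fft.rfft(white, axis=-1)
    spec *= amp
    return np.fft.irfft(spec, n=n, axis=-1).astype(dtype, copy=False)


def _band_fraction(n: int, fs: float, lo: float, hi: float) -> float:
    """Fraction of the pink-noise standard deviation inside [lo, hi] Hz."""
    f = np.fft.rfftfreq(n, 1.0 / fs)
    amp, _ = _pink_shape(n, fs)
    w = np.full(f.size, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    total = (w * amp ** 2).sum()
    band = ((f >= lo) & (f <= hi))
    return float(np.sqrt((w[band] * amp[band] ** 2).sum() / total))


def _ramp_envelope(times: np.ndarray, onset: float, ramp: float,
                   offset: float | None = None, down: float = 100.0) -> np.ndarray:
    """Raised-cosine onset ramp at ``onset`` (ms), sustain, optional release."""
    env = np.zeros_like(times)
    rise = (times >= onset) & (times < onset + ramp)
    env[rise] = 0.5 * (1 - np.cos(np.pi * (times[rise] - onset) / ramp))
    if offset is None:
        env[times >= onset + ramp] = 1.0
    else:
        env[(times >= onset + ramp) & (times < offset)] = 1.0
        fall = (times >= offset) & (times < offset + down)
        env[fall] = 0.5 * (1 + np.cos(np.pi * (times[fall] - offset) / down))
    return env


def _aware_erp_waveform(times: np.ndarray, onset: float,
                        phase: float = 0.0, carrier_hz: float = 5.0) -> np.ndarray:
    """Unit-amplitude awareness deflection starting at ``onset``: a theta
    (5 Hz) burst under a raised-cosine envelope (50 ms rise, ~400 ms total).

    The waveform is area-cancelled (envelope-weighted mean removed), so its
    energy sits well inside the 1-250 Hz analysis band and the zero-phase
    high-pass of the preprocessing stage passes it essentially undistorted;
    a sustained DC-like box would instead be smeared backward across the
    epoch.  ``phase`` offsets the carrier, letting different channels
    express different deflection dynamics.
    """
    env = _ramp_envelope(times, onset, 50.0, offset=onset + 300.0, down=150.0)
    w = env * np.sin(2 * np.pi * carrier_hz * (times - onset) / 1000.0 + phase)
    return w - env * (w.sum() / env.sum())


def _evoked_waveform(times: np.ndarray) -> np.ndarray:
    """Unit-amplitude biphasic stimulus-evoked transient (onset ~100 ms,
    peak ~150 ms, over by ~350 ms)."""
    t = (times - 100.0) / 1000.0
    w = np.zeros_like(times)
    on = t > 0
    w[on] = np.sin(2 * np.pi * 4.0 * t[on]) * np.exp(-t[on] / 0.08)
    return w


def synth_epochs(trials: pd.DataFrame, obs: ObserverSpec, montage: pd.DataFrame,
                 cfg: TaskConfig, rng: np.random.Generator,
                 noise_sd: float = 10.0, evoked_gain: float = 8.0,
                 common_noise_sd: float = 0.0) -> EpochArray:
    """Simulate the LFP epoch array for a labeled trial table.

    Every channel/trial is independent pink noise (sd ``noise_sd`` uV) plus,
    on stimulus-present trials, a contrast-scaled evoked transient.  Channels
    in ``obs.aware_channels`` additionally carry, in aware trials only, the
    programmed ERP deflection, high-gamma burst and lag-coupled 4 Hz
    oscillation (the oscillation is also present in unaware trials but with
    independent random phases per channel).  ``common_noise_sd`` adds shared
    pink noise per shaft, emulating a common reference later removed by
    bipolar re-referencing.
    """
    channels = montage["name"].tolist()
    missing = [c for c in obs.aware_channels if c not in channels]
    if missing:
        raise ValueError(f"aware_channels not in montage: {missing}")
    times = default_times(cfg.fs)
    n_ch, n_t, n_tr = len(channels), times.size, len(trials)
    amp, unit_var = _pink_shape(n_t, cfg.fs)
    scale = noise_sd / np.sqrt(unit_var)

    data = _shaped_noise((n_ch, n_tr, n_t), amp, rng) * scale

    if common_noise_sd > 0:
        shafts = montage["shaft"].to_numpy()
        for shaft in pd.unique(shafts):
            common = _shaped_noise((n_tr, n_t), amp, rng) * (
                common_noise_sd / np.sqrt(unit_var))
            data[shafts == shaft] += common

    contrast = trials["contrast_pct"].to_numpy(dtype=float)
    aware = trials["aware"].to_numpy(dtype=bool)
    stim = contrast > 0

    # stimulus-evoked transient on every channel, contrast-saturating gain
    ev = _evoked_waveform(times)
    ev_amp = evoked_gain * contrast / (contrast + obs.psy_c)
    data += ev_amp[None, :, None] * ev[None, None, :]

    aware_idx = [channels.index(c) for c in obs.aware_channels]
    if aware_idx:
        # (i) awareness-dependent ERP deflection; golden-angle carrier phase
        # per channel so the montage-wide effect never vanishes at one instant
        for k, ch in enumerate(aware_idx):
            erp_wave = _aware_erp_waveform(times, obs.erp_dot, phase=2.4 * k)
            data[ch, aware] += obs.erp_gain * erp_wave

        # (ii) high-gamma burst: band-limited noise scaled to hg_gain x
        # in-band noise RMS, gated by an envelope from hg_dot
        f = np.fft.rfftfreq(n_t, 1.0 / cfg.fs)
        band_amp = np.where((f >= 60) & (f <= 150), 1.0, 0.0)
        w = np.full(f.size, 2.0)
        w[0] = 1.0
        if n_t % 2 == 0:
            w[-1] = 1.0
        band_unit = np.sqrt((w * band_amp ** 2).sum() / n_t)
        inband_sd = noise_sd * _band_fraction(n_t, cfg.fs, 60.0, 150.0)
        hg_env = _ramp_envelope(times, obs.hg_dot, 50.0, offset=800.0)
        n_aware_tr = int(aware.sum())
        burst = _shaped_noise((len(aware_idx), n_aware_tr, n_t), band_amp, rng)
        burst *= (obs.hg_gain * inband_sd / band_unit)
        data[np.ix_(aware_idx, np.where(aware)[0])] += burst * hg_env

        # (iii) coupled 4 Hz oscillation with trial-consistent lag in aware
        # trials, independent phases in unaware trials
        plv_env = _ramp_envelope(times, obs.plv_onset, 100.0)
        base_phase = rng.uniform(-np.pi, np.pi, n_tr)
        osc_t = 2 * np.pi * 4.0 * times / 1000.0
        for k, ch in enumerate(aware_idx):
            phase = np.where(
                aware,
                base_phase + k * obs.plv_lag,
                rng.uniform(-np.pi, np.pi, n_tr))
            data[ch] += obs.plv_amp * plv_env[None, :] * np.cos(
                osc_t[None, :] + phase[:, None])

    # reorder to (channels, time, trials)
    return EpochArray(np.ascontiguousarray(data.transpose(0, 2, 1)),
                      times, channels, cfg.fs, reference="monopolar")


# ---------------------------------------------------------------------------
# Full session
# ---------------------------------------------------------------------------

def _trunc_normal(mu: float, sd: float, lo: float, hi: float,
                  rng: np.random.Generator) -> float:
    for _ in range(1000):
        v = rng.normal(mu, sd)
        if lo < v <= hi:
            return v
    return float(np.clip(mu, lo + 1e-6, hi))


def simulate_trials(cfg: TaskConfig, obs: ObserverSpec,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Simulate the behavioral trial table of one session (no gaze/LFP).

    The schedule is drawn, the staircase runs over the near-class trials in
    presentation order (it does not update on high/catch trials), reports are
    drawn from the logistic observer, and latencies from awareness-dependent
    truncated normals.
    """
    classes = schedule_session(cfg, rng)
    n = len(classes)
    near_mask = classes == "near"
    contrasts = np.zeros(n)
    sc, sc_aware = run_staircase(obs, cfg, int(near_mask.sum()), rng)
    contrasts[near_mask] = sc
    contrasts[classes == "high"] = high_contrast_value(obs)

    aware = np.empty(n, dtype=bool)
    aware[near_mask] = sc_aware
    for i in np.where(~near_mask)[0]:
        aware[i] = respond(obs, contrasts[i], rng)

    cue_color = rng.choice(["green", "red"], size=n)
    # task rule: seen & green -> right (+1), seen & red -> left (-1);
    # inverted when unseen
    direction = np.where(cue_color == "green", 1, -1) * np.where(aware, 1, -1)
    latency = np.array([
        _trunc_normal(obs.lat_aware_mu if a else obs.lat_unaware_mu,
                      obs.lat_sd, 80.0, cfg.max_response, rng)
        for a in aware])
    return pd.DataFrame({
        "trial": np.arange(n),
        "class": classes,
        "contrast_pct": contrasts,
        "aware": aware,
        "cue_color": cue_color,
        "correct_dir": direction,
        "latency_ms": latency,
        "valid": True,
    })


def simulate_session(cfg: TaskConfig | None = None,
                     obs: ObserverSpec | None = None,
                     montage: pd.DataFrame | None = None,
                     seed: int = 0, session_index: int = 0,
                     p_fixbreak: float = 0.05,
                     noise_sd: float = 10.0, evoked_gain: float = 8.0,
                     common_noise_sd: float = 5.0,
                     with_epochs: bool = True) -> SessionData:
    """Generate one complete synthetic session.

    The trial schedule, staircase, reports, saccade latencies, gaze traces
    and LFP epochs are all drawn from a single RNG stream keyed by
    ``(seed, session_index)``, so identical arguments give bit-identical
    sessions.  A fraction ``p_fixbreak`` of trials receives an injected
    fixation break (to exercise the exclusion stage).
    """
    cfg = cfg or TaskConfig()
    obs = obs or ObserverSpec()
    rng = session_rng(seed if obs.seed == 0 else obs.seed, session_index)
    if montage is None:
        montage = synth_montage(4, 8, rng=rng)
        if not obs.aware_channels:
            names = montage["name"].tolist()
            # spread designated channels across shafts, non-adjacent
            import dataclasses
            obs = dataclasses.replace(
                obs, aware_channels=tuple(names[i] for i in (1, 4, 10, 19, 26)))

    trials = simulate_trials(cfg, obs, rng)
    n = len(trials)
    break_trials = rng.random(n) < p_fixbreak
    t_gaze = gaze_times(cfg)
    gaze = np.empty((n, t_gaze.size, 2))
    for i in range(n):
        fb = None
        if break_trials[i]:
            fb = (cfg.check_window + 2.0, -cfg.fixation_dur / 2, 60.0)
        _, gaze[i] = synth_eye_trace(float(trials["latency_ms"].iloc[i]),
                                     int(trials["correct_dir"].iloc[i]), cfg,
                                     rng, fixation_break=fb)

    if with_epochs:
        epochs = synth_epochs(trials, obs, montage, cfg, rng,
                              noise_sd=noise_sd, evoked_gain=evoked_gain,
                              common_noise_sd=common_noise_sd)
    else:
        epochs = EpochArray(np.zeros((len(montage), default_times(cfg.fs).size, n)),
                            default_times(cfg.fs), montage["name"].tolist(), cfg.fs)
    return SessionData(trials, gaze, t_gaze, epochs, montage, cfg, obs)
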