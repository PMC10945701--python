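"""LFP conditioning: band-pass + notch filtering, epoching, channel
screening, and bipolar re-referencing along depth-electrode shafts."""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EpochArray, EPOCH_TMIN, EPOCH_TMAX, default_times

__all__ = ["design_lfp_filter", "filter_lfp", "make_epochs",
           "screen_channels", "bipolar_rereference", "zero_phase_fir"]

NOTCH_FREQS = (50.0, 100.0, 150.0, 200.0, 250.0)


def design_lfp_filter(fs: float, l_freq: float = 1.0, h_freq: float = 250.0,
                      notches: tuple = NOTCH_FREQS, notch_halfwidth: float = 2.0,
                      transition: float = 1.0) -> np.ndarray:
    """Linear-phase FIR combining the 1-250 Hz band-pass with line-noise
    notches.

    A single Hamming-windowed ``firwin2`` design with ~1 Hz transitions and
    +/- ``notch_halfwidth`` Hz stop bands around each notch frequency.  The
    kernel length is ``3.3 * fs / transition`` (rounded up to odd), the
    standard window-design rule for the requested transition width.
    """
    nyq = fs / 2.0
    if h_freq >= nyq:
        raise ValueError(f"band edge {h_freq} Hz requires fs > {2 * h_freq} Hz")
    numtaps = int(np.ceil(3.3 * fs / transition)) | 1
    pts = [(0.0, 0.0), (max(l_freq - transition / 2, 1e-6), 0.0),
           (l_freq + transition / 2, 1.0)]
    for f0 in sorted(notches):
        if f0 >= nyq:
            continue
        pts += [(f0 - notch_halfwidth - transition, 1.0),
                (f0 - notch_halfwidth, 0.0),
                (f0 + notch_halfwidth, 0.0),
                (f0 + notch_halfwidth + transition, 1.0)]
    if h_freq + transition / 2 < nyq:
        pts += [(h_freq - transition / 2, 1.0), (h_freq + transition / 2, 0.0),
                (nyq, 0.0)]
    else:
        pts += [(nyq, 1.0)]
    # clip overlapping breakpoints (e.g. 250 Hz notch meeting the band edge)
    freqs, gains = [], []
    for f, g in pts:
        f = min(max(f, 0.0), nyq)
        if freqs and f <= freqs[-1]:
            f = freqs[-1] + 1e-3
        freqs.append(f)
        gains.append(g)
    freqs[0], freqs[-1] = 0.0, nyq
    return signal.firwin2(numtaps, freqs, gains, fs=fs, window="hamming")


def zero_phase_fir(data: np.ndarray, kernel: np.ndarray,
                   chunk: int = 2048) -> np.ndarray:
    """Apply a symmetric (linear-phase) FIR along the last axis with odd
    reflection padding, so the output has zero phase delay and no edge step.

    ``data`` may have any leading shape; it is processed in chunks of
    ``chunk`` rows to bound memory.
    """
    half = len(kernel) // 2
    flat = data.reshape(-1, data.shape[-1])
    dtype = flat.dtype if flat.dtype in (np.float32, np.float64) else np.float64
    kernel = kernel.astype(dtype, copy=False)
    out = np.empty_like(flat, dtype=dtype)
    for i in range(0, flat.shape[0], chunk):
        x = flat[i:i + chunk].astype(dtype, copy=False)
        left = 2 * x[:, :1] - x[:, 1:half + 1][:, ::-1]
        right = 2 * x[:, -1:] - x[:, -half - 1:-1][:, ::-1]
        padded = np.concatenate([left, x, right], axis=1)
        y = signal.fftconvolve(padded, kernel[None, :], mode="same", axes=1)
        out[i:i + chunk] = y[:, half:half + data.shape[-1]]
    return out.reshape(data.shape)


def filter_lfp(epochs: EpochArray, kernel: np.ndarray | None = None) -> EpochArray:
    """Zero-phase 1-250 Hz band-pass plus 50 Hz-harmonic notches; the DC
    offset is removed explicitly.  Requires fs > 500 Hz."""
    fs = epochs.fs
    if fs <= 500.0:
        raise ValueError("sampling rate too low for a 250 Hz band edge")
    if kernel is None:
        kernel = design_lfp_filter(fs)
    # time axis last for filtering: (ch, trials, time)
    x = np.ascontiguousarray(epochs.data.transpose(0, 2, 1))
    x -= x.mean(axis=-1, keepdims=True)
    y = zero_phase_fir(x, kernel)
    del x
    return EpochArray(np.ascontiguousarray(y.transpose(0, 2, 1)), epochs.times,
                      epochs.channels, fs, epochs.reference)


def make_epochs(streams, onsets, channels, fs: float = 1000.0) -> EpochArray:
    """Cut the standard [-490, 1299] ms epoch out of per-trial continuous
    streams.

    ``streams`` is a sequence of ``(n_channels, n_times)`` arrays (one per
    trial) and ``onsets`` the stimulus-onset sample index within each stream.
    A trial whose stream does not cover the full window is rejected.
    """
    n_before = int(round(-EPOCH_TMIN * fs / 1000.0))
    n_after = int(round(EPOCH_TMAX * fs / 1000.0))
    times = default_times(fs)
    cut = []
    for k, (stream, onset) in enumerate(zip(streams, onsets)):
        stream = np.asarray(stream)
        if onset - n_before < 0 or onset + n_after >= stream.shape[-1]:
            raise ValueError(
                f"trial {k}: stream does not cover the [-490, 1299] ms window "
                f"around onset sample {onset}")
        cut.append(stream[:, onset - n_before:onset + n_after + 1])
    data = np.stack(cut, axis=-1)
    return EpochArray(data, times, channels, fs)


def screen_channels(epochs: EpochArray, line_ratio_max: float = 1.0,
                    mad_k: float = 5.0, var_floor: float = 1e-10) -> pd.DataFrame:
    """Automated bad-channel screening (a surrogate for visual inspection).

    Drops channels that are flat (variance below ``var_floor``), dominated by
    line noise (48-52 Hz PSD over 1-45 Hz PSD above ``line_ratio_max``), or
    whose broadband log-power deviates more than ``mad_k`` scaled MADs from
    the montage median.  All metrics are computed on the pre-stimulus
    baseline samples only, so genuine task responses never count against a
    channel; the MAD is floored at 0.1 dex to stay meaningful on very
    homogeneous montages.  Returns a per-channel report with ``keep`` flags
    and reasons; aborts when nothing survives.  Requires >= 10 trials.
    """
    if epochs.n_trials < 10:
        raise ValueError("need >= 10 trials for channel screening")
    pre = epochs.times < 0
    x = epochs.data[:, pre].transpose(0, 2, 1).reshape(epochs.n_channels, -1)
    var = x.var(axis=1)
    nper = min(int(epochs.fs), x.shape[1])
    f, psd = signal.welch(x, fs=epochs.fs, nperseg=nper, axis=1)
    line = psd[:, (f >= 48) & (f <= 52)].mean(axis=1)
    broad = psd[:, (f >= 1) & (f <= 45)].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(broad > 0, line / broad, np.inf)
        logpow = np.log10(np.maximum(var, 1e-300))
    med = np.median(logpow)
    mad = max(np.median(np.abs(logpow - med)) * 1.4826, 0.1)
    reasons = []
    for i in range(epochs.n_channels):
        r = ""
        if var[i] < var_floor:
            r = "flat"
        elif ratio[i] > line_ratio_max:
            r = "line_noise"
        elif mad > 0 and abs(logpow[i] - med) > mad_k * mad:
            r = "outlier_power"
        reasons.append(r)
    report = pd.DataFrame({
        "channel": epochs.channels, "keep": [r == "" for r in reasons],
        "reason": reasons, "variance": var, "line_ratio": ratio,
        "log_power": logpow,
    })
    if not report["keep"].any():
        raise RuntimeError("channel screening dropped every channel:\n"
                           + report.to_string())
    return report


def bipolar_rereference(epochs: EpochArray, montage: pd.DataFrame):
    """Re-reference each contact to its direct within-segment neighbor.

    Output channel ``Ak-Ak+1`` is ``contact_k - contact_{k+1}`` for adjacent
    within-shaft indices in the same segment; pairs never span the 10 mm
    segment gap.  The pair inherits the midpoint coordinates and the deeper
    (lower-index) contact's region label.  Shafts (or segments) left with a
    single surviving contact contribute no pair.

    Returns ``(EpochArray, pair_montage)``.
    """
    name_to_row = {r["name"]: r for _, r in montage.iterrows()}
    available = [c for c in epochs.channels if c in name_to_row]
    ch_index = {c: i for i, c in enumerate(epochs.channels)}
    pairs, rows = [], []
    monty = montage[montage["name"].isin(available)]
    for (shaft, segment), grp in monty.groupby(["shaft", "segment"], sort=False):
        grp = grp.sort_values("index")
        names = grp["name"].tolist()
        idxs = grp["index"].tolist()
        for a, b, ia, ib in zip(names[:-1], names[1:], idxs[:-1], idxs[1:]):
            if ib != ia + 1:
                continue  # a dropped contact breaks the chain
            ra, rb = name_to_row[a], name_to_row[b]
            pairs.append((ch_index[a], ch_index[b]))
            rows.append({
                "name": f"{a}-{b}",
                "x": (ra["x"] + rb["x"]) / 2, "y": (ra["y"] + rb["y"]) / 2,
                "z": (ra["z"] + rb["z"]) / 2,
                "shaft": shaft, "segment": segment, "index": ia,
                "region": ra["region"], "hemisphere": ra["hemisphere"],
            })
    if not pairs:
        raise ValueError("no adjacent contact pairs available for bipolar "
                         "re-referencing")
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    data = epochs.data[ia] - epochs.data[ib]
    pair_montage = pd.DataFrame(rows)
    out = EpochArray(data, epochs.times, pair_montage["name"].tolist(),
                     epochs.fs, reference="bipolar")
    return out, pair_montage
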