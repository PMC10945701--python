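"""High-gamma (60-150 Hz) time-frequency analysis.

Induced activity is isolated by subtracting each condition's mean evoked
response before wavelet decomposition (7-cycle Morlet, 60-150 Hz in 10 Hz
steps); the high-gamma magnitude is the wavelet magnitude averaged across
that grid.  Because of wavelet edge effects only the -200 to 800 ms window
is valid for reporting; the divergence machinery is then applied to the
baseline-normalized magnitude exactly as for the broadband ERP.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .divergence import DivergenceResult, divergence_analysis

__all__ = ["TFRArray", "remove_evoked", "morlet_tfr", "hg_magnitude",
           "compute_hg_magnitude", "baseline_normalize_hg", "spectrogram_db",
           "hg_divergence", "HG_FREQS", "VALID_WINDOW"]

HG_FREQS = np.arange(60.0, 151.0, 10.0)
N_CYCLES = 7.0
VALID_WINDOW = (-200.0, 800.0)


@dataclass
class TFRArray:
    """Wavelet magnitude: ``magnitude[channel, frequency, time, trial]``."""

    magnitude: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    fs: float
    valid_window: tuple = VALID_WINDOW


def remove_evoked(data: np.ndarray, conditions: np.ndarray) -> np.ndarray:
    """Subtract each trial's own-condition mean epoch (evoked response),
    leaving induced activity.  Warns implicitly through the result: a
    condition with a single trial becomes identically zero."""
    conditions = np.asarray(conditions)
    if conditions.size != data.shape[2]:
        raise ValueError("condition labels must cover all trials")
    dtype = data.dtype if data.dtype in (np.float32, np.float64) else np.float64
    out = data.astype(dtype, copy=True)
    for c in np.unique(conditions):
        idx = np.where(conditions == c)[0]
        out[:, :, idx] -= data[:, :, idx].mean(axis=2, keepdims=True)
    return out


def _check_edges(times: np.ndarray, fs: float, freqs: np.ndarray) -> None:
    # half-length of the longest wavelet must fit between the epoch edge and
    # the valid reporting window
    half_ms = N_CYCLES / freqs.min() / 2.0 * 1000.0
    if times[0] > VALID_WINDOW[0] - half_ms or times[-1] < VALID_WINDOW[1] + half_ms:
        raise ValueError(
            f"epoch [{times[0]}, {times[-1]}] ms too short for artifact-free "
            f"{VALID_WINDOW} ms reporting with {N_CYCLES}-cycle wavelets at "
            f"{freqs.min()} Hz")


def morlet_tfr(data: np.ndarray, times: np.ndarray, fs: float,
               freqs: np.ndarray = HG_FREQS, n_cycles: float = N_CYCLES,
               chunk: int = 100) -> TFRArray:
    """Morlet wavelet magnitude of (channels, times, trials) data.

    Thin wrapper over :func:`mne.time_frequency.tfr_array_morlet`, computed
    in trial chunks to bound memory.  Frequencies above Nyquist are rejected.
    """
    from mne.time_frequency import tfr_array_morlet
    freqs = np.asarray(freqs, dtype=float)
    if freqs.max() >= fs / 2.0:
        raise ValueError("wavelet frequency at or above Nyquist")
    _check_edges(times, fs, freqs)
    n_ch, n_t, n_tr = data.shape
    mag = np.empty((n_ch, freqs.size, n_t, n_tr), dtype=np.float32)
    for i in range(0, n_tr, chunk):
        block = data[:, :, i:i + chunk].transpose(2, 0, 1)  # (epochs, ch, time)
        power = tfr_array_morlet(block, sfreq=fs, freqs=freqs,
                                 n_cycles=n_cycles, output="power",
                                 verbose="error")
        mag[:, :, :, i:i + chunk] = np.sqrt(power).transpose(1, 2, 3, 0)
    return TFRArray(mag, freqs, np.asarray(times), fs)


def hg_magnitude(tfr: TFRArray) -> np.ndarray:
    """Average wavelet magnitude across the high-gamma frequency grid:
    (channels, times, trials)."""
    return tfr.magnitude.mean(axis=1)


def compute_hg_magnitude(data: np.ndarray, times: np.ndarray, fs: float,
                         freqs: np.ndarray = HG_FREQS,
                         n_cycles: float = N_CYCLES,
                         chunk: int = 50) -> np.ndarray:
    """High-gamma magnitude straight from epochs, streaming over trials.

    Equivalent to ``hg_magnitude(morlet_tfr(...))`` but never materializes
    the full channels x frequencies x times x trials array, which matters
    for sessions with many channels and trials.
    """
    from mne.time_frequency import tfr_array_morlet
    freqs = np.asarray(freqs, dtype=float)
    if freqs.max() >= fs / 2.0:
        raise ValueError("wavelet frequency at or above Nyquist")
    _check_edges(times, fs, freqs)
    n_ch, n_t, n_tr = data.shape
    out = np.empty((n_ch, n_t, n_tr), dtype=np.float32)
    for i in range(0, n_tr, chunk):
        block = data[:, :, i:i + chunk].transpose(2, 0, 1)
        power = tfr_array_morlet(block, sfreq=fs, freqs=freqs,
                                 n_cycles=n_cycles, output="power",
                                 verbose="error")
        out[:, :, i:i + chunk] = np.sqrt(power).mean(axis=2).transpose(1, 2, 0)
    return out


def baseline_normalize_hg(hg: np.ndarray, times: np.ndarray,
                          baseline: tuple[float, float] = (-200.0, 0.0)):
    """Z-style baseline normalization ``(x - mu) / sigma * 100``.

    mu and sigma are the mean and standard deviation of the high-gamma
    magnitude over the baseline window, pooled across trials and baseline
    samples, per channel.  Channels with sigma = 0 are flagged and skipped.
    Returns ``(normalized, flagged_channel_indices)``.
    """
    sel = (times >= baseline[0]) & (times <= baseline[1])
    base = hg[:, sel]
    mu = base.mean(axis=(1, 2))
    sigma = base.std(axis=(1, 2))
    flagged = np.where(sigma == 0)[0]
    dtype = hg.dtype if hg.dtype in (np.float32, np.float64) else np.float64
    out = hg.astype(dtype, copy=True)
    good = sigma > 0
    out[good] = (hg[good] - mu[good, None, None]) / sigma[good, None, None] * 100.0
    return out, flagged


def spectrogram_db(power: np.ndarray, times: np.ndarray,
                   baseline: tuple[float, float] = (-200.0, 0.0)) -> np.ndarray:
    """dB spectrogram relative to baseline: ``10 log10(x / mu)`` with mu the
    mean power over the baseline window per (channel, frequency), pooled
    across trials.  ``power`` is (channels, freqs, times, trials) and must be
    positive."""
    if np.any(power <= 0):
        raise ValueError("power must be positive for dB normalization")
    sel = (times >= baseline[0]) & (times <= baseline[1])
    mu = power[:, :, sel].mean(axis=(2, 3))
    return 10.0 * np.log10(power / mu[:, :, None, None])


def hg_divergence(data: np.ndarray, times: np.ndarray, fs: float,
                  conditions: np.ndarray, channels: list[str] | None = None,
                  q: float = 0.01, normalize: bool = True,
                  **tfr_kwargs) -> DivergenceResult:
    """NA-vs-NU divergence on high-gamma magnitude.

    Pipeline: remove per-condition evoked responses, compute streaming HG
    magnitude, baseline-normalize, then run the identical t-test -> FDR ->
    persistence machinery used for the broadband ERP.
    """
    induced = remove_evoked(data, conditions)
    hg = compute_hg_magnitude(induced, times, fs, **tfr_kwargs)
    if normalize:
        hg, _ = baseline_normalize_hg(hg, times)
    return divergence_analysis(hg, times, conditions, channels=channels,
                               q=q, fs=fs)
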