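"""Low-frequency (1-8 Hz) time-across phase-locking connectivity.

The time-across PLV at time t is the magnitude of the trial-averaged unit
phasor of the inter-channel phase difference,
``PLV_ij(t) = | mean_trials exp(i (phi_i(t) - phi_j(t))) |``: 0 for random
phase relations, 1 for a perfectly consistent lag.  Phases come from
zero-phase band-pass filtering into near-narrowband sub-bands ([1-4] and
[4-8] Hz) followed by the analytic-signal (Hilbert) phase; the PLV is
computed per sub-band and averaged, and each pair's mean baseline
(-200-0 ms) PLV is subtracted for display and statistics.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import ceil

import numpy as np
import pandas as pd
from scipy import signal as sig

from .preprocess import zero_phase_fir

__all__ = ["PLVResult", "bandpass_hilbert_phase", "plv_time_across",
           "baseline_subtract_plv", "region_average_plv", "top_fraction_edges",
           "site_to_rest_plv", "DEFAULT_BANDS", "VALID_WINDOW"]

DEFAULT_BANDS = ((1.0, 4.0), (4.0, 8.0))
#: first/last 500 ms of the epoch are unreliable after 1 Hz filtering
VALID_WINDOW = (-200.0, 800.0)


def _band_kernel(lo: float, hi: float, fs: float) -> np.ndarray:
    width = max(lo, 1.0)  # transition width scales with the low edge
    numtaps = int(np.ceil(3.3 * fs / width)) | 1
    return sig.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs,
                      window="hamming")


def bandpass_hilbert_phase(data: np.ndarray, fs: float,
                           bands: tuple = DEFAULT_BANDS,
                           chunk: int = 2048,
                           dtype=np.float32) -> np.ndarray:
    """Instantaneous phase per sub-band: (n_bands, channels, times, trials).

    Each sub-band is zero-phase FIR filtered and the phase taken from the
    analytic signal; a pure cosine at its peak has phase 0.
    """
    if min(lo for lo, _ in bands) <= 0:
        raise ValueError("band edges must be positive")
    if max(hi for _, hi in bands) >= fs / 2:
        raise ValueError("band edge at or above Nyquist")
    n_ch, n_t, n_tr = data.shape
    x = data.transpose(0, 2, 1).reshape(n_ch * n_tr, n_t)  # (ch*trial, time)
    phases = np.empty((len(bands), n_ch, n_t, n_tr), dtype=dtype)
    for b, (lo, hi) in enumerate(bands):
        kern = _band_kernel(lo, hi, fs)
        filt = zero_phase_fir(x, kern, chunk=chunk)
        ph = np.empty((n_ch * n_tr, n_t), dtype=dtype)
        for i in range(0, filt.shape[0], chunk):
            ph[i:i + chunk] = np.angle(
                sig.hilbert(filt[i:i + chunk], axis=-1)).astype(dtype)
        phases[b] = ph.reshape(n_ch, n_tr, n_t).transpose(0, 2, 1)
    return phases


@dataclass
class PLVResult:
    """Pair-wise PLV time courses (sub-band averaged)."""

    plv: np.ndarray                       # (n_pairs, n_times)
    pairs: list[tuple[int, int]]          # channel index pairs, i < j
    times: np.ndarray
    channels: list[str]
    bands: tuple = DEFAULT_BANDS
    baseline_corrected: bool = False
    per_band: np.ndarray | None = None    # (n_bands, n_pairs, n_times)


def plv_time_across(phases: np.ndarray, times: np.ndarray,
                    channels: list[str],
                    pairs: list[tuple[int, int]] | None = None,
                    bands: tuple = DEFAULT_BANDS,
                    pair_chunk: int = 64,
                    keep_bands: bool = False) -> PLVResult:
    """Time-across PLV for every channel pair (or a supplied pair list).

    ``phases`` is the (n_bands, channels, times, trials) array from
    :func:`bandpass_hilbert_phase`.  The PLV is computed per sub-band and
    averaged across sub-bands.  Requires >= 2 trials.
    """
    n_bands, n_ch, n_t, n_tr = phases.shape
    if n_tr < 2:
        raise ValueError("need >= 2 trials for a trial-averaged PLV")
    if pairs is None:
        pairs = list(combinations(range(n_ch), 2))
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    # precision follows the input: float64 phases give complex128 arithmetic
    f_dtype = np.float32 if phases.dtype == np.float32 else np.float64
    c_dtype = np.complex64 if f_dtype == np.float32 else np.complex128
    per_band = np.empty((n_bands, len(pairs), n_t), dtype=f_dtype)
    for b in range(n_bands):
        z = np.exp(1j * phases[b].astype(f_dtype)).astype(c_dtype)  # (ch, t, trials)
        for s in range(0, len(pairs), pair_chunk):
            zi = z[ii[s:s + pair_chunk]]
            zj = z[jj[s:s + pair_chunk]]
            per_band[b, s:s + pair_chunk] = np.abs(
                (zi * np.conj(zj)).mean(axis=-1))
    plv = per_band.mean(axis=0)
    return PLVResult(plv, list(pairs), np.asarray(times), list(channels),
                     bands=bands,
                     per_band=per_band if keep_bands else None)


def baseline_subtract_plv(res: PLVResult,
                          baseline: tuple[float, float] = (-200.0, 0.0)) -> PLVResult:
    """Subtract each pair's mean PLV over the baseline window from its whole
    time course."""
    sel = (res.times >= baseline[0]) & (res.times <= baseline[1])
    if not sel.any():
        raise ValueError("baseline window outside the PLV time axis")
    base = res.plv[:, sel].mean(axis=1, keepdims=True)
    return PLVResult(res.plv - base, res.pairs, res.times, res.channels,
                     res.bands, baseline_corrected=True)


def region_average_plv(res: PLVResult, montage: pd.DataFrame):
    """Average pair PLV according to the channels' atlas regions.

    Returns ``(matrix, regions)`` where ``matrix[a, b, t]`` is the mean PLV
    over all channel pairs with one endpoint in region a and the other in
    region b (within-region entries average the region's internal pairs,
    self-pairs excluded by construction); symmetric in the region indices.
    Regions with no contributing pair hold NaN.
    """
    region_of = dict(zip(montage["name"], montage["region"]))
    missing = [c for c in res.channels if c not in region_of]
    if missing:
        raise ValueError(f"channels without region labels: {missing}")
    regions = sorted({region_of[c] for c in res.channels})
    r_index = {r: k for k, r in enumerate(regions)}
    n_r, n_t = len(regions), res.times.size
    acc = np.zeros((n_r, n_r, n_t))
    cnt = np.zeros((n_r, n_r))
    for (i, j), row in zip(res.pairs, res.plv):
        a = r_index[region_of[res.channels[i]]]
        b = r_index[region_of[res.channels[j]]]
        acc[a, b] += row
        cnt[a, b] += 1
        if a != b:
            acc[b, a] += row
            cnt[b, a] += 1
    with np.errstate(invalid="ignore"):
        matrix = acc / cnt[:, :, None]
    return matrix, regions


def top_fraction_edges(matrix: np.ndarray, fraction: float = 0.15):
    """Strongest edges of a symmetric region matrix at one time point.

    Retains the ``ceil(fraction * n_edges)`` largest upper-triangle entries
    (NaN edges excluded); ties are broken by stable (row-major) edge order.
    Returns a list of ``(a, b, value)`` with a < b.
    """
    n = matrix.shape[0]
    edges = [(a, b, matrix[a, b]) for a in range(n) for b in range(a + 1, n)
             if np.isfinite(matrix[a, b])]
    if not edges:
        return []
    k = min(ceil(fraction * len(edges)), len(edges))
    vals = np.array([e[2] for e in edges])
    order = np.argsort(-vals, kind="stable")[:k]
    return [edges[i] for i in sorted(order)]


def site_to_rest_plv(res: PLVResult, sites: list[str]) -> pd.DataFrame:
    """Mean PLV from each selected site to all other channels.

    Returns a DataFrame indexed by time with one column per site — used to
    compare, per condition, the coupling of early-divergence sites with the
    rest of the montage.
    """
    if not sites:
        raise ValueError("site subset must be non-empty")
    idx_of = {c: i for i, c in enumerate(res.channels)}
    cols = {}
    for s in sites:
        si = idx_of[s]
        rows = [k for k, (i, j) in enumerate(res.pairs) if si in (i, j)]
        if not rows:
            raise ValueError(f"site {s} appears in no pair")
        cols[s] = res.plv[rows].mean(axis=0)
    return pd.DataFrame(cols, index=pd.Index(res.times, name="time_ms"))
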