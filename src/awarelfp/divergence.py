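"""Divergence-onset statistics: identify awareness-related channels and the
time at which near-threshold aware (NA) and unaware (NU) responses diverge.

The statistic: at every sample in the 0-650 ms window (stimulus onset to
saccade cue) compare NA vs NU trials with an independent-samples t-test,
correct jointly across channels and time points with Benjamini-Hochberg FDR
at q = 0.01, and call a channel awareness-related when significance persists
for more than 20 ms.  The first sample of the earliest qualifying run is the
divergence onset time (DOT); the mean NA-NU difference over that run is the
divergence amplitude (DA); normDOT min-max normalizes the time remaining to
the cue (650 - DOT) across a patient's awareness-related channels, so larger
normDOT means earlier divergence.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DivergenceResult", "pointwise_condition_test", "fdr_correct",
    "find_runs", "find_divergence", "normalize_dot", "baseline_normalize_erp",
    "population_divergence", "split_early_late", "divergence_analysis",
]

T_TARGET = 650.0  #: ms from stimulus onset to the saccade cue
ANALYSIS_WINDOW = (0.0, 650.0)


@dataclass
class DivergenceResult:
    """Per-channel divergence statistics plus the significance mask."""

    table: pd.DataFrame          # channel, aware_related, dot, da, td, norm_dot
    mask: np.ndarray             # (n_channels, n_window_times) significance
    times: np.ndarray            # ms, the analysis window time axis
    runs: dict = field(default_factory=dict)  # channel -> [(t_start, t_end), ...]
    q: float = 0.01

    @property
    def aware_related(self) -> pd.DataFrame:
        return self.table[self.table["aware_related"]]


def pointwise_condition_test(data_a: np.ndarray, data_b: np.ndarray):
    """Welch t-test at every (channel, time) cell between two trial groups.

    ``data_a``/``data_b`` are (channels, times, trials) arrays for the two
    conditions.  Returns ``(t, p)`` matrices of shape (channels, times); the
    test is two-sided and does not assume equal variances.
    """
    if data_a.shape[2] < 2 or data_b.shape[2] < 2:
        raise ValueError("need >= 2 trials per condition")
    res = stats.ttest_ind(data_a, data_b, axis=2, equal_var=False)
    return np.asarray(res.statistic), np.asarray(res.pvalue)


def fdr_correct(p: np.ndarray, q: float = 0.01) -> np.ndarray:
    """Benjamini-Hochberg step-up applied jointly over all cells of ``p``.

    Returns a boolean mask of the same shape, true where the BH-adjusted
    p-value is <= q.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adj = stats.false_discovery_control(p.ravel(), method="bh")
    return (adj <= q).reshape(p.shape)


def find_runs(mask_row: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of consecutive-True runs; stop exclusive."""
    padded = np.concatenate([[0], mask_row.astype(int), [0]])
    edges = np.diff(padded)
    starts = np.where(edges == 1)[0]
    stops = np.where(edges == -1)[0]
    return list(zip(starts, stops))


def find_divergence(mask: np.ndarray, times: np.ndarray,
                    diff: np.ndarray | None = None,
                    channels: list[str] | None = None,
                    min_persist: float = 20.0, fs: float = 1000.0,
                    q: float = 0.01) -> DivergenceResult:
    """Apply the persistence criterion and extract DOT/DA per channel.

    A channel is awareness-related iff its significance mask contains a run
    strictly longer than ``min_persist`` ms (> 20 samples at 1 kHz, i.e. at
    least 21).  DOT is the time of the first sample of the earliest
    qualifying run; DA is the mean of ``diff`` (the NA - NU mean difference
    series) over that run.
    """
    mask = np.atleast_2d(np.asarray(mask, dtype=bool))
    n_ch = mask.shape[0]
    channels = channels if channels is not None else [str(i) for i in range(n_ch)]
    need = int(round(min_persist * fs / 1000.0)) + 1  # strictly more than 20 ms
    rows, run_map = [], {}
    for i in range(n_ch):
        runs = [(s, e) for s, e in find_runs(mask[i]) if e - s >= need]
        run_map[channels[i]] = [(float(times[s]), float(times[e - 1])) for s, e in runs]
        if runs:
            s, e = runs[0]
            dot = float(times[s])
            da = float(diff[i, s:e].mean()) if diff is not None else np.nan
            rows.append({"channel": channels[i], "aware_related": True,
                         "dot": dot, "da": da, "td": T_TARGET - dot})
        else:
            rows.append({"channel": channels[i], "aware_related": False,
                         "dot": np.nan, "da": np.nan, "td": np.nan})
    table = pd.DataFrame(rows)
    table["norm_dot"] = normalize_dot(table["dot"].to_numpy())
    return DivergenceResult(table, mask, np.asarray(times), run_map, q)


def normalize_dot(dots: np.ndarray, t_target: float = T_TARGET) -> np.ndarray:
    """Min-max normalize Td = t_target - DOT across a patient's
    awareness-related channels; larger normDOT means earlier divergence.

    NaN DOTs (channels that never diverge) stay NaN.  With a single channel
    or all-equal DOTs the range is degenerate and every value is 0.5 by
    convention (the midpoint avoids asserting an extremal rank).
    """
    dots = np.asarray(dots, dtype=float)
    td = t_target - dots
    ok = np.isfinite(td)
    out = np.full(dots.shape, np.nan)
    if not ok.any():
        return out
    lo, hi = td[ok].min(), td[ok].max()
    if hi - lo < 1e-12:
        out[ok] = 0.5
    else:
        out[ok] = (td[ok] - lo) / (hi - lo)
    return out


def baseline_normalize_erp(data: np.ndarray, times: np.ndarray,
                           baseline: tuple[float, float] = (-200.0, 0.0),
                           mu_floor: float = 1.0):
    """Percent-of-baseline normalization ``(x - mu) / mu * 100`` per channel,
    with mu the mean amplitude over the baseline window pooled across trials.

    Channels whose |mu| falls below ``mu_floor`` (uV) are flagged and left
    unnormalized (the ratio would blow up).  Returns ``(normalized,
    flagged_channel_indices)``.
    """
    sel = (times >= baseline[0]) & (times <= baseline[1])
    mu = data[:, sel].mean(axis=(1, 2))
    flagged = np.where(np.abs(mu) < mu_floor)[0]
    out = data.astype(float).copy()
    good = np.abs(mu) >= mu_floor
    out[good] = (data[good] - mu[good, None, None]) / mu[good, None, None] * 100.0
    return out, flagged


def population_divergence(diff: np.ndarray, selected: np.ndarray | list):
    """Population time course of awareness-related activity.

    Because LFP polarity is physiologically ambiguous, the per-channel NA-NU
    mean-difference series are rectified (absolute value) before averaging
    across the selected channels.  Returns ``(mean, sem)`` over channels.
    """
    sel = np.asarray(selected)
    if sel.dtype == bool:
        sel = np.where(sel)[0]
    if sel.size == 0:
        raise ValueError("need >= 1 selected channel")
    absd = np.abs(diff[sel])
    mean = absd.mean(axis=0)
    sem = absd.std(axis=0, ddof=1) / np.sqrt(sel.size) if sel.size > 1 \
        else np.zeros_like(mean)
    return mean, sem


def split_early_late(dots: np.ndarray, cutoff: float = 350.0) -> dict:
    """Split awareness-related channels into early (DOT < cutoff) and late
    (DOT >= cutoff) groups; returns labels and group fractions."""
    dots = np.asarray(dots, dtype=float)
    ok = np.isfinite(dots)
    labels = np.array(["" for _ in dots], dtype=object)
    labels[ok & (dots < cutoff)] = "early"
    labels[ok & (dots >= cutoff)] = "late"
    n = int(ok.sum())
    return {
        "labels": labels,
        "n_early": int((labels == "early").sum()),
        "n_late": int((labels == "late").sum()),
        "frac_early": float((labels == "early").sum() / n) if n else np.nan,
        "frac_late": float((labels == "late").sum() / n) if n else np.nan,
    }


def divergence_analysis(data: np.ndarray, times: np.ndarray,
                        conditions: np.ndarray, channels: list[str] | None = None,
                        q: float = 0.01, window: tuple = ANALYSIS_WINDOW,
                        min_persist: float = 20.0, fs: float = 1000.0,
                        cond_a: str = "NA", cond_b: str = "NU") -> DivergenceResult:
    """Full NA-vs-NU divergence pipeline on one signal array.

    ``data`` is (channels, times, trials) — broadband amplitude for the ERP
    variant or high-gamma magnitude for the HG variant; ``conditions`` the
    per-trial condition labels.  Runs the pointwise Welch test within
    ``window``, joint BH-FDR at ``q``, and the persistence criterion.
    """
    conditions = np.asarray(conditions)
    ia = np.where(conditions == cond_a)[0]
    ib = np.where(conditions == cond_b)[0]
    if ia.size < 2 or ib.size < 2:
        raise ValueError(f"need >= 2 trials in each of {cond_a}/{cond_b}")
    sel = (times >= window[0]) & (times <= window[1])
    wa = data[:, sel][:, :, ia]
    wb = data[:, sel][:, :, ib]
    _, p = pointwise_condition_test(wa, wb)
    mask = fdr_correct(p, q=q)
    diff = wa.mean(axis=2) - wb.mean(axis=2)
    res = find_divergence(mask, times[sel], diff=diff, channels=channels,
                          min_persist=min_persist, fs=fs, q=q)
    return res
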