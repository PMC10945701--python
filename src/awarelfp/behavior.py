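"""Behavioral analysis: psychometric fitting, condition labeling, trial
exclusion, saccade-latency detection and the associated statistics.

Condition labels follow the standard four-way split of near-threshold
detection data: HA (high-contrast aware), NA (near-threshold aware), NU
(near-threshold unaware), LU (low-contrast unaware); all other
contrast/report combinations are rare and labeled ``other``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import TaskConfig

__all__ = [
    "PsychometricFit", "fit_psychometric", "pool_adjacent_levels",
    "level_table", "classify_contrast_levels", "label_conditions",
    "exclude_trials", "detect_saccade_latency", "compute_dprime",
    "wilcoxon_exact", "compare_latencies", "compare_contrast_distributions",
]

CONDITIONS = ("LU", "NU", "NA", "HA")


# ---------------------------------------------------------------------------
# Psychometric curve
# ---------------------------------------------------------------------------

def _logistic4(sc, a, b, c, d):
    return a + b / (1.0 + np.exp(-d * (sc - c)))


@dataclass
class PsychometricFit:
    """Four-parameter logistic fit of aware-report probability vs contrast:
    ``AP(SC) = a + b / (1 + exp(-d (SC - c)))``."""

    a: float
    b: float
    c: float
    d: float
    r2: float
    levels: pd.DataFrame  # columns: contrast, aware_frac, n
    converged: bool = True
    message: str = ""

    def __call__(self, sc):
        return _logistic4(np.asarray(sc, dtype=float), self.a, self.b,
                          self.c, self.d)


def level_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-contrast-level aware fractions ``(contrast, aware_frac, n)``."""
    g = trials.groupby("contrast_pct")["aware"]
    out = pd.DataFrame({
        "contrast": g.mean().index.to_numpy(dtype=float),
        "aware_frac": g.mean().to_numpy(dtype=float),
        "n": g.size().to_numpy(),
    })
    return out.sort_values("contrast", ignore_index=True)


def pool_adjacent_levels(levels: pd.DataFrame, n_out: int = 8) -> pd.DataFrame:
    """Average adjacent contrast levels down to ``n_out`` levels (used for
    population psychometric fits; contrasts and fractions are n-weighted)."""
    levels = levels.sort_values("contrast", ignore_index=True)
    groups = np.array_split(np.arange(len(levels)), n_out)
    rows = []
    for g in groups:
        if len(g) == 0:
            continue
        sub = levels.iloc[g]
        n = sub["n"].sum()
        rows.append({
            "contrast": np.average(sub["contrast"], weights=sub["n"]),
            "aware_frac": np.average(sub["aware_frac"], weights=sub["n"]),
            "n": n,
        })
    return pd.DataFrame(rows)


def fit_psychometric(levels: pd.DataFrame, n_starts: int = 8) -> PsychometricFit:
    """Least-squares logistic fit on per-level aware fractions.

    Multi-start nonlinear least squares (varying initial threshold and slope)
    with bounds 0 <= a <= 1, 0 <= b <= 1, d > 0; observations are weighted
    by the per-level trial counts.
    """
    if len(levels) < 4:
        raise ValueError("need at least 4 distinct contrast levels")
    sc = levels["contrast"].to_numpy(dtype=float)
    ap = levels["aware_frac"].to_numpy(dtype=float)
    n = levels["n"].to_numpy(dtype=float)
    w = np.sqrt(n / n.mean())
    span = max(sc.max() - sc.min(), 1e-6)

    def resid(p):
        return (_logistic4(sc, *p) - ap) * w

    best, best_cost = None, np.inf
    c_starts = np.linspace(sc.min(), sc.max(), max(n_starts // 2, 2))
    d_starts = [1.0 / span * 4, 1.0 / span * 16]
    lo = [0.0, 0.0, sc.min() - span, 1e-4]
    hi = [1.0, 1.0, sc.max() + span, 1e3 / span]
    for c0 in c_starts:
        for d0 in d_starts:
            p0 = [max(ap.min(), 0.0), min(max(ap.max() - ap.min(), 0.05), 1.0),
                  c0, d0]
            try:
                res = optimize.least_squares(resid, p0, bounds=(lo, hi))
            except Exception:
                continue
            if res.cost < best_cost:
                best, best_cost = res, res.cost
    if best is None:
        return PsychometricFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                               levels.copy(), converged=False,
                               message="all starts failed")
    a, b, c, d = best.x
    pred = _logistic4(sc, a, b, c, d)
    ss_res = float(np.sum(w ** 2 * (ap - pred) ** 2))
    ss_tot = float(np.sum(w ** 2 * (ap - np.average(ap, weights=w ** 2)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return PsychometricFit(float(a), float(b), float(c), float(d), r2,
                           levels.copy(), converged=best.success,
                           message=best.message)


# ---------------------------------------------------------------------------
# Level / condition labeling
# ---------------------------------------------------------------------------

def classify_contrast_levels(levels: pd.DataFrame) -> pd.DataFrame:
    """Label each contrast level low/near/high by its aware fraction:
    < 25% -> low, 25-75% (inclusive) -> near, > 75% -> high."""
    frac = levels["aware_frac"].to_numpy(dtype=float)
    label = np.where(frac < 0.25, "low", np.where(frac > 0.75, "high", "near"))
    out = levels.copy()
    out["level"] = label
    return out


def label_conditions(trials: pd.DataFrame,
                     levels: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assign LU/NU/NA/HA condition labels to valid trials.

    ``levels`` is the classified level table (from
    :func:`classify_contrast_levels`); if omitted it is computed from the
    valid trials.  Combinations outside the four conditions (aware at a low
    level, unaware at a high level) are labeled ``other`` and excluded from
    analysis; invalid trials get an empty label.
    """
    valid = trials[trials["valid"]]
    if levels is None:
        levels = classify_contrast_levels(level_table(valid))
    level_of = dict(zip(levels["contrast"], levels["level"]))
    out = trials.copy()
    cond = []
    for _, row in out.iterrows():
        if not row["valid"]:
            cond.append("")
            continue
        lvl = level_of.get(row["contrast_pct"])
        aware = bool(row["aware"])
        if lvl == "high" and aware:
            cond.append("HA")
        elif lvl == "near":
            cond.append("NA" if aware else "NU")
        elif lvl == "low" and not aware:
            cond.append("LU")
        else:
            cond.append("other")
    out["condition"] = cond
    return out


# ---------------------------------------------------------------------------
# Trial exclusion and saccade latency
# ---------------------------------------------------------------------------

def _longest_true_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate([[0], mask.astype(int), [0]])
    edges = np.diff(padded)
    starts = np.where(edges == 1)[0]
    ends = np.where(edges == -1)[0]
    return int((ends - starts).max())


def exclude_trials(trials: pd.DataFrame, gaze: np.ndarray,
                   gaze_times: np.ndarray, cfg: TaskConfig) -> pd.DataFrame:
    """Validity mask with per-trial exclusion reasons.

    A trial is invalid if, during the fixation period (fixation onset to the
    saccade cue), gaze leaves the square check window (half-width
    ``cfg.check_window`` degrees) for more than 40 consecutive ms, or if the
    saccade latency exceeds ``cfg.max_response`` (or no saccade was found).

    Returns a copy of ``trials`` with updated ``valid`` and a ``reason``
    column; attaches per-reason counts as ``DataFrame.attrs['exclusions']``.
    """
    if gaze.shape[0] != len(trials):
        raise ValueError("gaze and trial table have different trial counts")
    fix = (gaze_times >= -cfg.fixation_dur) & (gaze_times < cfg.stim_to_cue)
    max_run = int(round(40.0 * cfg.fs / 1000.0))  # samples; invalid if > this
    out = trials.copy()
    reasons = []
    for i in range(len(trials)):
        xy = gaze[i][fix]
        outside = (np.abs(xy[:, 0]) > cfg.check_window) | \
                  (np.abs(xy[:, 1]) > cfg.check_window)
        reason = ""
        if _longest_true_run(outside) > max_run:
            reason = "fixation_break"
        else:
            lat = trials["latency_ms"].iloc[i]
            if pd.isna(lat):
                reason = "no_saccade"
            elif lat > cfg.max_response:
                reason = "late_response"
        reasons.append(reason)
    out["valid"] = [r == "" for r in reasons]
    out["reason"] = reasons
    counts = pd.Series(reasons).value_counts().to_dict()
    counts.pop("", None)
    out.attrs["exclusions"] = counts
    return out


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average along the first axis (edges truncated)."""
    kernel = np.ones(width) / width
    if x.ndim == 1:
        num = np.convolve(x, kernel, mode="same")
        norm = np.convolve(np.ones_like(x), kernel, mode="same")
        return num / norm
    return np.stack([_moving_average(x[:, j], width) for j in range(x.shape[1])],
                    axis=1)


def detect_saccade_latency(gaze: np.ndarray, gaze_times: np.ndarray,
                           target_onset: float, cfg: TaskConfig,
                           vel_threshold: float = 30.0,
                           min_dur: float = 20.0) -> float | None:
    """Saccade latency from a 2-D gaze trace via a velocity-threshold rule.

    Position is smoothed with a centered 20 ms sliding window stepped 1
    sample, differentiated to a 2-D velocity whose Euclidean norm is smoothed
    the same way; saccade onset is the first time the smoothed speed exceeds
    ``vel_threshold`` (deg/s) sustained for more than ``min_dur`` ms (strict:
    at least 21 consecutive samples at 1 kHz).  Returns onset minus
    ``target_onset`` in ms, or ``None`` when no crossing qualifies.
    """
    width = int(round(20.0 * cfg.fs / 1000.0)) + 1  # 21 samples: centered 20 ms
    pos = _moving_average(gaze, width)
    vel = np.gradient(pos, axis=0) * cfg.fs  # deg/s per component
    speed = np.linalg.norm(vel, axis=1)
    speed = _moving_average(speed, width)

    search = gaze_times >= target_onset
    above = speed[search] > vel_threshold
    t_search = gaze_times[search]
    need = int(round(min_dur * cfg.fs / 1000.0)) + 1  # strictly more than 20 ms
    padded = np.concatenate([[0], above.astype(int), [0]])
    edges = np.diff(padded)
    starts = np.where(edges == 1)[0]
    ends = np.where(edges == -1)[0]
    for s, e in zip(starts, ends):
        if e - s >= need:
            return float(t_search[s] - target_onset)
    return None


# ---------------------------------------------------------------------------
# Signal-detection and group statistics
# ---------------------------------------------------------------------------

def compute_dprime(trials: pd.DataFrame) -> float:
    """d' = z(hit rate on high-contrast trials) - z(false-alarm rate on catch
    trials), with 0/1 rates corrected by the 1/(2N) rule."""
    valid = trials[trials["valid"]]
    signal = valid[valid["class"] == "high"]
    noise = valid[valid["class"] == "catch"]
    if len(signal) == 0 or len(noise) == 0:
        raise ValueError("d' undefined: need >= 1 valid high and catch trial")

    def rate(aware: np.ndarray) -> float:
        n = aware.size
        r = aware.mean()
        if r == 0.0:
            r = 1.0 / (2 * n)
        elif r == 1.0:
            r = 1.0 - 1.0 / (2 * n)
        return r

    hit = rate(signal["aware"].to_numpy(dtype=bool))
    fa = rate(noise["aware"].to_numpy(dtype=bool))
    return float(stats.norm.ppf(hit) - stats.norm.ppf(fa))


def wilcoxon_exact(x: np.ndarray, y: np.ndarray | None = None,
                   max_exact_n: int = 25) -> dict:
    """Wilcoxon signed-rank test with an exact enumerated null for small n.

    Zero differences are dropped; ties in absolute differences receive
    midranks.  For n <= ``max_exact_n`` the null distribution of W+ (sum of
    ranks of positive differences) is built by dynamic-programming
    convolution over the 2^n sign patterns; beyond that a normal
    approximation with tie correction is used.  Returns the statistic and
    one-sided (less: x < y) and two-sided p-values.  All-zero differences
    give p = 1 by convention.
    """
    d = np.asarray(x, dtype=float) - (0.0 if y is None else np.asarray(y, dtype=float))
    d = d[d != 0]
    n = d.size
    if n == 0:
        return {"statistic": 0.0, "n": 0, "p_one_sided": 1.0, "p_two_sided": 1.0,
                "method": "degenerate"}
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= max_exact_n:
        # DP over doubled ranks (midranks are multiples of 0.5)
        r2 = np.round(ranks * 2).astype(int)
        total = r2.sum()
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:
            counts[r:] += counts[:-r or None].copy() if r else counts.copy()
        counts /= counts.sum()
        w2 = int(round(w_plus * 2))
        cdf_le = counts[:w2 + 1].sum()
        sf_ge = counts[w2:].sum()
        p_less = cdf_le          # small W+ <-> x systematically below y
        p_two = min(1.0, 2.0 * min(cdf_le, sf_ge))
        method = "exact"
    else:
        tie_term = ((np.unique(ranks, return_counts=True)[1] ** 3
                     - np.unique(ranks, return_counts=True)[1]).sum())
        mu = n * (n + 1) / 4.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0)
        z = (w_plus - mu) / sigma
        p_less = float(stats.norm.cdf(z))
        p_two = float(2 * stats.norm.sf(abs(z)))
        method = "normal"
    return {"statistic": w_plus, "n": n, "p_one_sided": float(p_less),
            "p_two_sided": float(p_two), "method": method}


def compare_latencies(aware_means: np.ndarray, unaware_means: np.ndarray) -> dict:
    """Paired Wilcoxon signed-rank on per-subject mean latencies (aware vs
    unaware).  The one-sided alternative is aware < unaware (faster saccades
    when aware); both sidednesses are reported."""
    aware_means = np.asarray(aware_means, dtype=float)
    unaware_means = np.asarray(unaware_means, dtype=float)
    if aware_means.shape != unaware_means.shape:
        raise ValueError("paired samples must have equal length")
    if aware_means.size < 5:
        raise ValueError("need >= 5 paired subjects")
    res = wilcoxon_exact(aware_means, unaware_means)
    res["mean_difference"] = float(np.mean(aware_means - unaware_means))
    return res


def compare_contrast_distributions(contrasts_na: np.ndarray,
                                   contrasts_nu: np.ndarray) -> dict:
    """Two-sample Kolmogorov-Smirnov test on the contrast distributions of
    NA vs NU trials (a contrast-confound check), plus the mean difference."""
    a = np.asarray(contrasts_na, dtype=float)
    b = np.asarray(contrasts_nu, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ks = stats.ks_2samp(a, b, method="asymp")
    return {"D": float(ks.statistic), "p": float(ks.pvalue),
            "mean_difference": float(a.mean() - b.mean())}
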