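"""Behavioral analysis: psychometric fit, conditions, exclusion, saccades,
signal detection, and the group statistics with their exact oracles."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from awarelfp import behavior as bhv
from awarelfp.config import TaskConfig, ObserverSpec
from awarelfp import synth


def _levels_from_params(a, b, c, d, contrasts, n_per_level, rng):
    p = a + b / (1 + np.exp(-d * (contrasts - c)))
    frac = rng.binomial(n_per_level, p) / n_per_level
    return pd.DataFrame({"contrast": contrasts, "aware_frac": frac,
                         "n": n_per_level})


class TestPsychometricFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        contrasts = np.linspace(6, 14, 8)
        levels = _levels_from_params(0.05, 0.9, 10.0, 1.5, contrasts, 200, rng)
        fit = bhv.fit_psychometric(levels)
        assert fit.converged
        assert abs(fit.c - 10.0) < 0.5
        assert abs(fit.d - 1.5) / 1.5 < 0.30

    def test_midpoint_identity(self):
        rng = np.random.default_rng(1)
        levels = _levels_from_params(0.05, 0.9, 10.0, 1.5,
                                     np.linspace(6, 14, 8), 500, rng)
        fit = bhv.fit_psychometric(levels)
        assert fit(fit.c) == pytest.approx(fit.a + fit.b / 2, abs=1e-9)

    def test_flat_data_has_no_slope_information(self):
        levels = pd.DataFrame({"contrast": [5.0, 8.0, 11.0, 14.0],
                               "aware_frac": [0.5] * 4, "n": [100] * 4})
        fit = bhv.fit_psychometric(levels)
        # flat response: either no range or no slope, and nothing to explain
        assert min(fit.b, fit.d) < 0.05 or fit.r2 < 0.1

    def test_too_few_levels_rejected(self):
        levels = pd.DataFrame({"contrast": [1, 2, 3], "aware_frac": [0, 0.5, 1],
                               "n": [10] * 3})
        with pytest.raises(ValueError):
            bhv.fit_psychometric(levels)

    @pytest.mark.parametrize("delta", [-3.0, 5.0])
    def test_shift_consistency(self, delta):
        """Shifting all contrasts by delta shifts c-hat and preserves b, d."""
        rng = np.random.default_rng(2)
        base = _levels_from_params(0.02, 0.95, 10.0, 1.2,
                                   np.linspace(6, 14, 8), 400, rng)
        fit0 = bhv.fit_psychometric(base)
        shifted = base.copy()
        shifted["contrast"] = shifted["contrast"] + delta
        fit1 = bhv.fit_psychometric(shifted)
        assert fit1.c - fit0.c == pytest.approx(delta, abs=0.3)
        assert fit1.d == pytest.approx(fit0.d, rel=0.05)
        assert fit1.b == pytest.approx(fit0.b, abs=0.02)

    def test_pool_adjacent_levels_to_eight(self):
        levels = pd.DataFrame({"contrast": np.arange(16.0),
                               "aware_frac": np.linspace(0, 1, 16),
                               "n": np.full(16, 10)})
        pooled = bhv.pool_adjacent_levels(levels, 8)
        assert len(pooled) == 8
        assert pooled["n"].sum() == 160


class TestLevelsAndConditions:
    @pytest.mark.parametrize("frac,expected", [
        (0.80, "high"), (0.50, "near"), (0.10, "low"),
        (0.25, "near"), (0.75, "near"),
    ])
    def test_level_classification(self, frac, expected):
        levels = pd.DataFrame({"contrast": [5.0], "aware_frac": [frac],
                               "n": [40]})
        assert bhv.classify_contrast_levels(levels)["level"].iloc[0] == expected

    def test_condition_assignment(self):
        trials = pd.DataFrame({
            "contrast_pct": [10.0, 10.0, 0.0, 20.0, 20.0],
            "aware": [True, False, False, True, False],
            "valid": [True] * 5,
        })
        levels = pd.DataFrame({"contrast": [0.0, 10.0, 20.0],
                               "aware_frac": [0.0, 0.5, 0.9],
                               "n": [10, 10, 10]})
        labeled = bhv.label_conditions(
            trials, bhv.classify_contrast_levels(levels))
        assert labeled["condition"].tolist() == ["NA", "NU", "LU", "HA", "other"]

    def test_conditions_partition_valid_trials(self, strong_subject):
        trials = strong_subject[0]
        valid = trials[trials["valid"]]
        assert (valid["condition"] != "").all()
        counts = valid["condition"].value_counts()
        assert counts.sum() == len(valid)


class TestExclusion:
    def _trials_with_gaze(self, cfg, breaks):
        rng = np.random.default_rng(0)
        t = synth.gaze_times(cfg)
        gaze = np.zeros((len(breaks), t.size, 2))
        for i, br in enumerate(breaks):
            _, gaze[i] = synth.synth_eye_trace(300.0, 1, cfg, rng,
                                               fixation_break=br)
        trials = pd.DataFrame({"latency_ms": [300.0] * len(breaks),
                               "valid": [True] * len(breaks)})
        return trials, gaze, t

    def test_fixation_break_rules(self, task_cfg):
        trials, gaze, t = self._trials_with_gaze(task_cfg, [
            (6.0, -300.0, 60.0),   # 6 deg for 60 ms -> invalid
            (6.0, -300.0, 30.0),   # 30 ms -> under the 40 ms rule
            None,
        ])
        out = bhv.exclude_trials(trials, gaze, t, task_cfg)
        assert out["valid"].tolist() == [False, True, True]
        assert out["reason"].iloc[0] == "fixation_break"
        assert out.attrs["exclusions"] == {"fixation_break": 1}

    def test_late_response_excluded(self, task_cfg):
        trials, gaze, t = self._trials_with_gaze(task_cfg, [None])
        trials.loc[0, "latency_ms"] = 2500.0
        out = bhv.exclude_trials(trials, gaze, t, task_cfg)
        assert not out["valid"].iloc[0]
        assert out["reason"].iloc[0] == "late_response"


class TestSaccadeDetection:
    def test_round_trip_recovery(self, task_cfg):
        rng = np.random.default_rng(3)
        for lat in (150.0, 300.0, 650.0):
            t, xy = synth.synth_eye_trace(lat, 1, task_cfg, rng)
            det = bhv.detect_saccade_latency(xy, t, task_cfg.stim_to_cue,
                                             task_cfg)
            assert det == pytest.approx(lat, abs=5.0)

    def test_brief_velocity_transient_ignored(self, task_cfg):
        """A 1.2 deg instantaneous jump (1200 deg/s for one sample) crosses
        the 30 deg/s threshold only briefly after smoothing and fails the
        >20 ms persistence rule; a real 10 deg saccade is detected."""
        t = synth.gaze_times(task_cfg)
        xy = np.zeros((t.size, 2))
        i0 = np.argmin(np.abs(t - 900.0))
        xy[i0:, 0] = 1.2
        det = bhv.detect_saccade_latency(xy, t, task_cfg.stim_to_cue, task_cfg)
        assert det is None

    def test_stationary_gaze(self, task_cfg):
        t = synth.gaze_times(task_cfg)
        xy = np.zeros((t.size, 2))
        assert bhv.detect_saccade_latency(xy, t, task_cfg.stim_to_cue,
                                          task_cfg) is None


class TestDPrime:
    @staticmethod
    def _trials(n_hi, hit, n_ca, fa):
        hi_aware = [True] * int(round(n_hi * hit)) + \
                   [False] * (n_hi - int(round(n_hi * hit)))
        ca_aware = [True] * int(round(n_ca * fa)) + \
                   [False] * (n_ca - int(round(n_ca * fa)))
        return pd.DataFrame({
            "class": ["high"] * n_hi + ["catch"] * n_ca,
            "aware": hi_aware + ca_aware,
            "valid": [True] * (n_hi + n_ca),
        })

    def test_known_rates(self):
        # 2 * Phi^{-1}(0.95) = 3.2897
        d = bhv.compute_dprime(self._trials(100, 0.95, 100, 0.05))
        assert d == pytest.approx(2 * stats.norm.ppf(0.95), abs=1e-9)

    def test_equal_rates_give_zero(self):
        assert bhv.compute_dprime(self._trials(50, 0.4, 50, 0.4)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_extreme_rate_correction(self):
        # hit rate 1.0 with N=20 is corrected to 1 - 1/40 = 0.975
        d = bhv.compute_dprime(self._trials(20, 1.0, 20, 0.25))
        expected = stats.norm.ppf(0.975) - stats.norm.ppf(0.25)
        assert d == pytest.approx(expected, abs=1e-12)

    def test_missing_class_undefined(self):
        trials = pd.DataFrame({"class": ["high"] * 5, "aware": [True] * 5,
                               "valid": [True] * 5})
        with pytest.raises(ValueError, match="undefined"):
            bhv.compute_dprime(trials)


def _wilcoxon_brute_force(diffs):
    """Exact one-sided (less) and two-sided p by enumerating all sign
    patterns of the observed |differences| with midranks."""
    d = diffs[diffs != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    p_le = (ws <= w_obs + 1e-9).mean()
    p_ge = (ws >= w_obs - 1e-9).mean()
    return p_le, min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_all_negative_n10(self):
        """All 10 subjects faster when aware: one-sided exact p = 2^-10."""
        aware = np.arange(10, dtype=float)
        unaware = aware + 5.0
        res = bhv.compare_latencies(aware, unaware)
        assert res["p_one_sided"] == pytest.approx(9.765625e-4, rel=1e-9)
        assert res["method"] == "exact"

    def test_identical_pairs(self):
        x = np.arange(6, dtype=float)
        res = bhv.compare_latencies(x, x)
        assert res["p_one_sided"] == 1.0 and res["p_two_sided"] == 1.0

    @pytest.mark.parametrize("n", [5, 6, 8, 10, 12])
    def test_matches_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            d = np.round(rng.normal(0.3, 1.0, n), 1)
            res = bhv.wilcoxon_exact(d)
            p_le, p_two = _wilcoxon_brute_force(d[d != 0])
            assert res["p_one_sided"] == pytest.approx(p_le, abs=1e-12)
            assert res["p_two_sided"] == pytest.approx(p_two, abs=1e-12)

    def test_matches_scipy_without_ties(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 12)
        ref = stats.wilcoxon(x, alternative="two-sided", mode="exact")
        res = bhv.wilcoxon_exact(x)
        assert res["p_two_sided"] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_needs_five_subjects(self):
        with pytest.raises(ValueError):
            bhv.compare_latencies(np.ones(3), np.zeros(3))


class TestContrastDistributions:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        res = bhv.compare_contrast_distributions(x, x)
        assert res["D"] == 0.0 and res["p"] == pytest.approx(1.0)

    def test_disjoint_supports(self):
        res = bhv.compare_contrast_distributions(np.arange(5.0),
                                                 np.arange(10.0, 15.0))
        assert res["D"] == 1.0

    def test_matches_ecdf_scan_oracle(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(0.4, 1, 10)
        grid = np.sort(np.concatenate([a, b]))
        d_oracle = max(abs((a <= g).mean() - (b <= g).mean()) for g in grid)
        res = bhv.compare_contrast_distributions(a, b)
        assert res["D"] == pytest.approx(d_oracle, abs=1e-12)
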