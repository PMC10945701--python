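"""Configuration dataclasses for task timing, the simulated observer and decoding.

All times are in milliseconds relative to stimulus (grating) onset unless a
field name says otherwise; windows are closed on both ends.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Sequence


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class TaskConfig:
    """Timing and geometry of one behavioral session.

    The task: the subject fixates, a low-contrast Gabor grating flashes for
    ``stim_dur`` ms at ``stim_ecc`` degrees eccentricity, and ``stim_to_cue``
    ms after grating onset the fixation point changes color, cueing a saccade
    to one of two targets at ``target_ecc`` degrees.  Near-threshold trials
    are interleaved with clearly visible (high-contrast) and stimulus-absent
    (catch) trials.
    """

    fixation_dur: float = 600.0      # ms of required fixation before stimulus
    stim_dur: float = 50.0           # grating presentation, ms
    stim_to_cue: float = 650.0       # grating onset -> fixation color change (T_target)
    session_trials: int = 180
    prop_near: float = 0.70
    prop_high: float = 0.10
    prop_catch: float = 0.20
    staircase_step: float = 0.39     # contrast step, % (0.39 or 0.78)
    check_window: float = 4.0        # fixation window half-width, degrees
    stim_ecc: float = 7.0            # degrees
    target_ecc: float = 10.0         # degrees
    max_response: float = 2000.0     # ms after cue
    iti: float = 800.0               # ms
    fs: float = 1000.0               # Hz

    def __post_init__(self) -> None:
        _check(abs(self.prop_near + self.prop_high + self.prop_catch - 1.0) < 1e-9,
               "trial-class proportions must sum to 1")
        for name in ("fixation_dur", "stim_dur", "stim_to_cue", "max_response",
                     "iti", "fs"):
            _check(getattr(self, name) > 0, f"{name} must be positive")
        _check(self.session_trials > 0, "session_trials must be positive")
        _check(self.staircase_step >= 0, "staircase_step must be non-negative")

    @property
    def class_counts(self) -> dict[str, int]:
        """Exact per-class trial counts; rejects non-integral partitions."""
        counts = {}
        for name, prop in (("near", self.prop_near), ("high", self.prop_high),
                           ("catch", self.prop_catch)):
            n = prop * self.session_trials
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"session_trials * prop_{name} = {n} is not an integer; "
                    "adjust session_trials or the proportions")
            counts[name] = int(round(n))
        return counts


@dataclass
class ObserverSpec:
    """Parameters of the simulated psychometric observer and its neural effects.

    The probability of an "aware" report at stimulus contrast SC (%) is the
    four-parameter logistic ``a + b / (1 + exp(-d * (SC - c)))`` with guess
    floor ``a``, range ``b``, threshold ``c`` (% contrast) and slope ``d``.

    Neural-effect parameters program where and when awareness-dependent
    components appear in the simulated LFP: an extra evoked deflection of
    ``erp_gain`` uV from ``erp_dot`` ms, a 60-150 Hz burst with in-band power
    factor ``hg_gain`` from ``hg_dot`` ms, and a 4 Hz oscillation with a
    trial-consistent inter-channel phase lag ``plv_lag`` (rad) from
    ``plv_onset`` ms, all on ``aware_channels`` in aware trials only.
    """

    psy_a: float = 0.02
    psy_b: float = 0.96
    psy_c: float = 10.0     # threshold contrast, %
    psy_d: float = 1.5      # slope, per % contrast
    lat_aware_mu: float = 230.0    # mean saccade latency, aware trials, ms
    lat_unaware_mu: float = 280.0  # mean saccade latency, unaware trials, ms
    lat_sd: float = 40.0
    erp_dot: float = 250.0   # true ERP divergence onset, ms
    hg_dot: float = 230.0    # true high-gamma divergence onset, ms
    plv_onset: float = 250.0  # true phase-coupling onset, ms
    erp_gain: float = 50.0   # uV, amplitude of the awareness-dependent deflection
    hg_gain: float = 5.0     # burst amplitude as multiple of in-band noise RMS
    plv_lag: float = 0.7     # rad
    plv_amp: float = 10.0    # uV, amplitude of the coupled 4 Hz oscillation
    aware_channels: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        _check(0.0 <= self.psy_a <= 1.0, "psy_a must lie in [0, 1]")
        _check(self.psy_b >= 0.0 and self.psy_a + self.psy_b <= 1.0 + 1e-12,
               "psy_a + psy_b must lie in [0, 1]")
        _check(self.psy_d > 0, "psy_d must be positive")
        _check(self.lat_unaware_mu >= self.lat_aware_mu,
               "unaware latencies must not be faster than aware ones")
        for name in ("erp_dot", "hg_dot", "plv_onset"):
            v = getattr(self, name)
            _check(0 < v <= 650.0, f"{name} must lie in (0, 650] ms")
        self.aware_channels = tuple(self.aware_channels)

    def p_aware(self, contrast):
        """Probability of an aware report at contrast SC (%)."""
        import numpy as np
        sc = np.asarray(contrast, dtype=float)
        p = self.psy_a + self.psy_b / (1.0 + np.exp(-self.psy_d * (sc - self.psy_c)))
        return p if p.ndim else float(p)


@dataclass
class DecodingConfig:
    """Cross-validation layout for awareness-state decoding.

    Trials are class-balanced by undersampling, assigned to ``n_folds`` folds,
    sub-averaged in disjoint groups of ``subaverage_k`` within each fold, and
    scored leave-one-fold-out; the fold assignment is redrawn
    ``n_assignment_repeats`` times, so the score at each time point averages
    ``n_folds * n_assignment_repeats`` fold tests.
    """

    n_folds: int = 10
    subaverage_k: int = 4
    n_assignment_repeats: int = 5
    zscore: bool = True        # per-channel z-scoring using training statistics
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_folds >= 2, "need at least 2 folds")
        _check(self.subaverage_k >= 1, "subaverage_k must be >= 1")
        _check(self.n_assignment_repeats >= 1, "need >= 1 assignment repeat")

    @property
    def n_iterations(self) -> int:
        return self.n_folds * self.n_assignment_repeats


def config_from_dict(cls, d: dict):
    """Build a config dataclass from a mapping, rejecting unknown keys."""
    valid = {f.name for f in fields(cls)}
    unknown = set(d) - valid
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


def config_to_dict(cfg) -> dict:
    return asdict(cfg)
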