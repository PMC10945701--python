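"""In-memory containers shared across the pipeline.

Trial tables and electrode tables are plain :class:`pandas.DataFrame` objects
with documented column sets; epoched LFP lives in :class:`EpochArray`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: required columns of a trial table (one row per trial, in presentation order)
TRIAL_COLUMNS = ["trial", "class", "contrast_pct", "aware", "cue_color",
                 "correct_dir", "latency_ms", "valid"]

#: required columns of an electrode table (BIDS-iEEG electrodes.tsv style)
ELECTRODE_COLUMNS = ["name", "x", "y", "z", "shaft", "segment", "index",
                     "region", "hemisphere"]

EPOCH_TMIN = -490.0  #: epoch start, ms relative to grating onset
EPOCH_TMAX = 1299.0  #: epoch end, ms (inclusive)


@dataclass
class EpochArray:
    """Epoched multichannel LFP: ``data[channel, time, trial]`` in microvolts.

    The time axis is in milliseconds relative to stimulus onset and runs from
    -490 to 1299 ms inclusive at the sampling rate ``fs`` (1790 samples at
    1 kHz).  The trial axis is aligned row-for-row with the session's trial
    table.
    """

    data: np.ndarray                # (n_channels, n_times, n_trials), uV
    times: np.ndarray               # (n_times,), ms
    channels: list[str]
    fs: float = 1000.0
    reference: str = "monopolar"    # reference scheme tag

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        self.channels = list(self.channels)
        if self.data.ndim != 3:
            raise ValueError("EpochArray.data must be (channels, time, trials)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel axis does not match channel names")
        if self.data.shape[1] != self.times.size:
            raise ValueError("time axis does not match the time vector")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def time_index(self, t_ms: float) -> int:
        """Index of the sample at time ``t_ms`` (must be on the grid)."""
        idx = int(round((t_ms - self.times[0]) * self.fs / 1000.0))
        if not (0 <= idx < self.times.size) or abs(self.times[idx] - t_ms) > 1e-6:
            raise ValueError(f"time {t_ms} ms is not on the epoch time grid")
        return idx

    def window(self, tmin: float, tmax: float) -> slice:
        """Slice covering the closed window [tmin, tmax] ms."""
        return slice(self.time_index(tmin), self.time_index(tmax) + 1)

    def select_trials(self, idx) -> "EpochArray":
        return EpochArray(self.data[:, :, idx], self.times, self.channels,
                          self.fs, self.reference)

    def copy(self) -> "EpochArray":
        return EpochArray(self.data.copy(), self.times.copy(),
                          list(self.channels), self.fs, self.reference)


def default_times(fs: float = 1000.0) -> np.ndarray:
    """Standard epoch time axis [-490, 1299] ms at ``fs``."""
    n = int(round((EPOCH_TMAX - EPOCH_TMIN) * fs / 1000.0)) + 1
    return EPOCH_TMIN + np.arange(n) * 1000.0 / fs


def validate_trial_table(trials: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing required columns: {missing}")


def validate_electrode_table(montage: pd.DataFrame) -> None:
    missing = [c for c in ELECTRODE_COLUMNS if c not in montage.columns]
    if missing:
        raise ValueError(f"electrode table is missing required columns: {missing}")
    if montage["name"].duplicated().any():
        dup = montage.loc[montage["name"].duplicated(), "name"].tolist()
        raise ValueError(f"electrode names must be unique; duplicates: {dup}")


@dataclass
class SessionData:
    """One complete (synthetic or loaded) session."""

    trials: pd.DataFrame
    gaze: np.ndarray            # (n_trials, n_times_gaze, 2), degrees
    gaze_times: np.ndarray      # ms relative to stimulus onset
    epochs: EpochArray
    montage: pd.DataFrame
    config: object = None       # TaskConfig
    observer: object = None     # ObserverSpec

    def __post_init__(self) -> None:
        validate_trial_table(self.trials)
        validate_electrode_table(self.montage)
        if len(self.trials) != self.epochs.n_trials:
            raise ValueError("trial table and epoch trial axis are misaligned")
        if self.gaze.shape[0] != len(self.trials):
            raise ValueError("gaze trial axis and trial table are misaligned")
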