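"""Shared fixtures: small synthetic subjects generated at test time."""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from awarelfp import synth
from awarelfp.behavior import label_conditions
from awarelfp.config import TaskConfig, ObserverSpec


@pytest.fixture(scope="session")
def task_cfg() -> TaskConfig:
    return TaskConfig()


def make_subject(n_sessions: int = 1, seed: int = 0, n_shafts: int = 3,
                 contacts_per_shaft: int = 8, aware_every: int = 8,
                 **obs_kwargs):
    """Build a multi-session synthetic subject without gaze traces.

    Returns ``(trials, data, times, conditions, montage, observer)`` with
    ``data`` of shape (channels, times, trials) concatenated across sessions
    and condition labels already assigned.
    """
    cfg = TaskConfig()
    montage = synth.synth_montage(n_shafts, contacts_per_shaft,
                                  rng=np.random.default_rng(1000 + seed))
    names = montage["name"].tolist()
    aware = tuple(names[1::aware_every])
    obs = ObserverSpec(aware_channels=aware, **obs_kwargs)
    all_tr, all_ep = [], []
    for s in range(n_sessions):
        rng = synth.session_rng(seed, s)
        tr = synth.simulate_trials(cfg, obs, rng)
        ep = synth.synth_epochs(tr, obs, montage, cfg, rng)
        all_tr.append(tr)
        all_ep.append(ep.data)
    trials = pd.concat(all_tr, ignore_index=True)
    trials["trial"] = np.arange(len(trials))
    trials = label_conditions(trials)
    data = np.concatenate(all_ep, axis=2)
    return trials, data, ep.times, trials["condition"].to_numpy(), montage, obs


@pytest.fixture(scope="session")
def strong_subject():
    """One session with strong programmed ERP/HG/PLV effects."""
    return make_subject(n_sessions=1, seed=3, erp_gain=50.0, hg_gain=5.0)


@pytest.fixture(scope="session")
def null_subject():
    """One session with every awareness effect switched off."""
    return make_subject(n_sessions=1, seed=4, erp_gain=0.0, hg_gain=0.0,
                        plv_amp=0.0)
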