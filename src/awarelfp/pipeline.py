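"""End-to-end pipeline driver: simulate -> preprocess -> behavior -> ERP
divergence -> HG divergence -> decoding -> PLV, with per-stage outputs and a
line-delimited JSON provenance log.

Each stage reads only the files a previous stage wrote into the session
directory, so any stage can be re-run in isolation.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, connectivity, decoding, divergence, io, preprocess, spectral, synth
from .config import TaskConfig, ObserverSpec, DecodingConfig, config_from_dict, config_to_dict
from .containers import EpochArray

__all__ = ["PipelineConfig", "run_pipeline", "stage_simulate",
           "stage_preprocess", "stage_behavior", "stage_erp", "stage_hg",
           "stage_decode", "stage_plv"]


@dataclass
class PipelineConfig:
    """All pipeline parameters; unknown YAML keys are rejected."""

    seed: int = 0
    n_sessions: int = 5
    n_shafts: int = 6
    contacts_per_shaft: int = 8
    n_aware_channels: int = 5
    q: float = 0.01
    decode_step_ms: float = 10.0
    decode_window: tuple = (-100.0, 650.0)
    task: TaskConfig = field(default_factory=TaskConfig)
    observer: ObserverSpec = field(default_factory=ObserverSpec)
    decoding: DecodingConfig = field(default_factory=DecodingConfig)

    def __post_init__(self) -> None:
        if not (0 < self.q < 1):
            raise ValueError("FDR level q must lie in (0, 1)")
        if self.n_sessions < 1:
            raise ValueError("need >= 1 session")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        task = config_from_dict(TaskConfig, d.pop("task", None) or {})
        obs = config_from_dict(ObserverSpec, d.pop("observer", None) or {})
        dec = config_from_dict(DecodingConfig, d.pop("decoding", None) or {})
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        return cls(task=task, observer=obs, decoding=dec, **d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _hash(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


class _Log:
    def __init__(self, path: Path):
        self.path = path

    def write(self, stage: str, **fields) -> None:
        rec = {"stage": stage, "time": time.time(), **fields}
        with open(self.path, "a") as f:
            f.write(json.dumps(rec, default=str) + "\n")


def _config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    """Generate ``n_sessions`` sessions for one synthetic subject (shared
    montage and observer; independent RNG stream per session)."""
    out.mkdir(parents=True, exist_ok=True)
    rng = synth.session_rng(cfg.seed, 10_000)  # montage stream
    montage = synth.synth_montage(cfg.n_shafts, cfg.contacts_per_shaft, rng=rng)
    names = montage["name"].tolist()
    obs = cfg.observer
    if not obs.aware_channels:
        step = max(len(names) // cfg.n_aware_channels, 1)
        picks = tuple(names[(i * step + 1) % len(names)]
                      for i in range(cfg.n_aware_channels))
        obs = dataclasses.replace(obs, aware_channels=tuple(dict.fromkeys(picks)))
    all_trials, all_gaze, all_epochs = [], [], []
    for s in range(cfg.n_sessions):
        ses = synth.simulate_session(cfg.task, obs, montage=montage,
                                     seed=cfg.seed, session_index=s)
        t = ses.trials.copy()
        t["session"] = s
        all_trials.append(t)
        all_gaze.append(ses.gaze)
        all_epochs.append(ses.epochs.data)
        gaze_times = ses.gaze_times
        epoch_times = ses.epochs.times
    trials = pd.concat(all_trials, ignore_index=True)
    trials["trial"] = np.arange(len(trials))
    epochs = EpochArray(np.concatenate(all_epochs, axis=2), epoch_times,
                        names, cfg.task.fs)
    io.write_trial_table(trials, out / "trials.csv")
    io.write_gaze(np.concatenate(all_gaze, axis=0), gaze_times, out / "gaze.h5")
    io.write_epochs(epochs, out / "epochs.h5")
    io.write_electrode_table(montage, out / "electrodes.tsv")
    io.write_json({"aware_channels": list(obs.aware_channels),
                   "observer": config_to_dict(obs)}, out / "ground_truth.json")


def stage_preprocess(out: Path) -> None:
    """Filter, screen and bipolar-rereference the simulated epochs."""
    epochs = io.read_epochs(out / "epochs.h5")
    montage = io.read_electrode_table(out / "electrodes.tsv")
    filtered = preprocess.filter_lfp(epochs)
    del epochs
    report = preprocess.screen_channels(filtered)
    kept = report.loc[report["keep"], "channel"].tolist()
    keep_idx = [filtered.channels.index(c) for c in kept]
    screened = EpochArray(filtered.data[keep_idx], filtered.times, kept,
                          filtered.fs, filtered.reference)
    del filtered
    bipolar, pair_montage = preprocess.bipolar_rereference(screened, montage)
    del screened
    io.write_epochs(bipolar, out / "epochs_bipolar.h5")
    io.write_electrode_table(pair_montage, out / "electrodes_bipolar.tsv")
    io.write_json(report.to_dict(orient="list"), out / "screening.json")


def stage_behavior(out: Path) -> dict:
    """Latency detection, exclusion, condition labeling, psychometric fit,
    d' and the NA/NU contrast check; annotates trials.csv in place."""
    trials = io.read_trial_table(out / "trials.csv")
    gaze, gtimes = io.read_gaze(out / "gaze.h5")
    cfg = TaskConfig()
    detected = np.array([
        np.nan if (lat := behavior.detect_saccade_latency(
            gaze[i], gtimes, cfg.stim_to_cue, cfg)) is None else lat
        for i in range(len(trials))])
    trials["latency_ms"] = detected
    trials = behavior.exclude_trials(trials, gaze, gtimes, cfg)
    trials = behavior.label_conditions(trials)
    valid = trials[trials["valid"]]
    levels = behavior.level_table(valid)
    fit = behavior.fit_psychometric(behavior.pool_adjacent_levels(levels)
                                    if len(levels) > 8 else levels)
    dprime = behavior.compute_dprime(trials)
    ks = behavior.compare_contrast_distributions(
        valid.loc[valid["condition"] == "NA", "contrast_pct"].to_numpy(),
        valid.loc[valid["condition"] == "NU", "contrast_pct"].to_numpy())
    lat = {
        "aware_mean": float(valid.loc[valid["aware"], "latency_ms"].mean()),
        "unaware_mean": float(valid.loc[~valid["aware"].astype(bool),
                                        "latency_ms"].mean()),
    }
    report = {
        "n_trials": len(trials), "n_valid": int(trials["valid"].sum()),
        "exclusions": trials.attrs.get("exclusions", {}),
        "condition_counts": valid["condition"].value_counts().to_dict(),
        "psychometric": {"a": fit.a, "b": fit.b, "c": fit.c, "d": fit.d,
                         "r2": fit.r2, "converged": fit.converged},
        "dprime": dprime, "latency": lat, "contrast_ks": ks,
    }
    io.write_trial_table(trials, out / "trials.csv")
    io.write_json(report, out / "behavior.json")
    return report


def _load_analysis_inputs(out: Path):
    epochs = io.read_epochs(out / "epochs_bipolar.h5")
    trials = io.read_trial_table(out / "trials.csv")
    cond = trials["condition"].fillna("").astype(str).to_numpy()
    return epochs, trials, cond


def _divergence_to_json(res: divergence.DivergenceResult, path: Path) -> None:
    tab = res.table.copy()
    tab["runs"] = tab["channel"].map(res.runs)
    io.write_json({
        "q": res.q,
        "n_aware_related": int(res.table["aware_related"].sum()),
        "table": tab.to_dict(orient="records"),
    }, path)


def stage_erp(out: Path, q: float = 0.01) -> divergence.DivergenceResult:
    """Broadband-amplitude NA/NU divergence on the bipolar epochs."""
    epochs, trials, cond = _load_analysis_inputs(out)
    res = divergence.divergence_analysis(epochs.data, epochs.times, cond,
                                         channels=epochs.channels, q=q,
                                         fs=epochs.fs)
    _divergence_to_json(res, out / "erp_divergence.json")
    return res


def stage_hg(out: Path, q: float = 0.01) -> divergence.DivergenceResult:
    """High-gamma-magnitude NA/NU divergence on the bipolar epochs."""
    epochs, trials, cond = _load_analysis_inputs(out)
    res = spectral.hg_divergence(epochs.data, epochs.times, epochs.fs, cond,
                                 channels=epochs.channels, q=q)
    _divergence_to_json(res, out / "hg_divergence.json")
    return res


def stage_decode(out: Path, cfg: PipelineConfig) -> dict:
    """NA-vs-NU decoding time course plus HA/LU cross-condition transfer."""
    epochs, trials, cond = _load_analysis_inputs(out)
    sel = np.isin(cond, ["NA", "NU"])
    X = epochs.data.transpose(2, 0, 1)[sel]
    y = trials.loc[sel, "aware"].to_numpy(dtype=bool)
    step = int(round(cfg.decode_step_ms * epochs.fs / 1000.0))
    w0 = epochs.time_index(cfg.decode_window[0])
    w1 = epochs.time_index(cfg.decode_window[1])
    ti = np.arange(w0, w1 + 1, step)
    dcfg = dataclasses.replace(cfg.decoding, seed=cfg.seed)
    res = decoding.decode_timecourse(X, y, dcfg, epochs.times, time_indices=ti)
    selx = np.isin(cond, ["HA", "LU"])
    Xx = epochs.data.transpose(2, 0, 1)[selx]
    yx = trials.loc[selx, "aware"].to_numpy(dtype=bool)
    cross = decoding.cross_condition_generalization(X, y, Xx, yx, dcfg,
                                                    epochs.times,
                                                    time_indices=ti)
    payload = {
        "times_ms": res.times, "accuracy": res.accuracy,
        "n_iterations": res.n_iterations,
        "cross_condition_diag": cross.accuracy,
        "cross_condition_matrix": cross.matrix,
    }
    io.write_json(payload, out / "decoding.json")
    return payload


def stage_plv(out: Path) -> dict:
    """Condition-wise baseline-corrected PLV, region averages and the
    site-to-rest summary at early HG-divergence sites."""
    epochs, trials, cond = _load_analysis_inputs(out)
    montage = io.read_electrode_table(out / "electrodes_bipolar.tsv")
    phases = connectivity.bandpass_hilbert_phase(epochs.data, epochs.fs)
    result = {}
    for c in ("NA", "NU"):
        idx = np.where(cond == c)[0]
        res = connectivity.plv_time_across(phases[:, :, :, idx], epochs.times,
                                           epochs.channels)
        res = connectivity.baseline_subtract_plv(res)
        region_mat, regions = connectivity.region_average_plv(res, montage)
        result[c] = {"plv": res, "region_matrix": region_mat,
                     "regions": regions}
    # site-to-rest at early HG sites, if the HG stage ran
    hg_path = out / "hg_divergence.json"
    site_summary = None
    if hg_path.exists():
        tab = pd.DataFrame(io.read_json(hg_path)["table"])
        early = tab.loc[tab["aware_related"] & (tab["dot"] < 350.0), "channel"]
        sites = [c for c in early if c in epochs.channels]
        if sites:
            site_summary = {
                c: connectivity.site_to_rest_plv(result[c]["plv"], sites)
                for c in ("NA", "NU")}
    t_sel = (epochs.times >= connectivity.VALID_WINDOW[0]) & \
            (epochs.times <= connectivity.VALID_WINDOW[1])
    io.write_json({
        c: {"regions": result[c]["regions"],
            "region_matrix_mean_0_650": result[c]["region_matrix"][
                :, :, (epochs.times >= 0) & (epochs.times <= 650)].mean(axis=2)}
        for c in ("NA", "NU")}, out / "plv.json")
    summary = {c: {"mean_plv_post": float(
        result[c]["plv"].plv[:, (epochs.times >= 300) & (epochs.times <= 650)]
        .mean())} for c in ("NA", "NU")}
    if site_summary is not None:
        summary["early_hg_sites"] = {
            c: site_summary[c].mean(axis=1).to_numpy() for c in ("NA", "NU")}
    return summary


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Execute every stage in order, logging provenance; a stage failure
    halts with the stage name while earlier outputs remain on disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "provenance.jsonl")
    chash = _config_hash(cfg)
    io.write_json({"config": cfg.to_dict(), "config_hash": chash},
                  out / "config.json")
    results = {}
    stages = [
        ("simulate", lambda: stage_simulate(cfg, out)),
        ("preprocess", lambda: stage_preprocess(out)),
        ("behavior", lambda: stage_behavior(out)),
        ("erp", lambda: stage_erp(out, cfg.q)),
        ("hg", lambda: stage_hg(out, cfg.q)),
        ("decode", lambda: stage_decode(out, cfg)),
        ("plv", lambda: stage_plv(out)),
    ]
    for name, fn in stages:
        t0 = time.time()
        try:
            results[name] = fn()
        except Exception as err:
            log.write(name, status="failed", error=repr(err),
                      config_hash=chash)
            raise RuntimeError(f"pipeline stage '{name}' failed: {err}") from err
        log.write(name, status="ok", seconds=round(time.time() - t0, 2),
                  config_hash=chash, seed=cfg.seed)
    return results
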