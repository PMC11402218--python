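"""Reproducible end-to-end pipeline: simulate → preprocess → metrics →
encode → decode, with per-stage artifacts and manifests.

The pipeline defaults are desk-scale (a 32×32 grid, 80 trials, reduced
shift/bootstrap counts) so a full run finishes quickly on one CPU; every
knob is exposed in the YAML config.  The heavier publication-grade
settings (n_shifts = 500, n_boot = 1000) remain the library-level
defaults of the underlying functions.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decoding, encoding, metrics, preprocess, synth
from .core import DEFAULT_EPOCHS, ImagingStack
from .io import read_session, truth_summary, write_manifest, write_session


def _strict(cls, d: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**d)


@dataclass
class PreprocessBlock:
    baseline_duration: float = 0.3
    sigma_pixels: float = 2.0
    filter_window: int = 50
    filter_threshold: float = 0.55


@dataclass
class EncodingBlock:
    alpha_grid: list = field(default_factory=lambda: [0.0, 50.0, 0.5])  # start, stop, step
    n_folds: int = 3
    n_shifts: int = 50
    kernel_len: int | None = None
    groups_of_interest: tuple = ("stimulus_side", "lick_contra", "lick_ipsi")
    seed: int = 0

    def grid(self) -> np.ndarray:
        start, stop, step = self.alpha_grid
        return np.round(np.arange(start, stop + 1e-9, step), 6)


@dataclass
class DecodingBlock:
    n_folds: int = 5
    n_boot: int = 20
    downsample: int = 2
    seed: int = 0


@dataclass
class PipelineConfig:
    sim: synth.SimConfig = field(default_factory=synth.SimConfig)
    preprocess: PreprocessBlock = field(default_factory=PreprocessBlock)
    encoding: EncodingBlock = field(default_factory=EncodingBlock)
    decoding: DecodingBlock = field(default_factory=DecodingBlock)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        blocks = {}
        for name, sub in (("sim", synth.SimConfig),
                          ("preprocess", PreprocessBlock),
                          ("encoding", EncodingBlock),
                          ("decoding", DecodingBlock)):
            block = d.pop(name, {})
            if name == "sim" and "trial_window" in block:
                block["trial_window"] = tuple(block["trial_window"])
            if name == "sim" and "opto_epochs" in block:
                block["opto_epochs"] = tuple(block["opto_epochs"])
            if name == "encoding" and "groups_of_interest" in block:
                block["groups_of_interest"] = tuple(block["groups_of_interest"])
            blocks[name] = _strict(sub, block)
        if d:
            raise ValueError(f"unknown top-level config keys: {sorted(d)}")
        return cls(**blocks)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text) or {})

    def to_dict(self) -> dict:
        return {
            "sim": self.sim.to_dict(),
            "preprocess": dataclasses.asdict(self.preprocess),
            "encoding": dataclasses.asdict(self.encoding),
            "decoding": dataclasses.asdict(self.decoding),
        }


#: desk-scale default used by ``run-all``
SMALL_CONFIG = {
    "sim": {"n_pixels_y": 32, "n_pixels_x": 32, "n_trials": 80,
            "opto_regime": "global_excite"},
    "encoding": {"alpha_grid": [0.0, 50.0, 2.0], "n_shifts": 30,
                 "groups_of_interest": ["stimulus_side"]},
    "decoding": {"n_boot": 10, "n_folds": 3},
}


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> Path:
    t0 = time.time()
    session = synth.generate_session(cfg.sim)
    path = write_session(
        outdir / "session", session.stack, session.trials, session.licks,
        session.continuous, rois=session.rois,
        truth_summary=truth_summary(session.truth, cfg.sim))
    write_manifest(outdir / "manifest_simulate.json", "simulate", [],
                   sorted(path.glob("*")), {"seed": cfg.sim.seed}, t_start=t0)
    return path


def stage_preprocess(cfg: PipelineConfig, outdir: Path) -> dict:
    t0 = time.time()
    stack, trials, licks, continuous, rois = read_session(outdir / "session")
    dff = preprocess.compute_dff(stack, trials, cfg.preprocess.baseline_duration)
    dff = preprocess.spatial_smooth(dff, cfg.preprocess.sigma_pixels)
    traces, names = preprocess.aggregate_rois(dff, rois)
    include = preprocess.filter_trials_by_performance(
        trials, cfg.preprocess.filter_window, cfg.preprocess.filter_threshold)
    trials = trials.assign(included=include)
    out = write_session(outdir / "dff", dff, trials, licks, continuous, rois=rois)
    np.save(outdir / "roi_traces.npy", traces)
    (outdir / "roi_names.json").write_text(json.dumps(names))
    write_manifest(
        outdir / "manifest_preprocess.json", "preprocess",
        sorted((outdir / "session").glob("*")),
        sorted(out.glob("*")) + [outdir / "roi_traces.npy"],
        {}, t_start=t0)
    return {"dff": dff, "trials": trials, "licks": licks,
            "continuous": continuous, "rois": rois,
            "roi_traces": traces, "roi_names": names}


def stage_metrics(state: dict, outdir: Path) -> pd.DataFrame:
    t0 = time.time()
    trials, licks = state["trials"], state["licks"]
    dff: ImagingStack = state["dff"]
    rows = {
        "accuracy_pct": metrics.accuracy(trials),
        "omission_pct": metrics.omission_rate(trials),
        "switch_index": metrics.switch_index(licks),
        "n_trials": len(trials),
        "n_included": int(trials["included"].sum()),
    }
    contra = np.flatnonzero((trials["stimulus_side"] == "contra").to_numpy())
    ipsi = np.flatnonzero((trials["stimulus_side"] == "ipsi").to_numpy())
    if len(contra) >= 2 and len(ipsi) >= 2:
        dmap = metrics.d_prime_map(dff, None, contra, ipsi, (1.2, 1.9))
        np.save(outdir / "dprime_stimulus_late_delay.npy", dmap)
        rows["dprime_late_delay_max_abs"] = float(np.nanmax(np.abs(dmap)))
    opto_on = np.flatnonzero((trials["opto"] != "off").to_numpy())
    opto_off = np.flatnonzero((trials["opto"] == "off").to_numpy())
    if len(opto_on) >= 2:
        dmap = metrics.d_prime_map(dff, None, opto_on, opto_off, (1.2, 1.9))
        np.save(outdir / "dprime_opto_late_delay.npy", dmap)
        rows["dprime_opto_late_delay_max_abs"] = float(np.nanmax(np.abs(dmap)))
    table = pd.DataFrame([rows])
    table.to_csv(outdir / "metrics.csv", index=False)
    write_manifest(outdir / "manifest_metrics.json", "metrics",
                   [outdir / "dff" / "trials.csv"], [outdir / "metrics.csv"],
                   {}, t_start=t0)
    return table


def stage_encode(cfg: PipelineConfig, state: dict, outdir: Path) -> dict:
    """Pixel-wise CV R²; ΔR² and significance on the ROI traces."""
    t0 = time.time()
    dff: ImagingStack = state["dff"]
    trials, licks = state["trials"], state["licks"]
    dm = encoding.build_design_matrix(
        trials, licks, state["continuous"], dff.frame_times,
        kernel_len=cfg.encoding.kernel_len,
        baseline_duration=cfg.preprocess.baseline_duration)
    grid = cfg.encoding.grid()
    Y, flat_idx = encoding.flatten_stack(dff)
    fit = encoding.crossval_r2(dm, Y, n_folds=cfg.encoding.n_folds,
                               seed=cfg.encoding.seed, alpha_grid=grid)
    # unique variance on the ROI traces (cheap, interpretable targets)
    traces = state["roi_traces"]  # (rois, frames, trials)
    Yr = traces.transpose(2, 1, 0).reshape(-1, traces.shape[0])
    roi_fit = encoding.crossval_r2(dm, Yr, n_folds=cfg.encoding.n_folds,
                                   seed=cfg.encoding.seed, alpha_grid=grid)
    for group in cfg.encoding.groups_of_interest:
        roi_fit = encoding.delta_r2(
            dm, Yr, group, n_shifts=cfg.encoding.n_shifts,
            seed=cfg.encoding.seed, n_folds=cfg.encoding.n_folds,
            alpha_grid=grid, base_fit=roi_fit)
    roi_fit.included = encoding.exclude_unexplained(
        roi_fit.significant, cfg.encoding.groups_of_interest)
    np.savez(
        outdir / "encoding_fit.npz",
        pixel_cv_r2=fit.cv_r2, pixel_alpha=fit.alpha, pixel_index=flat_idx,
        roi_cv_r2=roi_fit.cv_r2, roi_included=roi_fit.included,
        **{f"delta_r2_{g}": roi_fit.delta_r2[g]
           for g in cfg.encoding.groups_of_interest},
        **{f"significant_{g}": roi_fit.significant[g]
           for g in cfg.encoding.groups_of_interest},
    )
    manifest_extra = {"seed": cfg.encoding.seed,
                      "alpha_grid": cfg.encoding.alpha_grid,
                      "n_folds": cfg.encoding.n_folds,
                      "n_shifts": cfg.encoding.n_shifts}
    write_manifest(outdir / "manifest_encode.json", "encode",
                   [outdir / "dff" / "session.h5"],
                   [outdir / "encoding_fit.npz"], manifest_extra, t_start=t0)
    return {"pixel_fit": fit, "roi_fit": roi_fit, "design": dm}


def stage_decode(cfg: PipelineConfig, state: dict, outdir: Path) -> dict:
    t0 = time.time()
    dff: ImagingStack = state["dff"]
    trials = state["trials"]
    res = decoding.bootstrap_significance(
        dff, trials, DEFAULT_EPOCHS, decoding.TASKS,
        n_boot=cfg.decoding.n_boot, n_folds=cfg.decoding.n_folds,
        seed=cfg.decoding.seed, downsample=cfg.decoding.downsample)
    payload = {
        "accuracy": {f"{e}/{t}": v for (e, t), v in res.accuracy.items()},
        "bootstrap_percentile": {f"{e}/{t}": v
                                 for (e, t), v in res.bootstrap_percentile.items()},
        "lambdas": {e: list(v) for e, v in res.lambdas.items()},
    }
    if (trials["opto"] != "off").any():
        cc = decoding.cross_condition_test(
            dff, trials, n_folds=cfg.decoding.n_folds, seed=cfg.decoding.seed,
            downsample=cfg.decoding.downsample)
        payload["cross_condition_predicted_contra"] = {
            f"{c}/{s}": v for (c, s), v in cc.predicted_contra.items()}
    (outdir / "decode_result.json").write_text(json.dumps(payload, indent=2))
    write_manifest(outdir / "manifest_decode.json", "decode",
                   [outdir / "dff" / "session.h5"],
                   [outdir / "decode_result.json"],
                   {"seed": cfg.decoding.seed, "n_boot": cfg.decoding.n_boot},
                   t_start=t0)
    return payload


def run_pipeline(cfg: PipelineConfig, outdir: str | Path,
                 stages: tuple[str, ...] = ("simulate", "preprocess", "metrics",
                                            "encode", "decode")) -> dict:
    """Run the requested stages in order; returns the decode payload (or {})."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "resolved_config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
    results: dict = {}
    if "simulate" in stages:
        stage_simulate(cfg, outdir)
    state = None
    if {"preprocess", "metrics", "encode", "decode"} & set(stages):
        state = stage_preprocess(cfg, outdir)
    if "metrics" in stages:
        results["metrics"] = stage_metrics(state, outdir)
    if "encode" in stages:
        results["encode"] = stage_encode(cfg, state, outdir)
    if "decode" in stages:
        results["decode"] = stage_decode(cfg, state, outdir)
    return results
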