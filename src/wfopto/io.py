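"""Session file I/O and run manifests.

A session lives in one directory: ``session.h5`` (fluorescence stack,
continuous traces, ROI masks, frame times), ``trials.csv``,
``licks.csv`` and ``truth.json`` (ground-truth summary, synthetic
sessions only).  All arrays round-trip bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import ImagingStack, ROISet, validate_trial_table

SCHEMA_VERSION = 1


def write_session(
    path: str | Path,
    stack: ImagingStack,
    trials: pd.DataFrame,
    licks: pd.DataFrame,
    continuous: dict[str, np.ndarray],
    rois: ROISet | None = None,
    truth_summary: dict | None = None,
) -> Path:
    """Write a session directory; returns its path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with h5py.File(path / "session.h5", "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["kind"] = stack.kind
        f.attrs["frame_rate"] = stack.frame_rate
        f.create_dataset("F", data=stack.data)
        f.create_dataset("frame_times", data=stack.frame_times)
        f.create_dataset("valid_mask", data=stack.valid_mask)
        g = f.create_group("continuous")
        for name, trace in continuous.items():
            g.create_dataset(name, data=trace)
        if rois is not None:
            r = f.create_group("rois")
            for name, mask in rois.items():
                r.create_dataset(name, data=mask)
    validate_trial_table(trials)
    trials.to_csv(path / "trials.csv", index=False)
    licks.to_csv(path / "licks.csv", index=False)
    if truth_summary is not None:
        (path / "truth.json").write_text(json.dumps(truth_summary, indent=2))
    return path


def read_session(path: str | Path):
    """Read a session directory → (stack, trials, licks, continuous, rois).

    Raises on a missing file, a schema-version mismatch, or an invalid
    trial table — never returns silently corrupted arrays.
    """
    path = Path(path)
    h5path = path / "session.h5"
    if not h5path.exists():
        raise FileNotFoundError(f"missing session file: {h5path}")
    with h5py.File(h5path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"session schema version {version} != supported {SCHEMA_VERSION}")
        stack = ImagingStack(
            f["F"][()], f["frame_times"][()],
            kind=str(f.attrs["kind"]), valid_mask=f["valid_mask"][()])
        continuous = {name: ds[()] for name, ds in f["continuous"].items()}
        rois = None
        if "rois" in f:
            rois = ROISet({name: ds[()].astype(bool)
                           for name, ds in f["rois"].items()})
    trials = pd.read_csv(path / "trials.csv")
    validate_trial_table(trials)
    licks = pd.read_csv(path / "licks.csv")
    if len(licks) == 0:
        licks = pd.DataFrame(columns=["trial_id", "time", "side"])
    return stack, trials, licks, continuous, rois


def truth_summary(truth, config) -> dict:
    """JSON-serialisable summary of the generative ground truth."""
    return {
        "config": config.to_dict(),
        "beta_map_peaks": {k: float(np.max(np.abs(v)))
                           for k, v in truth.beta_maps.items()},
        "opto_effect_extent": [float(truth.opto_effect_map.min()),
                               float(truth.opto_effect_map.max())],
        "template_overlap": float(
            truth.memory_template_contra.ravel()
            @ truth.memory_template_ipsi.ravel()),
        "decision_noise_sd": truth.decision_noise_sd,
        "kernel_length_frames": int(len(truth.temporal_kernel)),
    }


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, stage: str, inputs, outputs,
                   seeds: dict, warnings_list=None, t_start=None) -> Path:
    """One JSON manifest per pipeline stage, with artifact checksums."""
    manifest = {
        "stage": stage,
        "inputs": {str(p): file_checksum(p) for p in inputs if Path(p).exists()},
        "outputs": {str(p): file_checksum(p) for p in outputs},
        "seeds": seeds,
        "wall_clock_s": None if t_start is None else round(time.time() - t_start, 3),
        "warnings": list(warnings_list or []),
    }
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2))
    return path
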