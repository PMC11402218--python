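"""Shared containers for widefield imaging sessions.

Conventions used throughout the package:

* All times are in seconds relative to visual-stimulus onset (t = 0).
* Trial epochs are half-open intervals ``[start, end)`` so that shared
  boundaries never double-count a frame or a lick.
* Lick and stimulus sides are labelled ``"contra"`` / ``"ipsi"`` relative to
  the optogenetically stimulated hemisphere (hemisphere_Opto), which by
  convention occupies the left half (low x indices) of the pixel grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SIDES = ("contra", "ipsi")
OUTCOMES = ("correct", "error", "omission")

#: Stimulation-onset epochs used to tag optogenetic trials.  The stimulation
#: itself is modelled as a boxcar starting at the epoch onset.
OPTO_EPOCH_ONSETS = {
    "baseline": -0.5,
    "visual": 0.0,
    "delay": 1.0,
    "response": 2.0,
}

OPTO_CONDITIONS = ("off",) + tuple(OPTO_EPOCH_ONSETS)


class EpochRegistry:
    """Named, half-open analysis windows in seconds from stimulus onset."""

    def __init__(self, windows: dict[str, tuple[float, float]]):
        for name, (start, end) in windows.items():
            if not end > start:
                raise ValueError(f"epoch {name!r}: end must exceed start")
        self.windows = dict(windows)

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.windows[name]

    def __contains__(self, name: str) -> bool:
        return name in self.windows

    def names(self) -> list[str]:
        return list(self.windows)

    def frame_mask(self, name: str, frame_times: np.ndarray) -> np.ndarray:
        """Boolean mask over frames falling inside the named window."""
        start, end = self.windows[name]
        t = np.asarray(frame_times)
        mask = (t >= start) & (t < end)
        if not mask.any():
            raise ValueError(f"epoch {name!r} contains no frames")
        return mask

    def items(self):
        return self.windows.items()


#: Windows used for decoding and trial-epoch statistics.
DEFAULT_EPOCHS = EpochRegistry(
    {
        "baseline": (-0.3, 0.0),
        "visual": (0.0, 0.5),
        "early_delay": (0.5, 1.2),
        "late_delay": (1.2, 1.9),
        "choice": (2.0, 2.5),
    }
)


@dataclass
class ImagingStack:
    """Pixel fluorescence, ``data[y, x, frame, trial]``.

    ``kind`` distinguishes raw fluorescence from ΔF/F; ``valid_mask`` marks
    pixels that may enter any average (pixels under an implant, or whose
    baseline fluorescence is non-positive, are invalid).
    """

    data: np.ndarray
    frame_times: np.ndarray
    kind: str = "raw"
    valid_mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("data must be (y, x, frames, trials)")
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.ndim != 1 or len(self.frame_times) != self.data.shape[2]:
            raise ValueError("frame_times length must match the frame axis")
        dt = np.diff(self.frame_times)
        if len(dt) and (dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("frame_times must be strictly increasing and uniform")
        if self.kind not in ("raw", "dff"):
            raise ValueError(f"unknown stack kind {self.kind!r}")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.data.shape[:2], dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.data.shape[:2]:
                raise ValueError("valid_mask shape must match spatial dims")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def n_trials(self) -> int:
        return self.data.shape[3]

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(self.frame_times[1] - self.frame_times[0])

    def copy_with(self, **kw) -> "ImagingStack":
        return replace(self, **kw)


ROI_LABELS = ("V1", "Vlat", "Vmed", "PPC", "RS", "M1", "M2")
HEMISPHERES = ("hemiOpto", "hemiControl")


@dataclass
class ROISet:
    """Named boolean pixel masks, one per (region, hemisphere)."""

    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("all ROI masks must share one shape")
        for name, mask in self.masks.items():
            if not mask.any():
                raise ValueError(f"ROI {name!r} is empty")
        # overlap is forbidden within a hemisphere
        for hemi in HEMISPHERES:
            total = None
            for name, mask in self.masks.items():
                if not name.endswith(hemi):
                    continue
                if total is None:
                    total = mask.astype(int).copy()
                else:
                    total += mask
            if total is not None and (total > 1).any():
                raise ValueError(f"overlapping ROI masks within {hemi}")

    def names(self) -> list[str]:
        return list(self.masks)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def items(self):
        return self.masks.items()


TRIAL_COLUMNS = (
    "trial_id",
    "stimulus_side",
    "first_lick_side",
    "first_lick_time",
    "outcome",
    "opto",
    "session_id",
)


def validate_trial_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Check the per-trial metadata table against the schema.

    Returns the validated frame (unchanged) so calls can be chained.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    bad = set(trials["stimulus_side"]) - set(SIDES)
    if bad:
        raise ValueError(f"unknown stimulus_side labels: {sorted(bad)}")
    bad = set(trials["outcome"]) - set(OUTCOMES)
    if bad:
        raise ValueError(f"unknown outcome labels: {sorted(bad)}")
    bad = set(trials["opto"]) - set(OPTO_CONDITIONS)
    if bad:
        raise ValueError(f"unknown opto condition labels: {sorted(bad)}")
    responded = trials["outcome"] != "omission"
    if trials.loc[responded, "first_lick_side"].isna().any():
        raise ValueError("responded trials must carry a first lick side")
    if trials.loc[~responded, "first_lick_time"].notna().any():
        raise ValueError("omission trials must not carry a first lick time")
    return trials


def reference_time(opto_condition: str) -> float:
    """ΔF/F baseline reference event for one trial.

    The earlier of visual-stimulus onset (t = 0) and, on optogenetic trials,
    the stimulation onset.
    """
    if opto_condition == "off":
        return 0.0
    return min(0.0, OPTO_EPOCH_ONSETS[opto_condition])
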