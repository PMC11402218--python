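"""Raw-stack preprocessing: ΔF/F, smoothing, ROI traces, trial inclusion.

The pipeline order is fixed — ΔF/F, then spatial smoothing, then ROI
aggregation — mirroring how widefield data are normally reduced.  Masked
pixels (``valid_mask``) never contribute to any average.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import ImagingStack, ROISet, reference_time


def compute_dff(
    stack: ImagingStack,
    trials: pd.DataFrame,
    baseline_duration: float = 0.3,
    statistic: str = "mean",
) -> ImagingStack:
    """Per-trial fractional fluorescence change.

    ΔF/F = (F − F̄_base) / F̄_base, where F̄_base summarises the
    ``baseline_duration`` window (default 300 ms) ending at the trial's
    reference event — the earlier of visual-stimulus onset and, on
    optogenetic trials, stimulation onset.  Pixels whose baseline is not
    strictly positive in some trial are flagged invalid rather than
    silently zeroed.
    """
    if stack.kind != "raw":
        raise ValueError("compute_dff expects a raw stack")
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    t = stack.frame_times
    refs = np.array([reference_time(o) for o in trials["opto"]])
    data = np.asarray(stack.data, dtype=np.float64)
    out = np.empty_like(data, dtype=np.float32)
    valid = stack.valid_mask.copy()
    summarise = np.mean if statistic == "mean" else np.median
    for j, ref in enumerate(refs):
        win = (t >= ref - baseline_duration) & (t < ref)
        if not win.any():
            raise ValueError(
                f"baseline window of trial {j} lies outside the trial frames")
        base = summarise(data[:, :, win, j], axis=2)
        bad = base <= 0
        if bad.any():
            valid &= ~bad
            base = np.where(bad, 1.0, base)
        out[:, :, :, j] = (data[:, :, :, j] - base[:, :, None]) / base[:, :, None]
    if (~valid & stack.valid_mask).any():
        warnings.warn(
            "pixels with non-positive baseline fluorescence flagged invalid",
            stacklevel=2,
        )
    return ImagingStack(out, stack.frame_times, kind="dff", valid_mask=valid)


def spatial_smooth(stack: ImagingStack, sigma_pixels: float = 2.0) -> ImagingStack:
    """Per-frame 2-D Gaussian smoothing with masked normalisation.

    Invalid pixels are excluded from the kernel support and the remaining
    weights are renormalised, so a constant image stays constant near mask
    borders.  ``sigma_pixels = 0`` returns the input unchanged.
    """
    if sigma_pixels < 0:
        raise ValueError("sigma_pixels must be >= 0")
    if sigma_pixels == 0:
        return stack
    mask = stack.valid_mask.astype(np.float64)
    ny, nx, nf, nt = stack.data.shape
    flat = np.asarray(stack.data, dtype=np.float64) * mask[:, :, None, None]
    flat = flat.reshape(ny, nx, nf * nt)
    num = gaussian_filter(flat, sigma=(sigma_pixels, sigma_pixels, 0))
    den = gaussian_filter(mask, sigma=sigma_pixels)
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = num / den[:, :, None]
    sm = sm.reshape(ny, nx, nf, nt).astype(stack.data.dtype)
    sm[~stack.valid_mask] = 0.0
    return stack.copy_with(data=sm)


def aggregate_rois(stack: ImagingStack, rois: ROISet) -> tuple[np.ndarray, list[str]]:
    """Unweighted mean over the valid pixels of each mask.

    Returns ``(traces, names)`` with ``traces`` shaped
    (n_rois, n_frames, n_trials).
    """
    names = rois.names()
    out = np.empty((len(names), stack.n_frames, stack.n_trials), dtype=np.float64)
    for i, name in enumerate(names):
        m = rois[name] & stack.valid_mask
        if not m.any():
            raise ValueError(f"ROI {name!r} has no valid pixels")
        out[i] = stack.data[m].mean(axis=0, dtype=np.float64)
    return out, names


def filter_trials_by_performance(
    trials: pd.DataFrame, window: int = 50, threshold: float = 0.55
) -> np.ndarray:
    """Engagement filter: keep trials from locally well-performed stretches.

    A trial is included iff, within the centred ``window``-trial stretch
    around it (truncated at session edges), accuracy — correct over
    correct-plus-error, omissions excluded — exceeds ``threshold``
    separately for each stimulus side.  A side absent from the stretch
    leaves its criterion undefined and the trial is excluded.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(trials)
    sides = trials["stimulus_side"].to_numpy()
    outcome = trials["outcome"].to_numpy()
    include = np.zeros(n, dtype=bool)
    for i in range(n):
        start = max(0, i - (window - 1) // 2)
        stop = min(n, start + window)
        start = max(0, stop - window)
        ok = True
        for side in ("contra", "ipsi"):
            sel = (sides[start:stop] == side) & (outcome[start:stop] != "omission")
            n_corr = int(np.sum(outcome[start:stop][sel] == "correct"))
            n_resp = int(np.sum(sel))
            if n_resp == 0 or n_corr / n_resp <= threshold:
                ok = False
                break
        include[i] = ok
    return include
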