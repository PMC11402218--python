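"""Scalar behavioural / neural statistics and their map-valued extensions.

* d-prime: standardised mean difference between two trial conditions,
  (μA − μB) / sqrt(½(σA² + σB²)), with the sample (n−1) variance over
  trials by default.
* accuracy: correct / (correct + error) × 100, omissions excluded.
* omission rate: omissions / all trials × 100.
* switch index: normalised difference between contra→ipsi and
  ipsi→contra lick-side switches within a trial window; +1 means every
  switch was contraversive-to-ipsiversive.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import EpochRegistry, ImagingStack


def d_prime(values_a, values_b, ddof: int = 1) -> float:
    """Sensitivity index between two sets of per-trial scalars."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each condition needs at least 2 trials")
    num = a.mean() - b.mean()
    den = np.sqrt(0.5 * (a.var(ddof=ddof) + b.var(ddof=ddof)))
    if den == 0:
        if num == 0:
            return 0.0
        warnings.warn("zero variance with unequal means: d-prime is infinite",
                      stacklevel=2)
        return float(np.sign(num) * np.inf)
    return float(num / den)


def d_prime_map(
    data: np.ndarray | ImagingStack,
    frame_times: np.ndarray | None,
    trials_a: np.ndarray,
    trials_b: np.ndarray,
    epoch: tuple[float, float],
    ddof: int = 1,
) -> np.ndarray:
    """Per-pixel (or per-ROI) d-prime of epoch-mean activity, A minus B.

    ``data`` is either an :class:`ImagingStack` or an array whose last two
    axes are (frames, trials).  The epoch is half-open in seconds.
    """
    if isinstance(data, ImagingStack):
        frame_times = data.frame_times
        data = data.data
    t = np.asarray(frame_times)
    win = (t >= epoch[0]) & (t < epoch[1])
    if not win.any():
        raise ValueError("epoch window contains no frames")
    trials_a = np.asarray(trials_a)
    trials_b = np.asarray(trials_b)
    if trials_a.size < 2 or trials_b.size < 2:
        raise ValueError("each condition needs at least 2 trials")
    if np.intersect1d(trials_a, trials_b).size:
        raise ValueError("condition trial sets must be disjoint")
    mean = data[..., win, :].mean(axis=-2)  # (..., trials)
    A = mean[..., trials_a]
    B = mean[..., trials_b]
    num = A.mean(axis=-1) - B.mean(axis=-1)
    den = np.sqrt(0.5 * (A.var(axis=-1, ddof=ddof) + B.var(axis=-1, ddof=ddof)))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out = np.where((den == 0) & (num == 0), 0.0, out)
    return out


def accuracy(trials: pd.DataFrame) -> float:
    """Percent correct among responded trials; NaN when none responded."""
    n_hit = int((trials["outcome"] == "correct").sum())
    n_err = int((trials["outcome"] == "error").sum())
    if n_hit + n_err == 0:
        return float("nan")
    return 100.0 * n_hit / (n_hit + n_err)


def omission_rate(trials: pd.DataFrame) -> float:
    """Percent omissions among all trials; NaN on an empty subset."""
    n = len(trials)
    if n == 0:
        return float("nan")
    return 100.0 * int((trials["outcome"] == "omission").sum()) / n


def switch_index(licks: pd.DataFrame, window: float = 1.0) -> float:
    """Directional bias of within-trial lick-side switches.

    Counts consecutive lick pairs within ``[0, window)`` seconds of
    stimulus onset whose side changes; SI = (ΣC→I − ΣI→C)/(ΣC→I + ΣI→C).
    NaN when no switches occur.
    """
    n_ci = n_ic = 0
    sub = licks[(licks["time"] >= 0.0) & (licks["time"] < window)]
    for _, g in sub.groupby("trial_id"):
        sides = g.sort_values("time")["side"].to_numpy()
        for prev, cur in zip(sides[:-1], sides[1:]):
            if prev == "contra" and cur == "ipsi":
                n_ci += 1
            elif prev == "ipsi" and cur == "contra":
                n_ic += 1
    total = n_ci + n_ic
    if total == 0:
        return float("nan")
    return (n_ci - n_ic) / total


def lick_counts_by_epoch(
    trials: pd.DataFrame, licks: pd.DataFrame, epochs: EpochRegistry
) -> pd.DataFrame:
    """Per-trial lick counts per side per named epoch (half-open windows)."""
    records = []
    by_trial = dict(tuple(licks.groupby("trial_id")))
    for trial_id in trials["trial_id"]:
        g = by_trial.get(trial_id)
        for name, (start, end) in epochs.items():
            for side in ("contra", "ipsi"):
                if g is None:
                    count = 0
                else:
                    sel = (g["side"] == side) & (g["time"] >= start) & (g["time"] < end)
                    count = int(sel.sum())
                records.append((trial_id, name, side, count))
    return pd.DataFrame(records, columns=["trial_id", "epoch", "side", "n_licks"])
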