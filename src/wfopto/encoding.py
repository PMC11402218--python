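"""Event-kernel ridge-regression encoding model.

Each pixel's ΔF/F trace (all trials concatenated) is regressed on a
design matrix whose event predictors are time-expanded: an event
contributes one lagged indicator column per frame from its onset to the
end of the trial, so the fitted coefficients trace out the event's
temporal kernel.  Continuous nuisance predictors (body and eye movement)
enter as single min-max-normalised columns.

Regularisation is ridge with a per-pixel penalty chosen by nested
cross-validation (one-third of the training trials held out inside each
main fold).  Model quality is the trial-wise cross-validated R², and the
unique contribution of a predictor group is ΔR² — the drop in R² when
that group's per-trial event assignment is circularly rotated across the
trial sequence, which destroys the predictor-response alignment while
preserving its within-trial lag structure and marginal statistics.  A
group is significant when the intact R² exceeds the 95th percentile of
the rotated-R² distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ImagingStack, OPTO_EPOCH_ONSETS, reference_time

#: default ridge penalty grid: 0 to 50 in steps of 0.5, both ends included
DEFAULT_ALPHA_GRID = np.round(np.arange(0.0, 50.0 + 1e-9, 0.5), 6)

EVENT_GROUP_OF = {
    "stim_contra": "stimulus_side",
    "stim_ipsi": "stimulus_side",
    "opto": "opto",
    "lick_contra": "lick_contra",
    "lick_ipsi": "lick_ipsi",
}


@dataclass
class Predictor:
    name: str
    group: str
    kind: str  # "event" or "continuous"
    columns: np.ndarray  # column indices into X
    lags: np.ndarray | None = None  # frame lags retained (event predictors)


@dataclass
class DesignMatrix:
    """(frames·trials) × columns matrix with grouped predictor metadata.

    Rows are trial-major: row = trial·n_frames + frame.  All values lie
    in [0, 1]; the last column is the intercept.
    """

    X: np.ndarray
    groups: dict[str, np.ndarray]
    predictors: list[Predictor]
    trial_index: np.ndarray
    n_trials: int
    n_frames: int

    @property
    def intercept_col(self) -> int:
        return int(self.groups["intercept"][0])

    def group_block(self, group: str) -> np.ndarray:
        return self.groups[group]

    def with_shifted_group(self, group: str, shift: int) -> "DesignMatrix":
        """Rotate the group's per-trial event pattern across trials.

        Trial j receives the pattern of trial (j − shift) mod n_trials;
        the within-trial replication across timepoints is untouched.
        """
        cols = self.groups[group]
        X = self.X.copy()
        block = X[:, cols].reshape(self.n_trials, self.n_frames, len(cols))
        X[:, cols] = np.roll(block, shift, axis=0).reshape(-1, len(cols))
        return DesignMatrix(X, self.groups, self.predictors,
                            self.trial_index, self.n_trials, self.n_frames)


def _frame_of(frame_times: np.ndarray, t: float) -> int:
    rate = 1.0 / (frame_times[1] - frame_times[0])
    return int(round((t - frame_times[0]) * rate))


def build_design_matrix(
    trials: pd.DataFrame,
    licks: pd.DataFrame,
    continuous: dict[str, np.ndarray],
    frame_times: np.ndarray,
    kernel_len: int | None = None,
    baseline_duration: float = 0.3,
    rebaseline_continuous: bool = True,
) -> DesignMatrix:
    """Assemble the grouped design matrix for one session.

    Event predictors: stimulus side (one sub-predictor per side, onset at
    t = 0), optogenetic stimulation (onset at the trial's stimulation
    epoch), and licks per side (one impulse per lick).  Each expands into
    ``kernel_len`` lagged indicator columns (default: to the end of the
    trial); lag columns that are zero for every trial are dropped.

    Continuous predictors are, by default, re-baselined per trial
    (subtracting their mean over the same pre-event window used for
    ΔF/F) before min-max normalisation, keeping them commensurate with
    the baseline-subtracted response variable.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    nf = len(frame_times)
    nt = len(trials)
    if kernel_len is None:
        kernel_len = nf
    n_rows = nf * nt
    t0 = frame_times[0]
    t_end = frame_times[-1] + (frame_times[1] - frame_times[0])

    # collect event onsets (lists of arrays, one per trial, in table order)
    def onsets_for(name):
        out = []
        for trial in trials.itertuples():
            if name == "stim_contra":
                ts = [0.0] if trial.stimulus_side == "contra" else []
            elif name == "stim_ipsi":
                ts = [0.0] if trial.stimulus_side == "ipsi" else []
            elif name == "opto":
                ts = ([OPTO_EPOCH_ONSETS[trial.opto]]
                      if trial.opto != "off" else [])
            else:  # lick predictors
                side = name.split("_")[1]
                sel = (licks["trial_id"] == trial.trial_id) & (licks["side"] == side)
                ts = list(licks.loc[sel, "time"])
            if name.startswith("lick"):
                # recorded point events must lie inside the trial frames;
                # scheduled stimulus/opto onsets outside simply contribute
                # no columns
                for t in ts:
                    if not (t0 <= t < t_end):
                        raise ValueError(
                            f"event {name!r} at t={t:.3f}s of trial "
                            f"{trial.trial_id} lies outside the trial window")
            out.append(np.asarray(ts, dtype=float))
        return out

    blocks: list[np.ndarray] = []
    predictors: list[Predictor] = []
    groups: dict[str, list[int]] = {}
    col = 0

    for name in ("stim_contra", "stim_ipsi", "opto", "lick_contra", "lick_ipsi"):
        onsets = onsets_for(name)
        block = np.zeros((n_rows, kernel_len))
        for j, ts in enumerate(onsets):
            for t in ts:
                k = _frame_of(frame_times, t)
                lags = np.arange(kernel_len)
                keep = (k + lags >= 0) & (k + lags < nf)
                block[j * nf + k + lags[keep], lags[keep]] = 1.0
        used = block.any(axis=0)
        if not used.any():
            continue
        block = block[:, used]
        lags = np.flatnonzero(used)
        group = EVENT_GROUP_OF[name]
        idx = list(range(col, col + block.shape[1]))
        groups.setdefault(group, []).extend(idx)
        predictors.append(Predictor(name, group, "event", np.array(idx), lags))
        blocks.append(block)
        col += block.shape[1]

    refs = np.array([reference_time(o) for o in trials["opto"]])
    for name, trace in continuous.items():
        trace = np.asarray(trace, dtype=float)
        if trace.shape != (nf, nt):
            raise ValueError(f"continuous trace {name!r} must be (frames, trials)")
        vals = trace.T.reshape(-1).copy()
        if rebaseline_continuous:
            for j, ref in enumerate(refs):
                win = (frame_times >= ref - baseline_duration) & (frame_times < ref)
                sl = slice(j * nf, (j + 1) * nf)
                vals[sl] -= trace[win, j].mean()
        lo, hi = vals.min(), vals.max()
        if hi > lo:
            vals = (vals - lo) / (hi - lo)
        else:
            vals = np.zeros_like(vals)
        groups.setdefault(name, []).append(col)
        predictors.append(Predictor(name, name, "continuous", np.array([col])))
        blocks.append(vals[:, None])
        col += 1

    groups.setdefault("intercept", []).append(col)
    predictors.append(Predictor("intercept", "intercept", "continuous",
                                np.array([col])))
    blocks.append(np.ones((n_rows, 1)))

    X = np.hstack(blocks)
    trial_index = np.repeat(np.arange(nt), nf)
    return DesignMatrix(
        X=X,
        groups={g: np.asarray(ix, dtype=int) for g, ix in groups.items()},
        predictors=predictors,
        trial_index=trial_index,
        n_trials=nt,
        n_frames=nf,
    )


# ---------------------------------------------------------------------------
# ridge solvers


def ridge_solve(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    intercept_col: int | None = None,
    penalize_intercept: bool = False,
) -> np.ndarray:
    """Penalised normal-equation solution β = (XᵀX + αD)⁻¹ Xᵀy.

    D is the identity, except the intercept column is unpenalised unless
    ``penalize_intercept`` is set.  ``alpha = 0`` requires X to have full
    column rank and reduces to ordinary least squares.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if alpha == 0:
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError(
                "design matrix is rank deficient; alpha = 0 has no unique solution")
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return beta
    D = np.eye(X.shape[1])
    if not penalize_intercept and intercept_col is not None:
        D[intercept_col, intercept_col] = 0.0
    A = X.T @ X + alpha * D
    return np.linalg.solve(A, X.T @ y)


class _RidgePath:
    """Eigendecomposition-based ridge over a penalty grid, many targets.

    With an unpenalised intercept the problem is solved in centred
    coordinates (centre non-intercept columns and targets on the training
    set; the intercept is recovered afterwards), which is exactly
    equivalent to leaving the intercept out of the penalty.  Zero or
    near-zero eigenvalue directions are dropped (minimum-norm solution),
    so ``alpha = 0`` coincides with the pseudo-inverse least squares fit.
    """

    def __init__(self, X, Y, intercept_col=None, penalize_intercept=False):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        self.n_cols = X.shape[1]
        self.intercept_col = intercept_col
        self.center = intercept_col is not None and not penalize_intercept
        if self.center:
            self.keep = np.array([j for j in range(self.n_cols) if j != intercept_col])
            Z = X[:, self.keep]
            self.col_mean = Z.mean(axis=0)
            Z = Z - self.col_mean
            self.y_mean = Y.mean(axis=0)
            Yc = Y - self.y_mean
        else:
            self.keep = np.arange(self.n_cols)
            self.col_mean = np.zeros(self.n_cols)
            self.y_mean = np.zeros(Y.shape[1])
            Z = X
            Yc = Y
        A = Z.T @ Z
        self.evals, self.Q = np.linalg.eigh(A)
        self.evals = np.clip(self.evals, 0.0, None)
        self.U = self.Q.T @ (Z.T @ Yc)  # (c, P)
        self._tol = max(1e-10, self.evals.max() * 1e-12) if len(self.evals) else 0.0

    def _btilde(self, alpha):
        """Rotated coefficients for a scalar or per-target alpha array."""
        alpha = np.asarray(alpha, dtype=float)
        if alpha.ndim:  # one penalty per target
            denom = self.evals[:, None] + alpha[None, :]
        else:
            denom = self.evals[:, None] + alpha
        dead = denom <= self._tol
        with np.errstate(divide="ignore"):
            inv = np.where(dead, 0.0, 1.0 / np.where(dead, 1.0, denom))
        return self.U * inv

    def beta(self, alpha) -> np.ndarray:
        """Full-size coefficients (n_cols, P), intercept included."""
        b = self.Q @ self._btilde(alpha)
        out = np.zeros((self.n_cols, b.shape[1]))
        out[self.keep] = b
        if self.center:
            out[self.intercept_col] = self.y_mean - self.col_mean @ b
        return out

    def predict(self, X_new, alpha) -> np.ndarray:
        b = self.beta(alpha)
        return np.asarray(X_new, dtype=float) @ b

    def sse_grid(self, X_val, Y_val, alphas) -> np.ndarray:
        """Validation SSE for every (alpha, target) pair, (n_alpha, P)."""
        X_val = np.asarray(X_val, dtype=float)
        Y_val = np.asarray(Y_val, dtype=float)
        if Y_val.ndim == 1:
            Y_val = Y_val[:, None]
        V = (X_val[:, self.keep] - self.col_mean) @ self.Q
        R = Y_val - self.y_mean
        G = V.T @ V
        W = V.T @ R
        rss0 = np.einsum("ij,ij->j", R, R)
        out = np.empty((len(alphas), Y_val.shape[1]))
        for i, a in enumerate(alphas):
            b = self._btilde(float(a))
            out[i] = rss0 - 2 * np.einsum("cp,cp->p", b, W) \
                + np.einsum("cp,cp->p", b, G @ b)
        return np.clip(out, 0.0, None)


def _split_trials(trial_ids, rng):
    """Random 2/3 train, 1/3 validation split of trial identities."""
    ids = np.array(trial_ids)
    rng.shuffle(ids)
    n_val = max(1, len(ids) // 3)
    return ids[n_val:], ids[:n_val]


def select_alpha(
    X: np.ndarray,
    Y: np.ndarray,
    trial_index: np.ndarray,
    grid=DEFAULT_ALPHA_GRID,
    seed: int = 0,
    intercept_col: int | None = None,
    penalize_intercept: bool = False,
) -> np.ndarray:
    """Per-target ridge penalty minimising held-out SSE.

    One-third of the (training) trials is held out; the grid must be
    sorted ascending, ties resolve to the smallest penalty.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("alpha grid must be non-empty")
    if np.any(np.diff(grid) < 0):
        raise ValueError("alpha grid must be sorted ascending")
    trial_index = np.asarray(trial_index)
    uniq = np.unique(trial_index)
    if len(uniq) < 3:
        raise ValueError("need at least 3 trials for the inner alpha split")
    rng = np.random.default_rng(seed)
    train_ids, val_ids = _split_trials(uniq, rng)
    tr = np.isin(trial_index, train_ids)
    va = np.isin(trial_index, val_ids)
    Y2 = Y if Y.ndim == 2 else Y[:, None]
    path = _RidgePath(X[tr], Y2[tr], intercept_col, penalize_intercept)
    sse = path.sse_grid(X[va], Y2[va], grid)
    return grid[np.argmin(sse, axis=0)]


@dataclass
class EncodingFit:
    beta: np.ndarray          # (n_cols, P), fitted on all trials
    alpha: np.ndarray         # (P,) penalty used for the final fit
    cv_r2: np.ndarray         # (P,) pooled trial-wise cross-validated R²
    fold_of_trial: np.ndarray
    alpha_grid: np.ndarray
    delta_r2: dict[str, np.ndarray] = field(default_factory=dict)
    null_r2: dict[str, np.ndarray] = field(default_factory=dict)
    significant: dict[str, np.ndarray] = field(default_factory=dict)
    included: np.ndarray | None = None


def crossval_r2(
    dm: DesignMatrix,
    Y: np.ndarray,
    n_folds: int = 3,
    seed: int = 0,
    alpha_grid=DEFAULT_ALPHA_GRID,
    penalize_intercept: bool = False,
    fit_final: bool = True,
) -> EncodingFit:
    """Trial-wise k-fold cross-validated R² with nested alpha selection.

    Folds split whole trials.  R² pools residual and total sums of
    squares over folds; the total sum of squares is taken around each
    fold's own test mean.  A fold with zero test variance for a target is
    skipped for that target with a warning.
    """
    X = dm.X
    Y2 = Y if Y.ndim == 2 else Y[:, None]
    P = Y2.shape[1]
    rng = np.random.default_rng(seed)
    order = rng.permutation(dm.n_trials)
    fold_of_trial = np.empty(dm.n_trials, dtype=int)
    for f, chunk in enumerate(np.array_split(order, n_folds)):
        fold_of_trial[chunk] = f
    sse = np.zeros(P)
    sst = np.zeros(P)
    grid = np.asarray(alpha_grid, dtype=float)
    for f in range(n_folds):
        te = fold_of_trial[dm.trial_index] == f
        tr = ~te
        alphas = select_alpha(
            X[tr], Y2[tr], dm.trial_index[tr], grid, seed=seed + 1000 + f,
            intercept_col=dm.intercept_col, penalize_intercept=penalize_intercept)
        path = _RidgePath(X[tr], Y2[tr], dm.intercept_col, penalize_intercept)
        pred = path.predict(X[te], alphas)
        resid = Y2[te] - pred
        centred = Y2[te] - Y2[te].mean(axis=0)
        fold_sst = np.einsum("ij,ij->j", centred, centred)
        ok = fold_sst > 0
        if not ok.all():
            warnings.warn(
                f"fold {f}: {np.sum(~ok)} target(s) with zero test variance skipped",
                stacklevel=2)
        sse[ok] += np.einsum("ij,ij->j", resid[:, ok], resid[:, ok])
        sst[ok] += fold_sst[ok]
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - sse / sst
    r2 = np.where(sst > 0, r2, np.nan)

    if fit_final:
        alphas = select_alpha(
            X, Y2, dm.trial_index, grid, seed=seed + 999,
            intercept_col=dm.intercept_col, penalize_intercept=penalize_intercept)
        path = _RidgePath(X, Y2, dm.intercept_col, penalize_intercept)
        beta = path.beta(alphas)
    else:
        beta = np.zeros((X.shape[1], P))
        alphas = np.zeros(P)
    return EncodingFit(
        beta=beta, alpha=alphas, cv_r2=r2 if Y.ndim == 2 else r2,
        fold_of_trial=fold_of_trial, alpha_grid=grid)


def delta_r2(
    dm: DesignMatrix,
    Y: np.ndarray,
    group: str,
    n_shifts: int = 500,
    seed: int = 0,
    n_folds: int = 3,
    alpha_grid=DEFAULT_ALPHA_GRID,
    penalize_intercept: bool = False,
    base_fit: EncodingFit | None = None,
) -> EncodingFit:
    """Unique variance of a predictor group via circular trial rotations.

    Rotation offsets are drawn from 1..n_trials−1 without replacement
    when possible (with replacement, with a warning, otherwise).  The
    full cross-validated fit, including alpha selection, is recomputed
    for every rotation with the same fold assignment.  ΔR² is the intact
    R² minus the mean rotated R²; a target is significant when its intact
    R² exceeds the 95th percentile of its rotated-R² distribution.
    """
    if group not in dm.groups:
        raise KeyError(f"unknown predictor group {group!r}")
    Y2 = Y if Y.ndim == 2 else Y[:, None]
    fit = base_fit or crossval_r2(
        dm, Y2, n_folds=n_folds, seed=seed, alpha_grid=alpha_grid,
        penalize_intercept=penalize_intercept)
    if not dm.X[:, dm.groups[group]].any():
        warnings.warn(f"group {group!r} has no events; delta R2 is 0", stacklevel=2)
        P = Y2.shape[1]
        fit.delta_r2[group] = np.zeros(P)
        fit.null_r2[group] = np.zeros((0, P))
        fit.significant[group] = np.zeros(P, dtype=bool)
        return fit
    rng = np.random.default_rng([seed, 0x5C1F])
    candidates = np.arange(1, dm.n_trials)
    if n_shifts <= len(candidates):
        offsets = rng.choice(candidates, size=n_shifts, replace=False)
    else:
        warnings.warn(
            "more shifts than distinct rotations; sampling with replacement",
            stacklevel=2)
        offsets = rng.choice(candidates, size=n_shifts, replace=True)
    null = np.empty((n_shifts, Y2.shape[1]))
    for i, off in enumerate(offsets):
        shifted = dm.with_shifted_group(group, int(off))
        sub = crossval_r2(
            shifted, Y2, n_folds=n_folds, seed=seed, alpha_grid=alpha_grid,
            penalize_intercept=penalize_intercept, fit_final=False)
        null[i] = sub.cv_r2
    fit.delta_r2[group] = fit.cv_r2 - null.mean(axis=0)
    fit.null_r2[group] = null
    fit.significant[group] = fit.cv_r2 > np.quantile(null, 0.95, axis=0)
    return fit


def exclude_unexplained(
    significant: dict[str, np.ndarray], groups_of_interest
) -> np.ndarray:
    """Targets kept iff at least one group of interest is significant."""
    masks = [np.asarray(significant[g], dtype=bool) for g in groups_of_interest]
    if not masks:
        raise ValueError("no groups of interest given")
    return np.logical_or.reduce(masks)


def flatten_stack(stack: ImagingStack) -> tuple[np.ndarray, np.ndarray]:
    """ΔF/F stack → (rows × pixels) response matrix for valid pixels.

    Rows are trial-major to match :func:`build_design_matrix`; returns
    the matrix and the flat indices of the valid pixels.
    """
    ny, nx, nf, nt = stack.data.shape
    flat_idx = np.flatnonzero(stack.valid_mask.ravel())
    Y = stack.data.reshape(ny * nx, nf, nt)[flat_idx]  # (p, f, t)
    Y = np.ascontiguousarray(Y.transpose(2, 1, 0)).reshape(nf * nt, len(flat_idx))
    return Y, flat_idx
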