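"""Multi-task structured-sparsity decoding of stimulus side and lick side.

The decoder is a "dirty" multi-task linear model: the weight matrix over
pixel features decomposes as W = B + S, where B is row-sparse via an
l1/l-infinity penalty (features shared across tasks) and S is
element-wise l1-sparse (task-specific features).  With squared loss on
±1 labels the objective is

    sum_t ||X w_t - y_t||^2 + lambda_B * sum_rows max_t |B[row, t]|
                            + lambda_S * ||S||_1,

minimised by monotone accelerated proximal gradient descent.  Class
prediction is the sign of the linear score.

Decoding runs on class-balanced trial subsets (equal counts of
correct/error × contra/ipsi-stimulus trials), with stratified k-fold
cross-validation, label-randomisation bootstrap for significance, and
cross-condition generalisation (train on opto-off late-delay activity,
test on optogenetically stimulated trials).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DEFAULT_EPOCHS, EpochRegistry, ImagingStack

TASKS = ("stimulus_side", "lick_side")

_LABEL_COLUMN = {"stimulus_side": "stimulus_side", "lick_side": "first_lick_side"}


def task_labels(trials: pd.DataFrame, task: str) -> np.ndarray:
    """±1 labels for a task: contra → +1, ipsi → −1."""
    col = _LABEL_COLUMN[task]
    sides = trials[col].to_numpy()
    if pd.isna(sides).any():
        raise ValueError(f"undefined {task} label on some trials")
    return np.where(sides == "contra", 1.0, -1.0)


def balance_trials(trials: pd.DataFrame, seed: int = 0) -> np.ndarray:
    """Equal numbers of correct/error × contra/ipsi-stimulus trials.

    Returns positional indices into ``trials``.  Omissions never enter;
    the per-cell count is the smallest cell size, drawn without
    replacement.  An empty cell raises with all four cell counts.
    """
    rng = np.random.default_rng(seed)
    cells = {}
    for outcome in ("correct", "error"):
        for side in ("contra", "ipsi"):
            sel = np.flatnonzero(
                (trials["outcome"].to_numpy() == outcome)
                & (trials["stimulus_side"].to_numpy() == side))
            cells[(outcome, side)] = sel
    counts = {k: len(v) for k, v in cells.items()}
    if min(counts.values()) == 0:
        raise ValueError(f"empty condition cell; counts: {counts}")
    n = min(counts.values())
    picked = [rng.choice(v, size=n, replace=False) for v in cells.values()]
    return np.sort(np.concatenate(picked))


def block_average(frame: np.ndarray, factor: int) -> np.ndarray:
    """Spatially downsample a (y, x, ...) array by block averaging."""
    if factor <= 1:
        return frame
    ny, nx = frame.shape[:2]
    ny2, nx2 = ny // factor, nx // factor
    trimmed = frame[: ny2 * factor, : nx2 * factor]
    shape = (ny2, factor, nx2, factor) + frame.shape[2:]
    return trimmed.reshape(shape).mean(axis=(1, 3))


def featurize_epoch(
    stack: ImagingStack,
    epoch: tuple[float, float],
    trial_idx: np.ndarray,
    downsample: int = 1,
) -> np.ndarray:
    """Per-trial epoch-mean ΔF/F per feature → (trials × features).

    Features are the valid pixels, optionally block-averaged by
    ``downsample``.  Standardisation is left to the cross-validation
    loop, which must use training-set statistics only.
    """
    t = stack.frame_times
    win = (t >= epoch[0]) & (t < epoch[1])
    if not win.any():
        raise ValueError("epoch contains no frames")
    mean = stack.data[:, :, win][:, :, :, trial_idx].mean(
        axis=2, dtype=np.float64)  # (y, x, n)
    mask = stack.valid_mask
    if downsample > 1:
        mean = block_average(mean, downsample)
        mask = block_average(mask.astype(float), downsample) > 0.5
    return mean.reshape(-1, mean.shape[-1]).T[:, mask.ravel()]


# ---------------------------------------------------------------------------
# dirty-model solver


@dataclass
class DirtyModel:
    B: np.ndarray
    S: np.ndarray
    lambda_b: float
    lambda_s: float
    tasks: tuple[str, ...]
    converged: bool
    objective: list[float] = field(default_factory=list)

    @property
    def W(self) -> np.ndarray:
        return self.B + self.S

    def predict(self, X: np.ndarray) -> np.ndarray:
        """±1 predictions per task; zero scores break toward +1."""
        score = np.asarray(X) @ self.W
        return np.where(score >= 0, 1.0, -1.0)


def dirty_objective(X, Y, B, S, lambda_b, lambda_s) -> float:
    resid = X @ (B + S) - Y
    return (
        float(np.sum(resid**2))
        + lambda_b * float(np.sum(np.max(np.abs(B), axis=1)))
        + lambda_s * float(np.sum(np.abs(S)))
    )


def _project_l1_ball(V: np.ndarray, radius: float) -> np.ndarray:
    """Row-wise Euclidean projection onto the l1 ball of given radius."""
    if radius <= 0:
        return np.zeros_like(V)
    A = np.abs(V)
    n = V.shape[1]
    s = np.sort(A, axis=1)[:, ::-1]
    css = np.cumsum(s, axis=1) - radius
    ks = np.arange(1, n + 1)
    cond = s - css / ks > 0
    rho = n - 1 - np.argmax(cond[:, ::-1], axis=1)
    theta = np.maximum(css[np.arange(len(V)), rho] / (rho + 1), 0.0)
    inside = A.sum(axis=1) <= radius
    theta = np.where(inside, 0.0, theta)
    return np.sign(V) * np.maximum(A - theta[:, None], 0.0)


def _prox_linf(V: np.ndarray, t: float) -> np.ndarray:
    """Row-wise proximal operator of t·||row||_inf (Moreau identity)."""
    return V - _project_l1_ball(V, t)


def _soft(V: np.ndarray, t: float) -> np.ndarray:
    return np.sign(V) * np.maximum(np.abs(V) - t, 0.0)


def fit_dirty_model(
    X: np.ndarray,
    Y: np.ndarray,
    lambda_b: float,
    lambda_s: float,
    tasks: tuple[str, ...] = TASKS,
    max_iter: int = 2000,
    tol: float = 1e-9,
) -> DirtyModel:
    """Fit W = B + S by monotone accelerated proximal gradient.

    Momentum steps that would raise the objective fall back to a plain
    proximal-gradient step, so the recorded objective never increases.
    Non-convergence within ``max_iter`` returns the current iterate with
    ``converged=False`` and a warning.
    """
    if lambda_b < 0 or lambda_s < 0:
        raise ValueError("penalties must be >= 0")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    p, k = X.shape[1], Y.shape[1]
    sv = np.linalg.norm(X, 2) if min(X.shape) else 0.0
    L = 4.0 * sv**2 + 1e-12  # Hessian of f(B,S) is [[H,H],[H,H]], H = 2 XᵀX
    step = 1.0 / L
    B = np.zeros((p, k))
    S = np.zeros((p, k))
    Bm, Sm = B.copy(), S.copy()  # momentum extrapolation point
    t_mom = 1.0
    obj = [dirty_objective(X, Y, B, S, lambda_b, lambda_s)]
    converged = False
    for _ in range(max_iter):
        G = 2.0 * (X.T @ (X @ (Bm + Sm) - Y))
        B_new = _prox_linf(Bm - step * G, step * lambda_b)
        S_new = _soft(Sm - step * G, step * lambda_s)
        f_new = dirty_objective(X, Y, B_new, S_new, lambda_b, lambda_s)
        if f_new > obj[-1] + 1e-15:
            # fall back to a guaranteed-descent step from the last iterate
            G = 2.0 * (X.T @ (X @ (B + S) - Y))
            B_new = _prox_linf(B - step * G, step * lambda_b)
            S_new = _soft(S - step * G, step * lambda_s)
            f_new = dirty_objective(X, Y, B_new, S_new, lambda_b, lambda_s)
            t_mom = 1.0
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        Bm = B_new + (t_mom - 1.0) / t_next * (B_new - B)
        Sm = S_new + (t_mom - 1.0) / t_next * (S_new - S)
        t_mom = t_next
        gap = obj[-1] - f_new
        B, S = B_new, S_new
        obj.append(min(f_new, obj[-1]))
        if 0 <= gap <= tol * max(1.0, abs(obj[-1])):
            converged = True
            break
    if not converged:
        warnings.warn("dirty-model solver did not converge", stacklevel=2)
    return DirtyModel(B=B, S=S, lambda_b=lambda_b, lambda_s=lambda_s,
                      tasks=tuple(tasks), converged=converged, objective=obj)


def default_lambda_grid(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Log-spaced penalty grid anchored at the all-zero-solution scale."""
    lam_max = 2.0 * np.max(np.abs(X.T @ Y)) if X.size else 1.0
    return lam_max * np.array([0.01, 0.05, 0.2, 0.5])


# ---------------------------------------------------------------------------
# cross-validated decoding


@dataclass
class DecodeResult:
    accuracy: dict[tuple[str, str], float]      # (epoch, task) -> proportion
    weights: dict[tuple[str, str], np.ndarray]  # (epoch, task) -> feature map
    lambdas: dict[str, tuple[float, float]]     # epoch -> (lambda_b, lambda_s)
    balanced_index: np.ndarray
    fold_of_trial: np.ndarray
    oof_predictions: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    bootstrap_percentile: dict[tuple[str, str], float] = field(default_factory=dict)


def _stratified_folds(trials: pd.DataFrame, idx: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Fold id per balanced trial, stratified by outcome × stimulus side."""
    fold = np.empty(len(idx), dtype=int)
    sub = trials.iloc[idx]
    strata = sub["outcome"].astype(str) + "/" + sub["stimulus_side"].astype(str)
    for s in strata.unique():
        pos = np.flatnonzero(strata.to_numpy() == s)
        rng.shuffle(pos)
        fold[pos] = np.arange(len(pos)) % n_folds
    return fold


def _zscore_train(F_tr, F_te):
    mu = F_tr.mean(axis=0)
    sd = F_tr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (F_tr - mu) / sd, (F_te - mu) / sd


def _select_lambdas(F, Y, rng, grid_b=None, grid_s=None, inner_folds=3):
    """Inner grid search maximising mean CV accuracy over both tasks.

    Ties resolve toward the largest total penalty (the sparsest model).
    """
    if grid_b is None:
        grid_b = default_lambda_grid(F, Y)
    if grid_s is None:
        grid_s = default_lambda_grid(F, Y)
    n = len(F)
    fold = rng.permutation(n) % inner_folds
    best = None
    for lb in grid_b:
        for ls in grid_s:
            correct = total = 0
            for f in range(inner_folds):
                te = fold == f
                if te.all() or (~te).all():
                    continue
                Ftr, Fte = _zscore_train(F[~te], F[te])
                model = fit_dirty_model(Ftr, Y[~te], lb, ls, max_iter=500)
                correct += np.sum(model.predict(Fte) == Y[te])
                total += Y[te].size
            acc = correct / max(total, 1)
            key = (acc, lb + ls)
            if best is None or key > best[0]:
                best = (key, (float(lb), float(ls)))
    return best[1]


def crossval_decode(
    stack: ImagingStack,
    trials: pd.DataFrame,
    epochs: EpochRegistry = DEFAULT_EPOCHS,
    tasks: tuple[str, ...] = TASKS,
    n_folds: int = 5,
    seed: int = 0,
    downsample: int = 1,
    lambdas: tuple[float, float] | None = None,
    balanced_index: np.ndarray | None = None,
    fold_assignment: np.ndarray | None = None,
    check_folds: bool = True,
) -> DecodeResult:
    """Balanced, stratified k-fold decoding accuracy per epoch and task.

    Features are z-scored with training-fold statistics; penalties are
    chosen per epoch by an inner 3-fold grid search on the training folds
    of the first outer fold (or fixed via ``lambdas``).  Accuracy pools
    out-of-fold predictions.
    """
    if balanced_index is None:
        balanced_index = balance_trials(trials, seed=seed)
    idx = balanced_index
    labels = {t: task_labels(trials.iloc[idx], t) for t in tasks}
    Y = np.column_stack([labels[t] for t in tasks])
    rng = np.random.default_rng(seed)
    if fold_assignment is None:
        fold = _stratified_folds(trials, idx, n_folds, rng)
    else:
        fold = np.asarray(fold_assignment)
    if check_folds:
        for f in range(n_folds):
            for j, t in enumerate(tasks):
                if len(np.unique(Y[fold == f, j])) < 2:
                    raise ValueError(f"fold {f} holds a single class for task {t!r}")

    result = DecodeResult(accuracy={}, weights={}, lambdas={},
                          balanced_index=idx, fold_of_trial=fold)
    for epoch in epochs.names():
        F = featurize_epoch(stack, epochs[epoch], idx, downsample=downsample)
        if lambdas is None:
            tr0 = fold != 0
            Ftr, _ = _zscore_train(F[tr0], F[tr0])
            lam = _select_lambdas(Ftr, Y[tr0], np.random.default_rng(seed + 7))
        else:
            lam = lambdas
        result.lambdas[epoch] = lam
        pred = np.empty_like(Y)
        for f in range(n_folds):
            te = fold == f
            Ftr, Fte = _zscore_train(F[~te], F[te])
            model = fit_dirty_model(Ftr, Y[~te], *lam)
            pred[te] = model.predict(Fte)
        Fz, _ = _zscore_train(F, F)
        full = fit_dirty_model(Fz, Y, *lam)
        for j, t in enumerate(tasks):
            result.accuracy[(epoch, t)] = float(np.mean(pred[:, j] == Y[:, j]))
            result.weights[(epoch, t)] = full.W[:, j]
            result.oof_predictions[(epoch, t)] = pred[:, j]
    return result


def bootstrap_significance(
    stack: ImagingStack,
    trials: pd.DataFrame,
    epochs: EpochRegistry = DEFAULT_EPOCHS,
    tasks: tuple[str, ...] = TASKS,
    n_boot: int = 1000,
    n_folds: int = 5,
    seed: int = 0,
    downsample: int = 1,
    lambdas: tuple[float, float] | None = None,
    mode: str = "resample",
) -> DecodeResult:
    """Percentile of the observed accuracy in a randomised-label null.

    Each draw re-runs the full balanced cross-validation with labels
    randomised within the balanced subset — sampled i.i.d. with
    replacement from the empirical labels (``mode="resample"``) or
    permuted (``mode="permute"``).  The percentile counts strictly
    smaller null accuracies, so with one draw it is 0 or 100.
    """
    if mode not in ("resample", "permute"):
        raise ValueError("mode must be 'resample' or 'permute'")
    observed = crossval_decode(
        stack, trials, epochs, tasks, n_folds, seed, downsample, lambdas)
    # null draws reuse the observed balanced subset, fold layout and
    # per-epoch penalties; only the labels are randomised
    per_epoch = (observed.lambdas if lambdas is None
                 else {e: lambdas for e in epochs.names()})
    idx = observed.balanced_index
    fold = observed.fold_of_trial
    rng = np.random.default_rng([seed, 0xB007])
    null = {key: np.empty(n_boot) for key in observed.accuracy}
    for b in range(n_boot):
        shuffled = trials.copy()
        sub = trials.iloc[idx]
        for col in ("stimulus_side", "first_lick_side"):
            vals = sub[col].to_numpy()
            if mode == "resample":
                new = rng.choice(vals, size=len(vals), replace=True)
            else:
                new = rng.permutation(vals)
            shuffled.iloc[idx, shuffled.columns.get_loc(col)] = new
        for epoch in epochs.names():
            res_b = crossval_decode(
                stack, shuffled, EpochRegistry({epoch: epochs[epoch]}),
                tasks, n_folds, seed=seed + 1 + b, downsample=downsample,
                lambdas=per_epoch[epoch], balanced_index=idx,
                fold_assignment=fold, check_folds=False)
            for t in tasks:
                null[(epoch, t)][b] = res_b.accuracy[(epoch, t)]
    for key, obs in observed.accuracy.items():
        observed.bootstrap_percentile[key] = float(
            100.0 * np.mean(null[key] < obs))
    return observed


@dataclass
class CrossConditionResult:
    predicted_contra: dict[tuple[str, str], float]  # (condition, stimulus_side)
    n_trials: dict[tuple[str, str], int]
    task: str
    epoch: str


def cross_condition_test(
    stack: ImagingStack,
    trials: pd.DataFrame,
    epoch_name: str = "late_delay",
    task: str = "stimulus_side",
    epochs: EpochRegistry = DEFAULT_EPOCHS,
    opto_pool: tuple[str, ...] = ("baseline", "visual", "delay"),
    n_folds: int = 5,
    seed: int = 0,
    downsample: int = 1,
    lambdas: tuple[float, float] | None = None,
) -> CrossConditionResult:
    """Cross-condition generalisation of a late-delay stimulus decoder.

    A dirty model is trained on balanced opto-off trials; opto-off test
    proportions come from out-of-fold predictions, and stimulated trials
    (pooled over early stimulation epochs) are scored with the model
    refit on all balanced opto-off data.  Reported per (condition,
    stimulus side): the fraction of trials predicted "contra".
    """
    off_pos = np.flatnonzero((trials["opto"] == "off").to_numpy())
    opto_pos = np.flatnonzero(
        trials["opto"].isin(opto_pool).to_numpy()
        & (trials["outcome"] != "omission").to_numpy())
    if len(opto_pos) == 0:
        raise ValueError("no optogenetic trials in the pooled epochs")
    # balance within opto-off trials, expressed as stack-aligned positions
    bal_local = balance_trials(
        trials.iloc[off_pos].reset_index(drop=True), seed=seed)
    idx_off = off_pos[bal_local]
    window = EpochRegistry({epoch_name: epochs[epoch_name]})
    res = crossval_decode(
        stack, trials, window, (task,), n_folds, seed, downsample, lambdas,
        balanced_index=idx_off)
    # refit on the full balanced opto-off set for the transfer test
    F_off = featurize_epoch(stack, epochs[epoch_name],
                            idx_off, downsample=downsample)
    mu, sd = F_off.mean(axis=0), F_off.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    y_off = task_labels(trials.iloc[idx_off], task)[:, None]
    model = fit_dirty_model((F_off - mu) / sd, y_off, *res.lambdas[epoch_name])

    F_opto = featurize_epoch(stack, epochs[epoch_name], opto_pos,
                             downsample=downsample)
    pred_opto = model.predict((F_opto - mu) / sd)[:, 0]

    out = CrossConditionResult(predicted_contra={}, n_trials={},
                               task=task, epoch=epoch_name)
    oof = res.oof_predictions[(epoch_name, task)]
    sides_off = trials.iloc[idx_off]["stimulus_side"].to_numpy()
    sides_opto = trials.iloc[opto_pos]["stimulus_side"].to_numpy()
    for side in ("contra", "ipsi"):
        sel = sides_off == side
        out.predicted_contra[("opto_off", side)] = float(np.mean(oof[sel] > 0))
        out.n_trials[("opto_off", side)] = int(sel.sum())
        sel = sides_opto == side
        out.predicted_contra[("opto_on", side)] = float(np.mean(pred_opto[sel] > 0))
        out.n_trials[("opto_on", side)] = int(sel.sum())
    return out
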