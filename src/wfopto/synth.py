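"""Seeded synthetic widefield sessions for a delayed two-alternative task.

The generator emulates the statistical structure the downstream analyses
assume, at desk scale:

* 20 Hz frames over a per-trial window around visual-stimulus onset;
* a delayed-response trial: 500 ms lateralised stimulus, 1500 ms memory
  delay, then a response window in which the animal licks left or right;
* additive event-kernel pixel responses per predictor (stimulus side,
  licks per side), localised in disjoint ROI-like blobs;
* a late-delay "memory trace": a side-specific pixel template whose
  noisy projection drives the simulated choice;
* two optogenetic effect regimes — a global excitation of cortex and a
  local suppression of the stimulated hemisphere — applied as an
  epoch-level boxcar, plus a signed bias of the late-delay memory trace;
* Poisson lick trains whose rate is biased toward the chosen side in the
  response window;
* AR(1) body/eye nuisance traces coupled into every pixel, and i.i.d.
  Gaussian pixel noise.

All randomness flows from a single master seed through named substreams,
so perturbing one stage (e.g. the pixel noise) leaves the others
bit-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import (
    HEMISPHERES,
    ImagingStack,
    OPTO_EPOCH_ONSETS,
    ROI_LABELS,
    ROISet,
    validate_trial_table,
)

OPTO_REGIMES = ("none", "global_excite", "local_suppress")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic session.

    Amplitudes are in raw-fluorescence units on top of a baseline ``f0``;
    after ΔF/F they read directly as fractional change (f0 = 1).
    ``amplitude`` is the peak weight of the event beta maps (the temporal
    kernel has unit area, so the evoked ΔF/F transient peaks lower).

    The late-delay memory trace has a per-trial strength of ±1 (by
    stimulus side) in units of the template difference, jittered by
    ``memory_noise_sd``; the simulated choice follows the rendered trace
    plus downstream motor noise ``decision_noise_sd``.  The defaults
    (0.8 / 1.3) put task accuracy near the ~74% mice reach on this task
    while keeping the stimulus side decodable from the late delay even
    on error trials (errors arise mostly downstream of the trace).
    """

    n_pixels_y: int = 64
    n_pixels_x: int = 64
    frame_rate: float = 20.0
    n_trials: int = 200
    trial_window: tuple[float, float] = (-1.0, 3.0)
    stimulus_duration: float = 0.5
    delay_duration: float = 1.5
    response_duration: float = 0.5
    f0: float = 1.0
    amplitude: float = 0.2
    template_amplitude: float = 0.04
    opto_amplitude: float = 0.03
    opto_memory_bias: float = 0.03
    opto_duration: float = 1.0
    continuous_coupling: float = 0.02
    noise_sd: float = 0.02
    opto_regime: str = "none"
    opto_epochs: tuple[str, ...] = ("baseline",)
    opto_fraction: float = 0.3
    lick_rate_base: float = 1.0
    lick_rate_biased: float = 6.0
    opto_lick_rate_increment: float = 3.0
    omission_prob: float = 0.05
    memory_noise_sd: float = 0.8
    decision_noise_sd: float = 1.3
    kernel_rise: float = 0.05
    kernel_decay: float = 0.4
    seed: int = 0

    def __post_init__(self):
        for name in ("stimulus_duration", "delay_duration", "response_duration",
                     "opto_duration", "frame_rate", "f0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("lick_rate_base", "lick_rate_biased",
                     "opto_lick_rate_increment", "noise_sd",
                     "memory_noise_sd", "decision_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.opto_regime not in OPTO_REGIMES:
            raise ValueError(
                f"unknown opto_regime {self.opto_regime!r}; choose from {OPTO_REGIMES}")
        unknown = set(self.opto_epochs) - set(OPTO_EPOCH_ONSETS)
        if unknown:
            raise ValueError(f"unknown opto epochs: {sorted(unknown)}")
        if not 0.0 <= self.opto_fraction <= 1.0:
            raise ValueError("opto_fraction must lie in [0, 1]")
        if not 0.0 <= self.omission_prob < 1.0:
            raise ValueError("omission_prob must lie in [0, 1)")
        t0, t1 = self.trial_window
        if not (t0 <= -0.3 and t1 >= self.choice_end):
            raise ValueError("trial_window must contain [-0.3 s, choice end]")
        n = (t1 - t0) * self.frame_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("frame_rate x trial_window must give an integer frame count")

    # -- derived timing -------------------------------------------------
    @property
    def response_start(self) -> float:
        return self.stimulus_duration + self.delay_duration

    @property
    def choice_end(self) -> float:
        return self.response_start + self.response_duration

    @property
    def n_frames(self) -> int:
        t0, t1 = self.trial_window
        return int(round((t1 - t0) * self.frame_rate))

    @property
    def frame_times(self) -> np.ndarray:
        t0 = self.trial_window[0]
        return t0 + np.arange(self.n_frames) / self.frame_rate

    def frame_of(self, t: float) -> int:
        """Index of the frame whose start time is closest to ``t``."""
        return int(round((t - self.trial_window[0]) * self.frame_rate))

    def rng(self, stream: str) -> np.random.Generator:
        """Named independent substream of the master seed."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, zlib.crc32(stream.encode())]))

    def to_dict(self) -> dict:
        return asdict(self)


EVENT_PREDICTORS = ("stim_contra", "stim_ipsi", "lick_contra", "lick_ipsi")


@dataclass
class GroundTruth:
    """Generative parameters, kept so recovery can be scored exactly."""

    beta_maps: dict[str, np.ndarray]
    temporal_kernel: np.ndarray
    opto_effect_map: np.ndarray
    memory_template_contra: np.ndarray
    memory_template_ipsi: np.ndarray
    decision_noise_sd: float
    coupling_maps: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        tc = self.memory_template_contra.ravel()
        ti = self.memory_template_ipsi.ravel()
        nc, ni = np.linalg.norm(tc), np.linalg.norm(ti)
        if nc == 0 or ni == 0:
            raise ValueError("memory templates must be non-zero")
        cos = float(tc @ ti) / (nc * ni)
        if abs(cos) > 1 - 1e-9:
            raise ValueError("memory templates must be linearly independent")


@dataclass
class SimulatedSession:
    stack: ImagingStack
    trials: pd.DataFrame
    licks: pd.DataFrame
    continuous: dict[str, np.ndarray]
    truth: GroundTruth
    rois: ROISet
    config: SimConfig


# ---------------------------------------------------------------------------
# spatial layout

# fractional (y, x) centres within a hemisphere, loosely mimicking the
# posterior-to-anterior arrangement of dorsal-cortex areas
_ROI_CENTRES = {
    "V1": (0.78, 0.60),
    "Vlat": (0.80, 0.10),
    "Vmed": (0.97, 0.82),
    "PPC": (0.55, 0.35),
    "RS": (0.58, 0.82),
    "M1": (0.32, 0.30),
    "M2": (0.10, 0.65),
}


def _blob(ny: int, nx: int, cy: float, cx: float, sigma: float) -> np.ndarray:
    yy, xx = np.mgrid[0:ny, 0:nx]
    return np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))


def _roi_centre(config: SimConfig, label: str, hemi: str) -> tuple[float, float]:
    ny, nx = config.n_pixels_y, config.n_pixels_x
    fy, fx = _ROI_CENTRES[label]
    half = nx / 2.0
    cy = fy * (ny - 1)
    if hemi == "hemiOpto":  # left half of the grid
        cx = fx * (half - 1)
    else:
        cx = nx - 1 - fx * (half - 1)
    return cy, cx


def make_rois(config: SimConfig) -> ROISet:
    """Disjoint circular ROI masks, seven regions per hemisphere.

    The radius scales with the grid but is capped below half the
    smallest centre separation, so masks stay disjoint even on very
    small test grids (degenerating to single-pixel ROIs).
    """
    ny, nx = config.n_pixels_y, config.n_pixels_x
    centres = [_roi_centre(config, label, "hemiOpto") for label in ROI_LABELS]
    d_min = min(
        np.hypot(a[0] - b[0], a[1] - b[1])
        for i, a in enumerate(centres) for b in centres[i + 1:])
    radius = min(max(1.5, 0.07 * min(ny, nx / 2)), 0.49 * d_min)
    yy, xx = np.mgrid[0:ny, 0:nx]
    masks = {}
    for hemi in HEMISPHERES:
        for label in ROI_LABELS:
            cy, cx = _roi_centre(config, label, hemi)
            mask = ((yy - cy) ** 2 + (xx - cx) ** 2) <= radius**2
            if not mask.any():  # guarantee non-empty at degenerate radii
                mask[int(round(cy)), int(round(cx))] = True
            masks[f"{label}_{hemi}"] = mask
    return ROISet(masks)


def temporal_kernel(config: SimConfig) -> np.ndarray:
    """Causal difference-of-exponentials calcium kernel, unit area.

    Rise/decay time constants default to 50 ms / 400 ms; truncated at 2 s.
    """
    n = int(round(2.0 * config.frame_rate))
    t = np.arange(n) / config.frame_rate
    k = np.exp(-t / config.kernel_decay) - np.exp(-t / config.kernel_rise)
    k[k < 0] = 0.0
    return k / k.sum()


def _hemi_bump(config: SimConfig, hemi: str) -> np.ndarray:
    """Smooth positive bump covering one hemisphere, zero in the other."""
    ny, nx = config.n_pixels_y, config.n_pixels_x
    half = nx // 2
    sl = slice(0, half) if hemi == "hemiOpto" else slice(half, nx)
    bump = np.zeros((ny, nx))
    cy = (ny - 1) / 2.0
    cx = (sl.start + sl.stop - 1) / 2.0
    full = _blob(ny, nx, cy, cx, sigma=min(ny, half) / 3.0)
    bump[:, sl] = full[:, sl]
    return bump


def make_ground_truth(config: SimConfig) -> GroundTruth:
    """Beta maps, kernel, opto map and memory templates for one session.

    Event beta maps sit in disjoint blobs centred on ROIs: contra/ipsi
    stimulus responses in V1 of the contralateral-to-stimulus hemisphere,
    lick responses in M1 of the hemisphere driving the movement.  Memory
    templates occupy M2/PPC — the contra template in hemisphere_Opto so
    that local suppression of that hemisphere erodes the contra trace.
    """
    ny, nx = config.n_pixels_y, config.n_pixels_x
    sigma = max(1.5, 0.07 * min(ny, nx / 2))
    amp = config.amplitude

    def blob_at(label, hemi, amplitude):
        cy, cx = _roi_centre(config, label, hemi)
        return amplitude * _blob(ny, nx, cy, cx, sigma)

    beta_maps = {
        "stim_contra": blob_at("V1", "hemiOpto", amp),
        "stim_ipsi": blob_at("V1", "hemiControl", amp),
        "lick_contra": blob_at("M1", "hemiOpto", amp),
        "lick_ipsi": blob_at("M1", "hemiControl", amp),
    }
    ta = config.template_amplitude
    memory_contra = blob_at("M2", "hemiOpto", ta) + blob_at("PPC", "hemiOpto", ta)
    memory_ipsi = blob_at("M2", "hemiControl", ta) + blob_at("PPC", "hemiControl", ta)

    if config.opto_regime == "none":
        opto_map = np.zeros((ny, nx))
    elif config.opto_regime == "global_excite":
        # pronounced, grid-wide increase, strongest over the stimulated side
        opto_map = config.opto_amplitude * (
            0.3 + 0.7 * _hemi_bump(config, "hemiOpto"))
    elif config.opto_regime == "local_suppress":
        # brief decrease confined to the stimulated hemisphere
        opto_map = -config.opto_amplitude * _hemi_bump(config, "hemiOpto")
    else:  # pragma: no cover - guarded by SimConfig
        raise ValueError(f"unknown opto_regime {config.opto_regime!r}")

    c = config.continuous_coupling
    rng = config.rng("truth")
    coupling = {
        "body": c * (0.5 + 0.5 * rng.random((ny, nx))),
        "eye": c * 0.5 * (0.5 + 0.5 * rng.random((ny, nx))),
    }
    return GroundTruth(
        beta_maps=beta_maps,
        temporal_kernel=temporal_kernel(config),
        opto_effect_map=opto_map,
        memory_template_contra=memory_contra,
        memory_template_ipsi=memory_ipsi,
        decision_noise_sd=config.decision_noise_sd,
        coupling_maps=coupling,
    )


# ---------------------------------------------------------------------------
# trial schedule and behaviour


def make_trial_schedule(config: SimConfig) -> pd.DataFrame:
    """Stimulus sides and optogenetic tags, before behaviour is simulated."""
    rng = config.rng("schedule")
    n = config.n_trials
    sides = np.where(rng.random(n) < 0.5, "contra", "ipsi")
    opto = np.full(n, "off", dtype=object)
    if config.opto_regime != "none" and config.opto_fraction > 0:
        is_opto = rng.random(n) < config.opto_fraction
        epochs = rng.choice(list(config.opto_epochs), size=n)
        opto[is_opto] = epochs[is_opto]
    return pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "stimulus_side": sides,
            "opto": opto,
            "session_id": "sim",
        }
    )


def _opto_window(config: SimConfig, epoch: str) -> tuple[float, float]:
    onset = OPTO_EPOCH_ONSETS[epoch]
    return onset, onset + config.opto_duration


def simulate_continuous(config: SimConfig) -> dict[str, np.ndarray]:
    """AR(1) body and eye movement traces, min-max normalised to [0, 1].

    Shaped (n_frames, n_trials); the AR process runs continuously across
    the concatenated trials.
    """
    rng = config.rng("continuous")
    out = {}
    n = config.n_frames * config.n_trials
    for name, rho in (("body", 0.95), ("eye", 0.85)):
        e = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = e[0]
        for i in range(1, n):
            x[i] = rho * x[i - 1] + np.sqrt(1 - rho**2) * e[i]
        x = (x - x.min()) / (x.max() - x.min())
        out[name] = x.reshape(config.n_trials, config.n_frames).T.copy()
    return out


def assign_outcomes(
    trials: pd.DataFrame,
    stack: ImagingStack,
    truth: GroundTruth,
    config: SimConfig,
) -> pd.DataFrame:
    """Derive the intended choice of each trial from its late-delay pattern.

    The decision variable is the late-delay mean pixel pattern (above the
    baseline fluorescence f0) projected onto the difference of the two
    memory templates, scaled so a noiseless contra (ipsi) trial scores
    +1 (-1), plus Gaussian decision noise.  Positive values mean a
    contraversive choice.  Omissions are drawn independently with a
    fixed probability.
    """
    d = (truth.memory_template_contra - truth.memory_template_ipsi).ravel()
    denom = float(d @ d)
    if denom == 0:
        raise ValueError("memory templates are identical: degenerate projection")
    t = stack.frame_times
    late = (t >= 1.2) & (t < 1.9)
    pattern = (
        stack.data[:, :, late, :].mean(axis=2) - config.f0
    ).reshape(-1, stack.n_trials)
    v = 2.0 * (pattern.T @ d) / denom
    rng = config.rng("outcomes")
    v = v + config.decision_noise_sd * rng.standard_normal(len(v))
    out = trials.copy()
    out["decision_variable"] = v
    out["choice_side"] = np.where(v > 0, "contra", "ipsi")
    out["intended_omission"] = rng.random(len(v)) < config.omission_prob
    return out


def simulate_licks(trials: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Piecewise-homogeneous Poisson lick trains per side.

    Within the response window only the chosen side licks, at
    ``lick_rate_biased`` (the spout is two-sided but the animal commits);
    after the response window both sides lick at ``lick_rate_base``.
    Optogenetic trials add a contraversive (global excitation) or
    ipsiversive (local suppression) rate increment during the stimulation
    boxcar.  Intended omissions produce no response-window licks.

    ``trials`` needs ``choice_side`` / ``intended_omission`` columns (from
    :func:`assign_outcomes`); without them the stimulus side is used as the
    biased side and no omissions occur.
    """
    rng = config.rng("licks")
    t0, t1 = config.trial_window
    rs, re = config.response_start, config.choice_end
    rows = []

    def draw(trial_id, side, rate, a, b):
        if rate == 0 or b <= a:
            return
        n = rng.poisson(rate * (b - a))
        for time in np.sort(rng.uniform(a, b, size=n)):
            rows.append((trial_id, float(time), side))

    for trial in trials.itertuples():
        biased = getattr(trial, "choice_side", trial.stimulus_side)
        omit = bool(getattr(trial, "intended_omission", False))
        if not omit:
            draw(trial.trial_id, biased, config.lick_rate_biased, rs, re)
        for side in ("contra", "ipsi"):
            draw(trial.trial_id, side, config.lick_rate_base, re, t1)
        if trial.opto != "off" and config.opto_lick_rate_increment > 0:
            a, b = _opto_window(config, trial.opto)
            side = ("contra" if config.opto_regime == "global_excite" else "ipsi")
            if config.opto_regime != "none":
                draw(trial.trial_id, side, config.opto_lick_rate_increment,
                     max(a, t0), min(b, rs if omit else b))
    licks = pd.DataFrame(rows, columns=["trial_id", "time", "side"])
    return licks.sort_values(["trial_id", "time"], kind="stable").reset_index(drop=True)


def finalize_outcomes(
    trials: pd.DataFrame, licks: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Label each trial from its actual first response-window lick.

    A trial with no lick in the response window is an omission; otherwise
    the outcome compares the first lick side with the stimulus side.
    """
    out = trials.copy()
    out["first_lick_side"] = pd.NA
    out["first_lick_time"] = np.nan
    out["outcome"] = "omission"
    rs, re = config.response_start, config.choice_end
    window = licks[(licks["time"] >= rs) & (licks["time"] < re)]
    first = window.groupby("trial_id").first()
    for trial_id, row in first.iterrows():
        i = out.index[out["trial_id"] == trial_id][0]
        out.loc[i, "first_lick_side"] = row["side"]
        out.loc[i, "first_lick_time"] = row["time"]
        out.loc[i, "outcome"] = (
            "correct" if row["side"] == out.loc[i, "stimulus_side"] else "error")
    out["first_lick_time"] = out["first_lick_time"].where(
        out["outcome"] != "omission", np.nan)
    return out


# ---------------------------------------------------------------------------
# rendering


def _event_signal(
    onsets_per_trial: list[np.ndarray], kernel: np.ndarray, config: SimConfig
) -> np.ndarray:
    """Convolve per-trial event impulses with the kernel -> (frames, trials)."""
    nf, nt = config.n_frames, config.n_trials
    sig = np.zeros((nf, nt))
    for j, onsets in enumerate(onsets_per_trial):
        if len(onsets) == 0:
            continue
        imp = np.zeros(nf)
        for t in onsets:
            k = config.frame_of(t)
            if 0 <= k < nf:
                imp[k] += 1.0
        sig[:, j] = np.convolve(imp, kernel)[:nf]
    return sig


def _boxcar(config: SimConfig, start: float, end: float) -> np.ndarray:
    t = config.frame_times
    return ((t >= start) & (t < end)).astype(float)


def render_fluorescence(
    truth: GroundTruth,
    trials: pd.DataFrame,
    licks: pd.DataFrame | None,
    continuous: dict[str, np.ndarray],
    config: SimConfig,
) -> ImagingStack:
    """Raw fluorescence stack: baseline + additive components + noise.

    F(y, x, f, j) = f0
      + sum_events beta_map * (impulses (*) kernel)
      + template boxcar during the late delay (side-specific, plus the
        signed optogenetic memory bias on stimulated trials)
      + opto_effect_map during the stimulation boxcar
      + coupling_map * continuous traces
      + N(0, noise_sd).

    The pixel-noise substream depends only on the master seed, so the
    same session rendered with and without licks shares its noise.
    """
    nf, nt = config.n_frames, config.n_trials
    ny, nx = config.n_pixels_y, config.n_pixels_x
    F = np.full((ny, nx, nf, nt), config.f0, dtype=np.float64)

    def add(pixmap, sig):
        F[...] += pixmap[:, :, None, None] * sig[None, None, :, :]

    contra = (trials["stimulus_side"] == "contra").to_numpy()
    stim_on = np.array([0.0])
    none = np.array([])
    add(truth.beta_maps["stim_contra"],
        _event_signal([stim_on if c else none for c in contra],
                      truth.temporal_kernel, config))
    add(truth.beta_maps["stim_ipsi"],
        _event_signal([none if c else stim_on for c in contra],
                      truth.temporal_kernel, config))

    if licks is not None and len(licks):
        for side in ("contra", "ipsi"):
            sub = licks[licks["side"] == side]
            onsets = [
                sub.loc[sub["trial_id"] == tid, "time"].to_numpy()
                for tid in trials["trial_id"]
            ]
            add(truth.beta_maps[f"lick_{side}"],
                _event_signal(onsets, truth.temporal_kernel, config))

    # late-delay memory trace: per-trial signed strength m along the
    # template-difference axis (+1 contra, -1 ipsi), jittered trial to
    # trial, and biased by optogenetic stimulation
    late = _boxcar(config, 1.2, 1.9)
    opto_on = (trials["opto"] != "off").to_numpy()
    bias = config.opto_memory_bias / max(config.template_amplitude, 1e-12)
    sign = {"none": 0.0, "global_excite": 1.0, "local_suppress": -1.0}[config.opto_regime]
    m = np.where(contra, 1.0, -1.0)
    if config.memory_noise_sd > 0:
        m = m + config.memory_noise_sd * config.rng("memory").standard_normal(nt)
    m = m + sign * bias * opto_on
    add(truth.memory_template_contra, late[:, None] * (0.5 + 0.5 * m)[None, :])
    add(truth.memory_template_ipsi, late[:, None] * (0.5 - 0.5 * m)[None, :])

    if (truth.opto_effect_map != 0).any():
        sig = np.zeros((nf, nt))
        for j, epoch in enumerate(trials["opto"]):
            if epoch != "off":
                a, b = _opto_window(config, epoch)
                sig[:, j] = _boxcar(config, a, b)
        add(truth.opto_effect_map, sig)

    for name, trace in continuous.items():
        add(truth.coupling_maps[name], trace)

    if config.noise_sd > 0:
        rng = config.rng("noise")
        F += config.noise_sd * rng.standard_normal(F.shape)

    if not np.isfinite(F).all():
        raise FloatingPointError("non-finite fluorescence generated")
    return ImagingStack(F.astype(np.float32), config.frame_times, kind="raw")


def generate_session(config: SimConfig) -> SimulatedSession:
    """Full seeded session: schedule, stack, behaviour, ground truth.

    Licks respond to the simulated choice, and the choice is read from the
    rendered late-delay activity, so the stack is rendered in two additive
    passes: everything but licks first (choices are taken from it), then
    the lick-evoked component is added.  Lick responses are causal and
    start after the late delay, so the second pass cannot alter choices.
    """
    truth = make_ground_truth(config)
    schedule = make_trial_schedule(config)
    continuous = simulate_continuous(config)
    stack0 = render_fluorescence(truth, schedule, None, continuous, config)
    with_choice = assign_outcomes(schedule, stack0, truth, config)
    licks = simulate_licks(with_choice, config)
    trials = finalize_outcomes(with_choice, licks, config)

    if len(licks):
        lick_component = _render_lick_component(truth, trials, licks, config)
        data = stack0.data.astype(np.float64) + lick_component
        stack = ImagingStack(data.astype(np.float32), config.frame_times, kind="raw")
    else:
        stack = stack0

    validate_trial_table(trials)
    return SimulatedSession(
        stack=stack,
        trials=trials,
        licks=licks,
        continuous=continuous,
        truth=truth,
        rois=make_rois(config),
        config=config,
    )


def expected_lag_block(
    truth: GroundTruth,
    config: SimConfig,
    predictor: str,
    lags: np.ndarray,
) -> np.ndarray:
    """True lag × pixel response of one event predictor, in ΔF/F units.

    This is the generative counterpart of the time-expanded regression
    coefficients: the kernel-weighted beta map, plus — for the stimulus
    predictors — the late-delay memory template, and — for the opto
    predictor — the stimulation boxcar map and the signed memory bias.
    Amplitudes are divided by the baseline fluorescence ``f0`` because
    the regression target is ΔF/F.
    """
    lags = np.asarray(lags)
    kernel = truth.temporal_kernel
    npix = config.n_pixels_y * config.n_pixels_x
    block = np.zeros((len(lags), npix))
    kvals = np.where(lags < len(kernel), kernel[np.minimum(lags, len(kernel) - 1)], 0.0)

    def add(time_profile, pixmap):
        block[:] += np.outer(time_profile, pixmap.ravel() / config.f0)

    if predictor in ("stim_contra", "stim_ipsi", "lick_contra", "lick_ipsi"):
        add(kvals, truth.beta_maps[predictor])
    if predictor in ("stim_contra", "stim_ipsi"):
        t = lags / config.frame_rate  # event onset is stimulus onset
        late = ((t >= 1.2) & (t < 1.9)).astype(float)
        template = (truth.memory_template_contra if predictor == "stim_contra"
                    else truth.memory_template_ipsi)
        add(late, template)
    if predictor == "opto":
        if len(config.opto_epochs) != 1:
            raise ValueError("lag profile defined for a single opto epoch only")
        onset = OPTO_EPOCH_ONSETS[config.opto_epochs[0]]
        t = lags / config.frame_rate
        box = ((t >= 0) & (t < config.opto_duration)).astype(float)
        add(box, truth.opto_effect_map)
        late = ((onset + t >= 1.2) & (onset + t < 1.9)).astype(float)
        sign = {"none": 0.0, "global_excite": 1.0,
                "local_suppress": -1.0}[config.opto_regime]
        bias = sign * config.opto_memory_bias / max(config.template_amplitude, 1e-12)
        diff = 0.5 * (truth.memory_template_contra - truth.memory_template_ipsi)
        add(bias * late, diff)
    return block


def recovery_spatial_correlation(
    truth: GroundTruth,
    config: SimConfig,
    predictors,
    beta: np.ndarray,
    pixel_idx: np.ndarray,
) -> dict[str, float]:
    """Spatial correlation between fitted and generative event responses.

    For each event predictor, both the fitted lag × pixel coefficients
    and the ground-truth block (:func:`expected_lag_block`) are projected
    onto the predictor's own time course — the calcium kernel for
    stimulus and lick events, the stimulation boxcar for the opto
    predictor — giving one spatial map each; the Pearson correlation of
    the two maps over pixels is returned per predictor.
    """
    out = {}
    for p in predictors:
        if p.kind != "event":
            continue
        true = expected_lag_block(truth, config, p.name, p.lags)[:, pixel_idx]
        est = beta[p.columns, :]
        if p.name == "opto":
            t = p.lags / config.frame_rate
            w = ((t >= 0) & (t < config.opto_duration)).astype(float)
        else:
            k = truth.temporal_kernel
            w = np.where(p.lags < len(k), k[np.minimum(p.lags, len(k) - 1)], 0.0)
        m_true = w @ true
        m_est = w @ est
        out[p.name] = float(np.corrcoef(m_est, m_true)[0, 1])
    return out


def _render_lick_component(truth, trials, licks, config) -> np.ndarray:
    ny, nx = config.n_pixels_y, config.n_pixels_x
    out = np.zeros((ny, nx, config.n_frames, config.n_trials))
    for side in ("contra", "ipsi"):
        sub = licks[licks["side"] == side]
        onsets = [
            sub.loc[sub["trial_id"] == tid, "time"].to_numpy()
            for tid in trials["trial_id"]
        ]
        sig = _event_signal(onsets, truth.temporal_kernel, config)
        out += truth.beta_maps[f"lick_{side}"][:, :, None, None] * sig[None, None]
    return out
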