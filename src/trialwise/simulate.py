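"""Ground-truth synthetic EEG/behavior generator.

Emulates the study design the pipeline was built for: a visual search task
with 1920 trials per participant in 5 blocks, a 2 (perceptual certainty:
blurred vs. intact) x 4 (deviant position: left/right/top/bottom) factor
crossing, 40 participants, and two ERP components — a fronto-central negative
N2 (250-350 ms) and a centro-parietal positive P3b (400-550 ms) — with
by-participant and by-item random intercepts and slopes on their amplitudes.
Component magnitudes default to the reference-magnitude regime of visual-search ERP studies (intercepts
-3.42 / +4.20 uV, certainty effects -0.87 / +1.17 uV).  Noise is temporally
pink (1/f) and spatially smoothed across channels, because the cluster
permutation machinery must be calibrated under realistic spatio-temporal
correlation.  Reaction times follow a linear model on the simulated component
amplitudes (gaussian, truncated at the 2 s response timeout -> miss trials);
accuracy is Bernoulli through a logistic link.

Everything is deterministic under a fixed seed, and the generating parameters
are returned alongside the data for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import ChannelLayout, RawRecording
from .montage import N2_ROI, P3B_ROI, standard_layout
from .preprocessing import EpochSet

__all__ = [
    "ComponentSpec",
    "BehaviorSpec",
    "GroundTruth",
    "SimulatedSession",
    "simulate_design",
    "simulate_epochs",
    "simulate_behavior",
    "simulate_session",
    "simulate_continuous_recording",
    "simulate_null_condition_averages",
    "grid_layout",
]

CERTAINTY_LEVELS = ("blurred", "intact")
POSITION_LEVELS = ("left", "right", "top", "bottom")


@dataclass
class ComponentSpec:
    """One ERP component template and its amplitude model (all uV)."""

    name: str
    roi: tuple[str, ...]
    window_ms: tuple[float, float]
    amplitude: float                       # grand-mean amplitude
    certainty_effect: float = 0.0          # intact - blurred (sliding diff)
    position_effect: float = 0.0           # right - left
    subject_intercept_sd: float = 0.0
    subject_slope_sd: float = 0.0          # slope of the certainty effect
    item_intercept_sd: float = 0.0
    item_slope_sd: float = 0.0
    spatial_falloff: float = 0.5           # gaussian width around the ROI


@dataclass
class BehaviorSpec:
    """RT and accuracy model; reference-magnitude defaults.

    RT (ms) = intercept + certainty effect + per-component slopes x amplitude
    + subject/item effects + gaussian noise, truncated at the timeout (miss).
    Accuracy is Bernoulli with a logistic linear predictor.
    """

    rt_intercept: float = 470.0
    rt_certainty_effect: float = -30.0     # intact - blurred, ms
    rt_position_effect: float = 0.0
    rt_component_slopes: dict = field(default_factory=dict)  # name -> ms/uV
    rt_subject_intercept_sd: float = 50.0
    rt_subject_slope_sd: float = 15.0
    rt_item_intercept_sd: float = 10.0
    rt_residual_sd: float = 90.0
    timeout_ms: float = 2000.0
    acc_intercept: float = 3.31            # logit
    acc_certainty_effect: float = 0.96
    acc_position_effect: float = 0.32
    acc_subject_sd: float = 0.89
    acc_item_sd: float = 0.4


def _default_components() -> list[ComponentSpec]:
    return [
        ComponentSpec(
            name="N2", roi=N2_ROI, window_ms=(250.0, 350.0),
            amplitude=-3.42, certainty_effect=-0.87, position_effect=0.31,
            subject_intercept_sd=1.91, subject_slope_sd=0.48,
            item_intercept_sd=0.41, item_slope_sd=0.30,
        ),
        ComponentSpec(
            name="P3b", roi=P3B_ROI, window_ms=(400.0, 550.0),
            amplitude=4.20, certainty_effect=1.17, position_effect=0.0,
            subject_intercept_sd=3.17, subject_slope_sd=0.53,
            item_intercept_sd=0.59, item_slope_sd=0.59,
        ),
    ]


@dataclass
class GroundTruth:
    """Simulation parameters; defaults are the study's design."""

    n_participants: int = 40
    n_trials: int = 1920
    n_blocks: int = 5
    n_items: int = 4
    sampling_rate: float = 500.0
    epoch_window_ms: tuple[float, float] = (-200.0, 800.0)
    components: list[ComponentSpec] = field(default_factory=_default_components)
    behavior: BehaviorSpec = field(default_factory=BehaviorSpec)
    noise_sd: float = 1.0                  # uV, per channel/sample
    pink_fraction: float = 0.7             # share of 1/f noise vs. white
    spatial_smoothing: float = 0.4         # mixing width on the unit sphere
    artifact_rate: float = 0.0

    def cell_count(self) -> int:
        return len(CERTAINTY_LEVELS) * len(POSITION_LEVELS)


@dataclass
class SimulatedSession:
    epochs: list[EpochSet]
    behavior: list[pd.DataFrame]
    truth: dict


# ---------------------------------------------------------------------------
# Design

def simulate_design(
    gt: GroundTruth, seed: int | np.random.Generator = 0
) -> list[pd.DataFrame]:
    """Balanced randomized factor crossing per participant, with block labels.

    Each participant receives n_trials rows in randomized order with the
    certainty x position crossing (and item assignment) exactly balanced;
    trial_index is strictly increasing (recording order).
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    cells = gt.cell_count()
    if gt.n_trials % cells:
        nearest = max(cells, round(gt.n_trials / cells) * cells)
        raise ValueError(
            f"n_trials={gt.n_trials} not divisible by the {cells}-cell design; "
            f"nearest valid value: {nearest}"
        )
    reps = gt.n_trials // cells
    base = pd.DataFrame(
        [
            (c, p)
            for c in CERTAINTY_LEVELS
            for p in POSITION_LEVELS
            for _ in range(reps)
        ],
        columns=["perceptual_certainty", "deviant_position"],
    )
    items = np.array(
        [f"I{1 + i % gt.n_items}" for i in range(gt.n_trials)]
    )
    tables = []
    for p in range(gt.n_participants):
        order = rng.permutation(gt.n_trials)
        df = base.iloc[order].reset_index(drop=True)
        df["item_id"] = items[rng.permutation(gt.n_trials)]
        df["participant_id"] = f"P{p + 1:02d}"
        df["trial_index"] = np.arange(1, gt.n_trials + 1)
        df["block"] = 1 + (
            np.arange(gt.n_trials) * gt.n_blocks // gt.n_trials
        )
        tables.append(
            df[
                [
                    "participant_id", "trial_index", "block",
                    "perceptual_certainty", "deviant_position", "item_id",
                ]
            ]
        )
    return tables


def _certainty_code(values: pd.Series) -> np.ndarray:
    # sliding-difference code for 2 levels: blurred -> -1/2, intact -> +1/2
    return np.where(values.astype(str) == "intact", 0.5, -0.5)


def _position_code(values: pd.Series) -> np.ndarray:
    v = values.astype(str)
    return np.where(v == "right", 0.5, np.where(v == "left", -0.5, 0.0))


# ---------------------------------------------------------------------------
# EEG epochs

def _spatial_weights(comp: ComponentSpec, layout: ChannelLayout,
                     channels: Sequence[str]) -> np.ndarray:
    roi_pos = np.array([layout.position_of(c) for c in comp.roi])
    w = np.empty(len(channels))
    for i, ch in enumerate(channels):
        d = np.linalg.norm(roi_pos - layout.position_of(ch), axis=1).min()
        w[i] = np.exp(-((d / comp.spatial_falloff) ** 2))
    return w


def _temporal_kernel(comp: ComponentSpec, time_ms: np.ndarray) -> np.ndarray:
    """Raised-cosine bump spanning the component window.

    Scaled so that the *mean* over the window is 1 (peak 2): the ROI-window
    mean amplitude of a noise-free trial then equals the nominal component
    amplitude exactly.
    """
    w0, w1 = comp.window_ms
    k = np.zeros_like(time_ms)
    inside = (time_ms >= w0) & (time_ms < w1)
    phase = (time_ms[inside] - w0) / (w1 - w0)
    k[inside] = 1.0 - np.cos(2 * np.pi * phase)
    return k


def _pink_noise(rng, n_ch, n_samp, n_trials, pink_fraction):
    white = rng.standard_normal((n_ch, n_samp, n_trials))
    spec = np.fft.rfft(rng.standard_normal((n_ch, n_samp, n_trials)), axis=1)
    freqs = np.fft.rfftfreq(n_samp)
    with np.errstate(divide="ignore"):
        shaping = np.where(freqs > 0, 1.0 / np.sqrt(np.maximum(freqs, 1e-12)), 0.0)
    pink = np.fft.irfft(spec * shaping[None, :, None], n=n_samp, axis=1)
    sd = pink.std()
    if sd > 0:
        pink /= sd
    return pink_fraction * pink + (1 - pink_fraction) * white


def _smoothing_matrix(layout: ChannelLayout, channels: Sequence[str],
                      width: float) -> np.ndarray:
    pos = np.array([layout.position_of(c) for c in channels])
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
    k = np.exp(-(d ** 2) / (2 * width ** 2))
    # unit output variance for white unit-variance input
    return k / np.sqrt((k ** 2).sum(axis=1, keepdims=True))


def _random_effects(rng, levels: Sequence[str], sd: float) -> dict:
    return {l: sd * rng.standard_normal() for l in levels}


def simulate_epochs(
    design: pd.DataFrame,
    gt: GroundTruth,
    layout: ChannelLayout | None = None,
    channels: Sequence[str] | None = None,
    seed: int | np.random.Generator = 0,
    subject_effects: dict | None = None,
    item_effects: dict | None = None,
) -> tuple[EpochSet, dict[str, np.ndarray], np.ndarray]:
    """Epochs for one participant's design table.

    Returns (EpochSet, per-trial true component amplitudes, injected-artifact
    mask).  ``subject_effects``/``item_effects`` allow the caller to share
    random-effect draws across calls (simulate_session does).
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    layout = layout or standard_layout()
    channels = list(channels) if channels is not None else layout.scalp_labels()
    fs = gt.sampling_rate
    w0, w1 = gt.epoch_window_ms
    start = int(round(w0 * fs / 1000.0))
    stop = int(round(w1 * fs / 1000.0))
    time_ms = np.arange(start, stop) * 1000.0 / fs
    for comp in gt.components:
        if comp.window_ms[0] < w0 or comp.window_ms[1] > w1:
            raise ValueError(
                f"component {comp.name} window {comp.window_ms} outside epoch"
            )

    n_trials = len(design)
    pid = str(design["participant_id"].iloc[0])
    items = sorted(design["item_id"].astype(str).unique())
    cert = _certainty_code(design["perceptual_certainty"])
    posc = _position_code(design["deviant_position"])

    subject_effects = subject_effects if subject_effects is not None else {}
    item_effects = item_effects if item_effects is not None else {}

    data = np.zeros((len(channels), time_ms.size, n_trials))
    amplitudes: dict[str, np.ndarray] = {}
    for comp in gt.components:
        se = subject_effects.setdefault(
            comp.name,
            {
                pid: (
                    comp.subject_intercept_sd * rng.standard_normal(),
                    comp.subject_slope_sd * rng.standard_normal(),
                )
            },
        )
        if pid not in se:
            se[pid] = (
                comp.subject_intercept_sd * rng.standard_normal(),
                comp.subject_slope_sd * rng.standard_normal(),
            )
        ie = item_effects.setdefault(comp.name, {})
        for it in items:
            if it not in ie:
                ie[it] = (
                    comp.item_intercept_sd * rng.standard_normal(),
                    comp.item_slope_sd * rng.standard_normal(),
                )
        u0, u1 = se[pid]
        item_int = np.array([ie[i][0] for i in design["item_id"].astype(str)])
        item_slp = np.array([ie[i][1] for i in design["item_id"].astype(str)])
        amp = (
            comp.amplitude
            + comp.certainty_effect * cert
            + comp.position_effect * posc
            + u0 + u1 * cert
            + item_int + item_slp * cert
        )
        amplitudes[comp.name] = amp
        spatial = _spatial_weights(comp, layout, channels)
        kernel = _temporal_kernel(comp, time_ms)
        data += spatial[:, None, None] * kernel[None, :, None] * amp[None, None, :]

    if gt.noise_sd > 0:
        noise = _pink_noise(
            rng, len(channels), time_ms.size, n_trials, gt.pink_fraction
        )
        S = _smoothing_matrix(layout, channels, gt.spatial_smoothing)
        data += gt.noise_sd * np.einsum("ij,jkt->ikt", S, noise)

    artifact = np.zeros(n_trials, dtype=bool)
    if gt.artifact_rate > 0:
        artifact = rng.random(n_trials) < gt.artifact_rate
        for t in np.nonzero(artifact)[0]:
            ch = rng.integers(len(channels))
            s0 = rng.integers(time_ms.size - 10)
            data[ch, s0 : s0 + 10, t] += 200.0  # clear amplitude artifact

    ep = EpochSet(
        data=data,
        time_ms=time_ms,
        event_codes=["S 1"] * n_trials,
        participant_id=pid,
        channel_labels=channels,
    )
    return ep, amplitudes, artifact


# ---------------------------------------------------------------------------
# Behavior

def simulate_behavior(
    design: pd.DataFrame,
    amplitudes: dict[str, np.ndarray],
    gt: GroundTruth,
    seed: int | np.random.Generator = 0,
    subject_effects: dict | None = None,
    item_effects: dict | None = None,
) -> pd.DataFrame:
    """RT and response columns for one participant's design table.

    RTs beyond the timeout become miss trials (rt_ms = NaN); otherwise the
    response is "hit" or "error" by the logistic accuracy model.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    b = gt.behavior
    pid = str(design["participant_id"].iloc[0])
    items = sorted(design["item_id"].astype(str).unique())
    cert = _certainty_code(design["perceptual_certainty"])
    posc = _position_code(design["deviant_position"])

    subject_effects = subject_effects if subject_effects is not None else {}
    item_effects = item_effects if item_effects is not None else {}
    se = subject_effects.setdefault("behavior", {})
    if pid not in se:
        se[pid] = (
            b.rt_subject_intercept_sd * rng.standard_normal(),
            b.rt_subject_slope_sd * rng.standard_normal(),
            b.acc_subject_sd * rng.standard_normal(),
        )
    ie = item_effects.setdefault("behavior", {})
    for it in items:
        if it not in ie:
            ie[it] = (
                b.rt_item_intercept_sd * rng.standard_normal(),
                b.acc_item_sd * rng.standard_normal(),
            )
    u_rt, u_rt_slope, u_acc = se[pid]
    item_rt = np.array([ie[i][0] for i in design["item_id"].astype(str)])
    item_acc = np.array([ie[i][1] for i in design["item_id"].astype(str)])

    eta_rt = (
        b.rt_intercept
        + b.rt_certainty_effect * cert
        + b.rt_position_effect * posc
        + u_rt + u_rt_slope * cert + item_rt
    )
    for name, slope in b.rt_component_slopes.items():
        eta_rt = eta_rt + slope * np.asarray(amplitudes[name])
    rt = eta_rt + b.rt_residual_sd * rng.standard_normal(len(design))

    eta_acc = (
        b.acc_intercept
        + b.acc_certainty_effect * cert
        + b.acc_position_effect * posc
        + u_acc + item_acc
    )
    p_hit = 1.0 / (1.0 + np.exp(-eta_acc))
    hit = rng.random(len(design)) < p_hit

    out = design.copy()
    miss = rt > b.timeout_ms
    out["rt_ms"] = np.where(miss, np.nan, rt)
    out["response"] = np.where(miss, "miss", np.where(hit, "hit", "error"))
    return out


# ---------------------------------------------------------------------------
# Whole sessions

def simulate_session(
    gt: GroundTruth,
    seed: int = 0,
    layout: ChannelLayout | None = None,
    channels: Sequence[str] | None = None,
) -> SimulatedSession:
    """Design + epochs + behavior for all participants, with shared
    random-effect draws (items are crossed with participants) and the full
    generating truth attached."""
    rng = np.random.default_rng(seed)
    layout = layout or standard_layout()
    designs = simulate_design(gt, rng)
    subject_effects: dict = {}
    item_effects: dict = {}
    epochs, behavior = [], []
    truth_amplitudes: dict[str, list[np.ndarray]] = {
        c.name: [] for c in gt.components
    }
    artifacts = []
    for design in designs:
        ep, amps, art = simulate_epochs(
            design, gt, layout=layout, channels=channels, seed=rng,
            subject_effects=subject_effects, item_effects=item_effects,
        )
        beh = simulate_behavior(
            design, amps, gt, seed=rng,
            subject_effects=subject_effects, item_effects=item_effects,
        )
        epochs.append(ep)
        behavior.append(beh)
        artifacts.append(art)
        for name, a in amps.items():
            truth_amplitudes[name].append(a)
    truth = {
        "ground_truth": gt,
        "subject_effects": subject_effects,
        "item_effects": item_effects,
        "component_amplitudes": {
            k: np.concatenate(v) for k, v in truth_amplitudes.items()
        },
        "injected_artifacts": np.concatenate(artifacts),
        "seed": seed,
    }
    return SimulatedSession(epochs=epochs, behavior=behavior, truth=truth)


def simulate_continuous_recording(
    design: pd.DataFrame,
    gt: GroundTruth,
    layout: ChannelLayout | None = None,
    channels: Sequence[str] | None = None,
    seed: int | np.random.Generator = 0,
    iti_ms: float = 1500.0,
    stimulus_code: str = "S 1",
) -> RawRecording:
    """Continuous-mode variant: epochs embedded in an ongoing noise stream.

    Produces a RawRecording (with stimulus markers) that can be written as a
    BrainVision fixture and pushed through the full preprocessing path.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    layout = layout or standard_layout()
    channels = list(channels) if channels is not None else layout.scalp_labels()
    ep, _amps, _art = simulate_epochs(
        design, gt, layout=layout, channels=channels, seed=rng,
    )
    fs = gt.sampling_rate
    iti = int(round(iti_ms * fs / 1000.0))
    pre = int(round(-gt.epoch_window_ms[0] * fs / 1000.0))
    n_ep_samp = ep.time_ms.size
    n_trials = len(design)
    total = iti * (n_trials + 1) + n_ep_samp
    noise = _pink_noise(rng, len(channels), total, 1, gt.pink_fraction)[:, :, 0]
    data = gt.noise_sd * 0.5 * noise
    events = []
    for t in range(n_trials):
        onset = iti * (t + 1)
        data[:, onset - pre : onset - pre + n_ep_samp] += ep.data[:, :, t]
        events.append((onset, stimulus_code))
    return RawRecording(
        data=data,
        sampling_rate=fs,
        channel_labels=channels,
        reference_label="A1",
        events=events,
        meta={"simulated": True},
    )


# ---------------------------------------------------------------------------
# Null data for CBPT calibration

def grid_layout(n_channels: int, spacing: float = 1.0) -> ChannelLayout:
    """Synthetic planar grid layout (for calibration studies and tests)."""
    side = int(np.ceil(np.sqrt(n_channels)))
    labels, pos = [], []
    for i in range(n_channels):
        labels.append(f"ch{i:02d}")
        pos.append((spacing * (i % side), spacing * (i // side), 0.0))
    return ChannelLayout(
        labels=labels, positions=np.asarray(pos),
        scalp=np.ones(n_channels, dtype=bool),
    )


def simulate_null_condition_averages(
    n_participants: int,
    layout: ChannelLayout,
    n_samples: int,
    seed: int | np.random.Generator = 0,
    noise_sd: float = 1.0,
    pink_fraction: float = 0.7,
    spatial_smoothing: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two condition-average arrays drawn from the same distribution.

    Participant x channel x sample, spatially smoothed pink noise; the
    exchangeability null of the cluster permutation test holds exactly.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    channels = layout.scalp_labels()
    S = _smoothing_matrix(layout, channels, spatial_smoothing)

    def draw() -> np.ndarray:
        noise = _pink_noise(
            rng, len(channels), n_samples, n_participants, pink_fraction
        )
        return noise_sd * np.einsum(
            "ij,jkt->tik", S, noise
        )  # -> participants x channels x samples

    return draw(), draw()
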