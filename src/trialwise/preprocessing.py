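"""Deterministic signal conditioning: reference, filter, epoch, baseline, flags.

The pipeline order is fixed: average reference (with recovery of the original
reference channel) -> band-pass filter -> epoching -> baseline correction ->
artifact flagging.  Artifact detection only *flags* trials; nothing is ever
deleted, so the trial store keeps the original order of recording.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .io_formats import RawRecording

__all__ = [
    "PreprocessConfig",
    "EpochSet",
    "average_reference",
    "bandpass_filter",
    "epoch",
    "baseline_correct",
    "detect_artifacts",
    "preprocess_recording",
]

log = logging.getLogger("trialwise.preprocessing")


@dataclass
class PreprocessConfig:
    """Defaults are the study's settings: 0.5-40 Hz band pass, epochs from
    -200 to 800 ms (half-open), baseline [-200, 0), trials invalidated at
    |amplitude| > 150 uV or sample-to-sample steps > 50 uV."""

    highpass_hz: float = 0.5
    lowpass_hz: float = 40.0
    epoch_window_ms: tuple[float, float] = (-200.0, 800.0)
    baseline_window_ms: tuple[float, float] = (-200.0, 0.0)
    abs_thresh_uv: float = 150.0
    grad_thresh_uv: float = 50.0
    filter_order: int = 4

    def validate(self, sampling_rate: float) -> None:
        if not 0 < self.highpass_hz < self.lowpass_hz:
            raise ValueError("need 0 < highpass < lowpass")
        if self.lowpass_hz >= sampling_rate / 2:
            raise ValueError("lowpass must be below the Nyquist frequency")
        e0, e1 = self.epoch_window_ms
        b0, b1 = self.baseline_window_ms
        if not e0 < e1:
            raise ValueError("epoch window must be non-empty")
        if not (e0 <= b0 < b1 <= e1):
            raise ValueError("baseline window must lie within the epoch window")
        if self.abs_thresh_uv <= 0 or self.grad_thresh_uv <= 0:
            raise ValueError("artifact thresholds must be positive")


@dataclass
class EpochSet:
    """Epoched data for one participant: channels x samples x trials (uV)."""

    data: np.ndarray
    time_ms: np.ndarray                    # per-sample times relative to onset
    event_codes: list[str]
    participant_id: object
    channel_labels: list[str]
    dropped_events: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be channels x samples x trials")
        steps = np.diff(self.time_ms)
        if steps.size and (np.any(steps <= 0) or not np.allclose(steps, steps[0])):
            raise ValueError("time axis must be strictly increasing and uniform")

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]


def average_reference(
    rec: RawRecording, exclude: Sequence[str] = ()
) -> RawRecording:
    """Re-reference to the common average and recover the reference channel.

    The original reference (implicitly zero in the recorded data) is appended
    as a data channel; the average is taken over all scalp channels including
    it, so the per-sample mean of the output scalp channels is exactly zero.
    Channels in ``exclude`` (EOG etc.) are passed through untouched.
    """
    if rec.reference_label in rec.channel_labels:
        raise ValueError(
            f"reference channel {rec.reference_label!r} already present in data"
        )
    scalp_idx = [
        i for i, l in enumerate(rec.channel_labels) if l not in set(exclude)
    ]
    if not scalp_idx:
        raise ValueError("no scalp channels to average")
    # n recorded scalp channels + the implicit zero reference channel
    mean = rec.data[scalp_idx].sum(axis=0) / (len(scalp_idx) + 1)
    data = rec.data.copy()
    data[scalp_idx] -= mean
    data = np.vstack([data, -mean[None, :]])
    return RawRecording(
        data=data,
        sampling_rate=rec.sampling_rate,
        channel_labels=list(rec.channel_labels) + [rec.reference_label],
        reference_label=rec.reference_label,
        events=list(rec.events),
        meta={**rec.meta, "reference": "average"},
    )


def bandpass_filter(rec: RawRecording, cfg: PreprocessConfig) -> RawRecording:
    """Zero-phase Butterworth band pass (high-pass and low-pass cascaded)."""
    cfg.validate(rec.sampling_rate)
    sos_hp = signal.butter(
        cfg.filter_order, cfg.highpass_hz, "highpass", fs=rec.sampling_rate,
        output="sos",
    )
    sos_lp = signal.butter(
        cfg.filter_order, cfg.lowpass_hz, "lowpass", fs=rec.sampling_rate,
        output="sos",
    )
    data = signal.sosfiltfilt(sos_hp, rec.data, axis=1)
    data = signal.sosfiltfilt(sos_lp, data, axis=1)
    return RawRecording(
        data=data,
        sampling_rate=rec.sampling_rate,
        channel_labels=list(rec.channel_labels),
        reference_label=rec.reference_label,
        events=list(rec.events),
        meta={**rec.meta, "filter": (cfg.highpass_hz, cfg.lowpass_hz)},
    )


def epoch(
    rec: RawRecording,
    codes: Sequence[str],
    cfg: PreprocessConfig,
    participant_id: object = None,
) -> EpochSet:
    """Cut one epoch per matching event; half-open window [start, end).

    At 500 Hz a (-200, 800) ms window yields exactly 500 samples, the first
    post-stimulus sample sits at t = 0.  Events too close to a recording edge
    are dropped with a logged warning and their indices recorded.
    """
    cfg.validate(rec.sampling_rate)
    fs = rec.sampling_rate
    start = int(round(cfg.epoch_window_ms[0] * fs / 1000.0))
    stop = int(round(cfg.epoch_window_ms[1] * fs / 1000.0))
    n_samp = stop - start
    time_ms = (np.arange(start, stop)) * 1000.0 / fs

    codes_set = set(codes)
    matched = [(i, s, c) for i, (s, c) in enumerate(rec.events) if c in codes_set]
    if not matched:
        raise ValueError(f"no events matching codes {sorted(codes_set)}")

    trials, kept_codes, dropped = [], [], []
    for i, s, c in matched:
        lo, hi = s + start, s + stop
        if lo < 0 or hi > rec.n_samples:
            dropped.append(i)
            log.warning(
                "dropping event %d (code %s) at sample %d: epoch outside recording",
                i, c, s,
            )
            continue
        trials.append(rec.data[:, lo:hi])
        kept_codes.append(c)
    data = (
        np.stack(trials, axis=2)
        if trials
        else np.empty((rec.data.shape[0], n_samp, 0))
    )
    log.info(
        "epoched %d trials (%d dropped at edges) for participant %r",
        len(trials), len(dropped), participant_id,
    )
    return EpochSet(
        data=data,
        time_ms=time_ms,
        event_codes=kept_codes,
        participant_id=participant_id,
        channel_labels=list(rec.channel_labels),
        dropped_events=dropped,
    )


def baseline_correct(ep: EpochSet, cfg: PreprocessConfig) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    b0, b1 = cfg.baseline_window_ms
    mask = (ep.time_ms >= b0) & (ep.time_ms < b1)
    if not mask.any():
        raise ValueError(
            f"baseline window {cfg.baseline_window_ms} outside the epoch"
        )
    base = ep.data[:, mask, :].mean(axis=1, keepdims=True)
    return EpochSet(
        data=ep.data - base,
        time_ms=ep.time_ms,
        event_codes=list(ep.event_codes),
        participant_id=ep.participant_id,
        channel_labels=list(ep.channel_labels),
        dropped_events=list(ep.dropped_events),
    )


def detect_artifacts(
    ep: EpochSet, cfg: PreprocessConfig, channels: Sequence[str] | None = None
) -> np.ndarray:
    """Validity flag per trial (True = clean).

    A trial is invalid iff any checked channel exceeds +-abs_thresh_uv at any
    sample or steps by more than grad_thresh_uv between consecutive samples.
    """
    if channels is None:
        idx = np.arange(ep.data.shape[0])
    else:
        pos = {c: i for i, c in enumerate(ep.channel_labels)}
        idx = np.array([pos[c] for c in channels])
    d = ep.data[idx]
    over_abs = np.abs(d) > cfg.abs_thresh_uv
    over_grad = np.abs(np.diff(d, axis=1)) > cfg.grad_thresh_uv
    bad = over_abs.any(axis=(0, 1)) | over_grad.any(axis=(0, 1))
    n_bad = int(bad.sum())
    log.info("artifact flags: %d of %d trials invalidated", n_bad, ep.n_trials)
    return ~bad


def preprocess_recording(
    rec: RawRecording,
    codes: Sequence[str],
    cfg: PreprocessConfig | None = None,
    participant_id: object = None,
    eog_channels: Sequence[str] = ("IO1",),
) -> tuple[EpochSet, np.ndarray]:
    """Run the fixed stage order on one continuous recording.

    Returns the baseline-corrected EpochSet and the per-trial validity flags.
    Artifact thresholds are applied to scalp channels after re-referencing,
    filtering and baseline correction.
    """
    cfg = cfg or PreprocessConfig()
    exclude = [c for c in eog_channels if c in rec.channel_labels]
    rec = average_reference(rec, exclude=exclude)
    rec = bandpass_filter(rec, cfg)
    ep = epoch(rec, codes, cfg, participant_id=participant_id)
    ep = baseline_correct(ep, cfg)
    scalp = [c for c in ep.channel_labels if c not in set(exclude)]
    valid = detect_artifacts(ep, cfg, channels=scalp)
    return ep, valid
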