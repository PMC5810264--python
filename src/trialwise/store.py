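"""The 3-D single-trial store: channels x samples x trials across participants.

The central container of the pipeline: every epoch of every participant is kept
in one amplitude array, in the original order of recording, aligned row-for-row
with a behavioral metadata table.  Trials flagged as EEG artifacts are *kept*
(``eeg_valid = False``) so that behavioral-only analyses retain the full n;
ERP extraction masks them instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialStore",
    "build_store",
    "subset",
    "apply_analysis_filters",
    "mean_amplitude",
]

#: metadata columns every store carries
CORE_COLUMNS = ("participant_id", "trial_index", "eeg_valid")


@dataclass
class TrialStore:
    """Amplitudes (channels x samples x trials, microvolts) plus trial metadata.

    ``meta`` has exactly one row per trial, aligned by position with the third
    axis of ``amplitudes``.  Within each participant, ``trial_index`` is
    strictly increasing (recording order).
    """

    amplitudes: np.ndarray
    time_ms: np.ndarray
    channel_labels: list[str]
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.amplitudes.ndim != 3:
            raise ValueError("amplitudes must be channels x samples x trials")
        n_ch, n_s, n_t = self.amplitudes.shape
        if len(self.channel_labels) != n_ch:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {n_ch} channels"
            )
        if len(set(self.channel_labels)) != n_ch:
            raise ValueError("channel labels must be unique")
        if self.time_ms.shape != (n_s,):
            raise ValueError("time axis length must match sample axis")
        if len(self.meta) != n_t:
            raise ValueError(
                f"meta has {len(self.meta)} rows for {n_t} trials"
            )
        for col in CORE_COLUMNS:
            if col not in self.meta.columns:
                raise ValueError(f"meta is missing required column {col!r}")
        # recording order within participant is an invariant, not a convention
        for pid, grp in self.meta.groupby("participant_id", sort=False, observed=True):
            idx = np.asarray(grp["trial_index"])
            if np.any(np.diff(idx) <= 0):
                raise ValueError(
                    f"trial_index not strictly increasing for participant {pid!r}"
                )

    @property
    def n_trials(self) -> int:
        return self.amplitudes.shape[2]

    @property
    def n_channels(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.amplitudes.shape[1]

    @property
    def participants(self) -> list:
        return list(pd.unique(self.meta["participant_id"]))

    def channel_index(self, labels: Sequence[str]) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.channel_labels)}
        missing = [c for c in labels if c not in pos]
        if missing:
            raise KeyError(f"unknown channel(s): {', '.join(missing)}")
        return np.array([pos[c] for c in labels], dtype=int)

    def window_index(self, window_ms: tuple[float, float]) -> np.ndarray:
        """Sample indices with start <= t < end (half-open, like epochs)."""
        start, end = window_ms
        if not end > start:
            raise ValueError(f"empty window {window_ms}")
        mask = (self.time_ms >= start) & (self.time_ms < end)
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise ValueError(f"window {window_ms} contains no samples")
        return idx


def build_store(
    epochs_by_participant: Sequence,
    behavior_by_participant: Sequence[pd.DataFrame],
) -> TrialStore:
    """Concatenate per-participant epochs with their behavioral tables.

    The matching key is (participant, ordinal position in recording): row i of
    a participant's behavioral table describes epoch i.  A count mismatch is a
    hard error naming the participant — silent re-alignment would defeat the
    purpose of order preservation.
    """
    if len(epochs_by_participant) != len(behavior_by_participant):
        raise ValueError("one behavioral table per EpochSet required")
    if not epochs_by_participant:
        raise ValueError("no participants given")

    first = epochs_by_participant[0]
    blocks, metas = [], []
    for ep, beh in zip(epochs_by_participant, behavior_by_participant):
        if list(ep.channel_labels) != list(first.channel_labels):
            raise ValueError(
                f"channel set of participant {ep.participant_id!r} differs"
            )
        if not np.allclose(ep.time_ms, first.time_ms):
            raise ValueError(
                f"time axis of participant {ep.participant_id!r} differs"
            )
        n_ep, n_beh = ep.n_trials, len(beh)
        if n_ep != n_beh:
            raise ValueError(
                f"participant {ep.participant_id!r}: {n_ep} epochs but "
                f"{n_beh} behavioral rows"
            )
        meta = beh.copy()
        meta["participant_id"] = ep.participant_id
        if "trial_index" not in meta.columns:
            meta["trial_index"] = np.arange(1, n_ep + 1)
        if "eeg_valid" not in meta.columns:
            meta["eeg_valid"] = True
        blocks.append(ep.data)
        metas.append(meta)

    return TrialStore(
        amplitudes=np.concatenate(blocks, axis=2),
        time_ms=first.time_ms.copy(),
        channel_labels=list(first.channel_labels),
        meta=pd.concat(metas, ignore_index=True),
    )


def subset(store: TrialStore, predicate) -> TrialStore:
    """Trials where the predicate holds; order preserved, composable.

    ``predicate`` is either a pandas query string over metadata columns or a
    callable ``meta -> boolean mask``.
    """
    if callable(predicate):
        mask = np.asarray(predicate(store.meta), dtype=bool)
        if mask.shape != (store.n_trials,):
            raise ValueError("predicate must return one boolean per trial")
    else:
        try:
            mask = store.meta.eval(predicate)
        except pd.errors.UndefinedVariableError as err:
            raise KeyError(f"predicate references unknown column: {err}") from None
        mask = np.asarray(mask, dtype=bool)
    return TrialStore(
        amplitudes=store.amplitudes[:, :, mask],
        time_ms=store.time_ms,
        channel_labels=list(store.channel_labels),
        meta=store.meta.loc[mask].reset_index(drop=True),
    )


def apply_analysis_filters(store: TrialStore, stage: str) -> TrialStore:
    """The study's trial-exclusion rules as a conjunction of predicates.

    stage "accuracy": drop center-top/center-bottom deviants and miss trials
    (behavioral analyses keep error trials and EEG-invalid trials).
    stage "rt_erp": additionally drop error trials and EEG-invalid trials —
    RT and amplitude analyses use correct responses with clean EEG only.
    """
    if stage not in ("accuracy", "rt_erp"):
        raise ValueError(f"unknown stage {stage!r}; use 'accuracy' or 'rt_erp'")
    meta = store.meta
    mask = (
        np.asarray(meta["deviant_position"].isin(["left", "right"]))
        & np.asarray(meta["response"] != "miss")
    )
    if stage == "rt_erp":
        mask &= np.asarray(meta["response"] == "hit")
        mask &= np.asarray(meta["eeg_valid"], dtype=bool)
    return subset(store, lambda m, _mask=mask: _mask)


def mean_amplitude(
    store: TrialStore,
    channels: Sequence[str],
    window_ms: tuple[float, float],
    column: str | None = None,
) -> np.ndarray:
    """Per-trial mean over an ROI (channel set x half-open time window), in uV.

    EEG-invalid trials get NaN.  If ``column`` is given the values are also
    appended to ``store.meta`` under that name.
    """
    if len(channels) == 0:
        raise ValueError("empty ROI channel set")
    ch = store.channel_index(channels)
    sm = store.window_index(window_ms)
    vals = store.amplitudes[np.ix_(ch, sm)].mean(axis=(0, 1))
    valid = np.asarray(store.meta["eeg_valid"], dtype=bool)
    vals = np.where(valid, vals, np.nan)
    if column is not None:
        store.meta[column] = vals
    return vals
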