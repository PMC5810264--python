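"""ERP estimation: condition averages, regression-based ERPs, ERP images.

Averaging within participant x condition cells is the classical estimator;
ordinary least squares fitted independently at each (channel, sample) is its
strict generalization — with a one-hot condition design the two coincide
exactly, which is this module's core invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .store import TrialStore

__all__ = [
    "ConditionAverages",
    "condition_averages",
    "paired_condition_arrays",
    "regression_erp",
    "erp_image",
]


@dataclass
class ConditionAverages:
    """participants x conditions x channels x samples mean amplitudes (uV)."""

    data: np.ndarray
    participants: list
    conditions: list[tuple]                # factor-level tuples
    factor_names: list[str]
    channel_labels: list[str]
    time_ms: np.ndarray
    counts: np.ndarray                     # participants x conditions

    @property
    def empty_cells(self) -> list[tuple]:
        """(participant, condition) pairs with zero trials — flagged, not zeroed."""
        out = []
        for i, p in enumerate(self.participants):
            for j, c in enumerate(self.conditions):
                if self.counts[i, j] == 0:
                    out.append((p, c))
        return out


def condition_averages(
    store: TrialStore, factors: Sequence[str]
) -> ConditionAverages:
    """Mean over trials within each participant x condition cell."""
    meta = store.meta
    for f in factors:
        if f not in meta.columns:
            raise KeyError(f"unknown factor column {f!r}")
    participants = list(pd.unique(meta["participant_id"]))
    conditions = sorted(
        set(map(tuple, meta[list(factors)].astype(str).itertuples(index=False)))
    )
    cond_pos = {c: j for j, c in enumerate(conditions)}
    n_p, n_c = len(participants), len(conditions)
    n_ch, n_s = store.n_channels, store.n_samples

    sums = np.zeros((n_p, n_c, n_ch, n_s))
    counts = np.zeros((n_p, n_c), dtype=int)
    p_pos = {p: i for i, p in enumerate(participants)}
    keys = meta[list(factors)].astype(str)
    for t in range(store.n_trials):
        i = p_pos[meta["participant_id"].iat[t]]
        j = cond_pos[tuple(keys.iloc[t])]
        sums[i, j] += store.amplitudes[:, :, t]
        counts[i, j] += 1
    with np.errstate(invalid="ignore"):
        data = sums / counts[:, :, None, None]
    return ConditionAverages(
        data=data,
        participants=participants,
        conditions=conditions,
        factor_names=list(factors),
        channel_labels=list(store.channel_labels),
        time_ms=store.time_ms,
        counts=counts,
    )


def paired_condition_arrays(
    avgs: ConditionAverages, factor: str, level_a: str, level_b: str
) -> tuple[np.ndarray, np.ndarray]:
    """Extract the two participant x channel x sample arrays for a contrast.

    Averages over the remaining factors' levels within each participant.
    Participants with an empty cell on either side are excluded.
    """
    fi = avgs.factor_names.index(factor)

    def side(level: str) -> tuple[np.ndarray, np.ndarray]:
        js = [j for j, c in enumerate(avgs.conditions) if c[fi] == level]
        if not js:
            raise ValueError(f"no conditions with {factor}={level!r}")
        w = avgs.counts[:, js]
        ok = (w > 0).all(axis=1)
        return np.nanmean(avgs.data[:, js], axis=1), ok

    a, ok_a = side(level_a)
    b, ok_b = side(level_b)
    keep = ok_a & ok_b
    return a[keep], b[keep]


def regression_erp(
    store: TrialStore, design: pd.DataFrame | np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """OLS coefficient waveforms, fitted independently at each (channel, sample).

    ``design`` is the trials x predictors matrix (no implicit intercept).
    Returns (betas: predictors x channels x samples, predictor names).
    Rank deficiency is an error naming the collinear columns.
    """
    if isinstance(design, pd.DataFrame):
        names = [str(c) for c in design.columns]
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    if X.shape[0] != store.n_trials:
        raise ValueError("design rows must equal trial count")

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns that do not increase the rank incrementally
        bad, r = [], 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                bad.append(names[j])
            r = rj
        raise ValueError(f"design matrix is rank deficient; collinear: {bad}")

    Y = store.amplitudes.reshape(-1, store.n_trials).T  # trials x (ch*samp)
    B = np.linalg.pinv(X) @ Y
    betas = B.reshape(X.shape[1], store.n_channels, store.n_samples)
    return betas, names


def erp_image(
    store: TrialStore, channel: str, sort_col: str = "rt_ms"
) -> tuple[np.ndarray, np.ndarray]:
    """Single-trial amplitude image at one channel, rows sorted by a key.

    Returns (trials x samples matrix ordered ascending by ``sort_col``, the
    sorted key values).  Ties keep recording order (stable sort); NaN keys
    sort last; an all-NaN key is an error.
    """
    ci = store.channel_index([channel])[0]
    key = pd.to_numeric(store.meta[sort_col], errors="coerce").to_numpy(float)
    if np.all(np.isnan(key)):
        raise ValueError(f"sort column {sort_col!r} is all-NaN")
    order = np.argsort(key, kind="stable")
    return store.amplitudes[ci, :, order], key[order]
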