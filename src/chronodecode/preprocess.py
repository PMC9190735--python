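"""Epoch-level preprocessing: automated artifact rejection and downsampling."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import resample_poly

from .simulate import EpochArray

__all__ = ["reject_artifacts", "downsample", "RejectionReport"]


@dataclass(frozen=True)
class RejectionReport:
    removed_indices: tuple[int, ...]
    fraction_removed: float
    z_threshold: float
    metric: np.ndarray  # per-trial max-over-channels standardized deviation


def reject_artifacts(
    epochs: EpochArray, z_threshold: float = 20.0
) -> tuple[EpochArray, RejectionReport]:
    """Remove trials with extreme standardized deviations from the mean.

    Per trial and channel, the absolute deviation from the across-trial mean
    is summed over the epoch; these per-channel scores are z-scored across
    trials, and a trial is rejected when its maximum over channels exceeds
    ``z_threshold`` (default 20, a deliberately permissive jump-artifact
    criterion). A warning is emitted when more than 10 % of trials are
    removed, which in clean recordings should not happen.
    """
    if epochs.n_trials < 2:
        raise ValueError("artifact rejection needs at least 2 trials")
    x = epochs.data
    dev = np.abs(x - x.mean(axis=0, keepdims=True)).sum(axis=2)  # trials x channels
    mu = dev.mean(axis=0)
    sd = dev.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant channels cannot trigger rejection
    z = (dev - mu) / sd
    metric = z.max(axis=1)
    bad = metric > z_threshold
    if bad.all():
        raise ValueError("all trials rejected; threshold too strict for these data")
    frac = float(bad.mean())
    if frac > 0.10:
        warnings.warn(
            f"artifact rejection removed {frac:.1%} of trials (> 10 %)",
            RuntimeWarning,
            stacklevel=2,
        )
    report = RejectionReport(
        removed_indices=tuple(int(i) for i in np.flatnonzero(bad)),
        fraction_removed=frac,
        z_threshold=float(z_threshold),
        metric=metric,
    )
    return epochs.select(~bad), report


def downsample(epochs: EpochArray, fs_target: float) -> EpochArray:
    """Decimate epochs to ``fs_target`` with zero-phase FIR anti-alias filtering.

    ``fs_target`` must divide the current sampling rate (integer decimation).
    The new time axis keeps every q-th sample of the old one, so the epoch
    window is preserved.
    """
    if fs_target > epochs.fs:
        raise ValueError(f"fs_target={fs_target} exceeds current fs={epochs.fs}")
    q = epochs.fs / fs_target
    if abs(q - round(q)) > 1e-9:
        raise ValueError(
            f"fs_target={fs_target} does not divide fs={epochs.fs}; "
            "only integer decimation is supported"
        )
    q = int(round(q))
    if q == 1:
        return EpochArray(
            data=epochs.data.copy(),
            time_ms=epochs.time_ms.copy(),
            fs=epochs.fs,
            trial_meta=epochs.trial_meta.copy(),
            participant_id=epochs.participant_id,
        )
    # polyphase FIR decimation; linear-edge padding keeps constants constant
    data = resample_poly(epochs.data, 1, q, axis=2, padtype="line")
    return EpochArray(
        data=data,
        time_ms=epochs.time_ms[::q].copy(),
        fs=float(fs_target),
        trial_meta=epochs.trial_meta.copy(),
        participant_id=epochs.participant_id,
    )
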