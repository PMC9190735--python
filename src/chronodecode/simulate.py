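"""Synthetic epoched data with planted representational dynamics.

The generator plants per-object and per-category multivariate channel
patterns that switch on at configurable latencies inside the epoch, mixes
them through modality-specific channel bases (shared or independent across
modalities), and adds spatially correlated Gaussian noise. It stands in for
recorded EEG so every downstream stage — super-trial averaging, noise
normalization, pairwise decoding, cluster inference — can be verified
against known ground truth.

The signal model is deliberately simple: an object's single-trial response is

    snr * Q_m @ [ env_obj(t) * p_obj  +  env_cat(t) * sum_d p_cat[d, level] ]

plus noise with channel covariance ``noise_cov`` (white over time). ``Q_m``
is the modality's channel basis; with independent bases per modality the
planted codes do not transfer across modalities, mirroring a null
cross-modal result; with a shared basis they do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import toeplitz
from scipy.stats import ortho_group

from .design import DesignSpec, StimulusSet

__all__ = [
    "EpochArray",
    "SignalModel",
    "make_signal_model",
    "default_noise_cov",
    "simulate_epochs",
    "drop_oneback",
]


@dataclass
class EpochArray:
    """Epoched multichannel data: trials x channels x timepoints.

    ``time_ms`` is strictly increasing with uniform spacing ``1000 / fs``;
    ``trial_meta`` has one row per trial (same order as ``data``).
    """

    data: np.ndarray
    time_ms: np.ndarray
    fs: float
    trial_meta: pd.DataFrame
    participant_id: str = "p00"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.time_ms = np.asarray(self.time_ms, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x timepoints")
        if self.data.shape[2] != self.time_ms.size:
            raise ValueError("time axis length does not match data")
        if len(self.trial_meta) != self.data.shape[0]:
            raise ValueError("trial_meta row count does not match data")
        dt = np.diff(self.time_ms)
        if self.time_ms.size > 1:
            if np.any(dt <= 0):
                raise ValueError("time axis must be strictly increasing")
            if not np.allclose(dt, 1000.0 / self.fs, rtol=1e-6, atol=1e-9):
                raise ValueError("time axis spacing must equal 1000/fs ms")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def select(self, mask: np.ndarray) -> "EpochArray":
        """Subset trials by boolean mask or index array."""
        return EpochArray(
            data=self.data[mask],
            time_ms=self.time_ms,
            fs=self.fs,
            trial_meta=self.trial_meta.iloc[np.flatnonzero(mask)].reset_index(drop=True)
            if np.asarray(mask).dtype == bool
            else self.trial_meta.iloc[mask].reset_index(drop=True),
            participant_id=self.participant_id,
        )


def drop_oneback(epochs: EpochArray) -> EpochArray:
    """Remove one-back repeat trials (they are task trials, not analysis trials)."""
    keep = ~epochs.trial_meta["is_oneback_repeat"].to_numpy(dtype=bool)
    return epochs.select(keep)


def default_noise_cov(n_channels: int, length_scale: float = 5.0, scale: float = 1.0) -> np.ndarray:
    """Spatially correlated channel covariance: exponential-decay Toeplitz.

    Neighbouring channels share noise (as scalp sensors do); correlation
    decays as exp(-|i-j| / length_scale).
    """
    idx = np.arange(n_channels)
    cov = scale * toeplitz(np.exp(-idx / length_scale))
    return cov


@dataclass
class SignalModel:
    """Planted multivariate patterns and their temporal dynamics.

    ``object_patterns``: (n_objects, n_channels), row order = stimset order.
    ``category_patterns``: {(dimension, level): (n_channels,)}.
    ``modality_codes``: {modality: (C, C) matrix}; the identity for every
    modality yields a shared cross-modal code, while projectors onto
    disjoint orthogonal channel subspaces make cross-modal transfer exactly
    zero.
    ``envelope``: step onset with a linear ramp of ``ramp_ms``; optionally
    decays exponentially (time constant ``decay_ms``) towards
    ``sustain_level`` to emulate transient evoked responses. Default is a
    pure sustained step (sustain_level=1).
    """

    object_patterns: np.ndarray
    category_patterns: dict
    object_onset_ms: float = 75.0
    category_onset_ms: float = 305.0
    modality_codes: dict = field(default_factory=dict)
    noise_cov: np.ndarray | None = None
    snr: float = 1.0
    ramp_ms: float = 20.0
    sustain_level: float = 1.0
    decay_ms: float = 100.0

    def validate(self, design: DesignSpec) -> None:
        lo, hi = design.epoch_window
        for name, onset in (
            ("object_onset_ms", self.object_onset_ms),
            ("category_onset_ms", self.category_onset_ms),
        ):
            if not (lo <= onset <= hi):
                raise ValueError(f"{name}={onset} outside epoch window {design.epoch_window}")
        if self.noise_cov is not None:
            c = np.asarray(self.noise_cov)
            if not np.allclose(c, c.T):
                raise ValueError("noise_cov must be symmetric")
            if np.any(np.linalg.eigvalsh(c) <= 0):
                raise ValueError("noise_cov must be positive-definite")

    def envelope(self, time_ms: np.ndarray, onset_ms: float) -> np.ndarray:
        """Gain profile over the epoch for a component switching on at onset."""
        t = np.asarray(time_ms, dtype=float)
        ramp = np.clip((t - onset_ms) / max(self.ramp_ms, 1e-9), 0.0, 1.0)
        if self.sustain_level >= 1.0:
            return ramp
        after_peak = np.clip(t - (onset_ms + self.ramp_ms), 0.0, None)
        decay = self.sustain_level + (1.0 - self.sustain_level) * np.exp(
            -after_peak / max(self.decay_ms, 1e-9)
        )
        return ramp * decay


def make_signal_model(
    stimset: StimulusSet,
    n_channels: int,
    seed: int = 0,
    *,
    snr: float = 1.0,
    object_onset_ms: float = 75.0,
    category_onset_ms: float = 305.0,
    shared_modality_code: bool = False,
    modalities: tuple[str, ...] = ("auditory", "visual"),
    noise_cov: np.ndarray | None = None,
    ramp_ms: float = 20.0,
    sustain_level: float = 1.0,
    decay_ms: float = 100.0,
    category_strength: float = 1.0,
    object_strength: float = 1.0,
) -> SignalModel:
    """Draw random unit-norm planted patterns for every object and category level.

    With ``shared_modality_code=True`` all modalities use the identity channel
    basis (codes transfer across modalities); otherwise each modality's
    patterns are projected onto its own block of a random orthogonal channel
    basis, so one modality's planted signal lies in a subspace exactly
    orthogonal to the other's and carries zero cross-modal information.
    """
    rng = np.random.default_rng(seed)
    n_obj = stimset.n_objects
    if not shared_modality_code and n_channels < len(modalities):
        raise ValueError("need at least one channel per modality for disjoint codes")

    def unit_rows(n: int) -> np.ndarray:
        m = rng.standard_normal((n, n_channels))
        return m / np.linalg.norm(m, axis=1, keepdims=True)

    object_patterns = object_strength * unit_rows(n_obj)
    category_patterns = {}
    for dim in stimset.dimensions:
        pats = category_strength * unit_rows(2)
        for level in (0, 1):
            category_patterns[(dim, level)] = pats[level]

    codes = {}
    if shared_modality_code:
        for mod in modalities:
            codes[mod] = np.eye(n_channels)
    else:
        # Q_m = U_m V_m^T: U_m spans this modality's block of a common random
        # orthogonal channel basis (images of different modalities are exactly
        # orthogonal) and V_m is an independent random frame, so the two
        # modalities' planted patterns are also statistically independent —
        # without V_m the same pattern vector would appear in both subspaces
        # and whitening-based pipelines could recouple them
        basis = ortho_group.rvs(n_channels, random_state=rng)
        blocks = np.array_split(np.arange(n_channels), len(modalities))
        for mod, block in zip(modalities, blocks):
            sub = basis[:, block]
            frame = ortho_group.rvs(n_channels, random_state=rng)[:, : len(block)]
            codes[mod] = sub @ frame.T

    return SignalModel(
        object_patterns=object_patterns,
        category_patterns=category_patterns,
        object_onset_ms=object_onset_ms,
        category_onset_ms=category_onset_ms,
        modality_codes=codes,
        noise_cov=noise_cov if noise_cov is not None else default_noise_cov(n_channels),
        snr=snr,
        ramp_ms=ramp_ms,
        sustain_level=sustain_level,
        decay_ms=decay_ms,
    )


def _time_axis(window: tuple[float, float], fs: float) -> np.ndarray:
    dt = 1000.0 / fs
    n = int(round((window[1] - window[0]) / dt)) + 1
    return window[0] + dt * np.arange(n)


def simulate_epochs(
    trials: pd.DataFrame,
    stimset: StimulusSet,
    model: SignalModel,
    design: DesignSpec,
    seed: int = 0,
    *,
    fs: float | None = None,
    participant_id: str = "p00",
) -> EpochArray:
    """Render an EpochArray for the given trial table.

    Each trial's data is the planted object + category pattern for its
    object, gated by the temporal envelopes, projected through its
    modality's channel basis, scaled by ``model.snr``, plus Gaussian noise
    with channel covariance ``model.noise_cov`` (independent across trials
    and timepoints). One-back repeat trials carry the same object signal as
    their source trial. ``fs`` defaults to ``design.fs_raw``; passing
    ``design.fs_target`` simulates directly on the analysis time axis.
    """
    model.validate(design)
    fs = float(fs if fs is not None else design.fs_raw)
    time_ms = _time_axis(design.epoch_window, fs)
    n_ch = model.object_patterns.shape[1]
    if model.noise_cov is not None and model.noise_cov.shape[0] != n_ch:
        raise ValueError(
            f"noise_cov has {model.noise_cov.shape[0]} channels, patterns have {n_ch}"
        )
    missing = set(trials["object_id"]) - set(stimset.object_ids)
    if missing:
        raise ValueError(f"trial table references unknown objects: {sorted(missing)[:3]}")
    for dim in stimset.dimensions:
        for level in (0, 1):
            if (dim, level) not in model.category_patterns:
                raise ValueError(f"model lacks a pattern for {(dim, level)}")

    rng = np.random.default_rng(seed)
    env_obj = model.envelope(time_ms, model.object_onset_ms)
    env_cat = model.envelope(time_ms, model.category_onset_ms)

    obj_index = {o: i for i, o in enumerate(stimset.object_ids)}
    # per (modality, object) noiseless response, computed once
    responses: dict[tuple[str, str], np.ndarray] = {}
    for mod in trials["modality"].unique():
        code = model.modality_codes.get(mod)
        if code is None:
            code = np.eye(n_ch)
        if code.shape != (n_ch, n_ch):
            raise ValueError(f"modality code for {mod!r} has wrong shape {code.shape}")
        for obj in trials.loc[trials["modality"] == mod, "object_id"].unique():
            p_obj = model.object_patterns[obj_index[obj]]
            p_cat = np.zeros(n_ch)
            for dim in stimset.dimensions:
                level = int(stimset.labels.loc[obj, dim])
                p_cat = p_cat + model.category_patterns[(dim, level)]
            # channels x time
            sig = np.outer(code @ p_obj, env_obj) + np.outer(code @ p_cat, env_cat)
            responses[(mod, obj)] = model.snr * sig

    n_trials = len(trials)
    data = np.empty((n_trials, n_ch, time_ms.size))
    for i, (mod, obj) in enumerate(zip(trials["modality"], trials["object_id"])):
        data[i] = responses[(mod, obj)]
    if model.noise_cov is not None:
        chol = np.linalg.cholesky(model.noise_cov)
        noise = rng.standard_normal((n_trials, n_ch, time_ms.size))
        data += np.einsum("ij,njt->nit", chol, noise)

    return EpochArray(
        data=data,
        time_ms=time_ms,
        fs=fs,
        trial_meta=trials.reset_index(drop=True).copy(),
        participant_id=participant_id,
    )
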