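"""Group-level nonparametric inference on decoding time courses.

Two procedures:

* a sign-flip cluster-size permutation test: participants' chance-centered
  accuracies are randomly multiplied by +/-1 to build the null distribution
  of a pointwise group statistic; supra-threshold timepoints form contiguous
  clusters whose sizes are compared against the null distribution of the
  maximum cluster size, correcting for multiple comparisons over time;
* a bootstrap test for peak-latency differences: participants are resampled
  with replacement, the latency of the group-mean maximum is recorded per
  sample, and the one-tailed p-value is the fraction of bootstrap samples
  with a difference on the hypothesized side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .decoding import AccuracyTimecourse

__all__ = [
    "ClusterInferenceResult",
    "PeakLatencyTest",
    "cluster_permutation_test",
    "bootstrap_peak_latency_difference",
    "simulate_null_accuracies",
]


@dataclass(frozen=True)
class Cluster:
    start_ms: float
    end_ms: float
    size: int
    p_value: float
    significant: bool


@dataclass
class ClusterInferenceResult:
    significant_mask: np.ndarray  # bool per timepoint
    clusters: list[Cluster]
    time_ms: np.ndarray
    pointwise_p: np.ndarray  # per-timepoint sign-flip p (uncorrected)
    n_permutations: int
    alpha: float
    chance_level: float
    statistic: str

    def onset_ms(self) -> float | None:
        """First significant timepoint, or None when nothing is significant."""
        idx = np.flatnonzero(self.significant_mask)
        return float(self.time_ms[idx[0]]) if idx.size else None

    def offset_ms(self) -> float | None:
        idx = np.flatnonzero(self.significant_mask)
        return float(self.time_ms[idx[-1]]) if idx.size else None


def _as_values(acc) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(acc, AccuracyTimecourse):
        return acc.values, np.asarray(acc.time_ms, dtype=float)
    v = np.atleast_2d(np.asarray(acc, dtype=float))
    return v, np.arange(v.shape[-1], dtype=float)


def _run_lengths(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) index pairs (stop exclusive)."""
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def _max_run_lengths(masks: np.ndarray) -> np.ndarray:
    """Max contiguous True run per row of a (R, T) boolean array."""
    R, T = masks.shape
    padded = np.zeros((R, T + 2), dtype=int)
    padded[:, 1:-1] = masks
    d = np.diff(padded, axis=1)
    out = np.zeros(R, dtype=int)
    rows, starts = np.nonzero(d == 1)
    _, stops = np.nonzero(d == -1)
    lengths = stops - starts
    np.maximum.at(out, rows, lengths)
    return out


def cluster_permutation_test(
    acc,
    chance: float = 50.0,
    n_permutations: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
    statistic: str = "mean",
    time_ms: np.ndarray | None = None,
) -> ClusterInferenceResult:
    """One-sided sign-flip cluster-size permutation test against chance.

    ``acc`` is an AccuracyTimecourse or a (participants, timepoints) array.
    Participant data are centered on ``chance``; the pointwise group
    statistic ("mean" or "t") is compared against its sign-flip null, with
    the identity flip included as the first permutation so p-values are
    never below ``1/n_permutations``. Pointwise-significant timepoints
    (p < alpha) form contiguous candidate clusters scored by size and
    assessed against the null distribution of the maximum cluster size.
    """
    values, t_axis = _as_values(acc)
    if time_ms is not None:
        t_axis = np.asarray(time_ms, dtype=float)
    P, T = values.shape[0], values.shape[-1]
    if P < 2:
        raise ValueError("need at least 2 participants")
    if values.ndim != 2:
        raise ValueError("cluster test expects participants x timepoints data")
    if n_permutations < int(np.ceil(1.0 / alpha)):
        warnings.warn(
            f"n_permutations={n_permutations} cannot resolve p < alpha={alpha}",
            RuntimeWarning,
            stacklevel=2,
        )
    if statistic not in ("mean", "t"):
        raise ValueError("statistic must be 'mean' or 't'")

    D = values - chance
    rng = np.random.default_rng(seed)
    signs = np.empty((n_permutations, P))
    signs[0] = 1.0  # identity flip: observed data are permutation 0
    signs[1:] = rng.choice([-1.0, 1.0], size=(n_permutations - 1, P))

    m = signs @ D / P  # (R, T) flipped means
    if statistic == "mean":
        stats = m
    else:
        msq = (D**2).mean(axis=0)  # invariant under sign flips
        var = (msq[None, :] - m**2) * P / (P - 1)
        var = np.maximum(var, 1e-300)
        stats = m / np.sqrt(var / P)
    obs = stats[0]

    # pointwise one-sided p per timepoint (includes the observed flip)
    pointwise_p = (stats >= obs[None, :]).mean(axis=0)
    # common pointwise critical value per timepoint for cluster forming
    crit = np.quantile(stats, 1.0 - alpha, axis=0, method="higher")
    supra = stats > crit[None, :]  # (R, T)

    null_max = _max_run_lengths(supra)  # includes row 0 (observed)
    clusters: list[Cluster] = []
    mask = np.zeros(T, dtype=bool)
    for start, stop in _run_lengths(supra[0]):
        size = stop - start
        p = float((null_max >= size).mean())
        sig = p < alpha
        clusters.append(
            Cluster(
                start_ms=float(t_axis[start]),
                end_ms=float(t_axis[stop - 1]),
                size=int(size),
                p_value=p,
                significant=sig,
            )
        )
        if sig:
            mask[start:stop] = True
    return ClusterInferenceResult(
        significant_mask=mask,
        clusters=clusters,
        time_ms=t_axis,
        pointwise_p=pointwise_p,
        n_permutations=n_permutations,
        alpha=alpha,
        chance_level=chance,
        statistic=statistic,
    )


@dataclass
class PeakLatencyTest:
    peak_ms_a: float
    peak_ms_b: float
    boot_differences: np.ndarray  # per-bootstrap (peak_A - peak_B) in ms
    p_a_later: float  # fraction of bootstrap differences > 0
    p_b_later: float  # fraction of bootstrap differences < 0
    n_bootstrap: int
    flat_input: bool = False  # a group-mean curve had no unique maximum

    @property
    def p_one_tailed(self) -> float:
        """One-tailed p for 'A peaks later than B' (strict > 0 rule)."""
        return self.p_a_later


def _peak_latency(mean_curve: np.ndarray, time_ms: np.ndarray) -> float:
    # ties broken to the earliest timepoint (np.argmax takes the first max)
    return float(time_ms[int(np.argmax(mean_curve))])


def bootstrap_peak_latency_difference(
    acc_a,
    acc_b,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> PeakLatencyTest:
    """Bootstrap test for a peak-latency difference between two time courses.

    Participants are resampled with replacement (the same resample applied
    to both conditions), the group-mean curves' peak latencies are computed
    per sample, and their difference A - B recorded. ``p_a_later`` is the
    fraction of samples with a strictly positive difference.
    """
    va, ta = _as_values(acc_a)
    vb, tb = _as_values(acc_b)
    if va.shape != vb.shape or not np.allclose(ta, tb):
        raise ValueError("the two conditions must share participants and time axis")
    P = va.shape[0]
    rng = np.random.default_rng(seed)
    flat = bool(
        np.ptp(va.mean(axis=0)) == 0 or np.ptp(vb.mean(axis=0)) == 0
    )
    if flat:
        warnings.warn(
            "flat time course: peak latency tie-broken to the earliest timepoint",
            RuntimeWarning,
            stacklevel=2,
        )
    idx = rng.integers(0, P, size=(n_bootstrap, P))
    mean_a = va[idx].mean(axis=1)  # (n_boot, T)
    mean_b = vb[idx].mean(axis=1)
    peaks_a = ta[np.argmax(mean_a, axis=1)]
    peaks_b = tb[np.argmax(mean_b, axis=1)]
    diffs = peaks_a - peaks_b
    return PeakLatencyTest(
        peak_ms_a=_peak_latency(va.mean(axis=0), ta),
        peak_ms_b=_peak_latency(vb.mean(axis=0), tb),
        boot_differences=diffs,
        p_a_later=float((diffs > 0).mean()),
        p_b_later=float((diffs < 0).mean()),
        n_bootstrap=n_bootstrap,
        flat_input=flat,
    )


def simulate_null_accuracies(
    n_participants: int,
    n_timepoints: int,
    seed: int = 0,
    sd: float = 2.5,
    ar_coef: float = 0.8,
    chance: float = 50.0,
) -> np.ndarray:
    """Null decoding time courses: AR(1)-autocorrelated noise around chance.

    Used for false-positive-rate calibration of the cluster test; the
    temporal autocorrelation mimics the smoothness of real accuracy curves.
    """
    rng = np.random.default_rng(seed)
    innov = rng.standard_normal((n_participants, n_timepoints))
    x = np.empty_like(innov)
    scale = np.sqrt(1.0 - ar_coef**2)
    x[:, 0] = innov[:, 0]
    for t in range(1, n_timepoints):
        x[:, t] = ar_coef * x[:, t - 1] + scale * innov[:, t]
    return chance + sd * x
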