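"""Time-resolved pairwise decoding in four schemes.

All schemes classify channel patterns at single timepoints with a linear
maximum-margin classifier (cost fixed at 1.0) and leave-one-super-trial-out
cross-validation, reporting percent correct (chance = 50 for balanced
pairs):

* object level — every pair of object conditions, super-trials built from
  raw trials;
* category level — the two levels of one category dimension, super-trials
  built from per-object averages (train and test never share an object),
  averaged across dimensions;
* leave-one-object-out category variant — train on all object averages but
  one, labeled by category, test on the held-out object;
* cross-modal / temporal generalization — train in one modality, test in the
  other (at the same timepoint, or on the full train x test time grid),
  averaged over both directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .design import StimulusSet
from .noisenorm import NoiseNormalizer, apply_normalizer, fit_noise_normalizer
from .simulate import EpochArray
from .supertrials import (
    SuperTrialSet,
    make_category_supertrials,
    make_object_supertrials,
    object_averages,
)
from .svm import fit_linear_svm_batch, predict

__all__ = [
    "ClassifierSpec",
    "AccuracyTimecourse",
    "pairwise_decode",
    "object_decode",
    "category_decode",
    "leave_one_object_out_category_decode",
    "crossmodal_decode",
    "temporal_generalization",
]

_CHUNK = 40000  # problems per solver batch, keeps peak memory modest


@dataclass(frozen=True)
class ClassifierSpec:
    """Linear maximum-margin classifier on single-timepoint channel patterns."""

    cost: float = 1.0
    kind: str = "linear-svm"


@dataclass
class AccuracyTimecourse:
    """Decoding accuracies: participants x timepoints (or x train x test times).

    Values are percent correct in [0, 100].
    """

    values: np.ndarray
    time_ms: np.ndarray
    scheme: str = ""
    n_repetitions: int = 0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if np.any(self.values < 0) or np.any(self.values > 100):
            raise ValueError("accuracies must lie in [0, 100]")
        if self.values.shape[-1] != np.asarray(self.time_ms).size:
            raise ValueError("last axis must match the time axis")

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    def group_mean(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @classmethod
    def stack(
        cls, per_participant: list[np.ndarray], time_ms: np.ndarray, scheme: str = "",
        n_repetitions: int = 0,
    ) -> "AccuracyTimecourse":
        return cls(
            values=np.stack(per_participant, axis=0),
            time_ms=np.asarray(time_ms),
            scheme=scheme,
            n_repetitions=n_repetitions,
        )


def _chunked_fold_accuracy(
    Xtr: np.ndarray, y: np.ndarray, Xte: np.ndarray, yte: np.ndarray, cost: float
) -> np.ndarray:
    """Fraction correct per problem; problems solved in memory-bounded chunks."""
    B = Xtr.shape[0]
    out = np.empty(B)
    for lo in range(0, B, _CHUNK):
        hi = min(lo + _CHUNK, B)
        w, b = fit_linear_svm_batch(Xtr[lo:hi], y, C=cost)
        pred = predict(w, b, Xte[lo:hi])
        out[lo:hi] = (pred == yte[None, :]).mean(axis=1)
    return out


def _pairwise_accuracy(st: SuperTrialSet, cost: float) -> np.ndarray:
    """Leave-one-super-trial-out accuracy over all condition pairs: (T,) in %."""
    data = st.data  # cond x S x C x T
    n_cond, S, C, T = data.shape
    if n_cond < 2:
        raise ValueError("need at least 2 conditions for pairwise decoding")
    if S < 2:
        raise ValueError("need at least 2 super-trials per condition")
    ia, ib = np.triu_indices(n_cond, k=1)
    n_pairs = ia.size
    acc = np.zeros((n_pairs, T))
    y = np.array([-1.0] * (S - 1) + [1.0] * (S - 1))
    yte = np.array([-1.0, 1.0])
    for fold in range(S):
        others = [s for s in range(S) if s != fold]
        # (n_pairs, n_train, C, T) -> (n_pairs*T, n_train, C)
        Xtr = np.concatenate([data[ia][:, others], data[ib][:, others]], axis=1)
        Xtr = Xtr.transpose(0, 3, 1, 2).reshape(n_pairs * T, 2 * (S - 1), C)
        Xte = np.stack([data[ia, fold], data[ib, fold]], axis=1)
        Xte = Xte.transpose(0, 3, 1, 2).reshape(n_pairs * T, 2, C)
        acc += _chunked_fold_accuracy(Xtr, y, Xte, yte, cost).reshape(n_pairs, T)
    return 100.0 * acc.mean(axis=0) / S


def pairwise_decode(
    st: SuperTrialSet | Callable[[int], SuperTrialSet],
    spec: ClassifierSpec | None = None,
    n_repetitions: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Mean pairwise leave-one-super-trial-out accuracy per timepoint, in %.

    ``st`` is either a fixed SuperTrialSet (a single repetition is run) or a
    callable ``seed -> SuperTrialSet`` that regenerates the super-trials
    with a fresh random partition on each of ``n_repetitions`` repetitions;
    the returned time course is the average over condition pairs, folds and
    repetitions.
    """
    spec = spec or ClassifierSpec()
    if not callable(st):
        return _pairwise_accuracy(st, spec.cost)
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_repetitions)
    acc = None
    for s in rep_seeds:
        a = _pairwise_accuracy(st(int(s)), spec.cost)
        acc = a if acc is None else acc + a
    return acc / n_repetitions


def _maybe_normalizer(epochs: EpochArray, normalize: bool) -> NoiseNormalizer | None:
    return fit_noise_normalizer(epochs) if normalize else None


def object_decode(
    epochs: EpochArray,
    spec: ClassifierSpec | None = None,
    n_repetitions: int = 100,
    seed: int = 0,
    n_groups: int = 3,
    normalize: bool = True,
) -> np.ndarray:
    """Object-level decoding time course (percent correct, (T,))."""
    nn = _maybe_normalizer(epochs, normalize)

    def factory(s: int) -> SuperTrialSet:
        st = make_object_supertrials(epochs, n_groups=n_groups, seed=s)
        return apply_normalizer(st, nn) if nn is not None else st

    return pairwise_decode(factory, spec, n_repetitions, seed)


def category_decode(
    epochs: EpochArray,
    stimset: StimulusSet,
    spec: ClassifierSpec | None = None,
    n_repetitions: int = 100,
    seed: int = 0,
    dimensions: tuple[str, ...] | None = None,
    n_groups: int = 3,
    normalize: bool = True,
    return_dimensions: bool = False,
):
    """Category-level decoding: per-dimension time courses averaged together.

    For each dimension, the two category levels are decoded from object-
    average super-trials (train/test never share an object); the reported
    time course is the mean over dimensions. With ``return_dimensions``,
    also returns the per-dimension dict.
    """
    dims = tuple(dimensions) if dimensions is not None else stimset.dimensions
    nn = _maybe_normalizer(epochs, normalize)
    per_dim: dict[str, np.ndarray] = {}
    rng = np.random.default_rng(seed)
    for dim in dims:
        dim_seed = int(rng.integers(0, 2**31 - 1))

        def factory(s: int, _dim=dim) -> SuperTrialSet:
            st = make_category_supertrials(epochs, stimset, _dim, n_groups=n_groups, seed=s)
            return apply_normalizer(st, nn) if nn is not None else st

        per_dim[dim] = pairwise_decode(factory, spec, n_repetitions, dim_seed)
    mean = np.mean([per_dim[d] for d in dims], axis=0)
    return (mean, per_dim) if return_dimensions else mean


def leave_one_object_out_category_decode(
    epochs: EpochArray,
    stimset: StimulusSet,
    dimension: str,
    spec: ClassifierSpec | None = None,
    seed: int = 0,
    normalize: bool = True,
) -> np.ndarray:
    """Category decoding generalizing across objects by leave-one-object-out.

    Trains on all object averages but one (labeled by category level) and
    tests on the held-out object's average; the accuracy is averaged over
    held-out objects. Deterministic: the folds enumerate objects, so
    ``seed`` only exists for interface symmetry.
    """
    spec = spec or ClassifierSpec()
    if dimension not in stimset.dimensions:
        raise ValueError(f"unknown dimension {dimension!r}")
    objects, avg = object_averages(epochs)
    nn = _maybe_normalizer(epochs, normalize)
    if nn is not None:
        avg = np.einsum("ij,ojt->oit", nn.whitening_transform, avg)
    labels = np.array([int(stimset.labels.loc[o, dimension]) for o in objects])
    for level in (0, 1):
        if (labels == level).sum() < 2:
            raise ValueError(f"level {level} of {dimension!r} needs >= 2 objects")
    n_obj, C, T = avg.shape
    total = np.zeros(T)
    # group folds by held-out level so training labels are shared per batch
    for held_level in (0, 1):
        held = np.flatnonzero(labels == held_level)
        other = np.flatnonzero(labels == 1 - held_level)
        y_held = held_level * 2.0 - 1.0
        accs = np.zeros((held.size, T))
        for k, o in enumerate(held):
            train_idx = np.concatenate([held[held != o], other])
            y = np.concatenate(
                [np.full(held.size - 1, y_held), np.full(other.size, -y_held)]
            )
            Xtr = avg[train_idx].transpose(2, 0, 1)  # (T, n, C)
            w, b = fit_linear_svm_batch(Xtr, y, C=spec.cost)
            score = np.einsum("tc,ct->t", w, avg[o]) + b
            accs[k] = (np.where(score >= 0, 1.0, -1.0) == y_held).astype(float)
        total += accs.sum(axis=0)
    return 100.0 * total / n_obj


def _cross_accuracy(
    st_train: SuperTrialSet, st_test: SuperTrialSet, cost: float
) -> np.ndarray:
    """Train on every super-trial of one set, test on every one of the other."""
    if tuple(st_train.conditions) != tuple(st_test.conditions):
        raise ValueError("train and test super-trial sets have different conditions")
    A, Bb = st_train.data, st_test.data  # cond x S x C x T
    n_cond, S, C, T = A.shape
    ia, ib = np.triu_indices(n_cond, k=1)
    y = np.array([-1.0] * S + [1.0] * S)
    yte = np.array([-1.0] * Bb.shape[1] + [1.0] * Bb.shape[1])
    Xtr = np.concatenate([A[ia], A[ib]], axis=1).transpose(0, 3, 1, 2)
    Xtr = Xtr.reshape(ia.size * T, 2 * S, C)
    Xte = np.concatenate([Bb[ia], Bb[ib]], axis=1).transpose(0, 3, 1, 2)
    Xte = Xte.reshape(ia.size * T, yte.size, C)
    acc = _chunked_fold_accuracy(Xtr, y, Xte, yte, cost).reshape(ia.size, T)
    return 100.0 * acc.mean(axis=0)


def _crossmodal_supertrial_pair(
    epochs_A: EpochArray,
    epochs_B: EpochArray,
    stimset: StimulusSet,
    level: str,
    dim: str | None,
    n_groups: int,
    seeds: tuple[int, int],
    normalizers: tuple[NoiseNormalizer | None, NoiseNormalizer | None],
) -> tuple[SuperTrialSet, SuperTrialSet]:
    sts = []
    for ep, s, nn in zip((epochs_A, epochs_B), seeds, normalizers):
        if level == "category":
            st = make_category_supertrials(ep, stimset, dim, n_groups=n_groups, seed=s)
        else:
            st = make_object_supertrials(ep, n_groups=n_groups, seed=s)
        sts.append(apply_normalizer(st, nn) if nn is not None else st)
    return sts[0], sts[1]


def _crossmodal_core(
    epochs_A: EpochArray,
    epochs_B: EpochArray,
    stimset: StimulusSet,
    spec: ClassifierSpec,
    n_repetitions: int,
    seed: int,
    level: str,
    n_groups: int,
    normalize: bool,
    full_matrix: bool,
) -> np.ndarray:
    if epochs_A.time_ms.size != epochs_B.time_ms.size or not np.allclose(
        epochs_A.time_ms, epochs_B.time_ms
    ):
        raise ValueError("the two modalities must share the same time axis")
    if level not in ("category", "object"):
        raise ValueError("level must be 'category' or 'object'")
    nns = (
        (_maybe_normalizer(epochs_A, True), _maybe_normalizer(epochs_B, True))
        if normalize
        else (None, None)
    )
    dims: tuple = stimset.dimensions if level == "category" else (None,)
    rng = np.random.default_rng(seed)
    acc = None
    n_terms = 0
    for _ in range(n_repetitions):
        for dim in dims:
            seeds = (int(rng.integers(0, 2**31 - 1)), int(rng.integers(0, 2**31 - 1)))
            st_a, st_b = _crossmodal_supertrial_pair(
                epochs_A, epochs_B, stimset, level, dim, n_groups, seeds, nns
            )
            for st_tr, st_te in ((st_a, st_b), (st_b, st_a)):
                a = (
                    _generalization_matrix(st_tr, st_te, spec.cost)
                    if full_matrix
                    else _cross_accuracy(st_tr, st_te, spec.cost)
                )
                acc = a if acc is None else acc + a
                n_terms += 1
    return acc / n_terms


def _generalization_matrix(
    st_train: SuperTrialSet, st_test: SuperTrialSet, cost: float
) -> np.ndarray:
    """Full train-time x test-time accuracy matrix for one direction."""
    A, Bb = st_train.data, st_test.data
    n_cond, S, C, T = A.shape
    ia, ib = np.triu_indices(n_cond, k=1)
    y = np.array([-1.0] * S + [1.0] * S)
    m_te = 2 * Bb.shape[1]
    yte = np.array([-1.0] * Bb.shape[1] + [1.0] * Bb.shape[1])
    out = np.zeros((T, T))
    for p in range(ia.size):
        Xtr = np.concatenate([A[ia[p]], A[ib[p]]], axis=0)  # (2S, C, T)
        w, b = fit_linear_svm_batch(Xtr.transpose(2, 0, 1), y, C=cost)  # (T, C), (T,)
        Xte = np.concatenate([Bb[ia[p]], Bb[ib[p]]], axis=0)  # (m, C, T)
        scores = np.einsum("uc,mct->umt", w, Xte) + b[:, None, None]
        pred = np.where(scores >= 0, 1.0, -1.0)
        out += (pred == yte[None, :, None]).mean(axis=1)
    return 100.0 * out / ia.size


def crossmodal_decode(
    epochs_A: EpochArray,
    epochs_B: EpochArray,
    stimset: StimulusSet,
    spec: ClassifierSpec | None = None,
    n_repetitions: int = 100,
    seed: int = 0,
    level: str = "category",
    n_groups: int = 3,
    normalize: bool = True,
) -> np.ndarray:
    """Cross-modal decoding time course, averaged over both directions.

    At every timepoint a classifier is trained on all super-trials of one
    modality and tested on all super-trials of the other, in both
    directions; with ``level='category'`` (default) the super-trials are
    category-level (object-average based) and the result is also averaged
    over category dimensions.
    """
    return _crossmodal_core(
        epochs_A, epochs_B, stimset, spec or ClassifierSpec(), n_repetitions, seed,
        level, n_groups, normalize, full_matrix=False,
    )


def temporal_generalization(
    epochs_A: EpochArray,
    epochs_B: EpochArray,
    stimset: StimulusSet,
    spec: ClassifierSpec | None = None,
    n_repetitions: int = 100,
    seed: int = 0,
    level: str = "category",
    n_groups: int = 3,
    normalize: bool = True,
) -> np.ndarray:
    """Cross-modal temporal generalization: (train_time, test_time) accuracy.

    Classifiers trained at each timepoint of one modality are tested at all
    timepoints of the other; the matrix is averaged over both train/test
    directions (and category dimensions). Its diagonal equals the output of
    :func:`crossmodal_decode` for the same seed.
    """
    return _crossmodal_core(
        epochs_A, epochs_B, stimset, spec or ClassifierSpec(), n_repetitions, seed,
        level, n_groups, normalize, full_matrix=True,
    )
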