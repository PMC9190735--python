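"""Super-trial (pseudo-trial) construction for the two decoding schemes.

A super-trial is the average of a random subset of same-condition exemplars.
Averaging before classification raises the signal-to-noise ratio of the
patterns the classifier sees. Two schemes are supported:

* object level — the exemplars are raw trials of one object condition;
* category level — the exemplars are per-object averages, partitioned within
  each category level so that no individual object ever contributes to more
  than one super-trial (and hence train and test folds downstream never
  share an object).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .design import StimulusSet
from .simulate import EpochArray

__all__ = [
    "SuperTrialSet",
    "make_object_supertrials",
    "make_category_supertrials",
    "object_averages",
]


@dataclass
class SuperTrialSet:
    """conditions x n_supertrials x channels x timepoints averaged patterns.

    ``provenance[condition]`` is a tuple of tuples: the source items (trial
    indices, or object ids for the category scheme) averaged into each
    super-trial. Source items are pairwise disjoint across super-trials.
    """

    conditions: tuple
    data: np.ndarray
    time_ms: np.ndarray
    provenance: dict
    scheme: str = "object"
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be condition x supertrial x channel x time")
        if self.data.shape[0] != len(self.conditions):
            raise ValueError("condition axis does not match condition labels")

    @property
    def n_supertrials(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]


def _partition(items: np.ndarray, n_groups: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random near-equal partition; remainders land in random groups."""
    perm = rng.permutation(items)
    return np.array_split(perm, n_groups)


def make_object_supertrials(
    epochs: EpochArray, n_groups: int = 3, seed: int = 0
) -> SuperTrialSet:
    """Randomly partition each object's trials into ``n_groups`` and average.

    Raises if any object condition has fewer usable trials than groups.
    """
    rng = np.random.default_rng(seed)
    objects = tuple(sorted(epochs.trial_meta["object_id"].unique()))
    counts = epochs.trial_meta["object_id"].value_counts()
    too_few = [o for o in objects if counts[o] < n_groups]
    if too_few:
        raise ValueError(
            f"conditions with fewer than {n_groups} trials: {too_few[:5]}"
        )
    n_cond = len(objects)
    out = np.empty((n_cond, n_groups, epochs.n_channels, epochs.n_times))
    provenance: dict = {}
    obj_col = epochs.trial_meta["object_id"].to_numpy()
    for ci, obj in enumerate(objects):
        idx = np.flatnonzero(obj_col == obj)
        groups = _partition(idx, n_groups, rng)
        provenance[obj] = tuple(tuple(int(i) for i in g) for g in groups)
        for gi, g in enumerate(groups):
            out[ci, gi] = epochs.data[g].mean(axis=0)
    return SuperTrialSet(
        conditions=objects,
        data=out,
        time_ms=epochs.time_ms.copy(),
        provenance=provenance,
        scheme="object",
    )


def object_averages(epochs: EpochArray) -> tuple[tuple, np.ndarray]:
    """Average all trials of each object: (object ids, objects x channels x time)."""
    objects = tuple(sorted(epochs.trial_meta["object_id"].unique()))
    obj_col = epochs.trial_meta["object_id"].to_numpy()
    avg = np.stack(
        [epochs.data[obj_col == obj].mean(axis=0) for obj in objects], axis=0
    )
    return objects, avg


def make_category_supertrials(
    epochs: EpochArray,
    stimset: StimulusSet,
    dimension: str,
    n_groups: int = 3,
    seed: int = 0,
) -> SuperTrialSet:
    """Category-level super-trials from per-object averages.

    All trials are first averaged per object; within each of the dimension's
    two levels the object averages are randomly partitioned into
    ``n_groups`` groups and averaged. Provenance records the object ids in
    each super-trial, so a downstream fold can guarantee train and test
    share no object.
    """
    if dimension not in stimset.dimensions:
        raise ValueError(f"unknown dimension {dimension!r}")
    objects, avg = object_averages(epochs)
    obj_pos = {o: i for i, o in enumerate(objects)}
    levels = (0, 1)
    for level in levels:
        members = [o for o in stimset.level_members(dimension, level) if o in obj_pos]
        if len(members) < n_groups:
            raise ValueError(
                f"level {level} of {dimension!r} has {len(members)} objects "
                f"< n_groups={n_groups}"
            )
    n_ch, n_t = avg.shape[1], avg.shape[2]
    out = np.empty((2, n_groups, n_ch, n_t))
    provenance: dict = {}
    for li, level in enumerate(levels):
        members = np.array(
            sorted(o for o in stimset.level_members(dimension, level) if o in obj_pos)
        )
        # per-level stream keyed by the member set, not the level label, so a
        # symmetric relabeling of the two levels yields the same partitions
        level_rng = np.random.default_rng(
            [seed, zlib.crc32(",".join(members).encode())]
        )
        groups = _partition(members, n_groups, level_rng)
        provenance[(dimension, level)] = tuple(tuple(g.tolist()) for g in groups)
        for gi, g in enumerate(groups):
            out[li, gi] = avg[[obj_pos[o] for o in g]].mean(axis=0)
    return SuperTrialSet(
        conditions=((dimension, 0), (dimension, 1)),
        data=out,
        time_ms=epochs.time_ms.copy(),
        provenance=provenance,
        scheme="category",
    )
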