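"""Experimental design structures: balanced stimulus sets and trial sequences.

The design emulated here is a two-modality (auditory/visual) object
presentation experiment: a set of objects, each assigned to one level of
several orthogonal binary category dimensions (e.g. size, movement,
naturalness), presented repeatedly across runs with a one-back repetition
task interleaved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_DIMENSIONS = ("size", "movement", "naturalness")

__all__ = [
    "StimulusSet",
    "DesignSpec",
    "build_stimulus_set",
    "generate_trial_sequence",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = ["trial_index", "run_index", "modality", "object_id", "is_oneback_repeat"]


class DesignError(ValueError):
    """Raised when a requested design is structurally infeasible."""


@dataclass(frozen=True)
class StimulusSet:
    """A set of object conditions with balanced binary category labels.

    Parameters
    ----------
    object_ids
        Condition identifiers, one per object.
    labels
        DataFrame indexed by ``object_ids`` with one column per category
        dimension; entries are 0/1 level codes. Each dimension splits the
        objects exactly in half, and every level combination is carried by
        the same number of objects.
    """

    object_ids: tuple[str, ...]
    labels: pd.DataFrame

    @property
    def dimensions(self) -> tuple[str, ...]:
        return tuple(self.labels.columns)

    @property
    def n_objects(self) -> int:
        return len(self.object_ids)

    def level_members(self, dimension: str, level: int) -> tuple[str, ...]:
        """Object ids carrying ``level`` on ``dimension``."""
        mask = self.labels[dimension] == level
        return tuple(self.labels.index[mask])

    def validate(self) -> None:
        n = self.n_objects
        if list(self.labels.index) != list(self.object_ids):
            raise DesignError("labels index must equal object_ids")
        for dim in self.dimensions:
            counts = self.labels[dim].value_counts()
            if set(counts.index) != {0, 1} or counts[0] != counts[1]:
                raise DesignError(f"dimension {dim!r} does not split objects 50/50")
        combo_counts = self.labels.groupby(list(self.dimensions)).size()
        if combo_counts.nunique() != 1:
            raise DesignError("level combinations are not equally represented")
        expected = n // 2 ** len(self.dimensions)
        if combo_counts.iloc[0] != expected:
            raise DesignError("unexpected objects-per-combination count")


@dataclass(frozen=True)
class DesignSpec:
    """Session-level design parameters.

    Defaults reproduce the study design: 48 objects in 3 orthogonal binary
    dimensions, 8 auditory and 6 visual runs, 5 presentations per stimulus
    per run, 20 % one-back repeat trials (300 trials per run), epochs from
    -200 to +800 ms sampled at 1000 Hz and analysed at 200 Hz on 63 channels.
    """

    n_objects: int = 48
    n_dims: int = 3
    runs_per_modality: dict = field(default_factory=lambda: {"auditory": 8, "visual": 6})
    reps_per_stim_per_run: int = 5
    oneback_fraction: float = 0.20
    epoch_window: tuple[float, float] = (-200.0, 800.0)
    fs_raw: float = 1000.0
    fs_target: float = 200.0
    n_channels: int = 63

    def __post_init__(self) -> None:
        if not (0 <= self.oneback_fraction < 0.5):
            raise DesignError("oneback_fraction must be in [0, 0.5)")
        for name in ("n_objects", "n_dims", "reps_per_stim_per_run", "n_channels"):
            if getattr(self, name) <= 0:
                raise DesignError(f"{name} must be positive")
        lo, hi = self.epoch_window
        if not (lo < 0 < hi):
            raise DesignError("epoch_window must straddle stimulus onset (start < 0 < end)")
        if self.fs_target > self.fs_raw:
            raise DesignError("fs_target cannot exceed fs_raw")

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(self.runs_per_modality)

    def trials_per_run(self) -> int:
        """Total run length including one-back repeats."""
        base = self.n_objects * self.reps_per_stim_per_run
        return base + _n_repeats(base, self.oneback_fraction)


def _n_repeats(n_base: int, fraction: float) -> int:
    # repeats / (base + repeats) = fraction  =>  repeats = f * base / (1 - f)
    r = fraction * n_base / (1.0 - fraction)
    r_int = int(round(r))
    if abs(r - r_int) > 1e-9:
        # non-integer repeat count: round, the realised fraction deviates slightly
        pass
    if r_int > n_base:
        raise DesignError("oneback_fraction too high for sequence length")
    return r_int


def build_stimulus_set(
    n_objects: int = 48,
    n_dims: int = 3,
    seed: int = 0,
    dimension_names: tuple[str, ...] | None = None,
) -> StimulusSet:
    """Build a balanced stimulus set.

    Every object gets one level per dimension, each dimension splits the set
    exactly in half, and each of the ``2**n_dims`` level combinations is
    assigned to ``n_objects / 2**n_dims`` objects. The (seeded) randomness
    only shuffles which object id lands in which combination.
    """
    n_combos = 2**n_dims
    if n_objects % n_combos != 0:
        raise DesignError(
            f"n_objects={n_objects} is not divisible by 2**n_dims={n_combos}; "
            "a balanced assignment is impossible"
        )
    if dimension_names is None:
        dimension_names = tuple(DEFAULT_DIMENSIONS[:n_dims]) + tuple(
            f"dim{i}" for i in range(len(DEFAULT_DIMENSIONS), n_dims)
        )
    if len(dimension_names) != n_dims:
        raise DesignError("dimension_names length must equal n_dims")

    rng = np.random.default_rng(seed)
    per_combo = n_objects // n_combos
    combos = np.array(
        [[(c >> d) & 1 for d in range(n_dims)] for c in range(n_combos)], dtype=int
    )
    assignment = np.repeat(np.arange(n_combos), per_combo)
    rng.shuffle(assignment)

    width = max(2, len(str(n_objects - 1)))
    object_ids = tuple(f"obj{i:0{width}d}" for i in range(n_objects))
    labels = pd.DataFrame(
        combos[assignment], index=list(object_ids), columns=list(dimension_names)
    )
    ss = StimulusSet(object_ids=object_ids, labels=labels)
    ss.validate()
    return ss


def _shuffle_no_adjacent(items: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shuffle so no two adjacent entries are equal (repair-based)."""
    seq = items.copy()
    for _ in range(200):
        rng.shuffle(seq)
        for _ in range(20 * len(seq)):
            bad = np.flatnonzero(seq[1:] == seq[:-1]) + 1
            if bad.size == 0:
                return seq
            i = bad[0]
            # swap seq[i] with a position where neither side conflicts
            cand = np.flatnonzero(
                (seq != seq[i])
                & (np.roll(seq, 1) != seq[i])
                & (np.roll(seq, -1) != seq[i])
            )
            cand = cand[(cand != i - 1) & (cand != i)]
            if cand.size == 0:
                break
            j = rng.choice(cand)
            # ensure moving seq[j] out does not create a clash at j
            if (j > 0 and seq[j - 1] == seq[i]) or (
                j < len(seq) - 1 and seq[j + 1] == seq[i]
            ):
                continue
            seq[i], seq[j] = seq[j], seq[i]
        # fall through: reshuffle and retry
    raise DesignError("could not build a sequence without immediate repeats")


def generate_trial_sequence(
    design: DesignSpec, modality: str, seed: int = 0
) -> pd.DataFrame:
    """Generate the full trial table for one modality of a session.

    Per run, every object receives exactly ``reps_per_stim_per_run``
    unflagged presentations in a pseudorandom order without immediate
    repeats; one-back repeat trials (flagged, same object as the preceding
    trial) are then inserted at random non-adjacent positions until they
    make up ``oneback_fraction`` of the run.

    Returns a DataFrame with columns ``trial_index`` (session-wide),
    ``run_index``, ``modality``, ``object_id``, ``is_oneback_repeat``.
    """
    if modality not in design.runs_per_modality:
        raise DesignError(f"unknown modality {modality!r}")
    rng = np.random.default_rng(seed)
    stim_width = max(2, len(str(design.n_objects - 1)))
    objects = np.array([f"obj{i:0{stim_width}d}" for i in range(design.n_objects)])

    n_base = design.n_objects * design.reps_per_stim_per_run
    n_rep = _n_repeats(n_base, design.oneback_fraction)

    rows: list[tuple] = []
    trial_index = 0
    for run in range(design.runs_per_modality[modality]):
        base = _shuffle_no_adjacent(np.repeat(objects, design.reps_per_stim_per_run), rng)
        # each base position hosts at most one repeat => no two consecutive flags
        host = np.sort(rng.choice(n_base, size=n_rep, replace=False))
        hosts = set(host.tolist())
        for i, obj in enumerate(base):
            rows.append((trial_index, run, modality, obj, False))
            trial_index += 1
            if i in hosts:
                rows.append((trial_index, run, modality, obj, True))
                trial_index += 1
    table = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return table
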