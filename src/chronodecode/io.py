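"""Serialization: HDF5 epoch container and tab-separated result tables."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .decoding import AccuracyTimecourse
from .inference import ClusterInferenceResult, PeakLatencyTest
from .simulate import EpochArray
from .supertrials import SuperTrialSet

__all__ = [
    "save_epochs",
    "load_epochs",
    "write_trial_table",
    "read_trial_table",
    "write_accuracy",
    "read_accuracy",
    "write_generalization",
    "write_clusters",
    "write_bootstrap",
    "write_provenance",
    "read_brainvision_epochs",
]


def save_epochs(path, epochs_by_participant: dict[str, EpochArray]) -> None:
    """Write epochs to an HDF5 file, one group per participant.

    Each group holds ``data`` (trials x channels x timepoints), ``time_ms``,
    a ``fs`` attribute, and the trial metadata table as columnar datasets
    under ``trial_meta/``.
    """
    with h5py.File(path, "w") as f:
        for pid, ep in epochs_by_participant.items():
            g = f.create_group(pid)
            g.create_dataset("data", data=ep.data, compression="gzip", compression_opts=1)
            g.create_dataset("time_ms", data=ep.time_ms)
            g.attrs["fs"] = ep.fs
            meta = g.create_group("trial_meta")
            for col in ep.trial_meta.columns:
                vals = ep.trial_meta[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                meta.create_dataset(col, data=vals)
            meta.attrs["columns"] = json.dumps(list(ep.trial_meta.columns))


def load_epochs(path) -> dict[str, EpochArray]:
    out: dict[str, EpochArray] = {}
    with h5py.File(path, "r") as f:
        for pid in f:
            g = f[pid]
            cols = json.loads(g["trial_meta"].attrs["columns"])
            meta = {}
            for col in cols:
                vals = g["trial_meta"][col][()]
                if vals.dtype.kind == "S":
                    vals = vals.astype(str)
                meta[col] = vals
            out[pid] = EpochArray(
                data=g["data"][()],
                time_ms=g["time_ms"][()],
                fs=float(g.attrs["fs"]),
                trial_meta=pd.DataFrame(meta),
                participant_id=pid,
            )
    return out


def write_trial_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_trial_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_accuracy(path, acc: AccuracyTimecourse) -> None:
    """Participants x timepoints accuracy as TSV; columns are times in ms."""
    if acc.values.ndim != 2:
        raise ValueError("use write_generalization for train x test matrices")
    df = pd.DataFrame(
        acc.values,
        columns=[f"{t:g}" for t in acc.time_ms],
        index=[f"p{i:02d}" for i in range(acc.n_participants)],
    )
    df.index.name = "participant"
    df.to_csv(path, sep="\t")


def read_accuracy(path, scheme: str = "") -> AccuracyTimecourse:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return AccuracyTimecourse(
        values=df.to_numpy(),
        time_ms=np.array([float(c) for c in df.columns]),
        scheme=scheme,
    )


def write_generalization(path, acc: AccuracyTimecourse) -> None:
    """Long-format TSV: train_ms, test_ms, participant, accuracy."""
    if acc.values.ndim != 3:
        raise ValueError("expected participants x train_time x test_time values")
    P, Ttr, Tte = acc.values.shape
    rows = []
    for p in range(P):
        for i in range(Ttr):
            for j in range(Tte):
                rows.append((acc.time_ms[i], acc.time_ms[j], f"p{p:02d}", acc.values[p, i, j]))
    pd.DataFrame(rows, columns=["train_ms", "test_ms", "participant", "accuracy"]).to_csv(
        path, sep="\t", index=False
    )


def write_clusters(path, result: ClusterInferenceResult, scheme: str = "") -> None:
    rows = [
        (scheme, c.start_ms, c.end_ms, c.size, c.p_value, c.significant)
        for c in result.clusters
    ]
    pd.DataFrame(
        rows, columns=["scheme", "start_ms", "end_ms", "size", "p_value", "significant"]
    ).to_csv(path, sep="\t", index=False)


def write_bootstrap(path, test: PeakLatencyTest) -> None:
    pd.DataFrame({"peak_diff_ms": test.boot_differences}).to_csv(path, sep="\t", index=False)


def write_provenance(path, st: SuperTrialSet) -> None:
    rows = []
    for cond, groups in st.provenance.items():
        for gi, items in enumerate(groups):
            rows.append((str(cond), gi, ",".join(str(i) for i in items)))
    pd.DataFrame(rows, columns=["condition", "supertrial", "sources"]).to_csv(
        path, sep="\t", index=False
    )


def read_brainvision_epochs(vhdr_path, window_ms=(-200.0, 800.0)):
    """Read a BrainVision recording and return the raw object (delegated to mne).

    Optional convenience for recorded EEG; nothing in the pipeline requires
    it. Raises ImportError when mne is not installed.
    """
    import mne  # noqa: deferred import, optional dependency

    return mne.io.read_raw_brainvision(Path(vhdr_path), preload=True, verbose="error")
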