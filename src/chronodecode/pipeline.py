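"""End-to-end orchestration: synthesize -> preprocess -> decode -> infer.

Runs are fully reproducible: every stage's randomness derives from the
config's global seed, and a manifest (config echo, seeds, version, stage
timings) is written next to the result tables.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .decoding import (
    AccuracyTimecourse,
    ClassifierSpec,
    category_decode,
    crossmodal_decode,
    object_decode,
    temporal_generalization,
)
from .design import build_stimulus_set, generate_trial_sequence
from .inference import bootstrap_peak_latency_difference, cluster_permutation_test
from .io import (
    write_accuracy,
    write_bootstrap,
    write_clusters,
    write_generalization,
    write_trial_table,
)
from .preprocess import downsample, reject_artifacts
from .simulate import (
    EpochArray,
    default_noise_cov,
    drop_oneback,
    make_signal_model,
    simulate_epochs,
)

__all__ = ["run_pipeline", "summarize", "simulate_participant"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def simulate_participant(
    config: RunConfig, stimset, participant: int, seed: int
) -> dict[str, EpochArray]:
    """Simulate, artifact-reject and downsample one participant's session.

    Returns analysis-ready epochs (one-back repeats dropped) per modality.
    Patterns are drawn fresh per participant; onsets, SNR and the noise
    model are shared across participants.
    """
    design = config.design
    sig = config.signal
    model = make_signal_model(
        stimset,
        design.n_channels,
        seed=seed,
        snr=sig.snr,
        object_onset_ms=sig.object_onset_ms,
        category_onset_ms=sig.category_onset_ms,
        shared_modality_code=sig.shared_modality_code,
        modalities=design.modalities,
        noise_cov=default_noise_cov(design.n_channels, sig.noise_length_scale),
        ramp_ms=sig.ramp_ms,
        sustain_level=sig.sustain_level,
        decay_ms=sig.decay_ms,
        object_strength=sig.object_strength,
        category_strength=sig.category_strength,
    )
    rng = np.random.default_rng(seed)
    out: dict[str, EpochArray] = {}
    for modality in design.modalities:
        trials = generate_trial_sequence(design, modality, seed=int(rng.integers(2**31)))
        fs = design.fs_target if config.simulate_at_analysis_rate else None
        ep = simulate_epochs(
            trials, stimset, model, design,
            seed=int(rng.integers(2**31)),
            fs=fs,
            participant_id=f"p{participant:02d}",
        )
        ep, _ = reject_artifacts(ep, config.artifact_z_threshold)
        if ep.fs > design.fs_target:
            ep = downsample(ep, design.fs_target)
        out[modality] = drop_oneback(ep)
    return out


def _decode_stage(config: RunConfig, stimset, epochs, rng) -> dict[str, AccuracyTimecourse]:
    spec = ClassifierSpec(cost=config.classifier_cost)
    modalities = config.design.modalities
    results: dict[str, list[np.ndarray]] = {}
    time_ms = None
    for p_eps in epochs:
        time_ms = next(iter(p_eps.values())).time_ms
        for scheme in config.schemes:
            if scheme == "object":
                for mod in modalities:
                    acc = object_decode(
                        p_eps[mod], spec, config.n_repetitions,
                        seed=int(rng.integers(2**31)), n_groups=config.n_supertrials,
                    )
                    results.setdefault(f"object_{mod}", []).append(acc)
            elif scheme == "category":
                for mod in modalities:
                    acc = category_decode(
                        p_eps[mod], stimset, spec, config.n_repetitions,
                        seed=int(rng.integers(2**31)), n_groups=config.n_supertrials,
                    )
                    results.setdefault(f"category_{mod}", []).append(acc)
            elif scheme == "crossmodal":
                a, b = (p_eps[m] for m in modalities[:2])
                acc = crossmodal_decode(
                    a, b, stimset, spec, config.n_repetitions,
                    seed=int(rng.integers(2**31)),
                    level=config.crossmodal_level, n_groups=config.n_supertrials,
                )
                results.setdefault("crossmodal", []).append(acc)
            elif scheme == "generalization":
                a, b = (p_eps[m] for m in modalities[:2])
                acc = temporal_generalization(
                    a, b, stimset, spec, config.n_repetitions,
                    seed=int(rng.integers(2**31)),
                    level=config.crossmodal_level, n_groups=config.n_supertrials,
                )
                results.setdefault("generalization", []).append(acc)
    return {
        name: AccuracyTimecourse.stack(accs, time_ms, scheme=name,
                                       n_repetitions=config.n_repetitions)
        for name, accs in results.items()
    }


def run_pipeline(config: RunConfig, output_dir, force: bool = False) -> Path:
    """Run all configured stages and write result tables plus a manifest.

    Refuses to write into a non-empty directory unless ``force`` is set, so
    completed runs are never silently overwritten.
    """
    out = Path(output_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise PipelineError("setup", f"output directory {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    rng = np.random.default_rng(config.seed)

    t0 = time.perf_counter()
    try:
        stimset = build_stimulus_set(
            config.design.n_objects, config.design.n_dims, seed=int(rng.integers(2**31))
        )
        stimset.labels.to_csv(out / "stimulus_set.tsv", sep="\t")
        epochs = []
        for p in range(config.n_participants):
            p_eps = simulate_participant(config, stimset, p, seed=int(rng.integers(2**31)))
            if p == 0:
                for mod, ep in p_eps.items():
                    write_trial_table(out / f"trials_p00_{mod}.tsv", ep.trial_meta)
            epochs.append(p_eps)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - stage-named reraise
        raise PipelineError("simulate", str(e)) from e
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        timecourses = _decode_stage(config, stimset, epochs, rng)
        for name, acc in timecourses.items():
            if acc.values.ndim == 2:
                write_accuracy(out / f"accuracy_{name}.tsv", acc)
            else:
                write_generalization(out / f"accuracy_{name}.tsv", acc)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("decode", str(e)) from e
    timings["decode"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        stats_summary: dict[str, dict] = {}
        for name, acc in timecourses.items():
            if acc.values.ndim != 2:
                continue
            res = cluster_permutation_test(
                acc, chance=config.chance_level, n_permutations=config.n_permutations,
                alpha=config.alpha, seed=int(rng.integers(2**31)),
            )
            write_clusters(out / f"clusters_{name}.tsv", res, scheme=name)
            stats_summary[name] = {
                "onset_ms": res.onset_ms(),
                "offset_ms": res.offset_ms(),
                "n_significant_clusters": sum(c.significant for c in res.clusters),
                "peak_ms": float(acc.time_ms[int(np.argmax(acc.group_mean()))]),
                "peak_accuracy": float(acc.group_mean().max()),
            }
        for mod in config.design.modalities:
            a, b = f"object_{mod}", f"category_{mod}"
            if a in timecourses and b in timecourses:
                test = bootstrap_peak_latency_difference(
                    timecourses[a], timecourses[b],
                    n_bootstrap=config.n_bootstrap, seed=int(rng.integers(2**31)),
                )
                write_bootstrap(out / f"peak_bootstrap_{mod}.tsv", test)
                stats_summary[f"peak_test_{mod}"] = {
                    "peak_ms_object": test.peak_ms_a,
                    "peak_ms_category": test.peak_ms_b,
                    "p_object_later": test.p_a_later,
                    "p_category_later": test.p_b_later,
                }
        with open(out / "stats_summary.json", "w") as f:
            json.dump(stats_summary, f, indent=2)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("stats", str(e)) from e
    timings["stats"] = time.perf_counter() - t0

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "schemes": sorted(timecourses),
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return out


def summarize(results_dir, plot: bool = False) -> str:
    """Human-readable report of a completed run (onsets, peaks, p-values)."""
    out = Path(results_dir)
    stats_path = out / "stats_summary.json"
    if not stats_path.exists():
        raise FileNotFoundError(f"missing {stats_path}; is this a completed run?")
    with open(stats_path) as f:
        stats = json.load(f)
    lines = [f"Results in {out}"]
    for name, s in stats.items():
        if name.startswith("peak_test_"):
            mod = name.removeprefix("peak_test_")
            lines.append(
                f"  peak-latency test ({mod}): object {s['peak_ms_object']:g} ms vs "
                f"category {s['peak_ms_category']:g} ms; "
                f"p(object later) = {s['p_object_later']:.3f}, "
                f"p(category later) = {s['p_category_later']:.3f}"
            )
        else:
            if s["onset_ms"] is None:
                lines.append(f"  {name}: no significant timepoints")
            else:
                lines.append(
                    f"  {name}: significant {s['onset_ms']:g}-{s['offset_ms']:g} ms "
                    f"({s['n_significant_clusters']} cluster(s)); "
                    f"peak {s['peak_accuracy']:.1f} % at {s['peak_ms']:g} ms"
                )
    report = "\n".join(lines)
    if plot:
        _plot_timecourses(out)
        report += f"\nplots written to {out}"
    return report


def _plot_timecourses(out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .io import read_accuracy

    for path in sorted(out.glob("accuracy_*.tsv")):
        name = path.stem.removeprefix("accuracy_")
        if name == "generalization":
            continue
        acc = read_accuracy(path, scheme=name)
        fig, ax = plt.subplots(figsize=(6, 3))
        m = acc.group_mean()
        se = acc.values.std(axis=0, ddof=1) / np.sqrt(acc.n_participants)
        ax.fill_between(acc.time_ms, m - se, m + se, alpha=0.3)
        ax.plot(acc.time_ms, m)
        ax.axhline(50, color="k", lw=0.5)
        ax.axvline(0, color="k", lw=0.5)
        ax.set(xlabel="time (ms)", ylabel="accuracy (%)", title=name)
        fig.tight_layout()
        fig.savefig(out / f"plot_{name}.png", dpi=100)
        plt.close(fig)
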