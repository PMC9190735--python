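import pytest

import chronodecode as cd


@pytest.fixture(scope="session")
def small_design() -> cd.DesignSpec:
    """Desk-scale session: 8 objects, 2 runs/modality, 200 Hz analysis axis."""
    return cd.DesignSpec(
        n_objects=8,
        runs_per_modality={"auditory": 2, "visual": 2},
        reps_per_stim_per_run=3,
        epoch_window=(-100.0, 500.0),
        fs_raw=200.0,
        fs_target=200.0,
        n_channels=16,
    )


@pytest.fixture(scope="session")
def stimset8() -> cd.StimulusSet:
    return cd.build_stimulus_set(8, 3, seed=11)


def make_epochs(
    design,
    stimset,
    seed,
    modality="auditory",
    snr=3.0,
    object_onset_ms=75.0,
    category_onset_ms=305.0,
    shared_modality_code=False,
    drop_repeats=True,
    **model_kwargs,
):
    """Simulate one participant-modality at the analysis rate, repeats dropped."""
    model = cd.make_signal_model(
        stimset,
        design.n_channels,
        seed=seed,
        snr=snr,
        object_onset_ms=object_onset_ms,
        category_onset_ms=category_onset_ms,
        shared_modality_code=shared_modality_code,
        **model_kwargs,
    )
    trials = cd.generate_trial_sequence(design, modality, seed=seed + 1)
    ep = cd.simulate_epochs(
        trials, stimset, model, design, seed=seed + 2, fs=design.fs_target
    )
    return cd.drop_oneback(ep) if drop_repeats else ep


@pytest.fixture(scope="session")
def epochs_signal(small_design, stimset8) -> cd.EpochArray:
    """High-SNR epochs with object onset 75 ms, category onset 305 ms."""
    return make_epochs(small_design, stimset8, seed=100)


@pytest.fixture(scope="session")
def epochs_null(small_design, stimset8) -> cd.EpochArray:
    """Noise-only epochs (snr = 0)."""
    return make_epochs(small_design, stimset8, seed=200, snr=0.0)
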