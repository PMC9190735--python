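"""Run configuration: every pipeline constant in one overridable structure.

Defaults are the study's analysis constants: classifier cost 1, 3
super-trials, 100 super-trial repetitions, 10,000 sign-flip permutations,
1,000 bootstrap samples, alpha 0.05, 50 % chance level.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
import yaml

from .design import DesignSpec

__all__ = ["SignalConfig", "RunConfig", "load_config"]

ALL_SCHEMES = ("object", "category", "crossmodal", "generalization")


@dataclass
class SignalConfig:
    """Planted-signal parameters for the synthetic generator."""

    snr: float = 1.0
    object_onset_ms: float = 75.0
    category_onset_ms: float = 305.0
    shared_modality_code: bool = False
    ramp_ms: float = 20.0
    sustain_level: float = 1.0
    decay_ms: float = 100.0
    object_strength: float = 1.0
    category_strength: float = 1.0
    noise_length_scale: float = 5.0


@dataclass
class RunConfig:
    design: DesignSpec = field(default_factory=DesignSpec)
    signal: SignalConfig = field(default_factory=SignalConfig)
    n_participants: int = 12
    schemes: tuple[str, ...] = ("object", "category")
    classifier_cost: float = 1.0
    n_supertrials: int = 3
    n_repetitions: int = 100
    n_permutations: int = 10000
    n_bootstrap: int = 1000
    alpha: float = 0.05
    chance_level: float = 50.0
    seed: int = 0
    simulate_at_analysis_rate: bool = False
    artifact_z_threshold: float = 20.0
    crossmodal_level: str = "category"

    def __post_init__(self) -> None:
        unknown = set(self.schemes) - set(ALL_SCHEMES)
        if unknown:
            raise ValueError(f"unknown schemes: {sorted(unknown)}; valid: {ALL_SCHEMES}")
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants for group inference")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schemes"] = list(self.schemes)
        d["design"]["epoch_window"] = list(self.design.epoch_window)
        return d


def _from_section(cls, data: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML file; absent keys keep their defaults."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    design = raw.pop("design", {})
    if "epoch_window" in design:
        design["epoch_window"] = tuple(design["epoch_window"])
    signal = raw.pop("signal", {})
    if "schemes" in raw:
        raw["schemes"] = tuple(raw["schemes"])
    cfg_kwargs = dict(raw)
    cfg_kwargs["design"] = _from_section(DesignSpec, design)
    cfg_kwargs["signal"] = _from_section(SignalConfig, signal)
    return _from_section(RunConfig, cfg_kwargs)
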