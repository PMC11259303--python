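"""Run configuration: schema-validated YAML with filled defaults.

Unknown keys are rejected (a typo must fail loudly, not silently fall
back to a default), and cross-field constraints — window length vs
sampling rate, wavelet depth vs window samples, band edges vs Nyquist —
are checked at load time.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from vims_eeg.preprocess import DEFAULT_MONTAGE


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimSection(_Section):
    n_subjects: int = Field(default=25, ge=1)
    n_videos: int = Field(default=20, ge=1)
    duration_s: float = Field(default=120.0, gt=0)
    fs: float = Field(default=500.0, gt=0)
    contrast: float = Field(default=1.0, ge=0, le=1)
    onset_s: float = Field(default=56.0, ge=0)
    onset_slope: float = Field(default=0.15, gt=0)
    pink_noise_sd: float = Field(default=2.0, ge=0)
    white_noise_sd: float = Field(default=1.0, ge=0)


class PreprocessSection(_Section):
    low_hz: float = Field(default=0.5, gt=0)
    high_hz: float = Field(default=50.0, gt=0)
    channels: list[str] = Field(default_factory=lambda: list(DEFAULT_MONTAGE))
    reference: str = Field(default="mastoids", pattern="^(mastoids|average)$")
    pca: bool = False
    pca_var_threshold: float = Field(default=0.35, gt=0, le=1)
    pca_kurtosis_threshold: float = Field(default=8.0)


class FeatureSection(_Section):
    wpt_level: int = Field(default=8, ge=1, le=12)
    frames_per_second: float = Field(default=10.0, gt=0)
    wavelet: str = "db4"


class TrainSection(_Section):
    window_s: float = Field(default=10.0, gt=0)
    lr: float = Field(default=5e-5, gt=0)
    batch_size: int = Field(default=4, ge=1)
    epochs: int = Field(default=50, ge=1)
    weight_decay: float = Field(default=1e-8, ge=0)
    val_fraction: float = Field(default=0.15, gt=0, lt=1)
    test_fraction: float = Field(default=0.15, gt=0, lt=1)


class PredictSection(_Section):
    window_s: float = Field(default=10.0, gt=0)
    stride_s: float = Field(default=2.0, gt=0)


class RunConfig(_Section):
    seed: int = 0
    sim: SimSection = Field(default_factory=SimSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    features: FeatureSection = Field(default_factory=FeatureSection)
    training: TrainSection = Field(default_factory=TrainSection)
    predict: PredictSection = Field(default_factory=PredictSection)

    @model_validator(mode="after")
    def _cross_field(self) -> "RunConfig":
        fs = self.sim.fs
        for name, w in (("training.window_s", self.training.window_s),
                        ("predict.window_s", self.predict.window_s)):
            ns = w * fs
            if abs(ns - round(ns)) > 1e-6:
                raise ValueError(f"{name} * sim.fs = {ns} is not an integer "
                                 "number of samples")
        win_samples = int(round(self.training.window_s * fs))
        if win_samples < 2 ** self.features.wpt_level:
            raise ValueError(
                f"window of {win_samples} samples too short for WPT level "
                f"{self.features.wpt_level} (needs >= {2 ** self.features.wpt_level})")
        if not self.preprocess.low_hz < self.preprocess.high_hz < fs / 2:
            raise ValueError("preprocess band edges must satisfy "
                             f"low < high < Nyquist ({fs / 2})")
        block = fs / self.features.frames_per_second
        if abs(block - round(block)) > 1e-6:
            raise ValueError("sim.fs must be divisible by features.frames_per_second")
        return self

    def resolved(self) -> dict:
        return self.model_dump()

    def hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(path) -> RunConfig:
    """Load a YAML config file; an empty file yields all defaults."""
    text = Path(path).read_text() if path is not None else ""
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    return RunConfig(**raw)
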