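"""Synthetic EEG corpora with motion-sickness structure.

The study protocol this generator emulates: subjects watch VR videos
while 10-20 scalp EEG is recorded at 500 Hz; for every (subject, video)
pair there is a two-minute *normal* (rest) recording and a two-minute
*sickness* (task) recording, plus a 16-item SSQ questionnaire filled in
after the video.

Each non-mastoid channel is a sum of one sinusoid per EEG rhythm band
(delta, theta, alpha, beta) whose amplitude depends on the channel's
scalp region and on the sickness state, over a pink + white noise
floor.  Relative to the normal state, sickness raises frontal and
temporal broadband power, lowers the central/parietal/occipital alpha
rhythm, and raises beta power — the regional pattern reported for
visually induced motion sickness.  Mastoid channels carry reference
noise only.  Sickness severity is driven by a latent level m in [0, 1];
a logistic ramp (default onset 56 s) provides the time-resolved
trajectory used for real-time prediction experiments, and the SSQ item
scores are drawn with probabilities that increase monotonically with
the final latent level.

Everything is deterministic given ``(config, seed)``: per-recording
random streams are spawned from the corpus seed with
``np.random.SeedSequence`` spawn keys, so changing one recording's
content never perturbs another's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from vims_eeg.recording import EEGRecording, Epoch, EpochSet
from vims_eeg.ssq import SSQResponse, total_score, MAX_TOTAL
from vims_eeg.wpt import DEFAULT_BANDS

__all__ = [
    "SimConfig", "LatentSicknessTrajectory", "LabeledDataset",
    "channel_region", "simulate_recording", "simulate_ssq",
    "simulate_dataset", "default_amplitude_table",
]

REGIONS = ("frontal", "central", "parietal", "occipital", "temporal", "mastoid")

_REGION_PREFIXES = {
    "FP": "frontal", "AF": "frontal", "F": "frontal",
    "C": "central",
    "P": "parietal",
    "O": "occipital",
    "T": "temporal",
    "M": "mastoid", "A": "mastoid",
}

DEFAULT_CHANNELS = ["FP1", "FP2", "C3", "C4", "P3", "P4", "O1", "O2", "M1", "M2"]
STATES = ("normal", "sickness")


def channel_region(name: str) -> str:
    """Scalp region of a 10-20 channel label (prefix convention)."""
    key = name.upper()
    for plen in (2, 1):
        region = _REGION_PREFIXES.get(key[:plen])
        if region is not None:
            # FC/CP/PO midway labels are not needed for the 8-channel montage
            return region
    raise ValueError(f"cannot map channel {name!r} to a scalp region")


def default_amplitude_table() -> dict[tuple[str, str, str], float]:
    """Band sinusoid amplitudes in µV per (region, band, state).

    Chosen to mimic the regional normal-vs-sickness contrasts described
    above, with a posterior-dominant alpha rhythm in the normal state.
    """
    normal = {
        "frontal":   {"delta": 6.0, "theta": 4.0, "alpha": 5.0, "beta": 3.0},
        "central":   {"delta": 5.0, "theta": 4.0, "alpha": 6.0, "beta": 3.0},
        "parietal":  {"delta": 5.0, "theta": 4.0, "alpha": 7.0, "beta": 3.0},
        "occipital": {"delta": 4.0, "theta": 3.0, "alpha": 10.0, "beta": 3.0},
        "temporal":  {"delta": 5.0, "theta": 4.0, "alpha": 5.0, "beta": 3.0},
        "mastoid":   {"delta": 0.0, "theta": 0.0, "alpha": 0.0, "beta": 0.0},
    }
    sickness = {
        "frontal":   {"delta": 9.0, "theta": 7.0, "alpha": 7.5, "beta": 6.0},
        "central":   {"delta": 5.0, "theta": 5.0, "alpha": 3.5, "beta": 6.5},
        "parietal":  {"delta": 6.0, "theta": 5.0, "alpha": 4.5, "beta": 6.0},
        "occipital": {"delta": 4.0, "theta": 4.0, "alpha": 5.5, "beta": 6.5},
        "temporal":  {"delta": 8.0, "theta": 7.0, "alpha": 7.0, "beta": 6.0},
        "mastoid":   {"delta": 0.0, "theta": 0.0, "alpha": 0.0, "beta": 0.0},
    }
    table = {}
    for state, by_region in (("normal", normal), ("sickness", sickness)):
        for region, by_band in by_region.items():
            for band, amp in by_band.items():
                table[(region, band, state)] = amp
    return table


@dataclass(frozen=True)
class LatentSicknessTrajectory:
    """Latent sickness level m(t): a logistic ramp from 0 towards ``peak``.

    ``m(t) = peak / (1 + exp(-slope * (t - onset_s)))``; with the default
    onset of 56 s and slope 0.15 /s, m(0) is ~2e-4 (zero within tolerance)
    and the level saturates well before the end of a two-minute task.
    """

    onset_s: float = 56.0
    slope: float = 0.15
    peak: float = 1.0

    def __post_init__(self):
        if not 0 <= self.peak <= 1:
            raise ValueError("peak level must lie in [0, 1]")
        if self.slope <= 0:
            raise ValueError("slope must be positive")

    def level(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.peak / (1.0 + np.exp(-self.slope * (t - self.onset_s)))


@dataclass
class SimConfig:
    """Corpus-level generator settings (defaults = study conditions)."""

    n_subjects: int = 25
    n_videos: int = 20
    duration_s: float = 120.0
    fs: float = 500.0
    channels: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    band_amplitude_table: dict[tuple[str, str, str], float] = field(
        default_factory=default_amplitude_table)
    pink_noise_sd: float = 2.0
    white_noise_sd: float = 1.0
    onset_s: float = 56.0
    onset_slope: float = 0.15
    contrast: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_videos < 1:
            raise ValueError("need at least one subject and one video")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        if self.pink_noise_sd < 0 or self.white_noise_sd < 0:
            raise ValueError("noise levels must be nonnegative")
        for ch in self.channels:
            channel_region(ch)  # raises for unmappable channels
        for (region, band, state), amp in self.band_amplitude_table.items():
            if amp < 0:
                raise ValueError(f"negative amplitude for {(region, band, state)}")
            if region not in REGIONS or state not in STATES:
                raise ValueError(f"unknown table key {(region, band, state)}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    @property
    def total_duration_s(self) -> float:
        """Corpus duration over all (subject, video, state) recordings."""
        return self.n_subjects * self.n_videos * len(STATES) * self.duration_s

    def zero_contrast(self) -> "SimConfig":
        """Copy with identical normal/sickness statistics (chance-level)."""
        import dataclasses
        return dataclasses.replace(
            self, contrast=0.0,
            channels=list(self.channels),
            band_amplitude_table=dict(self.band_amplitude_table))

    def amplitude(self, region: str, band: str, state: str) -> float:
        return self.band_amplitude_table.get((region, band, state), 0.0)


@dataclass
class LabeledDataset:
    """Labelled epochs plus linked SSQ responses of a synthetic corpus."""

    epochs: EpochSet
    ssq: pd.DataFrame            # subject_id, video_id, m_end, item_1..16, total, total_norm
    responses: list[SSQResponse]
    config: SimConfig
    window_s: float


def _pink_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """1/f-shaped Gaussian noise with unit-sd normalization, scaled by sd."""
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    spec *= scale
    x = np.fft.irfft(spec, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


_STREAMS = {"normal": 0, "sickness": 1, "ssq": 2, "severity": 3}


def _recording_rng(config: SimConfig, subject: int, video: int,
                   stream: str) -> np.random.Generator:
    """Independent per-(subject, video, stream) random generator."""
    key = (subject, video, _STREAMS[stream])
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))


def simulate_recording(config: SimConfig, state: str,
                       seed: int | np.random.Generator | None = None,
                       trajectory: LatentSicknessTrajectory | None = None,
                       severity: float = 1.0) -> EEGRecording:
    """Generate one multi-channel recording in the given state.

    ``state='normal'`` holds the latent level m at 0; ``state='sickness'``
    holds it at ``severity`` (constant), or follows ``trajectory`` when
    one is passed, scaled by ``severity``.  Band sinusoid frequencies are
    drawn uniformly inside each rhythm band (5% edge margin) and phases
    uniformly in [0, 2pi), independently per channel.
    """
    config.validate()
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}; expected one of {STATES}")
    if not 0 <= severity <= 1:
        raise ValueError("severity must lie in [0, 1]")
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)

    n = config.n_samples
    t = np.arange(n) / config.fs
    if state == "normal":
        m = np.zeros(n)
    elif trajectory is not None:
        m = severity * trajectory.level(t)
    else:
        m = np.full(n, severity)
    m = m * config.contrast

    data = np.zeros((len(config.channels), n))
    for c, ch in enumerate(config.channels):
        region = channel_region(ch)
        sig = np.zeros(n)
        if region != "mastoid":
            for band in DEFAULT_BANDS:
                a0 = config.amplitude(region, band.name, "normal")
                a1 = config.amplitude(region, band.name, "sickness")
                amp = a0 + m * (a1 - a0)
                if np.all(amp == 0):
                    # keep the random stream aligned across configs
                    rng.uniform(), rng.uniform()
                    continue
                margin = 0.05 * (band.high_hz - band.low_hz)
                f = rng.uniform(band.low_hz + margin, band.high_hz - margin)
                phase = rng.uniform(0, 2 * np.pi)
                sig += amp * np.sin(2 * np.pi * f * t + phase)
        sig += _pink_noise(rng, n, config.pink_noise_sd)
        if config.white_noise_sd > 0:
            sig += config.white_noise_sd * rng.standard_normal(n)
        data[c] = sig
    return EEGRecording(data, config.fs, list(config.channels))


def simulate_ssq(m_end: float, seed: int | np.random.Generator | None = None,
                 subject_id: int = -1, video_id: int = -1) -> SSQResponse:
    """Draw a 16-item SSQ response whose severity tracks ``m_end``.

    Each item score is Binomial(3, m_end): an ordered categorical on
    {0..3} whose mean 3*m_end rises monotonically with the latent level;
    m_end = 0 forces all-zero items and m_end = 1 forces all-3 items.
    """
    if not 0 <= m_end <= 1:
        raise ValueError(f"m_end must lie in [0, 1], got {m_end}")
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)
    items = rng.binomial(3, m_end, size=16)
    return SSQResponse(items=items, subject_id=subject_id, video_id=video_id)


def _segment(rec: EEGRecording, window_s: float, subject: int, video: int,
             label: int, targets=None) -> list[Epoch]:
    ns = int(round(window_s * rec.fs))
    out = []
    for k in range(rec.n_samples // ns):
        sl = rec.data[:, k * ns:(k + 1) * ns]
        out.append(Epoch(sl.copy(), rec.fs, list(rec.channel_names),
                         label=label, origin=(subject, video, k * window_s),
                         target=None if targets is None else float(targets[k])))
    return out


def simulate_dataset(config: SimConfig, window_s: float = 10.0,
                     severity_range: tuple[float, float] = (0.6, 1.0)
                     ) -> LabeledDataset:
    """Generate the full labelled corpus.

    For every (subject, video): one normal and one sickness recording of
    ``config.duration_s`` seconds, segmented into non-overlapping
    ``window_s`` epochs (label 0/1), plus one SSQ response drawn from the
    sickness recording's latent severity.  Sickness severities vary
    across (subject, video) within ``severity_range`` so SSQ totals carry
    usable variance for the regression task.
    """
    config.validate()
    epochs: list[Epoch] = []
    rows = []
    responses = []
    for s in range(config.n_subjects):
        for v in range(config.n_videos):
            sev_rng = _recording_rng(config, s, v, "severity")
            severity = float(sev_rng.uniform(*severity_range))
            for state, label in (("normal", 0), ("sickness", 1)):
                rng = _recording_rng(config, s, v, state)
                rec = simulate_recording(config, state, seed=rng,
                                         severity=severity if label else 1.0)
                m_epoch = 0.0 if label == 0 else severity * config.contrast
                n_ep = rec.n_samples // int(round(window_s * rec.fs))
                epochs.extend(_segment(rec, window_s, s, v, label,
                                       targets=[m_epoch] * n_ep))
            m_end = severity * config.contrast
            resp = simulate_ssq(m_end, seed=_recording_rng(config, s, v, "ssq"),
                                subject_id=s, video_id=v)
            responses.append(resp)
            total = total_score(resp)
            rows.append({"subject_id": s, "video_id": v, "m_end": m_end,
                         **{f"item_{i + 1}": int(resp.items[i]) for i in range(16)},
                         "total": total, "total_norm": total / MAX_TOTAL})
    if not epochs:
        warnings.warn("recording shorter than one window; empty dataset")
    return LabeledDataset(EpochSet(epochs), pd.DataFrame(rows), responses,
                          config, window_s)


def simulate_trajectory_dataset(config: SimConfig, window_s: float = 10.0,
                                trajectory: LatentSicknessTrajectory | None = None
                                ) -> tuple[EpochSet, LatentSicknessTrajectory]:
    """Corpus for the real-time prediction task.

    Per (subject, video): one resting recording (label 0, target 0) and
    one task recording whose latent level follows the logistic onset
    trajectory (label 1); each epoch's regression target is the mean
    latent level over its window.  Returns the epochs and the
    trajectory used.
    """
    config.validate()
    if trajectory is None:
        trajectory = LatentSicknessTrajectory(onset_s=config.onset_s,
                                              slope=config.onset_slope)
    ns = int(round(window_s * config.fs))
    t = np.arange(config.n_samples) / config.fs
    m = trajectory.level(t) * config.contrast
    epochs: list[Epoch] = []
    for s in range(config.n_subjects):
        for v in range(config.n_videos):
            rest = simulate_recording(config, "normal",
                                      seed=_recording_rng(config, s, v, "normal"))
            epochs.extend(_segment(rest, window_s, s, v, 0,
                                   targets=[0.0] * (rest.n_samples // ns)))
            task = simulate_recording(config, "sickness",
                                      seed=_recording_rng(config, s, v, "sickness"),
                                      trajectory=trajectory)
            n_ep = task.n_samples // ns
            targets = [float(np.mean(m[k * ns:(k + 1) * ns])) for k in range(n_ep)]
            epochs.extend(_segment(task, window_s, s, v, 1, targets=targets))
    return EpochSet(epochs), trajectory
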