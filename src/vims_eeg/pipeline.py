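"""Wiring between corpus, preprocessing, features and models.

`build_feature_dataset` turns labelled raw epochs (10-channel, mastoids
included) into the (N, T, 40) feature tensor consumed by the networks:
band-pass filter, bilateral-mastoid re-reference, 8-channel selection,
then wavelet-packet band features per epoch.  Standardization is *not*
applied here — the training routines fit it on their train split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from vims_eeg.models import TrainedClassifier
from vims_eeg.preprocess import (DEFAULT_MONTAGE, bandpass_filter,
                                 pca_artifact_removal, rereference_mastoids,
                                 select_channels)
from vims_eeg.recording import Epoch, EpochSet
from vims_eeg.evaluation import (EvalReport, classification_metrics,
                                 confusion_matrix)
from vims_eeg.wpt import DEFAULT_BANDS, extract_features, stream_names

__all__ = ["FeatureDataset", "build_feature_dataset", "evaluate_classifier"]


@dataclass
class FeatureDataset:
    """Per-epoch feature sequences with labels, targets and provenance."""

    X: np.ndarray            # (N, T, n_streams), unstandardized
    y: np.ndarray            # (N,) 0/1 labels
    targets: np.ndarray      # (N,) normalized levels (NaN if absent)
    subject_ids: np.ndarray
    video_ids: np.ndarray
    stream_names: list[str]
    window_s: float
    frames_per_second: float

    def __len__(self) -> int:
        return len(self.X)


def preprocess_epoch(epoch: Epoch, low_hz: float = 0.5, high_hz: float = 50.0,
                     channels=DEFAULT_MONTAGE, pca: bool = False,
                     var_threshold: float = 0.35,
                     kurt_threshold: float = 8.0) -> Epoch:
    rec = epoch.as_recording()
    rec = bandpass_filter(rec, low_hz, high_hz)
    if pca:
        rec, _ = pca_artifact_removal(rec, var_threshold, kurt_threshold)
    if {"M1", "M2"}.issubset(rec.channel_names):
        rec = rereference_mastoids(rec)
    rec = select_channels(rec, channels)
    return Epoch(rec.data, rec.fs, list(rec.channel_names),
                 label=epoch.label, origin=epoch.origin, target=epoch.target)


def build_feature_dataset(epochs: EpochSet, low_hz: float = 0.5,
                          high_hz: float = 50.0, channels=DEFAULT_MONTAGE,
                          pca: bool = False, level: int = 8,
                          frames_per_second: float = 10.0,
                          bands=DEFAULT_BANDS,
                          wavelet: str = "db4") -> FeatureDataset:
    """Preprocess every epoch and extract its band-feature sequence."""
    if len(epochs) == 0:
        raise ValueError("no epochs to featurize")
    feats = []
    for ep in epochs:
        pe = preprocess_epoch(ep, low_hz, high_hz, channels, pca)
        feats.append(extract_features(pe, bands=bands, level=level,
                                      frames_per_second=frames_per_second,
                                      wavelet=wavelet))
    X = np.stack(feats)
    return FeatureDataset(
        X=X, y=epochs.labels, targets=epochs.targets,
        subject_ids=epochs.subject_ids, video_ids=epochs.video_ids,
        stream_names=stream_names(list(channels), bands),
        window_s=epochs[0].window_s, frames_per_second=frames_per_second)


def evaluate_classifier(model: TrainedClassifier, fd: FeatureDataset,
                        split: str = "test") -> EvalReport:
    """Confusion matrix and rates on one subject-grouped split."""
    subjects = model.split_subjects[split]
    mask = np.isin(fd.subject_ids, list(subjects))
    if not mask.any():
        raise ValueError(f"no epochs in split {split!r}")
    preds = model.predict(fd.X[mask])
    cm = confusion_matrix(fd.y[mask], preds, positive=1)
    return EvalReport(n=int(mask.sum()), confusion=cm,
                      classification=classification_metrics(cm))
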