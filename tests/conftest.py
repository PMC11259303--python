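"""Shared fixtures.

The three corpus-level runs (separable classifier, zero-contrast
classifier, trajectory predictor) are expensive (tens of seconds each),
so they are computed once per session and shared between the end-to-end
unit tests and the acceptance suite.  Corpus sizes are scaled-down
versions of the full study protocol (documented in docs/methods.md);
training settings (Adam, lr 5e-5, batch 4, 50 epochs) are not scaled.
"""

from __future__ import annotations

import numpy as np
import pytest

from vims_eeg.models import TrainConfig, train_classifier, train_predictor
from vims_eeg.pipeline import build_feature_dataset, evaluate_classifier
from vims_eeg.preprocess import preprocess_recording
from vims_eeg.synthetic import (SimConfig, simulate_dataset,
                                simulate_recording, simulate_trajectory_dataset,
                                _recording_rng)


@pytest.fixture(scope="session")
def separable_run():
    """Classifier trained on the default (clearly separable) corpus."""
    cfg = SimConfig(n_subjects=7, n_videos=3, duration_s=60.0, seed=11)
    ds = simulate_dataset(cfg, window_s=10.0)
    fd = build_feature_dataset(ds.epochs)
    model = train_classifier(fd.X, fd.y, fd.subject_ids, TrainConfig(seed=11))
    report = evaluate_classifier(model, fd)
    return {"cfg": cfg, "ds": ds, "fd": fd, "model": model, "report": report}


@pytest.fixture(scope="session")
def zero_contrast_run():
    """Classifier trained on a corpus with no normal/sickness contrast."""
    cfg = SimConfig(n_subjects=7, n_videos=3, duration_s=60.0,
                    seed=21).zero_contrast()
    ds = simulate_dataset(cfg, window_s=5.0)
    fd = build_feature_dataset(ds.epochs)
    model = train_classifier(fd.X, fd.y, fd.subject_ids, TrainConfig(seed=21))
    report = evaluate_classifier(model, fd)
    return {"cfg": cfg, "fd": fd, "model": model, "report": report}


@pytest.fixture(scope="session")
def predictor_run():
    """Predictor trained on a logistic-onset trajectory corpus, plus the
    sliding-window trajectory predicted for the held-out test subject."""
    from vims_eeg.models import predict_timeseries

    cfg = SimConfig(n_subjects=7, n_videos=2, duration_s=120.0, seed=7)
    epochs, traj = simulate_trajectory_dataset(cfg, window_s=10.0)
    fd = build_feature_dataset(epochs)
    model = train_predictor(fd.X, fd.targets, fd.y, fd.subject_ids,
                            TrainConfig(seed=7))
    s_test = sorted(model.split_subjects["test"])[0]
    rec = simulate_recording(cfg, "sickness",
                             seed=_recording_rng(cfg, s_test, 0, "sickness"),
                             trajectory=traj)
    times, levels = predict_timeseries(model, preprocess_recording(rec),
                                       s_test, window_s=10.0, stride_s=2.0)
    return {"cfg": cfg, "fd": fd, "model": model, "trajectory": traj,
            "subject": s_test, "times": times, "levels": levels,
            "latent": traj.level(times)}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
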