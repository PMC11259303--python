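"""GRU cell, losses, baselines and training mechanics."""

import numpy as np
import pytest

from vims_eeg.models import (GRUNet, MeanFrameBaseline, TrainConfig, bce_loss,
                             deviation_signal, gru_cell_step, prediction_loss,
                             split_by_subject)
from vims_eeg.models import PROB_CLIP, _run_training


def _zero_params(hidden, inp):
    return {k: np.zeros((hidden + inp, hidden)) for k in ("Wz", "Wr", "Wc")}


class TestGRUCell:
    def test_zero_weights_halve_state(self):
        # sigma(0) = 0.5, tanh(0) = 0 -> h = 0.5 * h_prev
        params = _zero_params(2, 3)
        h = gru_cell_step(params, np.full((1, 2), 0.8), np.zeros((1, 3)))
        assert np.allclose(h, 0.4)

    def test_zero_state_zero_input_stays_zero(self):
        params = _zero_params(4, 4)
        h = gru_cell_step(params, np.zeros((1, 4)), np.zeros((1, 4)))
        assert np.allclose(h, 0.0)

    def test_matches_independent_scalar_recursion(self, rng):
        """Dual oracle: an elementwise scalar-loop recursion of the gate
        equations, coded independently of the batched implementation."""
        H, D, T = 2, 3, 6
        params = {k: rng.normal(size=(H + D, H)) for k in ("Wz", "Wr", "Wc")}
        x_seq = rng.normal(size=(T, D))
        h_vec = np.zeros(H)

        def sig(v):
            return 1.0 / (1.0 + np.exp(-v))

        for t in range(T):
            c1 = np.concatenate([h_vec, x_seq[t]])
            z = np.array([sig(sum(c1[i] * params["Wz"][i, j]
                                  for i in range(H + D))) for j in range(H)])
            r = np.array([sig(sum(c1[i] * params["Wr"][i, j]
                                  for i in range(H + D))) for j in range(H)])
            c2 = np.concatenate([r * h_vec, x_seq[t]])
            hc = np.array([np.tanh(sum(c2[i] * params["Wc"][i, j]
                                       for i in range(H + D))) for j in range(H)])
            h_vec = (1 - z) * h_vec + z * hc

        h_batch = np.zeros((1, H))
        for t in range(T):
            h_batch = gru_cell_step(params, h_batch, x_seq[t][None])
        assert np.max(np.abs(h_batch[0] - h_vec)) < 1e-10

    def test_state_is_convex_blend(self, rng):
        """h_t lies elementwise between h_{t-1} and the candidate state."""
        H, D = 5, 4
        for _ in range(20):
            params = {k: rng.normal(scale=2.0, size=(H + D, H))
                      for k in ("Wz", "Wr", "Wc")}
            h_prev = rng.uniform(-1, 1, size=(1, H))
            x = rng.normal(size=(1, D))
            h = gru_cell_step(params, h_prev, x)
            c1 = np.concatenate([h_prev, x], axis=1)
            r = 1 / (1 + np.exp(-(c1 @ params["Wr"])))
            hc = np.tanh(np.concatenate([r * h_prev, x], axis=1) @ params["Wc"])
            lo = np.minimum(h_prev, hc) - 1e-12
            hi = np.maximum(h_prev, hc) + 1e-12
            assert np.all((lo <= h) & (h <= hi))

    def test_state_bounded_by_unit_or_previous(self, rng):
        H, D = 3, 3
        params = {k: rng.normal(scale=3.0, size=(H + D, H))
                  for k in ("Wz", "Wr", "Wc")}
        h = rng.uniform(-2, 2, size=(1, H))
        bound = np.maximum(np.abs(h), 1.0)
        for t in range(50):
            h = gru_cell_step(params, h, rng.normal(size=(1, D)))
            assert np.all(np.abs(h) <= bound + 1e-12)
            bound = np.maximum(np.abs(h), 1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gru_cell_step(_zero_params(2, 3), np.zeros((1, 2)), np.zeros((2, 3)))


class TestLosses:
    def test_bce_analytic_values(self):
        assert bce_loss([1.0], [1.0 - 1e-9]) == pytest.approx(0.0, abs=1e-6)
        assert bce_loss([1.0, 0.0], [0.5, 0.5]) == pytest.approx(np.log(2), abs=1e-9)
        assert bce_loss([0.0], [0.9]) == pytest.approx(-np.log(0.1), abs=1e-9)

    def test_bce_clipping_keeps_loss_finite(self):
        assert np.isfinite(bce_loss([1.0], [0.0]))
        assert bce_loss([1.0], [0.0]) == pytest.approx(-np.log(PROB_CLIP))

    def test_bce_length_mismatch(self):
        with pytest.raises(ValueError):
            bce_loss([1.0, 0.0], [0.5])

    def test_prediction_loss_analytic_values(self):
        assert prediction_loss([0.3], [0.3]) == 0.0
        assert prediction_loss([0.2], [0.5]) == pytest.approx(0.09, abs=1e-9)
        preds = np.array([0.1, 0.4, 0.6, 0.9])
        targets = np.array([0.0, 0.5, 0.5, 1.0])
        assert prediction_loss(preds, targets) == pytest.approx(
            np.mean((preds - targets) ** 2), abs=1e-12)


class TestDeviationSignal:
    def test_zero_when_features_equal_baseline(self):
        frames = np.full((10, 4), 2.0)
        base = MeanFrameBaseline().fit(frames[None])
        assert np.all(deviation_signal(frames, base) == 0)

    def test_absolute_difference(self):
        x = np.array([[1.0, -2.0]])
        ref = np.array([0.0, 1.0])
        assert np.allclose(deviation_signal(x, ref), [[1.0, 3.0]])

    def test_nonnegative(self, rng):
        frames = rng.normal(size=(20, 6))
        base = MeanFrameBaseline().fit(rng.normal(size=(3, 20, 6)))
        assert np.all(deviation_signal(frames, base) >= 0)

    def test_unfitted_baseline_raises(self):
        with pytest.raises(RuntimeError):
            MeanFrameBaseline()(np.zeros((2, 2)))

    def test_sickness_deviation_exceeds_normal(self, separable_run):
        """On the synthetic corpus, deviation from the resting baseline is
        larger in sickness epochs than in normal epochs."""
        fd = separable_run["fd"]
        means = {0: [], 1: []}
        for s in np.unique(fd.subject_ids):
            sel = fd.subject_ids == s
            base = MeanFrameBaseline().fit(fd.X[sel & (fd.y == 0)])
            for lab in (0, 1):
                E = deviation_signal(fd.X[sel & (fd.y == lab)], base)
                means[lab].append(E.mean())
        assert np.mean(means[1]) > np.mean(means[0])


class TestNetwork:
    def test_forward_output_in_unit_interval(self, rng):
        net = GRUNet(input_dim=6, td_units=6, hidden=4, head=(3,), seed=0)
        p = net.forward(rng.normal(size=(5, 8, 6)))
        assert p.shape == (5,)
        assert np.all((p > 0) & (p < 1))

    def test_gradients_match_finite_differences(self, rng):
        net = GRUNet(input_dim=4, td_units=5, hidden=3, head=(3,), seed=1)
        X = rng.normal(size=(2, 6, 4))
        y = np.array([1.0, 0.0])
        p, cache = net.forward(X, cache=True)
        dout = (np.clip(p, PROB_CLIP, 1 - PROB_CLIP) - y) / len(y)
        grads = net.backward(cache, dout)
        eps = 1e-6
        for key, w in net.params.items():
            flat = w.ravel()
            for idx in range(0, flat.size, max(1, flat.size // 4)):
                old = flat[idx]
                flat[idx] = old + eps
                lp = bce_loss(y, net.forward(X))
                flat[idx] = old - eps
                lm = bce_loss(y, net.forward(X))
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                assert grads[key].ravel()[idx] == pytest.approx(num, abs=2e-5)

    def test_architecture_widths(self):
        from vims_eeg.models import CLASSIFIER_HEAD, PREDICTOR_HEAD
        clf = GRUNet(head=CLASSIFIER_HEAD)
        assert clf.params["Wx"].shape == (40, 40)
        assert clf.params["Wz"].shape == (32 + 40, 32)
        assert [clf.params[f"Wh{i}"].shape for i in range(3)] == \
            [(32, 16), (16, 8), (8, 1)]
        pred = GRUNet(head=PREDICTOR_HEAD)
        assert [pred.params[f"Wh{i}"].shape for i in range(5)] == \
            [(32, 32), (32, 16), (16, 16), (16, 8), (8, 1)]


class TestTraining:
    def _toy_data(self, rng, n=24, t=10, d=6):
        y = np.tile([0.0, 1.0], n // 2)
        X = rng.normal(size=(n, t, d)) + y[:, None, None] * 1.5
        return X, y

    def test_identical_seed_identical_weights(self, rng):
        X, y = self._toy_data(rng)
        cfg = TrainConfig(epochs=3, seed=9)
        nets = []
        for _ in range(2):
            net = GRUNet(input_dim=6, td_units=6, hidden=4, head=(3,), seed=9)
            _run_training(net, X, y, cfg, "bce")
            nets.append(net)
        for k in nets[0].params:
            assert np.array_equal(nets[0].params[k], nets[1].params[k])

    def test_loss_history_decreases(self, rng):
        X, y = self._toy_data(rng)
        net = GRUNet(input_dim=6, td_units=6, hidden=4, head=(3,), seed=0)
        hist = _run_training(net, X, y, TrainConfig(epochs=10, lr=1e-3, seed=0),
                             "bce")
        assert hist["train_loss"].iloc[-1] <= hist["train_loss"].iloc[0]

    def test_constant_targets_converge_to_constant(self, rng):
        """Zero-information inputs with equal targets c: predictions
        approach c (the variance-floor fit)."""
        X = rng.normal(size=(16, 8, 5))
        t = np.full(16, 0.7)
        net = GRUNet(input_dim=5, td_units=5, hidden=4, head=(3,), seed=2)
        _run_training(net, X, t, TrainConfig(epochs=60, lr=5e-3, seed=2), "mse")
        preds = net.forward(X)
        assert np.abs(preds - 0.7).mean() < 0.1

    def test_empty_training_set_rejected(self):
        net = GRUNet(input_dim=5, td_units=5, hidden=4, head=(3,))
        with pytest.raises(ValueError):
            _run_training(net, np.zeros((0, 4, 5)), np.zeros(0),
                          TrainConfig(), "bce")


class TestSplit:
    def test_groups_are_disjoint_and_cover(self):
        ids = np.repeat(np.arange(10), 7)
        masks, subjects = split_by_subject(ids, 0.15, 0.15, seed=0)
        assert not (subjects["train"] & subjects["val"])
        assert not (subjects["train"] & subjects["test"])
        assert not (subjects["val"] & subjects["test"])
        assert subjects["train"] | subjects["val"] | subjects["test"] == set(range(10))
        total = masks["train"].sum() + masks["val"].sum() + masks["test"].sum()
        assert total == len(ids)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            split_by_subject(np.array([0, 0, 1]), 0.15, 0.15, seed=0)


def test_checkpoint_round_trip(tmp_path, separable_run):
    from vims_eeg.models import load_model
    model = separable_run["model"]
    model.save(tmp_path / "clf")
    back = load_model(tmp_path / "clf")
    fd = separable_run["fd"]
    assert np.allclose(back.predict_proba(fd.X[:8]), model.predict_proba(fd.X[:8]))
    assert back.split_subjects == {k: set(int(x) for x in v)
                                   for k, v in model.split_subjects.items()}
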