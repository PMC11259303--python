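"""GRU sequence models for motion-sickness classification and prediction.

The recurrent cell is the standard gated recurrent unit acting on the
concatenation ``[h_{t-1}, x_t]``:

    z_t = sigma(W_z . [h_{t-1}, x_t])            (update gate)
    r_t = sigma(W_r . [h_{t-1}, x_t])            (reset gate)
    hcand_t = tanh(W . [r_t * h_{t-1}, x_t])     (candidate state)
    h_t = (1 - z_t) * h_{t-1} + z_t * hcand_t    (convex blend)

Two fixed architectures share the cell: a *classifier* (time-distributed
Dense-40/ReLU -> GRU-32/tanh -> Dense-16/ReLU -> Dense-8/ReLU ->
Dense-1/sigmoid, binary cross-entropy loss) deciding normal vs sickness
windows, and a *predictor* (Dense-40/ReLU -> GRU-32/tanh -> Dense-32 ->
Dense-16 -> Dense-16 -> Dense-8, all ReLU, -> Dense-1/sigmoid, squared
error loss) regressing the normalized SSQ total from the absolute
deviation E_t = |x_t - R(x_t)| of the feature frames from a per-subject
resting baseline R.

Everything — forward pass, backprop through time, Adam with decoupled
weight decay — is implemented on NumPy arrays, which keeps training
fully deterministic under a fixed seed and makes the cell directly
checkable against the printed recursion.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from vims_eeg.ssq import MAX_TOTAL

__all__ = [
    "TrainConfig", "GRUNet", "gru_cell_step", "bce_loss", "prediction_loss",
    "MeanFrameBaseline", "deviation_signal", "split_by_subject",
    "train_classifier", "train_predictor", "TrainedClassifier",
    "TrainedPredictor", "predict_timeseries",
]

CLASSIFIER_HEAD = (16, 8)
PREDICTOR_HEAD = (32, 16, 16, 8)
PROB_CLIP = 1e-7


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


@dataclass
class TrainConfig:
    """Optimizer and loop settings (defaults follow the study setup)."""

    lr: float = 5e-5
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    weight_decay: float = 1e-8
    batch_size: int = 4
    epochs: int = 50
    seed: int = 0
    val_fraction: float = 0.15
    test_fraction: float = 0.15

    def __post_init__(self):
        if self.lr <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("lr, batch_size and epochs must be positive")


def gru_cell_step(params: dict, h_prev: np.ndarray, x_t: np.ndarray
                  ) -> np.ndarray:
    """One GRU step on a batch; ``params`` holds Wz, Wr, Wc (+ optional
    bz, br, bc), each weight shaped ``(hidden + input, hidden)``."""
    h_prev = np.atleast_2d(h_prev)
    x_t = np.atleast_2d(x_t)
    if h_prev.shape[0] != x_t.shape[0]:
        raise ValueError("batch size mismatch between h_prev and x_t")
    H = h_prev.shape[1]
    for k in ("Wz", "Wr", "Wc"):
        if params[k].shape != (H + x_t.shape[1], H):
            raise ValueError(f"{k} has shape {params[k].shape}, expected "
                             f"{(H + x_t.shape[1], H)}")
    c1 = np.concatenate([h_prev, x_t], axis=1)
    z = _sigmoid(c1 @ params["Wz"] + params.get("bz", 0.0))
    r = _sigmoid(c1 @ params["Wr"] + params.get("br", 0.0))
    c2 = np.concatenate([r * h_prev, x_t], axis=1)
    hcand = np.tanh(c2 @ params["Wc"] + params.get("bc", 0.0))
    return (1.0 - z) * h_prev + z * hcand


def bce_loss(y: np.ndarray, p: np.ndarray) -> float:
    """Mean binary cross-entropy with probability clipping."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("label/probability length mismatch")
    p = np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def prediction_loss(preds: np.ndarray, targets: np.ndarray) -> float:
    """Mean squared error between predicted and normalized SSQ levels."""
    preds = np.asarray(preds, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if preds.shape != targets.shape:
        raise ValueError("prediction/target length mismatch")
    return float(np.mean((preds - targets) ** 2))


class GRUNet:
    """Time-distributed dense front end, GRU, dense head, sigmoid output."""

    def __init__(self, input_dim: int = 40, td_units: int = 40,
                 hidden: int = 32, head: tuple[int, ...] = CLASSIFIER_HEAD,
                 seed: int = 0, bias: bool = True):
        self.input_dim = input_dim
        self.td_units = td_units
        self.hidden = hidden
        self.head = tuple(head)
        self.bias = bias
        rng = np.random.default_rng(seed)
        p = {}

        def glorot(n_in, n_out):
            lim = np.sqrt(6.0 / (n_in + n_out))
            return rng.uniform(-lim, lim, size=(n_in, n_out))

        p["Wx"] = glorot(input_dim, td_units)
        p["bx"] = np.zeros(td_units)
        cdim = hidden + td_units
        for gate in ("z", "r", "c"):
            p[f"W{gate}"] = glorot(cdim, hidden)
            p[f"b{gate}"] = np.zeros(hidden)
        sizes = (hidden,) + self.head + (1,)
        for i in range(len(sizes) - 1):
            p[f"Wh{i}"] = glorot(sizes[i], sizes[i + 1])
            p[f"bh{i}"] = np.zeros(sizes[i + 1])
        if not bias:
            for k in list(p):
                if k.startswith("b"):
                    p[k][:] = 0.0
        self.params = p

    @property
    def _bias_keys(self):
        return [k for k in self.params if k.startswith("b")]

    def forward(self, X: np.ndarray, cache: bool = False):
        """Probabilities for a batch of sequences ``X (B, T, input_dim)``."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[None]
        B, T, D = X.shape
        if D != self.input_dim:
            raise ValueError(f"expected input dim {self.input_dim}, got {D}")
        p = self.params
        Z0 = X @ p["Wx"] + p["bx"]
        A0 = np.maximum(Z0, 0.0)
        H = self.hidden
        h = np.zeros((B, H))
        steps = []
        for t in range(T):
            x_t = A0[:, t]
            c1 = np.concatenate([h, x_t], axis=1)
            z = _sigmoid(c1 @ p["Wz"] + p["bz"])
            r = _sigmoid(c1 @ p["Wr"] + p["br"])
            c2 = np.concatenate([r * h, x_t], axis=1)
            hcand = np.tanh(c2 @ p["Wc"] + p["bc"])
            h_new = (1.0 - z) * h + z * hcand
            if cache:
                steps.append((h, z, r, hcand))
            h = h_new
        acts = [h]
        a = h
        n_head = len(self.head) + 1
        for i in range(n_head - 1):
            a = np.maximum(a @ p[f"Wh{i}"] + p[f"bh{i}"], 0.0)
            acts.append(a)
        o = (a @ p[f"Wh{n_head - 1}"] + p[f"bh{n_head - 1}"]).ravel()
        prob = _sigmoid(o)
        if cache:
            return prob, {"X": X, "Z0": Z0, "A0": A0, "steps": steps,
                          "acts": acts, "o": o, "prob": prob}
        return prob

    def backward(self, cache: dict, dout: np.ndarray) -> dict:
        """Gradients of a scalar loss given d(loss)/d(pre-sigmoid output)."""
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        X, Z0, A0 = cache["X"], cache["Z0"], cache["A0"]
        B, T, _ = X.shape
        H = self.hidden
        n_head = len(self.head) + 1
        acts = cache["acts"]
        da = dout[:, None]  # gradient wrt pre-activation of output layer
        for i in range(n_head - 1, -1, -1):
            a_in = acts[i]
            grads[f"Wh{i}"] += a_in.T @ da
            grads[f"bh{i}"] += da.sum(axis=0)
            da = da @ p[f"Wh{i}"].T
            if i > 0:
                da = da * (acts[i] > 0)  # back through the ReLU
        dh = da  # gradient wrt final hidden state
        dA0 = np.zeros_like(A0)
        for t in range(T - 1, -1, -1):
            h_prev, z, r, hcand = cache["steps"][t]
            x_t = A0[:, t]
            dz = dh * (hcand - h_prev)
            dhcand = dh * z
            dh_prev = dh * (1.0 - z)
            dpre_c = dhcand * (1.0 - hcand ** 2)
            c2 = np.concatenate([r * h_prev, x_t], axis=1)
            grads["Wc"] += c2.T @ dpre_c
            grads["bc"] += dpre_c.sum(axis=0)
            dc2 = dpre_c @ p["Wc"].T
            drh = dc2[:, :H]
            dx_t = dc2[:, H:]
            dr = drh * h_prev
            dh_prev += drh * r
            dpre_z = dz * z * (1.0 - z)
            dpre_r = dr * r * (1.0 - r)
            c1 = np.concatenate([h_prev, x_t], axis=1)
            grads["Wz"] += c1.T @ dpre_z
            grads["bz"] += dpre_z.sum(axis=0)
            grads["Wr"] += c1.T @ dpre_r
            grads["br"] += dpre_r.sum(axis=0)
            dc1 = dpre_z @ p["Wz"].T + dpre_r @ p["Wr"].T
            dh_prev += dc1[:, :H]
            dx_t = dx_t + dc1[:, H:]
            dA0[:, t] = dx_t
            dh = dh_prev
        dZ0 = dA0 * (Z0 > 0)
        grads["Wx"] += X.reshape(-1, self.input_dim).T @ dZ0.reshape(-1, self.td_units)
        grads["bx"] += dZ0.sum(axis=(0, 1))
        if not self.bias:
            for k in self._bias_keys:
                grads[k][:] = 0.0
        return grads


class _Adam:
    def __init__(self, params: dict, cfg: TrainConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        c = self.cfg
        self.t += 1
        b1t = 1.0 - c.beta1 ** self.t
        b2t = 1.0 - c.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= c.lr * mhat / (np.sqrt(vhat) + c.eps)
            if c.weight_decay:
                params[k] -= c.lr * c.weight_decay * params[k]


# ---------------------------------------------------------------------------
# Baselines and deviation features


class MeanFrameBaseline:
    """Per-subject resting reference: the mean feature frame over the
    subject's normal-state epochs, broadcast over time."""

    def __init__(self):
        self.mean: np.ndarray | None = None

    def fit(self, normal_frames: np.ndarray) -> "MeanFrameBaseline":
        frames = np.asarray(normal_frames, dtype=float)
        self.mean = frames.reshape(-1, frames.shape[-1]).mean(axis=0)
        return self

    def __call__(self, frames: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise RuntimeError("baseline not fitted")
        return np.broadcast_to(self.mean, frames.shape)


def deviation_signal(frames: np.ndarray, baseline) -> np.ndarray:
    """E_t = |x_t - R(x_t)| elementwise; nonnegative by construction."""
    frames = np.asarray(frames, dtype=float)
    ref = baseline(frames) if callable(baseline) else np.asarray(baseline)
    return np.abs(frames - np.broadcast_to(ref, frames.shape))


# ---------------------------------------------------------------------------
# Training


def split_by_subject(subject_ids: np.ndarray, val_fraction: float,
                     test_fraction: float, seed: int):
    """Disjoint train/val/test subject groups (no epoch-level leakage)."""
    subjects = np.unique(subject_ids)
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects for a grouped split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(subjects)
    n_test = max(1, int(round(test_fraction * len(subjects))))
    n_val = max(1, int(round(val_fraction * len(subjects))))
    test_s = set(perm[:n_test].tolist())
    val_s = set(perm[n_test:n_test + n_val].tolist())
    train_s = set(perm[n_test + n_val:].tolist())
    if not train_s:
        raise ValueError("split left no training subjects")
    masks = {
        "train": np.isin(subject_ids, list(train_s)),
        "val": np.isin(subject_ids, list(val_s)),
        "test": np.isin(subject_ids, list(test_s)),
    }
    return masks, {"train": train_s, "val": val_s, "test": test_s}


def _fit_scaler(X: np.ndarray):
    from vims_eeg.wpt import FeatureScaler
    flat = X.reshape(-1, X.shape[-1])
    sc = FeatureScaler()
    sc.mean = flat.mean(axis=0)
    sc.std = np.maximum(flat.std(axis=0), 1e-12)
    return sc


def _run_training(net: GRUNet, X: np.ndarray, y: np.ndarray, cfg: TrainConfig,
                  loss: str, Xval=None, yval=None) -> pd.DataFrame:
    if len(X) == 0:
        raise ValueError("empty training set")
    adam = _Adam(net.params, cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            p, cache = net.forward(xb, cache=True)
            if loss == "bce":
                pc = np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)
                lval = bce_loss(yb, p)
                dout = (pc - yb) / len(yb)
            else:
                lval = prediction_loss(p, yb)
                dout = 2.0 * (p - yb) * p * (1.0 - p) / len(yb)
            if not np.isfinite(lval):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            grads = net.backward(cache, dout)
            adam.step(net.params, grads)
            losses.append(lval)
        row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if loss == "bce":
            row["train_acc"] = float(np.mean((net.forward(X) >= 0.5) == y))
        if Xval is not None and len(Xval):
            pv = net.forward(Xval)
            if loss == "bce":
                row["val_loss"] = bce_loss(yval, pv)
                row["val_acc"] = float(np.mean((pv >= 0.5) == yval))
            else:
                row["val_loss"] = prediction_loss(pv, yval)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class TrainedClassifier:
    net: GRUNet
    scaler: object
    cfg: TrainConfig
    split_subjects: dict
    history: pd.DataFrame

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.net.forward(self.scaler.transform(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)

    def save(self, prefix) -> None:
        _save_model(self, prefix, kind="classifier")


@dataclass
class TrainedPredictor:
    net: GRUNet
    scaler: object
    cfg: TrainConfig
    baselines: dict
    split_subjects: dict
    history: pd.DataFrame

    def predict_level(self, frames: np.ndarray, subject_id: int) -> np.ndarray:
        """Normalized sickness level for raw feature sequences ``(N, T, F)``."""
        base = self.baselines[subject_id]
        E = deviation_signal(frames, base)
        return self.net.forward(self.scaler.transform(E))

    def save(self, prefix) -> None:
        _save_model(self, prefix, kind="predictor")


def train_classifier(features: np.ndarray, labels: np.ndarray,
                     subject_ids: np.ndarray, cfg: TrainConfig | None = None
                     ) -> TrainedClassifier:
    """Train the normal-vs-sickness classifier on feature sequences.

    ``features`` is (N, T, 40) *unstandardized*; standardization
    statistics are fitted on the training split only.  The split is
    grouped by subject (70/15/15 by default).
    """
    cfg = cfg or TrainConfig()
    labels = np.asarray(labels, dtype=float)
    masks, subjects = split_by_subject(subject_ids, cfg.val_fraction,
                                       cfg.test_fraction, cfg.seed)
    scaler = _fit_scaler(features[masks["train"]])
    Xs = np.stack([scaler.transform(f) for f in features])
    net = GRUNet(input_dim=features.shape[-1], head=CLASSIFIER_HEAD,
                 seed=cfg.seed)
    history = _run_training(net, Xs[masks["train"]], labels[masks["train"]],
                            cfg, "bce",
                            Xs[masks["val"]], labels[masks["val"]])
    return TrainedClassifier(net, scaler, cfg, subjects, history)


def train_predictor(features: np.ndarray, targets: np.ndarray,
                    labels: np.ndarray, subject_ids: np.ndarray,
                    cfg: TrainConfig | None = None) -> TrainedPredictor:
    """Train the sickness-level predictor on deviation sequences.

    Per-subject resting baselines are fitted on each subject's
    normal-state epochs; the network then maps E_t = |x_t - R| to the
    [0, 1] targets (normalized SSQ totals or latent levels).
    """
    cfg = cfg or TrainConfig()
    targets = np.asarray(targets, dtype=float)
    if np.any(~np.isfinite(targets)):
        raise ValueError("predictor targets contain missing values")
    if targets.min() < 0 or targets.max() > 1:
        raise ValueError("predictor targets must be normalized to [0, 1]")
    baselines = {}
    for s in np.unique(subject_ids):
        normal = features[(subject_ids == s) & (labels == 0)]
        if len(normal) == 0:
            raise ValueError(f"subject {s} has no normal-state epochs for a baseline")
        baselines[int(s)] = MeanFrameBaseline().fit(normal)
    E = np.stack([deviation_signal(f, baselines[int(s)])
                  for f, s in zip(features, subject_ids)])
    masks, subjects = split_by_subject(subject_ids, cfg.val_fraction,
                                       cfg.test_fraction, cfg.seed)
    scaler = _fit_scaler(E[masks["train"]])
    Es = np.stack([scaler.transform(e) for e in E])
    net = GRUNet(input_dim=features.shape[-1], head=PREDICTOR_HEAD,
                 seed=cfg.seed)
    history = _run_training(net, Es[masks["train"]], targets[masks["train"]],
                            cfg, "mse",
                            Es[masks["val"]], targets[masks["val"]])
    return TrainedPredictor(net, scaler, cfg, baselines, subjects, history)


def predict_timeseries(predictor: TrainedPredictor, recording,
                       subject_id: int, window_s: float = 10.0,
                       stride_s: float = 2.0, level: int = 8,
                       frames_per_second: float = 10.0,
                       rescale_ssq: bool = False):
    """Sliding-window real-time sickness level over a preprocessed recording.

    Returns ``(times, levels)`` with one normalized level per window,
    timestamped at the window end; ``rescale_ssq`` multiplies by the
    maximum SSQ total (235.62) for reporting in questionnaire units.
    """
    from vims_eeg.recording import Epoch
    from vims_eeg.wpt import extract_features

    ns = int(round(window_s * recording.fs))
    stride = int(round(stride_s * recording.fs))
    if recording.n_samples < ns:
        raise ValueError("recording shorter than the prediction window")
    starts = range(0, recording.n_samples - ns + 1, stride)
    frames = np.stack([
        extract_features(Epoch(recording.data[:, s:s + ns], recording.fs,
                               list(recording.channel_names)),
                         level=level, frames_per_second=frames_per_second)
        for s in starts])
    levels = predictor.predict_level(frames, subject_id)
    times = recording.start_time_s + (np.array(starts) + ns) / recording.fs
    if rescale_ssq:
        levels = levels * MAX_TOTAL
    return times, levels


# ---------------------------------------------------------------------------
# Checkpoints


def _save_model(model, prefix, kind: str) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"param_{k}": v for k, v in model.net.params.items()}
    arrays["scaler_mean"] = model.scaler.mean
    arrays["scaler_std"] = model.scaler.std
    if kind == "predictor":
        for s, b in model.baselines.items():
            arrays[f"baseline_{s}"] = b.mean
    np.savez(prefix.with_suffix(".npz"), **arrays)
    manifest = {
        "kind": kind,
        "architecture": {"input_dim": model.net.input_dim,
                         "td_units": model.net.td_units,
                         "hidden": model.net.hidden,
                         "head": list(model.net.head)},
        "train_config": asdict(model.cfg),
        "split_subjects": {k: sorted(int(x) for x in v)
                           for k, v in model.split_subjects.items()},
    }
    prefix.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_model(prefix):
    """Load a checkpoint saved by ``TrainedClassifier/Predictor.save``."""
    from vims_eeg.wpt import FeatureScaler

    prefix = Path(prefix)
    manifest = json.loads(prefix.with_suffix(".json").read_text())
    arrays = np.load(prefix.with_suffix(".npz"))
    arch = manifest["architecture"]
    net = GRUNet(input_dim=arch["input_dim"], td_units=arch["td_units"],
                 hidden=arch["hidden"], head=tuple(arch["head"]))
    for k in net.params:
        net.params[k] = arrays[f"param_{k}"]
    scaler = FeatureScaler(mean=arrays["scaler_mean"], std=arrays["scaler_std"])
    cfg = TrainConfig(**manifest["train_config"])
    split = {k: set(v) for k, v in manifest["split_subjects"].items()}
    hist = pd.DataFrame()
    if manifest["kind"] == "classifier":
        return TrainedClassifier(net, scaler, cfg, split, hist)
    baselines = {}
    for k in arrays.files:
        if k.startswith("baseline_"):
            b = MeanFrameBaseline()
            b.mean = arrays[k]
            baselines[int(k.split("_", 1)[1])] = b
    return TrainedPredictor(net, scaler, cfg, baselines, split, hist)
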