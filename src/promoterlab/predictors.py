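"""Sequence-to-activity models: training, prediction, input gradients.

A named registry of five CPU-scale architectures covers the model families
used in published promoter-strength predictors:

``cnn``
    three-stage convolutional network (conv -> pool -> conv -> pool ->
    dense), the classic promoter-strength regressor.
``cnn_k15``
    a single wide (width-15) convolution layer followed by dense layers;
    wide first-layer filters act as soft motif scanners.
``attnbilstm``
    convolutional front end, bidirectional LSTM, softmax attention
    pooling, dense head — the architecture family used for yeast
    promoter-strength prediction.
``densenet``
    densely connected convolution blocks (each block sees the
    concatenation of all previous feature maps).
``dual_head``
    shared convolutional trunk with two output heads (head 0 returned by
    default), for paired-activity designs.

All nets use smooth activations (tanh / sigmoid), so input gradients are
well-defined everywhere and finite-difference checks are exact to
second order.  Tasks: ``regression`` (MSE on internally standardized
activities; predictions are returned on the original scale) or
``binary_classification`` (logistic loss; predictions are probabilities).
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import autodiff as ad
from .seqio import SequenceDataset, one_hot, one_hot_many

__all__ = [
    "PredictorSpec",
    "PredictorModel",
    "ARCHITECTURES",
    "train_predictor",
    "predict",
    "input_gradient",
    "save_predictor",
    "load_predictor",
]

ARCHITECTURES = ("cnn", "cnn_k15", "attnbilstm", "densenet", "dual_head")
_TASKS = ("regression", "binary_classification")


class CheckpointError(RuntimeError):
    """Raised for unreadable or incompatible predictor checkpoints."""


@dataclass(frozen=True)
class PredictorSpec:
    arch: str
    L: int
    task: str = "regression"
    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 1e-3
    val_fraction: float = 0.1
    hidden: int = 24
    seed: int = 0

    def __post_init__(self):
        if self.arch not in ARCHITECTURES:
            raise ValueError(f"arch must be one of {ARCHITECTURES}, got {self.arch!r}")
        if self.task not in _TASKS:
            raise ValueError(f"task must be one of {_TASKS}, got {self.task!r}")
        if self.L < 8:
            raise ValueError("L must be >= 8")
        if not 0.0 < self.val_fraction <= 0.5:
            raise ValueError("val_fraction must be in (0, 0.5]")


# -- architectures -----------------------------------------------------


class _Flatten:
    def __call__(self, x):
        B = x.shape[0]
        return ad.reshape(x, (B, -1))


class _CNN(nn.Module):
    def __init__(self, L, hidden, rng):
        self.c1 = nn.Conv1d(4, hidden, 7, rng)
        self.c2 = nn.Conv1d(hidden, hidden, 5, rng)
        l1 = (L - 6) // 2
        l2 = (l1 - 4) // 2
        if l2 < 1:
            raise ValueError(f"cnn needs L >= 18 (got {L})")
        self.d1 = nn.Dense(l2 * hidden, 32, rng)
        self.d2 = nn.Dense(32, 1, rng)

    def __call__(self, x):
        h = nn.avg_pool(ad.tanh(self.c1(x)))
        h = nn.avg_pool(ad.tanh(self.c2(h)))
        h = _Flatten()(h)
        return self.d2(ad.tanh(self.d1(h)))


class _CNNK15(nn.Module):
    def __init__(self, L, hidden, rng):
        width = 2 * hidden
        self.c1 = nn.Conv1d(4, width, 15, rng)
        l1 = (L - 14) // 2
        if l1 < 1:
            raise ValueError(f"cnn_k15 needs L >= 16 (got {L})")
        self.d1 = nn.Dense(l1 * width, 32, rng)
        self.d2 = nn.Dense(32, 1, rng)

    def __call__(self, x):
        h = nn.avg_pool(ad.tanh(self.c1(x)))
        h = _Flatten()(h)
        return self.d2(ad.tanh(self.d1(h)))


class _AttnBiLSTM(nn.Module):
    def __init__(self, L, hidden, rng):
        self.c1 = nn.Conv1d(4, hidden, 7, rng, padding="same")
        self.lstm = nn.BiLSTM(hidden, hidden, rng)
        self.attn = nn.AttentionPool(2 * hidden, rng)
        self.d1 = nn.Dense(2 * hidden, 16, rng)
        self.d2 = nn.Dense(16, 1, rng)

    def __call__(self, x):
        h = nn.avg_pool(ad.tanh(self.c1(x)))
        h = self.lstm(h)
        h = self.attn(h)
        return self.d2(ad.tanh(self.d1(h)))


class _DenseNet(nn.Module):
    def __init__(self, L, hidden, rng):
        g = max(8, hidden // 2)
        self.b1 = nn.Conv1d(4, g, 5, rng, padding="same")
        self.b2 = nn.Conv1d(4 + g, g, 5, rng, padding="same")
        self.b3 = nn.Conv1d(4 + 2 * g, g, 5, rng, padding="same")
        l1 = (L) // 2
        self.d1 = nn.Dense(l1 * (4 + 3 * g), 32, rng)
        self.d2 = nn.Dense(32, 1, rng)

    def __call__(self, x):
        h1 = ad.tanh(self.b1(x))
        cat1 = ad.concatenate([x, h1], axis=2)
        h2 = ad.tanh(self.b2(cat1))
        cat2 = ad.concatenate([cat1, h2], axis=2)
        h3 = ad.tanh(self.b3(cat2))
        cat3 = ad.concatenate([cat2, h3], axis=2)
        h = nn.avg_pool(cat3)
        return self.d2(ad.tanh(self.d1(_Flatten()(h))))


class _DualHead(nn.Module):
    def __init__(self, L, hidden, rng):
        self.c1 = nn.Conv1d(4, hidden, 7, rng)
        l1 = (L - 6) // 2
        self.d1 = nn.Dense(l1 * hidden, 32, rng)
        self.head0 = nn.Dense(32, 1, rng)
        self.head1 = nn.Dense(32, 1, rng)

    def __call__(self, x, head: int = 0):
        h = nn.avg_pool(ad.tanh(self.c1(x)))
        h = ad.tanh(self.d1(_Flatten()(h)))
        return self.head0(h) if head == 0 else self.head1(h)


_BUILDERS = {
    "cnn": _CNN,
    "cnn_k15": _CNNK15,
    "attnbilstm": _AttnBiLSTM,
    "densenet": _DenseNet,
    "dual_head": _DualHead,
}


class PredictorModel:
    """Trained activity predictor with a pure, batch-invariant predict."""

    def __init__(self, spec: PredictorSpec, net: nn.Module,
                 y_mean: float = 0.0, y_std: float = 1.0,
                 training_report: list[dict] | None = None,
                 metrics: dict | None = None,
                 validation_ids: list[str] | None = None,
                 head: int = 0):
        self.spec = spec
        self.net = net
        self.y_mean = y_mean
        self.y_std = y_std
        self.training_report = training_report or []
        self.metrics = metrics or {}
        self.validation_ids = validation_ids or []
        self.head = head

    @property
    def L(self) -> int:
        return self.spec.L

    def forward_relaxed(self, x: ad.Tensor) -> ad.Tensor:
        """Differentiable prediction from a (B, L, 4) simplex input."""
        if self.spec.arch == "dual_head":
            raw = self.net(x, head=self.head)
        else:
            raw = self.net(x)
        out = ad.reshape(raw, (x.shape[0],))
        if self.spec.task == "binary_classification":
            return ad.sigmoid(out)
        return out * self.y_std + self.y_mean

    def predict_array(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        if X.shape[0] == 0:
            return np.zeros(0)
        outs = []
        for start in range(0, X.shape[0], batch):
            xt = ad.Tensor(X[start : start + batch])
            outs.append(self.forward_relaxed(xt).data)
        return np.concatenate(outs)

    def predict_strings(self, seqs) -> np.ndarray:
        seqs = list(seqs)
        if not seqs:
            return np.zeros(0)
        if len(seqs[0]) != self.spec.L:
            raise ValueError(
                f"sequence length {len(seqs[0])} != predictor L {self.spec.L}"
            )
        return self.predict_array(one_hot_many(seqs))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def train_predictor(ds: SequenceDataset, spec: PredictorSpec) -> PredictorModel:
    """Fit a predictor; the train/validation split is a seeded shuffle with
    the last ``val_fraction`` held out, recorded in the checkpoint."""
    if not ds.has_activity:
        raise ValueError("training dataset must carry activities")
    if ds.length != spec.L:
        raise ValueError(f"dataset length {ds.length} != spec.L {spec.L}")
    if len(ds) < 50:
        raise ValueError("need at least 50 records to train a predictor")
    y = ds.activities
    if spec.task == "binary_classification" and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binary classification requires activities in {0, 1}")
    rng = np.random.default_rng(spec.seed)
    net = _BUILDERS[spec.arch](spec.L, spec.hidden, rng)
    params = net.parameters()

    order = rng.permutation(len(ds))
    n_val = max(1, int(round(spec.val_fraction * len(ds))))
    train_idx, val_idx = order[:-n_val], order[-n_val:]
    X = one_hot_many(ds.sequences)
    if spec.task == "regression":
        y_mean = float(np.mean(y[train_idx]))
        y_std = float(np.std(y[train_idx]))
        if y_std == 0.0:
            y_std = 1.0
        yz = (y - y_mean) / y_std
    else:
        y_mean, y_std = 0.0, 1.0
        yz = y

    opt = nn.Adam(params, lr=spec.learning_rate)
    report = []
    model = PredictorModel(spec, net, y_mean, y_std)
    for epoch in range(spec.epochs):
        perm = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(perm) - spec.batch_size + 1, spec.batch_size):
            idx = perm[start : start + spec.batch_size]
            xt = ad.Tensor(X[idx])
            if spec.arch == "dual_head":
                raw = net(xt, head=0)
            else:
                raw = net(xt)
            out = ad.reshape(raw, (len(idx),))
            target = ad.Tensor(yz[idx])
            if spec.task == "regression":
                diff = out - target
                loss = ad.tmean(diff * diff)
            else:
                # numerically stable logistic loss on the raw logit
                z = out
                loss = ad.tmean(
                    ad.relu(z) - z * target + ad.log(1.0 + ad.exp(-1.0 * _abs(z)))
                )
            grads = ad.grad(loss, params)
            opt.step([g.data for g in grads])
            losses.append(float(loss.data))
        val_pred = model.predict_array(X[val_idx])
        if spec.task == "regression":
            val_loss = float(np.mean(((val_pred - y_mean) / y_std - yz[val_idx]) ** 2))
        else:
            p = np.clip(val_pred, 1e-12, 1 - 1e-12)
            val_loss = float(np.mean(-(yz[val_idx] * np.log(p) + (1 - yz[val_idx]) * np.log(1 - p))))
        report.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_loss": val_loss}
        )
    val_pred = model.predict_array(X[val_idx])
    if spec.task == "regression":
        metrics = {"val_pearson_r": _pearson(val_pred, y[val_idx])}
    else:
        metrics = {"val_accuracy": float(np.mean((val_pred > 0.5) == (y[val_idx] > 0.5)))}
    model.training_report = report
    model.metrics = metrics
    model.validation_ids = [ds.records[i].id for i in val_idx]
    return model


def _abs(z: ad.Tensor) -> ad.Tensor:
    return ad.relu(z) + ad.relu(-1.0 * z)


def predict(m: PredictorModel, ds: SequenceDataset) -> list[float]:
    """One finite prediction per record, order preserved."""
    if len(ds) == 0:
        return []
    if ds.length != m.spec.L:
        raise ValueError(f"dataset length {ds.length} != predictor L {m.spec.L}")
    return [float(v) for v in m.predict_strings(ds.sequences)]


def input_gradient(m: PredictorModel, seq: str) -> np.ndarray:
    """d prediction / d one_hot(seq) as an L x 4 matrix."""
    if len(seq) != m.spec.L:
        raise ValueError(f"sequence length {len(seq)} != predictor L {m.spec.L}")
    x = ad.Tensor(one_hot(seq)[None, :, :], requires_grad=True)
    out = ad.tsum(m.forward_relaxed(x))
    g = ad.grad(out, x)
    return g.data[0]


# -- checkpointing -----------------------------------------------------


def save_predictor(m: PredictorModel, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "spec.json").write_text(json.dumps(asdict(m.spec), indent=2) + "\n")
    state = dict(m.net.state_dict())
    state["_y_mean"] = np.array(m.y_mean)
    state["_y_std"] = np.array(m.y_std)
    np.savez(path / "weights.npz", **state)
    with open(path / "training_report.csv", "w", newline="") as fh:
        if m.training_report:
            w = csv.DictWriter(fh, fieldnames=list(m.training_report[0]), lineterminator="\n")
            w.writeheader()
            w.writerows(m.training_report)
        else:
            fh.write("epoch,train_loss,val_loss\n")
    (path / "validation_ids.txt").write_text("\n".join(m.validation_ids) + "\n")
    (path / "metrics.json").write_text(json.dumps(m.metrics, indent=2) + "\n")


def load_predictor(path) -> PredictorModel:
    path = Path(path)
    spec_file = path / "spec.json"
    if not spec_file.exists():
        raise CheckpointError(f"{path}: no spec.json (not a predictor checkpoint)")
    try:
        spec = PredictorSpec(**json.loads(spec_file.read_text()))
    except (json.JSONDecodeError, TypeError, ValueError) as e:
        raise CheckpointError(f"{path}: bad spec.json: {e}") from None
    rng = np.random.default_rng(spec.seed)
    net = _BUILDERS[spec.arch](spec.L, spec.hidden, rng)
    try:
        with np.load(path / "weights.npz") as npz:
            state = {k: npz[k] for k in npz.files}
    except Exception as e:
        raise CheckpointError(f"{path}: unreadable weights: {e}") from None
    y_mean = float(state.pop("_y_mean", 0.0))
    y_std = float(state.pop("_y_std", 1.0))
    try:
        net.load_state_dict(state)
    except ValueError as e:
        raise CheckpointError(f"{path}: corrupt checkpoint: {e}") from None
    report = []
    rf = path / "training_report.csv"
    if rf.exists():
        with open(rf) as fh:
            for row in csv.DictReader(fh):
                report.append({k: float(v) for k, v in row.items()})
    metrics = {}
    mf = path / "metrics.json"
    if mf.exists():
        metrics = json.loads(mf.read_text())
    vids = []
    vf = path / "validation_ids.txt"
    if vf.exists():
        vids = [s for s in vf.read_text().splitlines() if s]
    return PredictorModel(spec, net, y_mean, y_std, report, metrics, vids)
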