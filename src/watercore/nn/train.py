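"""Training loop, evaluation and checkpointing for the spectral classifiers.

Labels are 1-based grade levels throughout the public interface and shifted
to 0-based class indices only around the cross-entropy.  All randomness
(shuffling; dropout and init live in the model) derives from the config
seed, so identical seeds give identical weights and curves in this
single-threaded NumPy implementation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from watercore.nn.layers import Network, cross_entropy, softmax
from watercore.nn.metrics import Metrics, confusion_matrix, metrics_from_confusion
from watercore.nn.model import ModelConfig, build_model
from watercore.nn.radam import RAdam
from watercore.spectra import Spectrum, WavelengthGrid
from watercore.preprocess import resample_matrix


class TrainingError(ValueError):
    """Invalid training input."""


@dataclass
class TrainingCurves:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    test_loss: list[float] = field(default_factory=list)
    test_acc: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_dict(self) -> dict:
        return {
            "train_loss": self.train_loss,
            "train_acc": self.train_acc,
            "test_loss": self.test_loss,
            "test_acc": self.test_acc,
            "best_epoch": self.best_epoch,
        }


def _as_batch(X: np.ndarray, input_length: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[:, None, :]
    if X.shape[2] != input_length:
        raise TrainingError(f"input length {X.shape[2]} != model length {input_length}")
    return X


def _eval_pass(net: Network, X: np.ndarray, y0: np.ndarray, chunk: int = 256):
    losses, correct = [], 0
    for i in range(0, len(X), chunk):
        logits = net.forward(X[i : i + chunk], training=False)
        loss, _ = cross_entropy(logits, y0[i : i + chunk])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y0[i : i + chunk]).sum())
    return float(np.sum(losses) / len(X)), correct / len(X)


def train(
    net: Network,
    X_train: np.ndarray,
    y_train: np.ndarray,
    cfg: ModelConfig,
    X_test: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
) -> TrainingCurves:
    """Minimize cross-entropy with RAdam; checkpoint best test accuracy.

    When a test set is supplied, the weights achieving the highest test
    accuracy are restored before returning.
    """
    X = _as_batch(X_train, cfg.input_length)
    y = np.asarray(y_train, dtype=int)
    if len(X) == 0:
        raise TrainingError("empty training set")
    if np.unique(y).size < 2:
        raise TrainingError("training set must contain at least 2 classes")
    if y.min() < 1 or y.max() > cfg.n_classes:
        raise TrainingError(f"labels must lie in 1..{cfg.n_classes}")
    y0 = y - 1

    have_test = X_test is not None and y_test is not None
    if have_test:
        Xt = _as_batch(X_test, cfg.input_length)
        yt0 = np.asarray(y_test, dtype=int) - 1

    rng = np.random.default_rng(cfg.seed + 0x5EED)
    opt = RAdam(net.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    curves = TrainingCurves()
    best_acc, best_state = -1.0, None

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(X))
        epoch_loss, epoch_correct = 0.0, 0
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = net.forward(X[idx], training=True)
            loss, dlogits = cross_entropy(logits, y0[idx])
            net.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
            epoch_correct += int((logits.argmax(axis=1) == y0[idx]).sum())
        curves.train_loss.append(epoch_loss / len(X))
        curves.train_acc.append(epoch_correct / len(X))
        if have_test:
            t_loss, t_acc = _eval_pass(net, Xt, yt0)
            curves.test_loss.append(t_loss)
            curves.test_acc.append(t_acc)
            if t_acc > best_acc:
                best_acc = t_acc
                best_state = net.state()
                curves.best_epoch = epoch

    if best_state is not None:
        net.load_state(best_state)
    return curves


def predict_proba(net: Network, X: np.ndarray, input_length: int) -> np.ndarray:
    logits = net.forward(_as_batch(X, input_length), training=False)
    return softmax(logits)


def evaluate(net: Network, X: np.ndarray, y: np.ndarray, cfg: ModelConfig) -> Metrics:
    """Deterministic forward pass + full metric set on a labelled set."""
    y = np.asarray(y, dtype=int)
    if len(y) == 0:
        raise TrainingError("empty evaluation set")
    proba = predict_proba(net, X, cfg.input_length)
    pred = proba.argmax(axis=1) + 1
    C = confusion_matrix(y, pred, cfg.n_classes)
    return metrics_from_confusion(C)


def predict_grade(
    net: Network,
    s: Spectrum,
    cfg: ModelConfig,
    train_grid: WavelengthGrid | None = None,
) -> tuple[int, np.ndarray]:
    """Grade one spectrum: (argmax level 1..n_classes, class probabilities)."""
    if train_grid is not None and s.grid != train_grid:
        raise TrainingError("spectrum wavelength grid differs from the training grid")
    x = resample_matrix(s.intensity[None, :], cfg.input_length)
    proba = predict_proba(net, x, cfg.input_length)[0]
    return int(proba.argmax()) + 1, proba


# ---------------------------------------------------------------------------
# checkpointing (self-describing: config + stem kind + optional grid embedded)
# ---------------------------------------------------------------------------

def save_checkpoint(
    path: str | Path,
    net: Network,
    cfg: ModelConfig,
    quadratic: bool,
    grid: WavelengthGrid | None = None,
) -> None:
    arrays: dict[str, np.ndarray] = {}
    for i, layer_state in enumerate(net.state()):
        for key, value in layer_state.items():
            arrays[f"layer{i:02d}.{key}"] = value
    meta = {"config": cfg.to_dict(), "quadratic": quadratic}
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    if grid is not None:
        arrays["__grid__"] = grid.values
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path):
    """Returns (net, cfg, quadratic, grid-or-None)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = ModelConfig.from_dict(meta["config"])
        quadratic = bool(meta["quadratic"])
        net = build_model(cfg, quadratic=quadratic)
        state = []
        for i in range(len(net.layers)):
            prefix = f"layer{i:02d}."
            state.append(
                {k[len(prefix):]: data[k] for k in data.files if k.startswith(prefix)}
            )
        net.load_state(state)
        grid = WavelengthGrid(data["__grid__"]) if "__grid__" in data.files else None
    return net, cfg, quadratic, grid
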