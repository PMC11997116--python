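"""The CNN+transformer modification scorer.

Architecture (fixed by :class:`ModelConfig`, defaults matching the published
counts): four same-padded Conv1d layers of 64 filters, kernel 5, ReLU, with
batch normalization between consecutive convolutions; sinusoidal positional
embeddings added to the convolutional output; three pre-layer-norm
transformer encoder layers (multi-head scaled dot-product attention, GELU
feed-forward, dropout 0.1); flatten; one fully connected ReLU layer; a
two-unit softmax output whose "modified" probability is the *modification
score*.

Implemented on plain numpy (see ``_nn``): trains on one CPU, is fully
deterministic under a fixed seed, and round-trips through ``.npz``
checkpoints bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _nn
from .features import MeasurementWindow, layout_channels

logger = logging.getLogger("smrtmod")


def sinusoidal_embedding(n_positions: int, d: int) -> np.ndarray:
    """Standard base-10000 sinusoidal positional embedding.

    ``out[pos, 2i] = sin(pos / 10000**(2i/d))``,
    ``out[pos, 2i+1] = cos(pos / 10000**(2i/d))``.
    """
    if d % 2 != 0:
        raise ValueError("embedding dimension must be even")
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    pos = np.arange(n_positions)[:, None]
    i = np.arange(d // 2)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / d)
    out = np.zeros((n_positions, d))
    out[:, 0::2] = np.sin(angle)
    out[:, 1::2] = np.cos(angle)
    return out


@dataclass(frozen=True)
class ModelConfig:
    n_conv_layers: int = 4
    conv_filters: int = 64
    conv_kernel: int = 5
    n_transformer_layers: int = 3
    d_model: int = 64
    n_heads: int = 4
    ff_dim: int = 128
    fc_units: int = 128
    dropout: float = 0.1

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.d_model != self.conv_filters:
            raise ValueError("d_model must equal conv_filters (embeddings are "
                             "added to the convolutional output)")


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 20
    patience: int = 3
    val_fraction: float = 0.2
    balance: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0, 1)")


class _Network:
    def __init__(self, cfg: ModelConfig, width: int, n_channels: int, seed: int):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.width = width
        self.n_channels = n_channels
        self.convs: list[_nn.Layer] = []
        c_in = n_channels
        for i in range(cfg.n_conv_layers):
            self.convs.append(_nn.Conv1dSame(c_in, cfg.conv_filters,
                                             cfg.conv_kernel, rng))
            if i < cfg.n_conv_layers - 1:
                self.convs.append(_nn.BatchNorm(cfg.conv_filters))
            self.convs.append(_nn.ReLU())
            c_in = cfg.conv_filters
        self.pos = sinusoidal_embedding(width, cfg.d_model).astype(_nn.DTYPE)
        self.blocks = [
            _nn.TransformerBlock(cfg.d_model, cfg.n_heads, cfg.ff_dim,
                                 cfg.dropout, rng)
            for _ in range(cfg.n_transformer_layers)
        ]
        self.fc1 = _nn.Dense(width * cfg.d_model, cfg.fc_units, rng)
        self.relu = _nn.ReLU()
        self.fc2 = _nn.Dense(cfg.fc_units, 2, rng, gain=1.0)

    # -- introspection -----------------------------------------------------
    @property
    def n_conv_layers(self) -> int:
        return sum(isinstance(l, _nn.Conv1dSame) for l in self.convs)

    @property
    def n_transformer_layers(self) -> int:
        return len(self.blocks)

    @property
    def output_dim(self) -> int:
        return self.fc2.W.value.shape[1]

    # -- passes ------------------------------------------------------------
    def set_dropout_rng(self, rng):
        for b in self.blocks:
            b.set_dropout_rng(rng)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = np.asarray(x, dtype=_nn.DTYPE)
        for l in self.convs:
            h = l.forward(h, train)
        h = h + self.pos
        for b in self.blocks:
            h = b.forward(h, train)
        self._flat_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        h = self.relu.forward(self.fc1.forward(h, train), train)
        return self.fc2.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.fc1.backward(self.relu.backward(self.fc2.backward(dlogits)))
        d = d.reshape(self._flat_shape)
        for b in reversed(self.blocks):
            d = b.backward(d)
        for l in reversed(self.convs):
            d = l.backward(d)

    def params(self) -> list[_nn.Param]:
        out = []
        for l in self.convs:
            out.extend(l.params())
        for b in self.blocks:
            out.extend(b.params())
        out.extend(self.fc1.params())
        out.extend(self.fc2.params())
        return out

    def state(self) -> dict[str, np.ndarray]:
        st = {f"p{i}": p.value for i, p in enumerate(self.params())}
        bn = [l for l in self.convs if isinstance(l, _nn.BatchNorm)]
        for i, l in enumerate(bn):
            st[f"rm{i}"] = l.running_mean
            st[f"rv{i}"] = l.running_var
        return st

    def load_state(self, st: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value = np.array(st[f"p{i}"], dtype=_nn.DTYPE)
        bn = [l for l in self.convs if isinstance(l, _nn.BatchNorm)]
        for i, l in enumerate(bn):
            l.running_mean = np.array(st[f"rm{i}"], dtype=_nn.DTYPE)
            l.running_var = np.array(st[f"rv{i}"], dtype=_nn.DTYPE)


@dataclass
class TrainedModel:
    """A (possibly untrained) scorer bound to one feature layout and task."""

    config: ModelConfig
    layout: str
    width: int
    mod_type: str
    strand_mode: str
    network: _Network
    metadata: dict = field(default_factory=dict)

    def _check_layout(self, X: np.ndarray) -> None:
        n_ch = len(layout_channels(self.layout))
        if X.ndim != 3 or X.shape[1] != self.width or X.shape[2] != n_ch:
            raise ValueError(
                f"window shape {X.shape[1:]} does not match model layout "
                f"{self.layout!r} (width {self.width}, {n_ch} channels)")

    def predict(self, windows: np.ndarray | Sequence[MeasurementWindow],
                batch_size: int = 512) -> np.ndarray:
        """Modification scores in [0, 1]; batch order preserved."""
        if isinstance(windows, np.ndarray):
            X = windows
        else:
            mats = []
            for w in windows:
                if not w.valid:
                    raise ValueError(
                        f"window at {w.molecule_id}:{w.position} is a no-call; "
                        "filter invalid windows before scoring")
                if w.layout != self.layout or w.width != self.width:
                    raise ValueError(
                        f"window layout {w.layout!r}/{w.width} does not match "
                        f"model layout {self.layout!r}/{self.width}")
                mats.append(w.matrix)
            X = np.stack(mats) if mats else np.zeros((0, self.width,
                                                      len(layout_channels(self.layout))))
        self._check_layout(X)
        scores = np.empty(X.shape[0])
        for i in range(0, X.shape[0], batch_size):
            logits = self.network.forward(X[i:i + batch_size], train=False)
            scores[i:i + batch_size] = _nn.softmax(logits)[:, 1]
        return scores

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        meta = {
            "config": asdict(self.config),
            "layout": self.layout,
            "width": self.width,
            "mod_type": self.mod_type,
            "strand_mode": self.strand_mode,
            "metadata": self.metadata,
        }
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **self.network.state())

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            state = {k: z[k] for k in z.files if k != "__meta__"}
        cfg = ModelConfig(**meta["config"])
        n_channels = len(layout_channels(meta["layout"]))
        net = _Network(cfg, meta["width"], n_channels, seed=0)
        net.load_state(state)
        return cls(config=cfg, layout=meta["layout"], width=meta["width"],
                   mod_type=meta["mod_type"], strand_mode=meta["strand_mode"],
                   network=net, metadata=meta["metadata"])


def build_model(config: ModelConfig = ModelConfig(), *, layout: str,
                width: int = 21, mod_type: str = "5mC",
                strand_mode: str = "duplex", seed: int = 0) -> TrainedModel:
    """An untrained scorer for the given feature layout and task."""
    n_channels = len(layout_channels(layout))
    net = _Network(config, width, n_channels, seed)
    return TrainedModel(config=config, layout=layout, width=width,
                        mod_type=mod_type, strand_mode=strand_mode,
                        network=net, metadata={"seed": seed, "trained": False})


def train(model: TrainedModel, X: np.ndarray, y: np.ndarray,
          tc: TrainConfig = TrainConfig()) -> tuple[TrainedModel, dict]:
    """Train in place; returns the model at its best-validation-AUC
    checkpoint plus a history of per-epoch loss and validation AUC."""
    from .evalx import roc_auc

    model._check_layout(X)
    y = np.asarray(y, dtype=np.int64)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain both classes")

    rng = np.random.default_rng(tc.seed)
    model.network.set_dropout_rng(rng)

    if tc.balance:
        n_min = min(int((y == c).sum()) for c in classes)
        keep = np.concatenate([
            rng.choice(np.flatnonzero(y == c), size=n_min, replace=False)
            for c in classes])
        rng.shuffle(keep)
        X, y = X[keep], y[keep]

    n = X.shape[0]
    perm = rng.permutation(n)
    n_val = max(2, int(round(tc.val_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]
    if np.unique(yval).size < 2 or np.unique(ytr).size < 2:
        raise ValueError("train/validation split lost a class; provide more data")

    opt = _nn.Adam(model.network.params(), lr=tc.lr)
    history = {"loss": [], "val_auc": []}
    best_auc, best_state, since_best = -np.inf, None, 0

    for epoch in range(tc.max_epochs):
        order = rng.permutation(Xtr.shape[0])
        losses = []
        for i in range(0, order.size, tc.batch_size):
            b = order[i:i + tc.batch_size]
            if b.size < 2:
                continue  # batch statistics need >= 2 examples
            opt.zero_grad()
            logits = model.network.forward(Xtr[b], train=True)
            loss, dlogits = _nn.cross_entropy(logits, ytr[b])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {i}: "
                    f"{loss}; lower the learning rate")
            model.network.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_scores = model.predict(Xval)
        auc = roc_auc(val_scores, yval)
        history["loss"].append(float(np.mean(losses)))
        history["val_auc"].append(float(auc))
        logger.info("epoch %d: loss %.4f val AUC %.4f", epoch,
                    history["loss"][-1], auc)
        if auc > best_auc:
            best_auc = auc
            best_state = {k: v.copy() for k, v in model.network.state().items()}
            since_best = 0
        else:
            since_best += 1
            if since_best >= tc.patience:
                break

    if best_state is not None:
        model.network.load_state(best_state)
    model.metadata.update({
        "trained": True,
        "train_seed": tc.seed,
        "n_train": int(Xtr.shape[0]),
        "n_val": int(Xval.shape[0]),
        "best_val_auc": float(best_auc),
        "data_hash": hashlib.md5(np.ascontiguousarray(X).tobytes()).hexdigest()[:12],
    })
    return model, history
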