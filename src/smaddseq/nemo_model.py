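"""NEMO: a 1D residual network scoring 400-sample current windows.

Maps a window of normalized nanopore current to a modification probability.
The network is a standard 1D residual stack — stem convolution, residual
blocks of (conv-BN-ReLU-conv-BN) with identity or projection shortcuts,
global average pooling, and a sigmoid head — implemented directly in NumPy
(im2col convolutions, hand-derived backward passes, Adam, binary
cross-entropy), so training is deterministic given a seed and runs anywhere
NumPy does.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve

# ---------------------------------------------------------------------------
# Configs and reports
# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    """Architecture parameters of the residual classifier.

    ``downsample_every``: every that-many-th residual block halves the
    temporal resolution (stride 2). ``stem_stride`` sets the initial
    downsampling of the stem convolution.
    """

    input_len: int = 400
    n_blocks: int = 4
    base_filters: int = 32
    kernel: int = 7
    downsample_every: int = 2
    stem_stride: int = 2
    head: str = "avg"  # "avg" (global average pool) or "avgmax" (GAP + max)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.input_len <= 0 or self.kernel < 1:
            raise ValueError("invalid input_len or kernel")
        if self.head not in ("avg", "avgmax"):
            raise ValueError("head must be 'avg' or 'avgmax'")


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 512
    batches_per_epoch: int = 1000
    val_batches_per_epoch: int = 500
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("epochs", "batch_size", "batches_per_epoch",
                     "val_batches_per_epoch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainLog:
    train_acc: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        """1-based epoch with the highest validation accuracy (first max)."""
        return int(np.argmax(self.val_acc)) + 1

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch\ttrain_acc\ttrain_loss\tval_acc\tval_loss\n")
            for i in range(len(self.val_acc)):
                fh.write(
                    f"{i + 1}\t{self.train_acc[i]:.6f}\t{self.train_loss[i]:.6f}"
                    f"\t{self.val_acc[i]:.6f}\t{self.val_loss[i]:.6f}\n"
                )


@dataclass
class EvalReport:
    tpr: float
    fpr: float
    tnr: float
    fnr: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float  # NaN when undefined (single-class test set)
    roc_fpr: np.ndarray | None = None
    roc_tpr: np.ndarray | None = None
    roc_thresholds: np.ndarray | None = None
    threshold: float = 0.5
    n: int = 0

    def to_json(self, path: str | Path) -> None:
        d = {
            k: (None if isinstance(v, float) and np.isnan(v) else v)
            for k, v in self.__dict__.items()
            if not k.startswith("roc_")
        }
        if self.roc_fpr is not None:
            d["roc"] = {
                "fpr": self.roc_fpr.tolist(),
                "tpr": self.roc_tpr.tolist(),
                "thresholds": self.roc_thresholds.tolist(),
            }
        Path(path).write_text(json.dumps(d, indent=2))


# ---------------------------------------------------------------------------
# Layers (NumPy, with explicit backward passes)
# ---------------------------------------------------------------------------


class _Conv1d:
    def __init__(self, rng, in_ch, out_ch, kernel, stride=1):
        self.stride = stride
        self.kernel = kernel
        self.pad = kernel // 2
        scale = np.sqrt(2.0 / (in_ch * kernel))  # He initialization
        self.W = rng.normal(0.0, scale, size=(out_ch, in_ch, kernel)).astype(
            np.float32
        )
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def out_len(self, L: int) -> int:
        return (L + 2 * self.pad - self.kernel) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, L = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        win = win[:, :, :: self.stride, :]  # (N, C, L_out, K)
        L_out = win.shape[2]
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
            N * L_out, C * self.kernel
        )
        self._cols = cols
        self._in_shape = (N, C, L)
        out = cols @ self.W.reshape(self.W.shape[0], -1).T + self.b
        return out.reshape(N, L_out, -1).transpose(0, 2, 1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, C, L = self._in_shape
        F = self.W.shape[0]
        L_out = dout.shape[2]
        dr = np.ascontiguousarray(dout.transpose(0, 2, 1)).reshape(N * L_out, F)
        self.db += dr.sum(axis=0)
        self.dW += (dr.T @ self._cols).reshape(self.W.shape)
        dcols = (dr @ self.W.reshape(F, -1)).reshape(N, L_out, C, self.kernel)
        dcols = dcols.transpose(0, 2, 1, 3)  # (N, C, L_out, K)
        dxp = np.zeros((N, C, L + 2 * self.pad), dtype=np.float32)
        offsets = np.arange(L_out) * self.stride
        for kk in range(self.kernel):
            dxp[:, :, offsets + kk] += dcols[:, :, :, kk]
        self._cols = None
        return dxp[:, :, self.pad : self.pad + L]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _BatchNorm1d:
    def __init__(self, ch, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(ch, dtype=np.float32)
        self.beta = np.zeros(ch, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) * inv[None, :, None]
        if train:
            self._xhat = xhat.astype(np.float32)
            self._inv = inv.astype(np.float32)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        m = dout.shape[0] * dout.shape[2]
        self.dgamma += (dout * xhat).sum(axis=(0, 2))
        self.dbeta += dout.sum(axis=(0, 2))
        dxhat = dout * self.gamma[None, :, None]
        term1 = dxhat.sum(axis=(0, 2), keepdims=True)
        term2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        dx = (inv[None, :, None] / m) * (m * dxhat - term1 - xhat * term2)
        self._xhat = None
        return dx.astype(np.float32)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class _ResBlock:
    def __init__(self, rng, in_ch, out_ch, kernel, stride):
        self.conv1 = _Conv1d(rng, in_ch, out_ch, kernel, stride)
        self.bn1 = _BatchNorm1d(out_ch)
        self.conv2 = _Conv1d(rng, out_ch, out_ch, kernel, 1)
        self.bn2 = _BatchNorm1d(out_ch)
        self.project = stride != 1 or in_ch != out_ch
        if self.project:
            self.conv_sc = _Conv1d(rng, in_ch, out_ch, 1, stride)
            self.bn_sc = _BatchNorm1d(out_ch)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.conv1.forward(x)
        h = self.bn1.forward(h, train)
        self._mask1 = h > 0
        h = h * self._mask1
        h = self.conv2.forward(h)
        h = self.bn2.forward(h, train)
        sc = x
        if self.project:
            sc = self.bn_sc.forward(self.conv_sc.forward(x), train)
        out = h + sc
        self._mask_out = out > 0
        return out * self._mask_out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = dout * self._mask_out
        dh = self.bn2.backward(dout)
        dh = self.conv2.backward(dh)
        dh = dh * self._mask1
        dh = self.bn1.backward(dh)
        dx = self.conv1.backward(dh)
        if self.project:
            dsc = self.bn_sc.backward(dout)
            dx = dx + self.conv_sc.backward(dsc)
        else:
            dx = dx + dout
        self._mask1 = self._mask_out = None
        return dx

    def params(self):
        out = self.conv1.params() + self.bn1.params() + self.conv2.params()
        out += self.bn2.params()
        if self.project:
            out += self.conv_sc.params() + self.bn_sc.params()
        return out


class ResNet1D:
    """Residual 1D convolutional classifier over current windows."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f = config.base_filters
        self.stem = _Conv1d(rng, 1, f, config.kernel, config.stem_stride)
        self.stem_bn = _BatchNorm1d(f)
        self.blocks = []
        for i in range(1, config.n_blocks + 1):
            stride = 2 if (config.downsample_every > 0
                           and i % config.downsample_every == 0) else 1
            self.blocks.append(_ResBlock(rng, f, f, config.kernel, stride))
        head_dim = 2 * f if config.head == "avgmax" else f
        self.head_w = rng.normal(
            0.0, 1.0 / np.sqrt(head_dim), size=(head_dim,)
        ).astype(np.float32)
        self.head_b = np.zeros(1, dtype=np.float32)
        self.dhead_w = np.zeros_like(self.head_w)
        self.dhead_b = np.zeros_like(self.head_b)

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch of windows, x of shape (n, input_len)."""
        if x.ndim != 2 or x.shape[1] != self.config.input_len:
            raise ValueError(
                f"expected windows of shape (n, {self.config.input_len}), "
                f"got {x.shape}"
            )
        h = x[:, None, :].astype(np.float32)
        h = self.stem.forward(h)
        h = self.stem_bn.forward(h, train)
        self._stem_mask = h > 0
        h = h * self._stem_mask
        for b in self.blocks:
            h = b.forward(h, train)
        self._gap_len = h.shape[2]
        if self.config.head == "avgmax":
            # detection head: mean pooling for context, max pooling so a
            # short anomalous (modified) segment cannot be averaged away
            self._argmax = h.argmax(axis=2)
            pooled = np.concatenate([h.mean(axis=2), h.max(axis=2)], axis=1)
        else:
            pooled = h.mean(axis=2)
        self._pooled = pooled
        return pooled @ self.head_w + self.head_b[0]

    def backward(self, dlogits: np.ndarray) -> None:
        self.dhead_w += dlogits @ self._pooled
        self.dhead_b += dlogits.sum(keepdims=True)
        dpooled = np.outer(dlogits, self.head_w)
        f = self.config.base_filters
        dh = np.repeat(
            dpooled[:, :f, None] / self._gap_len, self._gap_len, axis=2
        ).astype(np.float32)
        if self.config.head == "avgmax":
            n, _ = self._argmax.shape
            ii, cc = np.meshgrid(np.arange(n), np.arange(f), indexing="ij")
            dh[ii, cc, self._argmax] += dpooled[:, f:]
            self._argmax = None
        for b in reversed(self.blocks):
            dh = b.backward(dh)
        dh = dh * self._stem_mask
        dh = self.stem_bn.backward(dh)
        self.stem.backward(dh)
        self._stem_mask = self._pooled = None

    def params(self):
        out = self.stem.params() + self.stem_bn.params()
        for b in self.blocks:
            out += b.params()
        out += [(self.head_w, self.dhead_w), (self.head_b, self.dhead_b)]
        return out

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0.0

    # -- prediction --------------------------------------------------------
    def predict_proba(self, windows: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Modification probabilities in (0, 1), order-preserving."""
        windows = np.asarray(windows, dtype=np.float32)
        if windows.ndim == 1:
            windows = windows[None, :]
        out = np.empty(len(windows), dtype=np.float64)
        for i in range(0, len(windows), batch_size):
            z = self.forward(windows[i : i + batch_size], train=False)
            out[i : i + batch_size] = _sigmoid(z)
        return out

    # -- state -------------------------------------------------------------
    def get_state(self) -> list[np.ndarray]:
        state = [p.copy() for p, _ in self.params()]
        for bn in self._batchnorms():
            state.append(bn.running_mean.copy())
            state.append(bn.running_var.copy())
        return state

    def set_state(self, state: Sequence[np.ndarray]) -> None:
        n_params = len(self.params())
        for (p, _), s in zip(self.params(), state[:n_params]):
            p[...] = s
        rest = state[n_params:]
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean[...] = rest[2 * i]
            bn.running_var[...] = rest[2 * i + 1]

    def _batchnorms(self):
        out = [self.stem_bn]
        for b in self.blocks:
            out += [b.bn1, b.bn2]
            if b.project:
                out.append(b.bn_sc)
        return out


def build_model(config: ModelConfig | None = None) -> ResNet1D:
    return ResNet1D(config or ModelConfig())


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and gradient wrt logits."""
    z = z.astype(np.float64)
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    dz = (_sigmoid(z) - y) / len(z)
    return float(loss), dz.astype(np.float32)


class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)


# ---------------------------------------------------------------------------
# Training / evaluation protocol
# ---------------------------------------------------------------------------


def train(model: ResNet1D, train_sampler, val_sampler,
          config: TrainConfig | None = None) -> tuple[ResNet1D, TrainLog]:
    """Adam/BCE training; returns the checkpoint with best validation accuracy.

    Per epoch, ``batches_per_epoch`` training batches are drawn and
    ``val_batches_per_epoch`` validation batches are scored in eval mode;
    accuracy and loss are logged per epoch. Fully reproducible under
    ``config.seed``.
    """
    config = config or TrainConfig()
    if len(train_sampler.classes) < 2:
        raise ValueError("training data contains a single class")
    rng = np.random.default_rng(config.seed)
    opt = _Adam(model.params(), lr=config.learning_rate)
    log = TrainLog()
    best_state, best_acc = None, -1.0
    for epoch in range(config.epochs):
        losses, accs = [], []
        for _ in range(config.batches_per_epoch):
            X, y = train_sampler.sample_batch(rng, config.batch_size)
            model.zero_grad()
            z = model.forward(X, train=True)
            loss, dz = _bce_with_logits(z, y)
            model.backward(dz)
            opt.step()
            losses.append(loss)
            accs.append(float(np.mean((z > 0) == (y > 0.5))))
        vl, va = [], []
        for _ in range(config.val_batches_per_epoch):
            Xv, yv = val_sampler.sample_batch(rng, config.batch_size)
            zv = model.forward(Xv, train=False)
            lossv, _ = _bce_with_logits(zv, yv)
            vl.append(lossv)
            va.append(float(np.mean((zv > 0) == (yv > 0.5))))
        log.train_loss.append(float(np.mean(losses)))
        log.train_acc.append(float(np.mean(accs)))
        log.val_loss.append(float(np.mean(vl)))
        log.val_acc.append(float(np.mean(va)))
        if log.val_acc[-1] > best_acc:
            best_acc = log.val_acc[-1]
            best_state = model.get_state()
    best_model = ResNet1D(model.config)
    best_model.set_state(best_state)
    return best_model, log


def predict_windows(model: ResNet1D, windows: np.ndarray) -> np.ndarray:
    """Score normalized windows; deterministic and order-preserving."""
    return model.predict_proba(windows)


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """P(score_pos > score_neg) + 0.5 P(tie); NaN if one class absent."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels) > 0.5
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return float((gt + 0.5 * eq) / (len(pos) * len(neg)))


def evaluate(
    model: ResNet1D,
    windows: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
) -> EvalReport:
    """Point metrics at ``threshold`` plus the empirical ROC and trapezoid AUC.

    On a single-class test set the ROC/AUC are reported as undefined (NaN)
    while the point metrics are still computed. Score ties on the ROC follow
    the Mann-Whitney convention (each tie contributes 1/2).
    """
    scores = model.predict_proba(np.asarray(windows, dtype=np.float32))
    return evaluate_scores(scores, labels, threshold)


def evaluate_scores(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> EvalReport:
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels) > 0.5
    pred = scores >= threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))
    n_pos, n_neg = tp + fn, fp + tn
    tpr = tp / n_pos if n_pos else float("nan")
    fpr = fp / n_neg if n_neg else float("nan")
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tpr if n_pos else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) > 0 else 0.0)
    if n_pos and n_neg:
        roc_fpr, roc_tpr, roc_thr = roc_curve(y.astype(int), scores)
        auc = float(np.trapezoid(roc_tpr, roc_fpr))
    else:
        roc_fpr = roc_tpr = roc_thr = None
        auc = float("nan")
    return EvalReport(
        tpr=tpr, fpr=fpr,
        tnr=1.0 - fpr if n_neg else float("nan"),
        fnr=1.0 - tpr if n_pos else float("nan"),
        accuracy=(tp + tn) / len(y),
        precision=precision, recall=recall, f1=f1, auc=auc,
        roc_fpr=roc_fpr, roc_tpr=roc_tpr, roc_thresholds=roc_thr,
        threshold=threshold, n=len(y),
    )


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(model: ResNet1D, path: str | Path, norm_stats=None,
                    extra: dict | None = None) -> None:
    """Versioned checkpoint embedding ModelConfig and normalization stats."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": model.config.__dict__,
        "norm_stats": None if norm_stats is None
        else {"mean": norm_stats.mean, "sd": norm_stats.sd},
        "extra": extra or {},
    }
    state = model.get_state()
    arrays = {f"state_{i}": s for i, s in enumerate(state)}
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path):
    """Returns (model, NormStats | None, extra dict)."""
    from .preprocess import NormStats

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        cfg = ModelConfig(**{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in meta["config"].items()
        })
        model = ResNet1D(cfg)
        state = [data[f"state_{i}"]
                 for i in range(sum(1 for k in data.files if k.startswith("state_")))]
        model.set_state(state)
    stats = None
    if meta["norm_stats"] is not None:
        stats = NormStats(**meta["norm_stats"])
    return model, stats, meta.get("extra", {})
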