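"""Current-signal preprocessing: clip, normalize, window, split.

The pipeline order is clip -> normalize -> window. Normalization statistics
are computed once on the training pool (after clipping) and frozen for
validation, test, and chromatin inference, so held-out data never leaks into
the scaling. Splits are made by read, not by window, to keep overlapping
windows of one read out of two splits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .signal_sim import SimulatedRead

CLIP_LO = -50.0
CLIP_HI = 150.0
WINDOW = 400


@dataclass
class PreprocConfig:
    clip_lo: float = CLIP_LO
    clip_hi: float = CLIP_HI
    window: int = WINDOW
    train_step: int = 1
    infer_step: int = 200
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clip_lo >= self.clip_hi:
            raise ValueError("clip_lo must be < clip_hi")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.train_step < 1 or self.infer_step < 1:
            raise ValueError("steps must be >= 1")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class NormStats:
    """Frozen dataset-level mean/sd (population sd) used for z-scaling."""

    mean: float
    sd: float

    def to_json(self) -> str:
        return json.dumps({"mean": self.mean, "sd": self.sd})

    @classmethod
    def from_json(cls, s: str) -> "NormStats":
        d = json.loads(s)
        return cls(mean=d["mean"], sd=d["sd"])


def clip_signal(x, lo: float = CLIP_LO, hi: float = CLIP_HI):
    """Clamp current values into [lo, hi]. NaNs are rejected."""
    arr = np.asarray(x, dtype=np.float64)
    if np.isnan(arr).any():
        raise ValueError("signal contains NaN")
    out = np.clip(arr, lo, hi)
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


def compute_norm_stats(
    signals: Sequence[np.ndarray], config: PreprocConfig | None = None
) -> NormStats:
    """Pooled mean and population sd of clipped signals."""
    config = config or PreprocConfig()
    n = 0
    total = 0.0
    total_sq = 0.0
    for s in signals:
        c = np.clip(np.asarray(s, dtype=np.float64), config.clip_lo, config.clip_hi)
        n += c.size
        total += c.sum()
        total_sq += (c**2).sum()
    if n == 0:
        raise ValueError("no samples to compute statistics from")
    mean = total / n
    var = total_sq / n - mean**2
    if var <= 0:
        raise ValueError("constant signal pool: sd is zero")
    return NormStats(mean=float(mean), sd=float(np.sqrt(var)))


def normalize(signals, stats: NormStats):
    """Z-scale by frozen dataset statistics; shape-preserving."""
    if stats.sd <= 0:
        raise ValueError("normalization sd must be positive")
    return (np.asarray(signals, dtype=np.float64) - stats.mean) / stats.sd


def preprocess_signal(
    signal: np.ndarray, stats: NormStats, config: PreprocConfig | None = None
) -> np.ndarray:
    """Clip then normalize one raw signal (the canonical pipeline order)."""
    config = config or PreprocConfig()
    return normalize(clip_signal(signal, config.clip_lo, config.clip_hi), stats)


def window_offsets(length: int, window: int = WINDOW, step: int = 1) -> np.ndarray:
    """Offsets 0, step, 2*step, ... with no partial windows.

    floor((length - window)/step) + 1 offsets for length >= window, else none.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if length < window:
        return np.array([], dtype=np.int64)
    n = (length - window) // step + 1
    return np.arange(n, dtype=np.int64) * step


def window_read(
    signal: np.ndarray, window: int = WINDOW, step: int = 1
) -> list[tuple[int, np.ndarray]]:
    """(offset, window-slice) pairs for one signal; short reads yield []."""
    signal = np.asarray(signal)
    return [(int(o), signal[o : o + window])
            for o in window_offsets(len(signal), window, step)]


def shift_augment(
    signal: np.ndarray, offsets: Sequence[int], window: int = WINDOW
) -> list[tuple[int, np.ndarray]]:
    """For each base window at offset o, also emit the o+1 window.

    Captures the sequential nature of the signal by pairing every window
    with its one-sample shift; at the read end, where o+1 would overrun,
    only the base window is emitted.
    """
    signal = np.asarray(signal)
    out = []
    for o in offsets:
        o = int(o)
        out.append((o, signal[o : o + window]))
        if o + 1 + window <= len(signal):
            out.append((o + 1, signal[o + 1 : o + 1 + window]))
    return out


@dataclass
class ReadSplits:
    """Read-level train/val/test assignment per class (no window leakage)."""

    train: list[tuple[SimulatedRead, float]]
    val: list[tuple[SimulatedRead, float]]
    test: list[tuple[SimulatedRead, float]]


def make_splits(
    pos_reads: Sequence[SimulatedRead],
    neg_reads: Sequence[SimulatedRead],
    config: PreprocConfig | None = None,
) -> ReadSplits:
    """Shuffle each class by seed and split by read into 60/20/20.

    Positive reads are labeled 1.0 and negative reads 0.0. Requires at least
    5 reads per class so every split is nonempty.
    """
    config = config or PreprocConfig()
    if len(pos_reads) == 0 or len(neg_reads) == 0:
        raise ValueError("both classes must be nonempty")
    if len(pos_reads) < 5 or len(neg_reads) < 5:
        raise ValueError("need >= 5 reads per class to split 60/20/20")
    rng = np.random.default_rng(config.seed)
    splits: dict[str, list] = {"train": [], "val": [], "test": []}
    for reads, label in ((pos_reads, 1.0), (neg_reads, 0.0)):
        order = rng.permutation(len(reads))
        n = len(reads)
        n_train = int(round(config.split[0] * n))
        n_val = int(round(config.split[1] * n))
        for j, i in enumerate(order):
            if j < n_train:
                part = "train"
            elif j < n_train + n_val:
                part = "val"
            else:
                part = "test"
            splits[part].append((reads[i], label))
    return ReadSplits(**splits)


class WindowSampler:
    """Random labeled 400-sample windows from a pool of preprocessed reads.

    Signals are clipped and z-scaled once at construction with the frozen
    ``stats``. ``sample_batch`` draws (read, offset) pairs uniformly — a
    random sampling of the same step-1 window universe the enumeration-based
    pipeline would produce.
    """

    def __init__(
        self,
        labeled_reads: Sequence[tuple[SimulatedRead, float]],
        stats: NormStats,
        config: PreprocConfig | None = None,
    ):
        self.config = config or PreprocConfig()
        self.window = self.config.window
        self._signals = []
        self._labels = []
        for read, label in labeled_reads:
            if len(read.signal) < self.window:
                continue
            self._signals.append(
                preprocess_signal(read.signal, stats, self.config).astype(np.float32)
            )
            self._labels.append(float(label))
        if not self._signals:
            raise ValueError("no reads long enough for a single window")
        self._labels = np.asarray(self._labels, dtype=np.float32)
        self._max_offsets = np.array(
            [len(s) - self.window for s in self._signals], dtype=np.int64
        )

    @property
    def n_reads(self) -> int:
        return len(self._signals)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self._labels)

    def sample_batch(
        self, rng: np.random.Generator, batch_size: int
    ) -> tuple[np.ndarray, np.ndarray]:
        idx = rng.integers(0, len(self._signals), size=batch_size)
        X = np.empty((batch_size, self.window), dtype=np.float32)
        for row, i in enumerate(idx):
            o = int(rng.integers(0, self._max_offsets[i] + 1))
            X[row] = self._signals[i][o : o + self.window]
        return X, self._labels[idx]

    def enumerate_windows(
        self, step: int | None = None
    ) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
        """All windows at the given step with labels and (read, offset) provenance."""
        step = step or self.config.infer_step
        X, y, prov = [], [], []
        for i, s in enumerate(self._signals):
            for o in window_offsets(len(s), self.window, step):
                X.append(s[o : o + self.window])
                y.append(self._labels[i])
                prov.append((i, int(o)))
        return np.asarray(X, dtype=np.float32), np.asarray(y, dtype=np.float32), prov
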