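"""Single-molecule clustering of modification tracks at a locus.

Builds a reads x positions probability matrix for a genomic region, drops
poorly covering and saturated (fully modified) reads, imputes residual
missing values column-wise, k-means-clusters the reads, and summarizes each
cluster as a min-max-normalized mean accessibility track.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .genome_mapping import ReadModTrack

logger = logging.getLogger(__name__)


@dataclass
class ClusterConfig:
    min_cover_frac: float = 0.8
    high_mod_cutoff: float = 0.8
    k: int = 2
    n_iter: int = 300
    n_init: int = 10
    quantize_decimals: int | None = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.min_cover_frac <= 1):
            raise ValueError("min_cover_frac must be in (0, 1]")
        if self.k < 1 or self.n_iter < 1 or self.n_init < 1:
            raise ValueError("k, n_iter, n_init must be >= 1")


@dataclass
class ReadMatrix:
    """Region-aligned reads x positions probability matrix (NaN = missing)."""

    contig: str
    start: int
    end: int
    read_ids: list[str]
    values: np.ndarray  # (n_reads, end - start)
    n_dropped_coverage: int = 0
    n_dropped_high_mod: int = 0

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.start, self.end)

    @property
    def row_means(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=1)


@dataclass
class ClusterResult:
    labels: np.ndarray  # per read, in [0, k_effective)
    k_effective: int
    profiles: np.ndarray  # (k_effective, n_positions) min-max normalized
    inertia: float
    read_order: np.ndarray  # rows sorted by (cluster, read id)


def parse_region(region: str) -> tuple[str, int, int]:
    """'contig:start-end' (1-based inclusive, as in locus notation) to
    0-based half-open coordinates."""
    m = re.fullmatch(r"(.+):([\d,]+)-([\d,]+)", region.strip())
    if not m:
        raise ValueError(f"cannot parse region {region!r}")
    contig = m.group(1)
    start = int(m.group(2).replace(",", "")) - 1
    end = int(m.group(3).replace(",", ""))
    if start < 0 or end <= start:
        raise ValueError(f"empty region {region!r}")
    return contig, start, end


def build_read_matrix(
    tracks: Sequence[ReadModTrack],
    region: tuple[str, int, int] | str,
    config: ClusterConfig | None = None,
) -> ReadMatrix:
    """Matrix of reads covering >= min_cover_frac of the region positions.

    Coverage counts positions with a defined score. Dropped reads are
    counted; zero qualifying reads is an error naming the region.
    """
    config = config or ClusterConfig()
    if isinstance(region, str):
        region = parse_region(region)
    contig, start, end = region
    if start >= end:
        raise ValueError("region start must be < end")
    width = end - start
    rows, ids = [], []
    n_dropped = 0
    for t in tracks:
        if t.contig != contig:
            continue
        lo, hi = max(t.start, start), min(t.end, end)
        row = np.full(width, np.nan)
        if lo < hi:
            row[lo - start : hi - start] = t.scores[lo - t.start : hi - t.start]
        frac = float((~np.isnan(row)).mean())
        if frac >= config.min_cover_frac:
            rows.append(row)
            ids.append(t.read_id)
        else:
            n_dropped += 1
    if not rows:
        raise ValueError(
            f"no reads cover >= {config.min_cover_frac:.0%} of "
            f"{contig}:{start}-{end}"
        )
    if n_dropped:
        logger.info("dropped %d reads below %.0f%% coverage of %s:%d-%d",
                    n_dropped, 100 * config.min_cover_frac, contig, start, end)
    return ReadMatrix(
        contig=contig, start=start, end=end, read_ids=ids,
        values=np.vstack(rows), n_dropped_coverage=n_dropped,
    )


def filter_high_mod(
    matrix: ReadMatrix, config: ClusterConfig | None = None
) -> ReadMatrix:
    """Drop saturated reads with mean score >= high_mod_cutoff (inclusive).

    These are naked-DNA-like molecules that carry no footprint information.
    Raises if every read would be removed.
    """
    config = config or ClusterConfig()
    means = matrix.row_means
    # inclusive >= cutoff, tolerant of float accumulation at the boundary
    drop = (means >= config.high_mod_cutoff) | np.isclose(
        means, config.high_mod_cutoff, rtol=0.0, atol=1e-9
    )
    keep = ~drop
    n_removed = int((~keep).sum())
    if not keep.any():
        raise ValueError("all reads are highly modified; nothing to cluster")
    if n_removed:
        logger.info("filtered %d highly modified reads (mean >= %.2f)",
                    n_removed, config.high_mod_cutoff)
    return ReadMatrix(
        contig=matrix.contig, start=matrix.start, end=matrix.end,
        read_ids=[r for r, k in zip(matrix.read_ids, keep) if k],
        values=matrix.values[keep],
        n_dropped_coverage=matrix.n_dropped_coverage,
        n_dropped_high_mod=matrix.n_dropped_high_mod + n_removed,
    )


def impute_missing(
    matrix: ReadMatrix, config: ClusterConfig | None = None
) -> ReadMatrix:
    """Column-wise most-frequent imputation after quantization.

    Observed values are rounded to ``quantize_decimals`` before taking the
    per-column mode (continuous probabilities rarely repeat exactly, so the
    mode is taken on the quantized scale; set quantize_decimals=None for
    exact-value mode). Ties pick the smallest modal value. A fully missing
    column is an error.
    """
    config = config or ClusterConfig()
    values = matrix.values.copy()
    for j in range(values.shape[1]):
        col = values[:, j]
        missing = np.isnan(col)
        if not missing.any():
            continue
        observed = col[~missing]
        if len(observed) == 0:
            raise ValueError(f"column {j} (position {matrix.start + j}) is "
                             "fully missing; cannot impute")
        if config.quantize_decimals is not None:
            observed = np.round(observed, config.quantize_decimals)
        uniq, counts = np.unique(observed, return_counts=True)
        mode = uniq[counts == counts.max()].min()  # ties -> smallest value
        col[missing] = mode
    return ReadMatrix(
        contig=matrix.contig, start=matrix.start, end=matrix.end,
        read_ids=list(matrix.read_ids), values=values,
        n_dropped_coverage=matrix.n_dropped_coverage,
        n_dropped_high_mod=matrix.n_dropped_high_mod,
    )


def _minmax(profile: np.ndarray) -> np.ndarray:
    lo, hi = profile.min(), profile.max()
    if hi == lo:
        return np.full_like(profile, 0.5)  # constant profile convention
    return (profile - lo) / (hi - lo)


def cluster_reads(
    matrix: ReadMatrix, config: ClusterConfig | None = None
) -> ClusterResult:
    """Seeded k-means over read rows with canonical cluster labeling.

    Lloyd's algorithm (Euclidean, ``n_init`` random restarts keeping the
    lowest within-cluster sum of squares, <= ``n_iter`` iterations each).
    Clusters are relabeled by descending mean row score so cluster 0 is
    always the most accessible; identical rows degrade to k_effective=1
    with a warning.
    """
    config = config or ClusterConfig()
    X = matrix.values
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; impute first")
    n = X.shape[0]
    if n < config.k:
        raise ValueError(f"{n} reads < k={config.k}")
    if config.k == 1 or np.allclose(X, X[0]):
        if config.k > 1:
            warnings.warn("all rows identical; returning a single cluster")
        profile = _minmax(X.mean(axis=0))
        return ClusterResult(
            labels=np.zeros(n, dtype=np.int64), k_effective=1,
            profiles=profile[None, :], inertia=0.0,
            read_order=np.arange(n),
        )
    km = KMeans(
        n_clusters=config.k, n_init=config.n_init, max_iter=config.n_iter,
        init="random", random_state=config.seed,
    ).fit(X)
    raw_labels = km.labels_
    present = np.unique(raw_labels)
    # canonical order: descending mean accessibility of the cluster
    means = {c: X[raw_labels == c].mean() for c in present}
    order = sorted(present, key=lambda c: -means[c])
    remap = {c: i for i, c in enumerate(order)}
    labels = np.array([remap[c] for c in raw_labels], dtype=np.int64)
    k_eff = len(present)
    if k_eff < config.k:
        warnings.warn(f"only {k_eff} of {config.k} clusters are nonempty")
    profiles = np.vstack(
        [_minmax(X[labels == i].mean(axis=0)) for i in range(k_eff)]
    )
    read_order = np.lexsort((np.asarray(matrix.read_ids), labels))
    return ClusterResult(
        labels=labels, k_effective=k_eff, profiles=profiles,
        inertia=float(km.inertia_), read_order=read_order,
    )


def cluster_profiles(matrix: ReadMatrix, labels: np.ndarray) -> np.ndarray:
    """Min-max normalized per-cluster mean tracks (rows ordered by label)."""
    out = []
    for c in range(int(labels.max()) + 1):
        out.append(_minmax(matrix.values[labels == c].mean(axis=0)))
    return np.vstack(out)


def silhouette_sweep(
    matrix: ReadMatrix, ks: Sequence[int], config: ClusterConfig | None = None
) -> dict[int, float]:
    """Optional silhouette score per candidate k (user still chooses k)."""
    from sklearn.metrics import silhouette_score

    config = config or ClusterConfig()
    out = {}
    for k in ks:
        if not (2 <= k < matrix.values.shape[0]):
            continue
        res = cluster_reads(
            matrix, ClusterConfig(**{**config.__dict__, "k": k})
        )
        if res.k_effective < 2:
            continue
        out[k] = float(silhouette_score(matrix.values, res.labels))
    return out


def render_locus(
    matrix: ReadMatrix,
    result: ClusterResult,
    path: str | Path,
    annotations: Sequence[tuple[int, int, str]] = (),
    title: str | None = None,
) -> None:
    """Heatmap of reads grouped by cluster with per-cluster mean wiggles.

    Color scale: dark blue = probability 0 (occupied), bright yellow = 1
    (accessible). ``annotations`` are optional (start, end, label) gene
    glyphs in reference coordinates.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_rows = max(1, len(matrix.read_ids))
    fig, axes = plt.subplots(
        2, 1, figsize=(10, 3 + 0.08 * n_rows),
        gridspec_kw={"height_ratios": [1, 3]}, sharex=True,
    )
    x = matrix.positions
    for c in range(result.k_effective):
        axes[0].plot(x, result.profiles[c], label=f"C{c + 1}", lw=1.2)
    axes[0].set_ylabel("norm. score")
    axes[0].legend(loc="upper right", fontsize=7)
    ordered = matrix.values[result.read_order]
    im = axes[1].imshow(
        ordered, aspect="auto", interpolation="nearest", cmap="viridis",
        vmin=0.0, vmax=1.0,
        extent=[x[0], x[-1] + 1, len(ordered), 0],
    )
    boundaries = np.flatnonzero(np.diff(result.labels[result.read_order])) + 1
    for b in boundaries:
        axes[1].axhline(b, color="white", lw=0.8)
    for a_start, a_end, label in annotations:
        axes[1].axvspan(a_start, a_end, color="gray", alpha=0.15)
        axes[1].text(a_start, -0.5, label, fontsize=7)
    axes[1].set_xlabel(f"{matrix.contig} position")
    axes[1].set_ylabel("reads")
    fig.colorbar(im, ax=axes, label="modification probability", shrink=0.6)
    if title:
        axes[0].set_title(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_cluster_assignments(
    matrix: ReadMatrix, result: ClusterResult, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tcluster\n")
        for rid, lab in zip(matrix.read_ids, result.labels):
            fh.write(f"{rid}\t{int(lab)}\n")


def write_cluster_profiles(
    matrix: ReadMatrix, result: ClusterResult, path: str | Path
) -> None:
    """Per-cluster profile bedGraph (one track line per cluster)."""
    with open(path, "w") as fh:
        for c in range(result.k_effective):
            fh.write(f'track type=bedGraph name="cluster{c + 1}"\n')
            for p, v in zip(matrix.positions, result.profiles[c]):
                fh.write(f"{matrix.contig}\t{p}\t{p + 1}\t{v:.4f}\n")
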