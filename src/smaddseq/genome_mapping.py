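"""Projection of window modification scores onto reference coordinates.

A window of raw signal maps, through the move table, to the read-local bases
that emitted it; those map to reference positions (flipped for
reverse-strand reads). Scores of overlapping windows covering the same
position are averaged into a per-read track; tracks stack into a genome-wide
pileup. All coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .preprocess import NormStats, PreprocConfig, preprocess_signal, window_offsets
from .signal_sim import KMER_K, SimulatedRead

logger = logging.getLogger(__name__)


@dataclass
class ReadModTrack:
    """Per-read, per-reference-position modification probabilities.

    ``scores[i]`` is the probability at reference position ``start + i``
    (NaN where no window covered the position); ``n_windows[i]`` counts
    contributing windows.
    """

    read_id: str
    contig: str
    strand: str
    start: int
    scores: np.ndarray
    n_windows: np.ndarray

    @property
    def end(self) -> int:
        return self.start + len(self.scores)

    def score_at(self, position: int) -> float:
        if not (self.start <= position < self.end):
            return float("nan")
        return float(self.scores[position - self.start])


@dataclass
class GenomeTrack:
    """contig -> (positions, mean score, read depth) arrays."""

    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    def at(self, contig: str, position: int) -> tuple[float, int]:
        pos, mean, depth = self.data[contig]
        i = np.searchsorted(pos, position)
        if i < len(pos) and pos[i] == position:
            return float(mean[i]), int(depth[i])
        return float("nan"), 0


def window_span_to_positions(
    read: SimulatedRead, offset: int, window_len: int
) -> tuple[int, int]:
    """Half-open reference interval of bases emitting signal [offset, offset+len).

    The move table gives the read-local 6-mer event index of every raw
    sample; the bases of those events map to reference coordinates,
    strand-flipped for reverse reads.
    """
    if offset < 0 or offset + window_len > len(read.moves):
        raise ValueError(
            f"window [{offset}, {offset + window_len}) outside the move table "
            f"range [0, {len(read.moves)})"
        )
    seg = read.moves[offset : offset + window_len]
    b_lo, b_hi = int(seg[0]), int(seg[-1])  # moves are nondecreasing
    L = len(read.sequence)
    # events b_lo..b_hi are 6-mer windows; covered read-local bases:
    lo, hi = b_lo, b_hi + KMER_K  # half-open
    if read.strand == "+":
        return read.start + lo, read.start + hi
    return read.start + L - hi, read.start + L - lo


def windows_to_track(
    read: SimulatedRead,
    scored_windows: Iterable[tuple[int, int, float]],
) -> ReadModTrack:
    """Average overlapping window scores per reference position.

    ``scored_windows``: (offset, window_len, score) triples with scores in
    [0, 1]. Positions covered by no window are NaN. An empty window list
    yields an empty track (flagged by a log message).
    """
    L = len(read.sequence)
    sums = np.zeros(L, dtype=np.float64)
    counts = np.zeros(L, dtype=np.int64)
    n = 0
    for offset, wlen, score in scored_windows:
        if not (0.0 <= score <= 1.0):
            raise ValueError(f"window score {score} outside [0, 1]")
        lo, hi = window_span_to_positions(read, offset, wlen)
        sums[lo - read.start : hi - read.start] += score
        counts[lo - read.start : hi - read.start] += 1
        n += 1
    if n == 0:
        logger.warning("read %s produced no windows; empty track", read.read_id)
    with np.errstate(invalid="ignore"):
        scores = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return ReadModTrack(
        read_id=read.read_id, contig=read.contig, strand=read.strand,
        start=read.start, scores=scores, n_windows=counts,
    )


def predict_read_track(
    model,
    read: SimulatedRead,
    stats: NormStats,
    config: PreprocConfig | None = None,
) -> ReadModTrack:
    """Score a read with the classifier: clip/normalize, slide a 400-sample
    window in steps of ``infer_step``, project scores to the reference, and
    average overlaps."""
    config = config or PreprocConfig()
    signal = preprocess_signal(read.signal, stats, config).astype(np.float32)
    offsets = window_offsets(len(signal), config.window, config.infer_step)
    if len(offsets) == 0:
        return windows_to_track(read, [])
    X = np.stack([signal[o : o + config.window] for o in offsets])
    probs = model.predict_proba(X)
    return windows_to_track(
        read, [(int(o), config.window, float(p)) for o, p in zip(offsets, probs)]
    )


def predict_read_tracks(model, reads, stats, config=None) -> list[ReadModTrack]:
    return [predict_read_track(model, r, stats, config) for r in reads]


def pileup(tracks: Sequence[ReadModTrack]) -> GenomeTrack:
    """Genome-wide mean modification score and read depth per position."""
    by_contig: dict[str, list[ReadModTrack]] = {}
    for t in tracks:
        by_contig.setdefault(t.contig, []).append(t)
    data = {}
    for contig, ts in by_contig.items():
        lo = min(t.start for t in ts)
        hi = max(t.end for t in ts)
        sums = np.zeros(hi - lo)
        depth = np.zeros(hi - lo, dtype=np.int64)
        for t in ts:
            valid = ~np.isnan(t.scores)
            sl = slice(t.start - lo, t.end - lo)
            sums[sl][valid] += t.scores[valid]
            depth[sl][valid] += 1
        covered = depth > 0
        pos = np.flatnonzero(covered) + lo
        mean = sums[covered] / depth[covered]
        data[contig] = (pos, mean, depth[covered])
    return GenomeTrack(data=data)


def group_tracks_by_contig(
    tracks: Sequence[ReadModTrack],
) -> dict[str, list[ReadModTrack]]:
    out: dict[str, list[ReadModTrack]] = {}
    for t in tracks:
        out.setdefault(t.contig, []).append(t)
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_read_tracks(tracks: Sequence[ReadModTrack], path: str | Path) -> None:
    """Per-read TSV: read_id, contig, start, end, strand, comma-joined scores."""
    with open(path, "w") as fh:
        fh.write("read_id\tcontig\tstart\tend\tstrand\tscores\n")
        for t in tracks:
            joined = ",".join(
                "." if np.isnan(s) else f"{s:.4f}" for s in t.scores
            )
            fh.write(f"{t.read_id}\t{t.contig}\t{t.start}\t{t.end}\t{t.strand}\t{joined}\n")


def read_read_tracks(path: str | Path) -> list[ReadModTrack]:
    tracks = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            read_id, contig, start, end, strand, joined = line.rstrip("\n").split("\t")
            scores = np.array(
                [np.nan if s == "." else float(s) for s in joined.split(",")]
            )
            tracks.append(
                ReadModTrack(
                    read_id=read_id, contig=contig, strand=strand,
                    start=int(start), scores=scores,
                    n_windows=(~np.isnan(scores)).astype(np.int64),
                )
            )
    return tracks


def write_bedgraph(track: GenomeTrack, path: str | Path) -> None:
    """bedGraph of the pileup mean score (0-based half-open intervals)."""
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="modification"\n')
        for contig in sorted(track.data):
            pos, mean, _ = track.data[contig]
            for p, m in zip(pos, mean):
                fh.write(f"{contig}\t{p}\t{p + 1}\t{m:.4f}\n")
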