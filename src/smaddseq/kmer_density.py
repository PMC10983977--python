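"""Informative k-mer discovery from event-aligned current signals.

Pools event mean currents per 6-mer across reads, estimates a normalized
density histogram per k-mer, finds density peaks by topographic prominence,
and flags k-mers whose modified-sample density carries a secondary
(adduct-shifted) peak that the unmodified sample lacks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_prominences

from .signal_sim import BASES, KMER_K

logger = logging.getLogger(__name__)


@dataclass
class PeakConfig:
    """Density histogram and peak-detection parameters.

    ``prominence`` is in density units (the histogram integrates to 1 over
    [hist_lo, hist_hi]); ``distance`` is a minimum peak separation in bins.

    The default bin width is ~2 pA (63 bins over [25, 150]): at realistic
    per-k-mer event counts (hundreds to a few thousand) 1-pA histograms are
    mode-unstable and spray spurious prominence-passing peaks, while 2-pA
    bins keep a 12 pA adduct shift comfortably above ``distance`` bins.
    See docs/methods.md for the resolution/noise analysis.
    """

    hist_lo: float = 25.0
    hist_hi: float = 150.0
    n_bins: int = 63
    prominence: float = 0.005
    distance: int = 5
    min_events: int = 50

    def __post_init__(self) -> None:
        if self.hist_lo >= self.hist_hi:
            raise ValueError("hist_lo must be < hist_hi")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.prominence <= 0:
            raise ValueError("prominence must be positive")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(self.hist_lo, self.hist_hi, self.n_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        edges = self.bin_edges
        return 0.5 * (edges[:-1] + edges[1:])


@dataclass
class KmerPeakReport:
    kmer: str
    peaks_pos: list[float]
    peaks_neg: list[float]
    informative: bool
    n_events_pos: int = 0
    n_events_neg: int = 0


class KmerSignalTable:
    """kmer -> array of event mean currents (pA), pooled over one sample."""

    def __init__(self, data: Mapping[str, Sequence[float]] | None = None):
        self._data: dict[str, np.ndarray] = {}
        if data:
            for k, v in data.items():
                self._data[k.upper()] = np.asarray(v, dtype=np.float64)

    def __getitem__(self, kmer: str) -> np.ndarray:
        return self._data[kmer]

    def __contains__(self, kmer: str) -> bool:
        return kmer in self._data

    def __len__(self) -> int:
        return len(self._data)

    def kmers(self) -> list[str]:
        return sorted(self._data)

    def items(self):
        return self._data.items()


def _is_valid_kmer(kmer: str) -> bool:
    return len(kmer) == KMER_K and all(c in BASES for c in kmer)


def aggregate_kmer_means(
    records: pd.DataFrame | Iterable | str | Path,
) -> tuple[KmerSignalTable, int]:
    """Pool event mean currents per reference 6-mer from eventalign records.

    Accepts an eventalign DataFrame, a path to an eventalign TSV, or an
    iterable of (contig, position, reference_kmer, read_name,
    event_level_mean) rows. Rows with non-ACGT k-mers or unparseable values
    are dropped and counted.

    Returns (table, n_dropped). Raises if no usable rows remain.
    """
    if isinstance(records, (str, Path)):
        records = pd.read_csv(records, sep="\t")
    if isinstance(records, pd.DataFrame):
        kmers = records["reference_kmer"].astype(str).str.upper()
        means = pd.to_numeric(records["event_level_mean"], errors="coerce")
        ok = means.notna() & np.isfinite(means)
        ok &= kmers.str.len() == KMER_K
        ok &= kmers.str.fullmatch(f"[{BASES}]{{{KMER_K}}}").fillna(False)
        n_dropped = int((~ok).sum())
        grouped = means[ok].groupby(kmers[ok])
        data = {k: v.to_numpy() for k, v in grouped}
    else:
        buckets: dict[str, list[float]] = {}
        n_dropped = 0
        for row in records:
            try:
                kmer = str(row[2]).upper()
                value = float(row[4])
            except (IndexError, TypeError, ValueError):
                n_dropped += 1
                continue
            if not _is_valid_kmer(kmer) or not np.isfinite(value):
                n_dropped += 1
                continue
            buckets.setdefault(kmer, []).append(value)
        data = {k: np.asarray(v) for k, v in buckets.items()}
    if not data:
        raise ValueError("no usable eventalign rows")
    if n_dropped:
        logger.info("dropped %d malformed/non-ACGT eventalign rows", n_dropped)
    return KmerSignalTable(data), n_dropped


def signal_density(
    values: Sequence[float], config: PeakConfig | None = None
) -> np.ndarray:
    """Density-normalized histogram of current values over [hist_lo, hist_hi].

    Values outside the range are excluded; the result integrates to 1 over
    the range. Raises if no value falls inside the range.
    """
    config = config or PeakConfig()
    values = np.asarray(values, dtype=np.float64)
    inside = values[(values >= config.hist_lo) & (values <= config.hist_hi)]
    if len(inside) == 0:
        raise ValueError("all values outside the histogram range")
    density, _ = np.histogram(
        inside, bins=config.n_bins, range=(config.hist_lo, config.hist_hi),
        density=True,
    )
    return density


def find_signal_peaks(
    density: np.ndarray, config: PeakConfig | None = None
) -> np.ndarray:
    """Peak locations (pA, bin centers) by prominence and minimum separation.

    Candidates are local maxima with topographic prominence >=
    ``config.prominence``; peaks closer than ``config.distance`` bins are
    resolved greedily, keeping the higher peak (equal heights: the lower-pA
    peak wins, a deterministic tie rule).
    """
    config = config or PeakConfig()
    density = np.asarray(density, dtype=np.float64)
    candidates, props = find_peaks(density, prominence=config.prominence)
    if len(candidates) == 0:
        return np.array([], dtype=np.float64)
    # greedy distance selection: height desc, ties -> lower index first
    order = sorted(range(len(candidates)),
                   key=lambda i: (-density[candidates[i]], candidates[i]))
    kept: list[int] = []
    for i in order:
        c = candidates[i]
        if all(abs(c - k) >= config.distance for k in kept):
            kept.append(c)
    kept.sort()
    return config.bin_centers[np.asarray(kept, dtype=np.int64)]


def identify_informative_kmers(
    pos: KmerSignalTable,
    neg: KmerSignalTable,
    config: PeakConfig | None = None,
) -> list[KmerPeakReport]:
    """Flag k-mers with a secondary density peak in the modified sample.

    One report per k-mer present in ``pos`` with at least ``min_events``
    events (low-count k-mers are excluded and counted); ``informative`` is
    true iff the positive-sample density has >= 2 peaks. Negative-sample
    peaks are reported for the QC expectation that unmodified data is
    unimodal.
    """
    config = config or PeakConfig()
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both signal tables must be nonempty")
    reports = []
    n_excluded = 0
    for kmer in pos.kmers():
        values = pos[kmer]
        if len(values) < config.min_events:
            n_excluded += 1
            continue
        peaks_pos = find_signal_peaks(signal_density(values, config), config)
        if kmer in neg and len(neg[kmer]) >= config.min_events:
            peaks_neg = find_signal_peaks(signal_density(neg[kmer], config), config)
            n_neg = len(neg[kmer])
        else:
            peaks_neg = np.array([])
            n_neg = len(neg[kmer]) if kmer in neg else 0
        reports.append(
            KmerPeakReport(
                kmer=kmer,
                peaks_pos=[float(p) for p in peaks_pos],
                peaks_neg=[float(p) for p in peaks_neg],
                informative=len(peaks_pos) >= 2,
                n_events_pos=len(values),
                n_events_neg=n_neg,
            )
        )
    if n_excluded:
        logger.info("excluded %d k-mers with < %d events", n_excluded,
                    config.min_events)
    return reports


def position_frequency_matrix(kmers: Sequence[str]) -> np.ndarray:
    """4 x 6 base-frequency matrix (rows A, C, G, T; columns sum to 1)."""
    if len(kmers) == 0:
        raise ValueError("empty k-mer list")
    pfm = np.zeros((4, KMER_K))
    for kmer in kmers:
        if len(kmer) != KMER_K:
            raise ValueError(f"k-mer {kmer!r} is not length {KMER_K}")
        for j, base in enumerate(kmer.upper()):
            pfm[BASES.index(base), j] += 1
    return pfm / len(kmers)


def write_peak_reports(reports: Sequence[KmerPeakReport], path: str | Path) -> None:
    rows = [
        {
            "kmer": r.kmer,
            "n_events_pos": r.n_events_pos,
            "n_events_neg": r.n_events_neg,
            "peaks_pos": ",".join(f"{p:.2f}" for p in r.peaks_pos),
            "peaks_neg": ",".join(f"{p:.2f}" for p in r.peaks_neg),
            "informative": int(r.informative),
        }
        for r in reports
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_pfm(pfm: np.ndarray, path: str | Path) -> None:
    """PFM TSV (rows A,C,G,T), consumable by standard logo tools."""
    df = pd.DataFrame(pfm, index=list(BASES),
                      columns=[f"pos{j}" for j in range(pfm.shape[1])])
    df.to_csv(path, sep="\t", index_label="base")
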