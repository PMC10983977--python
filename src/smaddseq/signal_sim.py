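"""Synthetic nanopore squiggle simulator with known modification ground truth.

Generates R9.4.1-like current signals for unmodified DNA, for DNA carrying
small-molecule (angelicin-type) thymine adducts at 5'-TAT motifs, and for
chromatin-like molecules in which nucleosome cores protect the DNA from
modification while linkers remain accessible.

The pore model used here is synthetic: a seeded, sequence-correlated 6-mer
level table standing in for a vendor level table. Users with a real level
table can load one with :func:`PoreModel.from_tsv`.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KMER_K = 6
BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")

RAW_CONTAINER_VERSION = 1
EVENTALIGN_COLUMNS = [
    "contig",
    "position",
    "reference_kmer",
    "read_name",
    "event_level_mean",
]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _seq_to_indices(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    if (out < 0).any():
        raise ValueError("sequence contains non-ACGT characters")
    return out


def kmer_indices(seq: str, k: int = KMER_K) -> np.ndarray:
    """Integer index (base-4 encoding) of each k-mer window of ``seq``."""
    b = _seq_to_indices(seq)
    if len(b) < k:
        raise ValueError(f"sequence length {len(b)} shorter than k={k}")
    idx = np.zeros(len(b) - k + 1, dtype=np.int64)
    for j in range(k):
        idx = idx * 4 + b[j : len(b) - k + 1 + j]
    return idx


def index_to_kmer(idx: int, k: int = KMER_K) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[idx % 4])
        idx //= 4
    return "".join(reversed(out))


# ---------------------------------------------------------------------------
# Pore model
# ---------------------------------------------------------------------------


@dataclass
class PoreModel:
    """6-mer -> (level mean pA, level sd pA) table.

    Means are stored as a dense array indexed by the base-4 encoding of the
    k-mer (A=0, C=1, G=2, T=3), which makes signal simulation a single fancy
    -indexing operation.
    """

    k: int
    means: np.ndarray  # (4**k,) pA
    sds: np.ndarray  # (4**k,) pA

    def __post_init__(self) -> None:
        n = 4**self.k
        if len(self.means) != n or len(self.sds) != n:
            raise ValueError(f"pore model must have exactly {n} entries")
        if not (self.sds > 0).all():
            raise ValueError("all level sds must be positive")
        if self.means.min() < 50 or self.means.max() > 130:
            raise ValueError("level means must lie within [50, 130] pA")

    @property
    def levels(self) -> dict[str, tuple[float, float]]:
        """Mapping view ``kmer -> (mean_pA, sd_pA)`` (built on demand)."""
        return {
            index_to_kmer(i, self.k): (float(self.means[i]), float(self.sds[i]))
            for i in range(4**self.k)
        }

    def mean_of(self, kmer: str) -> float:
        return float(self.means[kmer_indices(kmer, self.k)[0]])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("kmer\tlevel_mean\tlevel_stdv\n")
            for i in range(4**self.k):
                fh.write(
                    f"{index_to_kmer(i, self.k)}\t{self.means[i]:.4f}\t{self.sds[i]:.4f}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path, k: int = KMER_K) -> "PoreModel":
        df = pd.read_csv(path, sep="\t")
        means = np.zeros(4**k)
        sds = np.zeros(4**k)
        for kmer, m, s in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2]):
            means[kmer_indices(str(kmer), k)[0]] = m
            sds[kmer_indices(str(kmer), k)[0]] = s
        return cls(k=k, means=means, sds=sds)


def build_pore_model(seed: int, k: int = KMER_K) -> PoreModel:
    """Seeded synthetic level table with sequence-correlated 6-mer means.

    Each position in the pore contributes an additive, base-dependent weight
    (central positions weighted more strongly, as in real pores), plus a
    per-k-mer jitter so that k-mers sharing 5 bases are correlated but never
    forced equal. Means are affinely rescaled into [55, 125] pA.
    """
    rng = np.random.default_rng(seed)
    n = 4**k
    # positional influence profile: central bases dominate the current level
    pos_scale = np.array([0.5, 1.0, 1.6, 1.6, 1.0, 0.5])[:k]
    weights = rng.normal(0.0, 4.0, size=(k, 4)) * pos_scale[:, None]
    digits = np.zeros((n, k), dtype=np.int64)
    idx = np.arange(n)
    for j in range(k - 1, -1, -1):
        digits[:, j] = idx % 4
        idx = idx // 4
    raw = weights[np.arange(k)[None, :], digits].sum(axis=1)
    raw = raw + rng.normal(0.0, 1.5, size=n)  # per-k-mer jitter
    lo, hi = raw.min(), raw.max()
    means = 55.0 + (raw - lo) * (125.0 - 55.0) / (hi - lo)
    sds = rng.uniform(1.2, 2.5, size=n)
    return PoreModel(k=k, means=means, sds=sds)


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Parameters of the squiggle and chromatin-geometry simulation.

    Currents are in pA, lengths in bp. ``samples_per_base`` is the mean dwell
    (raw samples emitted per 6-mer event); ``dwell_dispersion`` controls dwell
    variance (0 = deterministic dwell of round(samples_per_base)).
    ``mod_delta_pA`` is added to the level mean of an event once per modified
    base inside the event's 6-mer window.
    """

    seed: int = 0
    samples_per_base: float = 9.0
    dwell_dispersion: float = 1.0
    noise_sd: float = 3.0
    mod_motif: str = "TAT"
    mod_delta_pA: float = -12.0
    mod_rate_accessible: float = 0.8
    mod_rate_protected: float = 0.05
    nucleosome_len: int = 147
    linker_len_range: tuple[int, int] = (20, 90)
    dyad_jitter_sd: float = 10.0
    ndr_len: int = 140
    read_len_mean: int = 1500
    read_len_sd: int = 150

    def __post_init__(self) -> None:
        if not (0 <= self.mod_rate_protected < self.mod_rate_accessible <= 1):
            raise ValueError(
                "require 0 <= mod_rate_protected < mod_rate_accessible <= 1"
            )
        if self.nucleosome_len <= 0:
            raise ValueError("nucleosome_len must be positive")
        lo, hi = self.linker_len_range
        if hi < lo:
            raise ValueError("linker_len_range is empty")
        if self.samples_per_base <= 0:
            raise ValueError("samples_per_base must be positive")
        if self.dwell_dispersion < 0:
            raise ValueError("dwell_dispersion must be nonnegative")


@dataclass
class SimulatedRead:
    """One simulated molecule: sequence, raw signal, move table, truth.

    ``moves[j]`` is the read-local index of the 6-mer event that emitted raw
    sample ``j`` (nondecreasing, covering 0..len(sequence)-k).
    ``truth_mod_sites`` are read-local positions of adduct-carrying T bases.
    """

    read_id: str
    contig: str
    start: int
    strand: str
    sequence: str
    signal: np.ndarray
    moves: np.ndarray
    truth_mod_sites: frozenset[int] = field(default_factory=frozenset)

    @property
    def n_events(self) -> int:
        return len(self.sequence) - KMER_K + 1

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


def modifiable_positions(sequence: str, motif: str = "TAT") -> np.ndarray:
    """Read-local positions p where ``sequence[p:p+len(motif)] == motif``.

    The modified base is the 5' T of the motif occurrence.
    """
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    m = len(motif)
    if len(arr) < m:
        return np.array([], dtype=np.int64)
    mask = np.ones(len(arr) - m + 1, dtype=bool)
    for j, ch in enumerate(motif.upper()):
        mask &= arr[j : len(arr) - m + 1 + j] == ord(ch)
    return np.flatnonzero(mask).astype(np.int64)


def _draw_dwells(n: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    m = config.samples_per_base
    if config.dwell_dispersion == 0:
        return np.full(n, max(1, int(round(m))), dtype=np.int64)
    # 1 + negative binomial with mean m-1; dispersion scales the variance
    mean = max(m - 1.0, 1e-9)
    var = mean * (1.0 + config.dwell_dispersion)
    p = mean / var
    r = mean * p / (1.0 - p) if p < 1 else None
    if r is None:
        extra = rng.poisson(mean, size=n)
    else:
        extra = rng.negative_binomial(r, p, size=n)
    return 1 + extra.astype(np.int64)


def simulate_read(
    sequence: str,
    mod_sites: Iterable[int],
    config: SimConfig,
    pore: PoreModel,
    rng: np.random.Generator | None = None,
    read_id: str = "read0",
    contig: str = "synthetic",
    start: int = 0,
    strand: str = "+",
) -> SimulatedRead:
    """Emit a noisy squiggle for ``sequence`` with adducts at ``mod_sites``.

    Every 6-mer window emits ~samples_per_base Gaussian draws around its pore
    level; the level is shifted by ``mod_delta_pA`` once for each modified
    base inside the window.
    """
    if len(sequence) < pore.k:
        raise ValueError(
            f"sequence length {len(sequence)} is shorter than k={pore.k}; "
            "cannot emit any signal events"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sites = np.asarray(sorted(set(int(s) for s in mod_sites)), dtype=np.int64)
    valid = modifiable_positions(sequence, config.mod_motif)
    bad = np.setdiff1d(sites, valid)
    if len(bad):
        raise ValueError(
            f"mod_sites {bad.tolist()} do not match motif {config.mod_motif!r}"
        )
    kidx = kmer_indices(sequence, pore.k)
    event_means = pore.means[kidx].copy()
    if len(sites):
        ind = np.zeros(len(sequence), dtype=np.float64)
        ind[sites] = 1.0
        # count of modified bases inside each k-mer window
        cum = np.concatenate([[0.0], np.cumsum(ind)])
        counts = cum[pore.k :] - cum[: len(kidx)]
        event_means += config.mod_delta_pA * counts
    dwells = _draw_dwells(len(kidx), config, rng)
    total = int(dwells.sum())
    signal = np.repeat(event_means, dwells)
    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, size=total)
    moves = np.repeat(np.arange(len(kidx), dtype=np.int64), dwells)
    return SimulatedRead(
        read_id=read_id,
        contig=contig,
        start=start,
        strand=strand,
        sequence=sequence.upper(),
        signal=signal.astype(np.float32),
        moves=moves,
        truth_mod_sites=frozenset(int(s) for s in sites),
    )


def event_level_means(read: SimulatedRead) -> np.ndarray:
    """Observed mean current of each 6-mer event (from the raw samples)."""
    boundaries = np.flatnonzero(np.diff(read.moves)) + 1
    starts = np.concatenate([[0], boundaries])
    sums = np.add.reduceat(read.signal.astype(np.float64), starts)
    counts = np.diff(np.concatenate([starts, [len(read.signal)]]))
    return sums / counts


# ---------------------------------------------------------------------------
# Genome helpers
# ---------------------------------------------------------------------------


def random_genome(
    contig_lengths: Mapping[str, int], seed: int, at_content: float = 0.62
) -> dict[str, str]:
    """Random genome with the given AT fraction (yeast-like default)."""
    rng = np.random.default_rng(seed)
    p = np.array(
        [at_content / 2, (1 - at_content) / 2, (1 - at_content) / 2, at_content / 2]
    )
    out = {}
    for name, length in contig_lengths.items():
        draws = rng.choice(4, size=length, p=p)
        out[name] = "".join(BASES[i] for i in draws)
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-contig FASTA reader (wrapped lines supported)."""
    try:
        from pyfaidx import Fasta

        fa = Fasta(str(path))
        return {name: str(fa[name][:]) for name in fa.keys()}
    except ImportError:  # pragma: no cover - pyfaidx is a declared dependency
        out: dict[str, str] = {}
        name, chunks = None, []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if name is not None:
                        out[name] = "".join(chunks)
                    name, chunks = line[1:].split()[0], []
                elif line:
                    chunks.append(line)
        if name is not None:
            out[name] = "".join(chunks)
        return out


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED (3+ columns, 0-based half-open) with optional name/score/strand."""
    names = ["contig", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : min(6, df.shape[1])]
    df.columns = names[: df.shape[1]]
    if "strand" not in df.columns:
        df["strand"] = "+"
    if "name" not in df.columns:
        df["name"] = [f"region{i}" for i in range(len(df))]
    return df


# ---------------------------------------------------------------------------
# Control datasets
# ---------------------------------------------------------------------------


def _genome_as_dict(genome: Mapping[str, str] | str | Path) -> dict[str, str]:
    if isinstance(genome, (str, Path)):
        return read_fasta(genome)
    return dict(genome)


def _eventalign_for_read(read: SimulatedRead) -> pd.DataFrame:
    """Eventalign-dialect rows (one per 6-mer event) for a simulated read."""
    means = event_level_means(read)
    n = len(means)
    L = len(read.sequence)
    i = np.arange(n)
    if read.strand == "+":
        pos = read.start + i
        kmers = [read.sequence[j : j + KMER_K] for j in i]
    else:
        pos = read.start + L - i - KMER_K
        kmers = [revcomp(read.sequence[j : j + KMER_K]) for j in i]
    return pd.DataFrame(
        {
            "contig": read.contig,
            "position": pos,
            "reference_kmer": kmers,
            "read_name": read.read_id,
            "event_level_mean": means,
        }
    )


def simulate_control_dataset(
    genome: Mapping[str, str] | str | Path,
    n_reads: int,
    modified: bool,
    config: SimConfig,
    pore: PoreModel,
    emit_eventalign: bool = True,
) -> tuple[list[SimulatedRead], pd.DataFrame | None]:
    """Naked-DNA control reads: fully modifiable (positive) or unmodified.

    With ``modified=True`` every motif T is modified independently with
    probability ``mod_rate_accessible``; with ``modified=False`` no site is.
    """
    genome = _genome_as_dict(genome)
    if not genome:
        raise ValueError("genome is empty")
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(config.seed)
    contigs = list(genome)
    lens = np.array([len(genome[c]) for c in contigs], dtype=np.float64)
    probs = lens / lens.sum()
    reads: list[SimulatedRead] = []
    tables: list[pd.DataFrame] = []
    tag = "pos" if modified else "neg"
    for i in range(n_reads):
        ci = rng.choice(len(contigs), p=probs)
        contig = contigs[ci]
        L = int(np.clip(rng.normal(config.read_len_mean, config.read_len_sd),
                        5 * KMER_K, lens[ci]))
        start = int(rng.integers(0, len(genome[contig]) - L + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = genome[contig][start : start + L]
        if strand == "-":
            seq = revcomp(seq)
        sites: np.ndarray = np.array([], dtype=np.int64)
        if modified:
            cand = modifiable_positions(seq, config.mod_motif)
            if len(cand):
                keep = rng.random(len(cand)) < config.mod_rate_accessible
                sites = cand[keep]
        read = simulate_read(
            seq, sites, config, pore, rng=rng,
            read_id=f"{tag}_{i:05d}", contig=contig, start=start, strand=strand,
        )
        reads.append(read)
        if emit_eventalign:
            tables.append(_eventalign_for_read(read))
    eventalign = pd.concat(tables, ignore_index=True) if emit_eventalign else None
    return reads, eventalign


# ---------------------------------------------------------------------------
# Chromatin datasets
# ---------------------------------------------------------------------------


@dataclass
class MoleculeTruth:
    """Ground-truth occupancy for one simulated chromatin molecule."""

    read_id: str
    contig: str
    span: tuple[int, int]  # reference half-open interval of the molecule
    strand: str
    core_intervals: list[tuple[int, int]]  # reference half-open nucleosome cores
    dyad: int  # jittered +1 dyad used for this molecule


def _tile_cores(
    dyad: int, span: tuple[int, int], config: SimConfig, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Nucleosome core intervals tiled from a +1 dyad across ``span``.

    Downstream: cores separated by random linkers. Upstream: a
    nucleosome-depleted region of ``ndr_len`` directly upstream of the +1
    core, then regular cores again.
    """
    half = config.nucleosome_len // 2
    lo, hi = span
    cores = []
    start = dyad - half
    while start < hi:
        end = start + config.nucleosome_len
        if end > lo and start < hi:
            cores.append((max(start, lo), min(end, hi)))
        start = end + int(rng.integers(config.linker_len_range[0],
                                       config.linker_len_range[1] + 1))
    end = dyad - half - config.ndr_len
    while end > lo:
        start = end - config.nucleosome_len
        if end > lo and start < hi:
            cores.append((max(start, lo), min(end, hi)))
        end = start - int(rng.integers(config.linker_len_range[0],
                                       config.linker_len_range[1] + 1))
    return sorted(cores)


def simulate_chromatin_dataset(
    genome: Mapping[str, str] | str | Path,
    dyads: pd.DataFrame | Sequence[tuple],
    n_molecules_per_locus: int,
    config: SimConfig,
    pore: PoreModel,
    molecule_flank: int = 2200,
    emit_signal: bool = True,
) -> tuple[list[SimulatedRead], list[MoleculeTruth]]:
    """Chromatin-like molecules around +1 dyads, with truth occupancy.

    Per molecule the +1 dyad is jittered by N(0, dyad_jitter_sd), nucleosome
    cores of ``nucleosome_len`` are tiled with random linkers (plus an
    upstream NDR), and motif T's are modified at ``mod_rate_accessible`` in
    linkers versus ``mod_rate_protected`` inside cores.

    Dyads falling outside their contig are skipped with a warning.
    Set ``emit_signal=False`` to skip squiggle synthesis when only the truth
    geometry is needed (sequence/moves are still produced).
    """
    genome = _genome_as_dict(genome)
    if isinstance(dyads, pd.DataFrame):
        dyad_rows = [
            (r.contig, int(r.start), getattr(r, "strand", "+"),
             getattr(r, "name_", None) or getattr(r, "name", f"dyad{i}"))
            for i, r in enumerate(dyads.itertuples(index=False))
        ]
    else:
        dyad_rows = [
            (d[0], int(d[1]), d[2] if len(d) > 2 else "+",
             d[3] if len(d) > 3 else f"dyad{i}")
            for i, d in enumerate(dyads)
        ]
    if n_molecules_per_locus <= 0:
        raise ValueError("n_molecules_per_locus must be positive")
    rng = np.random.default_rng(config.seed)
    reads: list[SimulatedRead] = []
    truths: list[MoleculeTruth] = []
    n_skipped = 0
    for contig, dyad, strand, name in dyad_rows:
        if contig not in genome or not (0 <= dyad < len(genome[contig])):
            warnings.warn(f"dyad {name} at {contig}:{dyad} outside contig; skipped")
            n_skipped += 1
            continue
        clen = len(genome[contig])
        for m in range(n_molecules_per_locus):
            d = dyad + int(round(rng.normal(0.0, config.dyad_jitter_sd))) \
                if config.dyad_jitter_sd > 0 else dyad
            lo = max(0, d - molecule_flank)
            hi = min(clen, d + molecule_flank)
            cores = _tile_cores(d, (lo, hi), config, rng)
            seq = genome[contig][lo:hi]
            read_strand = "+" if rng.random() < 0.5 else "-"
            rseq = seq if read_strand == "+" else revcomp(seq)
            cand = modifiable_positions(rseq, config.mod_motif)
            L = hi - lo
            if read_strand == "+":
                ref_pos = lo + cand
            else:
                ref_pos = lo + L - 1 - cand
            protected = np.zeros(len(cand), dtype=bool)
            for cs, ce in cores:
                protected |= (ref_pos >= cs) & (ref_pos < ce)
            rate = np.where(protected, config.mod_rate_protected,
                            config.mod_rate_accessible)
            keep = rng.random(len(cand)) < rate
            sites = cand[keep]
            read_id = f"{name}_mol{m:04d}"
            if emit_signal:
                read = simulate_read(
                    rseq, sites, config, pore, rng=rng, read_id=read_id,
                    contig=contig, start=lo, strand=read_strand,
                )
            else:
                read = SimulatedRead(
                    read_id=read_id, contig=contig, start=lo, strand=read_strand,
                    sequence=rseq, signal=np.array([], dtype=np.float32),
                    moves=np.array([], dtype=np.int64),
                    truth_mod_sites=frozenset(int(s) for s in sites),
                )
            reads.append(read)
            truths.append(
                MoleculeTruth(
                    read_id=read_id, contig=contig, span=(lo, hi),
                    strand=strand, core_intervals=cores, dyad=d,
                )
            )
    if n_skipped:
        logger.warning("skipped %d dyads outside their contig", n_skipped)
    return reads, truths


def truth_accessibility_tracks(
    truths: Sequence[MoleculeTruth],
    config: SimConfig,
    seed: int,
    score_noise_sd: float = 0.1,
):
    """Per-molecule accessibility score tracks derived from truth occupancy.

    Positions in linkers score around ``mod_rate_accessible``, positions in
    cores around ``mod_rate_protected``, plus Gaussian noise clipped to
    [0, 1]. Useful for exercising the downstream chromatin analytics without
    running the classifier.
    """
    from .genome_mapping import ReadModTrack

    rng = np.random.default_rng(seed)
    tracks = []
    for t in truths:
        lo, hi = t.span
        scores = np.full(hi - lo, config.mod_rate_accessible, dtype=np.float64)
        for cs, ce in t.core_intervals:
            scores[cs - lo : ce - lo] = config.mod_rate_protected
        if score_noise_sd > 0:
            scores = scores + rng.normal(0.0, score_noise_sd, size=len(scores))
        scores = np.clip(scores, 0.0, 1.0)
        tracks.append(
            ReadModTrack(
                read_id=t.read_id, contig=t.contig, strand="+", start=lo,
                scores=scores, n_windows=np.ones(len(scores), dtype=np.int64),
            )
        )
    return tracks


def aggregate_truth_accessibility(
    truths: Sequence[MoleculeTruth], span: tuple[int, int]
) -> np.ndarray:
    """Fraction of molecules in which each position of ``span`` is accessible."""
    lo, hi = span
    acc = np.zeros(hi - lo)
    n = np.zeros(hi - lo)
    for t in truths:
        tlo, thi = t.span
        a, b = max(lo, tlo), min(hi, thi)
        if a >= b:
            continue
        n[a - lo : b - lo] += 1
        occ = np.zeros(b - a)
        for cs, ce in t.core_intervals:
            cs2, ce2 = max(cs, a), min(ce, b)
            if cs2 < ce2:
                occ[cs2 - a : ce2 - a] = 1
        acc[a - lo : b - lo] += 1 - occ
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, acc / np.maximum(n, 1), np.nan)


# ---------------------------------------------------------------------------
# Raw-read container and eventalign I/O
# ---------------------------------------------------------------------------


def save_reads(reads: Sequence[SimulatedRead], path: str | Path) -> None:
    """Versioned NPZ container for raw reads (signal, moves, placement)."""
    meta = [
        {
            "read_id": r.read_id,
            "contig": r.contig,
            "start": int(r.start),
            "strand": r.strand,
            "sequence": r.sequence,
            "truth_mod_sites": sorted(r.truth_mod_sites),
        }
        for r in reads
    ]
    arrays = {"__version__": np.array([RAW_CONTAINER_VERSION])}
    for i, r in enumerate(reads):
        arrays[f"signal_{i}"] = r.signal
        arrays[f"moves_{i}"] = r.moves
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez_compressed(path, **arrays)


def load_reads(path: str | Path) -> list[SimulatedRead]:
    with np.load(path) as data:
        version = int(data["__version__"][0])
        if version != RAW_CONTAINER_VERSION:
            raise ValueError(f"unsupported raw-read container version {version}")
        meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
        reads = []
        for i, m in enumerate(meta):
            reads.append(
                SimulatedRead(
                    read_id=m["read_id"], contig=m["contig"], start=m["start"],
                    strand=m["strand"], sequence=m["sequence"],
                    signal=data[f"signal_{i}"], moves=data[f"moves_{i}"],
                    truth_mod_sites=frozenset(m["truth_mod_sites"]),
                )
            )
    return reads


def write_eventalign(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=EVENTALIGN_COLUMNS)


def read_eventalign(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
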