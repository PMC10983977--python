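"""End-to-end pipelines tying the modules together, plus run configuration.

Each ``run_*`` function is a pure function of (inputs, config, seed): rerun
with the same arguments and it writes identical outputs. Every output
directory receives an echo of the fully resolved configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chromatin_analysis as ca
from . import genome_mapping as gm
from . import kmer_density as kd
from . import nemo_model as nn
from . import preprocess as pp
from . import signal_sim as sim
from . import single_molecule as sm

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Nested per-stage configuration with seeded determinism."""

    seed: int = 0
    log_level: str = "INFO"
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    peaks: kd.PeakConfig = field(default_factory=kd.PeakConfig)
    preproc: pp.PreprocConfig = field(default_factory=pp.PreprocConfig)
    model: nn.ModelConfig = field(default_factory=nn.ModelConfig)
    train: nn.TrainConfig = field(default_factory=nn.TrainConfig)
    metagene: ca.MetageneConfig = field(default_factory=ca.MetageneConfig)
    qc: ca.QCConfig = field(default_factory=ca.QCConfig)
    select: ca.SelectConfig = field(default_factory=ca.SelectConfig)
    cluster: sm.ClusterConfig = field(default_factory=sm.ClusterConfig)

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj):
                return {k: conv(v) for k, v in obj.__dict__.items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return conv(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        sections = {
            "sim": sim.SimConfig, "peaks": kd.PeakConfig,
            "preproc": pp.PreprocConfig, "model": nn.ModelConfig,
            "train": nn.TrainConfig, "metagene": ca.MetageneConfig,
            "qc": ca.QCConfig, "select": ca.SelectConfig,
            "cluster": sm.ClusterConfig,
        }
        for key, value in (d or {}).items():
            if key in sections:
                fields = {f.name for f in dataclasses.fields(sections[key])}
                clean = {}
                for k, v in value.items():
                    if k not in fields:
                        raise ValueError(f"unknown config key {key}.{k}")
                    clean[k] = tuple(v) if isinstance(v, list) else v
                kwargs[key] = sections[key](**clean)
            elif key in ("seed", "log_level"):
                kwargs[key] = value
            else:
                raise ValueError(f"unknown config section {key!r}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def echo(self, outdir: str | Path) -> None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        (Path(outdir) / "config.resolved.yaml").write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True)
        )


def _derive_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------


def run_simulate(
    config: RunConfig,
    outdir: str | Path,
    fasta: str | Path | None = None,
    dyads_bed: str | Path | None = None,
    n_reads: int = 200,
    n_molecules_per_locus: int = 20,
    genome_len: int = 50_000,
) -> dict:
    """Simulate control datasets (and chromatin data when dyads are given)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.echo(outdir)
    seeds = _derive_seeds(config.seed, 6)
    pore = sim.build_pore_model(seeds[0])
    pore.to_tsv(outdir / "pore_model.tsv")
    if fasta is not None:
        genome = sim.read_fasta(fasta)
    else:
        genome = sim.random_genome({"chrSim": genome_len}, seeds[1])
        sim.write_fasta(genome, outdir / "genome.fa")
    manifest = {"seed": config.seed, "files": {}}
    for tag, modified, s in (("pos", True, seeds[2]), ("neg", False, seeds[3])):
        cfg = dataclasses.replace(config.sim, seed=s)
        reads, ev = sim.simulate_control_dataset(genome, n_reads, modified, cfg, pore)
        sim.save_reads(reads, outdir / f"{tag}_reads.npz")
        sim.write_eventalign(ev, outdir / f"{tag}_eventalign.tsv")
        manifest["files"][tag] = {
            "reads": f"{tag}_reads.npz",
            "eventalign": f"{tag}_eventalign.tsv",
            "n_reads": len(reads),
            "n_truth_sites": int(sum(len(r.truth_mod_sites) for r in reads)),
        }
    if dyads_bed is not None:
        dyads = sim.read_bed(dyads_bed)
        cfg = dataclasses.replace(config.sim, seed=seeds[4])
        reads, truths = sim.simulate_chromatin_dataset(
            genome, dyads, n_molecules_per_locus, cfg, pore
        )
        sim.save_reads(reads, outdir / "chromatin_reads.npz")
        truth_rows = [
            {"read_id": t.read_id, "contig": t.contig, "span": list(t.span),
             "dyad": t.dyad, "cores": [list(c) for c in t.core_intervals]}
            for t in truths
        ]
        (outdir / "chromatin_truth.json").write_text(json.dumps(truth_rows))
        manifest["files"]["chromatin"] = {
            "reads": "chromatin_reads.npz", "truth": "chromatin_truth.json",
            "n_molecules": len(reads),
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def run_kmers(
    pos_eventalign: str | Path,
    neg_eventalign: str | Path,
    config: RunConfig,
    outdir: str | Path,
) -> list[kd.KmerPeakReport]:
    """Informative-k-mer discovery: peak reports TSV + PFM TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.echo(outdir)
    pos, _ = kd.aggregate_kmer_means(pos_eventalign)
    neg, _ = kd.aggregate_kmer_means(neg_eventalign)
    reports = kd.identify_informative_kmers(pos, neg, config.peaks)
    kd.write_peak_reports(reports, outdir / "kmer_peaks.tsv")
    informative = [r.kmer for r in reports if r.informative]
    if informative:
        kd.write_pfm(kd.position_frequency_matrix(informative),
                     outdir / "informative_pfm.tsv")
    return reports


def run_train(
    pos_reads_path: str | Path,
    neg_reads_path: str | Path,
    config: RunConfig,
    outdir: str | Path,
) -> tuple[nn.ResNet1D, nn.TrainLog, nn.EvalReport]:
    """Control-data training: checkpoint + per-epoch log + test evaluation."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.echo(outdir)
    pos_reads = sim.load_reads(pos_reads_path)
    neg_reads = sim.load_reads(neg_reads_path)
    splits = pp.make_splits(pos_reads, neg_reads, config.preproc)
    stats = pp.compute_norm_stats(
        [r.signal for r, _ in splits.train], config.preproc
    )
    train_sampler = pp.WindowSampler(splits.train, stats, config.preproc)
    val_sampler = pp.WindowSampler(splits.val, stats, config.preproc)
    model = nn.build_model(config.model)
    best, log = nn.train(model, train_sampler, val_sampler, config.train)
    X_test, y_test, _ = pp.WindowSampler(
        splits.test, stats, config.preproc
    ).enumerate_windows(config.preproc.infer_step)
    report = nn.evaluate(best, X_test, y_test)
    nn.save_checkpoint(best, outdir / "nemo_checkpoint.npz", norm_stats=stats,
                       extra={"seed": config.seed})
    log.to_tsv(outdir / "train_log.tsv")
    report.to_json(outdir / "eval_report.json")
    return best, log, report


def run_predict(
    reads_path: str | Path,
    checkpoint: str | Path,
    config: RunConfig,
    outdir: str | Path,
) -> list[gm.ReadModTrack]:
    """Per-read modification tracks + genome-wide bedGraph."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.echo(outdir)
    model, stats, _ = nn.load_checkpoint(checkpoint)
    if stats is None:
        raise ValueError("checkpoint has no frozen normalization statistics")
    reads = sim.load_reads(reads_path)
    tracks = gm.predict_read_tracks(model, reads, stats, config.preproc)
    gm.write_read_tracks(tracks, outdir / "read_tracks.tsv")
    gm.write_bedgraph(gm.pileup(tracks), outdir / "pileup.bedgraph")
    return tracks


def run_metagene(
    tracks_path: str | Path,
    dyads_bed: str | Path,
    config: RunConfig,
    outdir: str | Path,
) -> dict:
    """Metagene TSV + periodicity QC JSON + structured-gene selection TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.echo(outdir)
    tracks = gm.read_read_tracks(tracks_path)
    by_contig = gm.group_tracks_by_contig(tracks)
    dyads_df = sim.read_bed(dyads_bed)
    dyads = [
        (r.contig, int(r.start), r.strand, str(r.name))
        for r in dyads_df.itertuples(index=False)
    ]
    flank = config.metagene.flank
    profiles = [ca.gene_profile(by_contig, d[:3], flank) for d in dyads]
    mg = ca.metagene(profiles, flank)
    mg.to_tsv(outdir / "metagene.tsv")
    r, passed = ca.qc_periodicity(mg, config.qc)
    ca.write_qc_report(r, passed, outdir / "qc.json", config.qc)
    stats = ca.compute_gene_stats(by_contig, dyads, mg, config.select, flank)
    selection = ca.select_structured_genes(stats, config.select)
    ca.write_gene_selection(selection, outdir / "gene_selection.tsv")
    return {"qc_r": r, "qc_pass": passed,
            "n_selected": int(selection["selected"].sum())}


def run_cluster(
    tracks_path: str | Path,
    region: str,
    config: RunConfig,
    outdir: str | Path,
) -> sm.ClusterResult:
    """Single-molecule clustering at a locus: assignments, profiles, figure."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.echo(outdir)
    tracks = gm.read_read_tracks(tracks_path)
    matrix = sm.build_read_matrix(tracks, region, config.cluster)
    matrix = sm.filter_high_mod(matrix, config.cluster)
    matrix = sm.impute_missing(matrix, config.cluster)
    result = sm.cluster_reads(matrix, config.cluster)
    sm.write_cluster_assignments(matrix, result, outdir / "clusters.tsv")
    sm.write_cluster_profiles(matrix, result, outdir / "cluster_profiles.bedgraph")
    sm.render_locus(matrix, result, outdir / "locus.png", title=region)
    return result


# ---------------------------------------------------------------------------
# Classifier benchmark (control-read AUC at desk scale)
# ---------------------------------------------------------------------------


def run_auc_benchmark(
    seed: int,
    n_reads_per_class: int = 1000,
    read_len: int = 1500,
    genome_len: int = 200_000,
    at_content: float = 0.62,
    samples_per_base: float = 400 / 75,
    epochs: int = 10,
    batches_per_epoch: int = 100,
    batch_size: int = 128,
    val_batches_per_epoch: int = 40,
) -> dict:
    """Held-out AUC of the classifier on simulated control reads.

    Simulates positive (adduct-carrying, site rate 0.8) and negative
    (unmodified) ~1.5 kb reads on a yeast-like AT-rich synthetic genome,
    preprocesses (clip [-50, 150], frozen z-normalization, 400-sample
    windows), splits 60/20/20 by read, trains a compact ResNet1D on CPU,
    and evaluates window-level AUC on the test reads.

    ``samples_per_base`` defaults to 400/75, i.e. a 400-sample window spans
    ~75 bp (half a nucleosome footprint) — the regime the window length was
    chosen for.
    """
    seeds = _derive_seeds(seed, 7)
    pore = sim.build_pore_model(seeds[0])
    genome = sim.random_genome({"chrSim": genome_len}, seeds[1], at_content)
    sim_cfg = sim.SimConfig(
        samples_per_base=samples_per_base,
        noise_sd=3.0, mod_delta_pA=-12.0, mod_rate_accessible=0.8,
        read_len_mean=read_len, read_len_sd=read_len // 10,
    )
    pos_reads, _ = sim.simulate_control_dataset(
        genome, n_reads_per_class, True,
        dataclasses.replace(sim_cfg, seed=seeds[2]), pore, emit_eventalign=False,
    )
    neg_reads, _ = sim.simulate_control_dataset(
        genome, n_reads_per_class, False,
        dataclasses.replace(sim_cfg, seed=seeds[3]), pore, emit_eventalign=False,
    )
    preproc = pp.PreprocConfig(seed=seeds[4])
    splits = pp.make_splits(pos_reads, neg_reads, preproc)
    stats = pp.compute_norm_stats([r.signal for r, _ in splits.train], preproc)
    train_sampler = pp.WindowSampler(splits.train, stats, preproc)
    val_sampler = pp.WindowSampler(splits.val, stats, preproc)
    model = nn.build_model(nn.ModelConfig(
        n_blocks=3, base_filters=24, kernel=7, downsample_every=1,
        stem_stride=2, head="avg", seed=seeds[5],
    ))
    train_cfg = nn.TrainConfig(
        epochs=epochs, batch_size=batch_size,
        batches_per_epoch=batches_per_epoch,
        val_batches_per_epoch=val_batches_per_epoch,
        learning_rate=2e-3, seed=seeds[6],
    )
    best, log = nn.train(model, train_sampler, val_sampler, train_cfg)
    X_test, y_test, _ = pp.WindowSampler(
        splits.test, stats, preproc
    ).enumerate_windows(preproc.infer_step)
    report = nn.evaluate(best, X_test, y_test)
    return {
        "auc": report.auc,
        "report": report,
        "log": log,
        "model": best,
        "norm_stats": stats,
        "n_test_windows": int(len(y_test)),
        "n_test_reads": len(splits.test),
    }
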