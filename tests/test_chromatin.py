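"""Metagene aggregation, periodicity QC, and structured-gene selection."""

import numpy as np
import pandas as pd
import pytest

from smaddseq import (
    MetageneProfile,
    QCConfig,
    SelectConfig,
    SimConfig,
    build_pore_model,
    estimate_nrl,
    gene_profile,
    intersect_replicates,
    metagene,
    periodic_template,
    qc_config_for_sim,
    qc_periodicity,
    select_structured_genes,
    simulate_chromatin_dataset,
    truth_accessibility_tracks,
)
from smaddseq.chromatin_analysis import compute_gene_stats
from smaddseq.genome_mapping import ReadModTrack, group_tracks_by_contig
from smaddseq.signal_sim import random_genome

FLANK = 700


def _track(contig, start, scores, read_id="r", strand="+"):
    scores = np.asarray(scores, dtype=np.float64)
    return ReadModTrack(read_id=read_id, contig=contig, strand=strand,
                        start=start, scores=scores,
                        n_windows=np.ones(len(scores), dtype=np.int64))


class TestGeneProfile:
    def test_constant_read_gives_constant_profile(self):
        t = _track("c", 900, np.full(300, 0.3))
        prof = gene_profile([t], ("c", 1000, "+"), flank=200)
        covered = prof[~np.isnan(prof)]
        np.testing.assert_allclose(covered, 0.3)

    def test_minus_strand_profile_is_reverse_of_plus(self, rng):
        scores = rng.random(401)
        t = _track("c", 800, scores)
        plus = gene_profile([t], ("c", 1000, "+"), flank=200)
        minus = gene_profile([t], ("c", 1000, "-"), flank=200)
        np.testing.assert_allclose(minus, plus[::-1])

    def test_no_reads_yields_empty_profile(self):
        prof = gene_profile([], ("c", 1000, "+"), flank=100)
        assert np.isnan(prof).all()

    def test_simulated_locus_alternates_with_truth_cores(self, pore):
        cfg = SimConfig(seed=8, mod_rate_accessible=0.9,
                        mod_rate_protected=0.05, dyad_jitter_sd=0.0,
                        linker_len_range=(40, 40))
        genome = random_genome({"c": 10_000}, seed=1)
        _, truths = simulate_chromatin_dataset(
            genome, [("c", 5000, "+", "g")], 30, cfg, pore,
            molecule_flank=FLANK + 100, emit_signal=False,
        )
        tracks = truth_accessibility_tracks(truths, cfg, seed=2,
                                            score_noise_sd=0.05)
        prof = gene_profile(tracks, ("c", 5000, "+"), flank=FLANK)
        # +1 core is [dyad-73, dyad+74): profile low inside, high in linker
        core = prof[FLANK - 60 : FLANK + 60].mean()
        linker = prof[FLANK + 80 : FLANK + 110].mean()
        assert core < 0.3 and linker > 0.6


class TestMetagene:
    def test_identical_profiles_pass_through(self):
        p = np.linspace(0, 1, 2 * 100 + 1)
        mg = metagene([p, p.copy()], flank=100)
        np.testing.assert_allclose(mg.mean, p)
        assert (mg.n_genes == 2).all()

    def test_antisymmetric_profiles_cancel(self):
        base = np.full(201, 0.5)
        delta = np.sin(np.linspace(0, 6 * np.pi, 201)) * 0.3
        mg = metagene([base + delta, base - delta], flank=100)
        np.testing.assert_allclose(mg.mean, 0.5, atol=1e-12)

    def test_zscore_is_affine_invariant_for_pearson(self, rng):
        p = rng.random(201)
        mg = metagene([p], flank=100)
        template = periodic_template(mg.offsets, QCConfig())
        r_raw = np.corrcoef(template, mg.mean)[0, 1]
        r_z = np.corrcoef(template, mg.zscored)[0, 1]
        assert np.isclose(r_raw, r_z)

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            metagene([], flank=100)


class TestQC:
    def _profile_from(self, values, flank=1000):
        return MetageneProfile(offsets=np.arange(-flank, flank + 1),
                               mean=np.asarray(values, dtype=np.float64),
                               n_genes=np.ones(2 * flank + 1, dtype=np.int64))

    def test_template_itself_passes_with_r_one(self):
        cfg = QCConfig()
        offsets = np.arange(-1000, 1001)
        r, passed = qc_periodicity(
            self._profile_from(periodic_template(offsets, cfg)), cfg
        )
        assert np.isclose(r, 1.0) and passed

    def test_negated_template_fails_with_r_minus_one(self):
        cfg = QCConfig()
        offsets = np.arange(-1000, 1001)
        r, passed = qc_periodicity(
            self._profile_from(-periodic_template(offsets, cfg)), cfg
        )
        assert np.isclose(r, -1.0) and not passed

    def test_flat_profile_fails_with_undefined_r(self):
        r, passed = qc_periodicity(self._profile_from(np.full(2001, 0.7)))
        assert np.isnan(r) and not passed

    def test_chromatin_passes_naked_dna_fails(self, pore):
        genome = random_genome({"c": 20_000}, seed=3)
        cfg = SimConfig(seed=4, dyad_jitter_sd=5.0)  # default linker geometry
        _, truths = simulate_chromatin_dataset(
            genome, [("c", 10_000, "+", "g")], 60, cfg, pore,
            molecule_flank=2100, emit_signal=False,
        )
        tracks = truth_accessibility_tracks(truths, cfg, seed=5)
        mg = metagene(
            [gene_profile(tracks, ("c", 10_000, "+"), 2000)], flank=2000
        )
        qc = qc_config_for_sim(cfg)  # template period = expected NRL
        r, passed = qc_periodicity(mg, qc)
        assert passed, f"chromatin simulation failed QC with r={r:.3f}"
        # naked DNA: uniformly accessible, no periodicity
        naked = [
            _track("c", 8_000, 0.8 + 0.05 * np.random.default_rng(6).standard_normal(4000), "n")
        ]
        mg2 = metagene([gene_profile(naked, ("c", 10_000, "+"), 2000)],
                       flank=2000)
        r2, passed2 = qc_periodicity(mg2, qc)
        assert not passed2


class TestNRLRecovery:
    @pytest.mark.parametrize("linker,nrl", [(10, 157), (30, 177), (50, 197)])
    def test_metagene_minima_spacing_recovers_nrl(self, pore, linker, nrl):
        genome = random_genome({"c": 24_000}, seed=7)
        cfg = SimConfig(seed=nrl, dyad_jitter_sd=5.0,
                        linker_len_range=(linker, linker))
        dyads = [("c", p, "+", f"g{p}") for p in range(6_000, 19_000, 2_600)]
        _, truths = simulate_chromatin_dataset(
            genome, dyads, 15, cfg, pore, molecule_flank=1300,
            emit_signal=False,
        )
        tracks = truth_accessibility_tracks(truths, cfg, seed=9)
        by_contig = group_tracks_by_contig(tracks)
        profiles = [gene_profile(by_contig, d[:3], 1200) for d in dyads]
        mg = metagene(profiles, flank=1200)
        got = estimate_nrl(mg, max_offset=1000)
        assert abs(got - nrl) <= 10


class TestSelection:
    def _stats(self):
        # hand-set metrics for 8 toy genes
        return pd.DataFrame({
            "gene": [f"g{i}" for i in range(8)],
            "r": [0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2],
            "coverage": [50, 40, 45, 10, 60, 20, 30, 15],
            "variance": [0.01, 0.02, 0.05, 0.01, 0.3, 0.2, 0.1, 0.4],
        })

    def test_matches_brute_force_triple_threshold(self):
        stats = self._stats()
        out = select_structured_genes(stats)
        # oracle: explicit quartile thresholds in each favorable direction
        r_thr = np.percentile(stats["r"], 75)
        cov_thr = np.percentile(stats["coverage"], 75)
        var_thr = np.percentile(stats["variance"], 25)
        expected = {
            row.gene
            for row in stats.itertuples()
            if row.r >= r_thr and row.coverage >= cov_thr
            and row.variance <= var_thr
        }
        assert set(out[out.selected].gene) == expected

    def test_sorted_by_r_then_coverage_then_variance(self):
        out = select_structured_genes(self._stats())
        rs = out["r"].tolist()
        assert rs == sorted(rs, reverse=True)

    def test_identical_metrics_all_selected_by_boundary_rule(self):
        stats = pd.DataFrame({
            "gene": list("abcd"), "r": [0.5] * 4,
            "coverage": [10] * 4, "variance": [0.1] * 4,
        })
        out = select_structured_genes(stats)
        assert out.selected.all()  # inclusive >=/<= keeps ties

    def test_selection_is_monotone_in_r(self):
        stats = self._stats()
        out1 = select_structured_genes(stats)
        selected_before = set(out1[out1.selected].gene)
        # improving a selected gene's r must not deselect it
        stats2 = stats.copy()
        stats2.loc[stats2.gene == "g0", "r"] = 0.99
        out2 = select_structured_genes(stats2)
        assert selected_before <= set(out2[out2.selected].gene) | {"g0"}
        assert "g0" in set(out2[out2.selected].gene) or "g0" not in selected_before

    def test_fewer_than_four_genes_is_error(self):
        with pytest.raises(ValueError, match="4 genes"):
            select_structured_genes(self._stats().head(3))


class TestComputeGeneStats:
    def test_planted_structured_gene_outranks_noise_gene(self, pore):
        genome = random_genome({"c": 20_000}, seed=13)
        cfg = SimConfig(seed=14, dyad_jitter_sd=0.0, linker_len_range=(30, 30))
        dyads = [("c", 5_000, "+", "good"), ("c", 15_000, "+", "noisy")]
        _, truths = simulate_chromatin_dataset(
            genome, dyads[:1], 20, cfg, pore, molecule_flank=2100,
            emit_signal=False,
        )
        tracks = truth_accessibility_tracks(truths, cfg, seed=15)
        rng = np.random.default_rng(16)
        for i in range(20):  # unstructured locus: white-noise tracks
            tracks.append(_track("c", 12_900, rng.random(4200), f"noise{i}"))
        by_contig = group_tracks_by_contig(tracks)
        profiles = [gene_profile(by_contig, d[:3], 2000) for d in dyads]
        mg = metagene(profiles, flank=2000)
        stats = compute_gene_stats(by_contig, dyads, mg)
        good = stats[stats.gene == "good"].iloc[0]
        noisy = stats[stats.gene == "noisy"].iloc[0]
        assert good.r > noisy.r
        assert good.variance < noisy.variance
        assert good.coverage == 20


class TestIntersect:
    def test_basic_intersection_keeps_a_order(self):
        assert intersect_replicates(["g1", "g2"], ["g2", "g3"]) == ["g2"]
        assert intersect_replicates(["g2", "g1"], ["g1", "g2"]) == ["g2", "g1"]
        assert intersect_replicates(["g1"], ["g2"]) == []

    def test_replicated_structured_genes_recovered(self, pore):
        """Loci planted with well-positioned arrays in both replicate
        simulations are recovered by the replicate intersection, while
        unstructured (noise) loci are not."""
        genome = random_genome({"c": 40_000}, seed=21)
        good = [("c", p, "+", f"good{p}") for p in range(4_000, 9_000, 4_000)]
        noisy = [("c", p, "+", f"noise{p}") for p in
                 range(14_000, 35_000, 4_000)]
        dyads = good + noisy
        selections = []
        for rep_seed in (31, 32):
            cfg = SimConfig(seed=rep_seed, dyad_jitter_sd=5.0,
                            linker_len_range=(30, 30))
            _, truths = simulate_chromatin_dataset(
                genome, good, 12, cfg, pore, molecule_flank=2100,
                emit_signal=False,
            )
            tracks = truth_accessibility_tracks(truths, cfg, seed=rep_seed + 50)
            rng = np.random.default_rng(rep_seed + 100)
            for contig, pos, _, name in noisy:
                for i in range(12):
                    tracks.append(_track("c", pos - 2100, rng.random(4200),
                                         f"{name}_r{i}"))
            by_contig = group_tracks_by_contig(tracks)
            profiles = [gene_profile(by_contig, d[:3], 2000) for d in dyads]
            mg = metagene(profiles, flank=2000)
            stats = compute_gene_stats(by_contig, dyads, mg)
            out = select_structured_genes(stats)
            selections.append(out[out.selected].gene.tolist())
        shared = intersect_replicates(*selections)
        assert shared
        assert all(g.startswith("good") for g in shared)
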