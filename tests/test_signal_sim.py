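"""Squiggle simulator: determinism, signal-level identities, geometry."""

import numpy as np
import pytest

from smaddseq import (
    SimConfig,
    build_pore_model,
    modifiable_positions,
    random_genome,
    simulate_chromatin_dataset,
    simulate_control_dataset,
    simulate_read,
)
from smaddseq.signal_sim import (
    aggregate_truth_accessibility,
    event_level_means,
    kmer_indices,
    revcomp,
    load_reads,
    save_reads,
)


class TestPoreModel:
    def test_deterministic_and_complete(self):
        a = build_pore_model(seed=1)
        b = build_pore_model(seed=1)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.sds, b.sds)
        assert len(a.means) == 4**6
        assert (a.sds > 0).all()
        assert a.means.min() >= 50 and a.means.max() <= 130

    def test_neighbouring_kmers_not_forced_equal(self, pore):
        # k-mers sharing 5 bases must differ (sequence-correlated, not tied)
        i1 = kmer_indices("AACGTA")[0]
        i2 = kmer_indices("AACGTC")[0]
        assert pore.means[i1] != pore.means[i2]

    def test_tsv_round_trip(self, pore, tmp_path):
        path = tmp_path / "pore.tsv"
        pore.to_tsv(path)
        loaded = type(pore).from_tsv(path)
        np.testing.assert_allclose(loaded.means, pore.means, atol=1e-3)


class TestSimulateRead:
    def test_zero_noise_event_means_equal_pore_means(self, pore, quiet_config):
        seq = "ACGTACGTTGCAATCGGCTA" * 5
        read = simulate_read(seq, [], quiet_config, pore)
        means = event_level_means(read)
        np.testing.assert_allclose(means, pore.means[kmer_indices(seq)],
                                   atol=1e-5)

    def test_modified_site_shifts_covering_kmers_by_delta(self, pore,
                                                          quiet_config):
        seq = "GGCCGGTATCGGCCGGCCAA"
        site = modifiable_positions(seq)[0]
        read = simulate_read(seq, [site], quiet_config, pore)
        means = event_level_means(read)
        expected = pore.means[kmer_indices(seq)].copy()
        for i in range(len(expected)):  # oracle: table lookup + delta
            if i <= site <= i + 5:
                expected[i] += quiet_config.mod_delta_pA
        np.testing.assert_allclose(means, expected, atol=1e-5)

    def test_tatata_modified_center_gives_two_level_groups(self, pore,
                                                           quiet_config):
        # modifiable k-mer context: modified vs unmodified events separate
        # into two current levels, the simulated analogue of the bimodal
        # density of modified TATATA
        seq = "GGGGG" + "TATATA" * 4 + "GGGGG"
        sites = modifiable_positions(seq)
        read_mod = simulate_read(seq, [sites[2]], quiet_config, pore)
        read_un = simulate_read(seq, [], quiet_config, pore)
        shifted = set(np.round(event_level_means(read_mod), 4)) - set(
            np.round(event_level_means(read_un), 4)
        )
        assert shifted  # a distinct shifted level group exists
        deltas = [
            m - u
            for m, u in zip(event_level_means(read_mod),
                            event_level_means(read_un))
            if abs(m - u) > 1e-9
        ]
        assert np.allclose(deltas, quiet_config.mod_delta_pA)

    def test_double_modification_shifts_twice(self, pore, quiet_config):
        seq = "GGGGGTATATGGGGGG"
        sites = modifiable_positions(seq)  # TAT at 5 and ATA..: check
        assert len(sites) >= 1
        seq = "GGGGTATATATGGGG"
        sites = modifiable_positions(seq)
        assert len(sites) >= 2
        read = simulate_read(seq, sites[:2], quiet_config, pore)
        means = event_level_means(read)
        base = pore.means[kmer_indices(seq)]
        max_shift = (means - base).min()
        assert np.isclose(max_shift, 2 * quiet_config.mod_delta_pA)

    def test_rejects_short_sequence_and_bad_sites(self, pore, quiet_config):
        with pytest.raises(ValueError, match="shorter than k"):
            simulate_read("ACGTA", [], quiet_config, pore)
        with pytest.raises(ValueError, match="motif"):
            simulate_read("ACGTACGTACGT", [0], quiet_config, pore)

    def test_moves_conservation_and_coverage(self, pore):
        cfg = SimConfig(seed=9, samples_per_base=6.0, dwell_dispersion=1.5)
        seq = random_genome({"c": 300}, seed=5)["c"]
        read = simulate_read(seq, [], cfg, pore)
        assert len(read.moves) == len(read.signal)
        assert (np.diff(read.moves) >= 0).all()
        assert set(np.unique(read.moves)) == set(range(len(seq) - 6 + 1))

    def test_determinism(self, pore):
        cfg = SimConfig(seed=21, noise_sd=2.0)
        seq = random_genome({"c": 200}, seed=8)["c"]
        a = simulate_read(seq, [], cfg, pore)
        b = simulate_read(seq, [], cfg, pore)
        assert np.array_equal(a.signal, b.signal)
        assert np.array_equal(a.moves, b.moves)


class TestControlDataset:
    def test_unmodified_has_no_truth_sites(self, pore):
        genome = random_genome({"chr1": 20_000}, seed=2)
        cfg = SimConfig(seed=4, read_len_mean=500, read_len_sd=50)
        reads, ev = simulate_control_dataset(genome, 20, False, cfg, pore)
        assert all(len(r.truth_mod_sites) == 0 for r in reads)
        assert set(ev.columns) >= {"contig", "position", "reference_kmer",
                                   "read_name", "event_level_mean"}

    def test_rate_one_modifies_every_motif_site(self, pore):
        genome = random_genome({"chr1": 20_000}, seed=2)
        cfg = SimConfig(seed=4, mod_rate_accessible=1.0, read_len_mean=500,
                        read_len_sd=50)
        reads, _ = simulate_control_dataset(genome, 10, True, cfg, pore,
                                            emit_eventalign=False)
        for r in reads:
            assert r.truth_mod_sites == set(
                modifiable_positions(r.sequence).tolist()
            )

    def test_modified_fraction_matches_binomial_rate(self, pore):
        genome = random_genome({"chr1": 50_000}, seed=2)
        cfg = SimConfig(seed=7, mod_rate_accessible=0.7, read_len_mean=1000,
                        read_len_sd=100)
        reads, _ = simulate_control_dataset(genome, 200, True, cfg, pore,
                                            emit_eventalign=False)
        n_sites = sum(len(modifiable_positions(r.sequence)) for r in reads)
        n_mod = sum(len(r.truth_mod_sites) for r in reads)
        se = np.sqrt(0.7 * 0.3 / n_sites)
        assert abs(n_mod / n_sites - 0.7) < 3 * se

    def test_eventalign_reverse_strand_kmers_match_reference(self, pore):
        genome = random_genome({"chr1": 5_000}, seed=3)
        cfg = SimConfig(seed=12, read_len_mean=300, read_len_sd=10)
        reads, ev = simulate_control_dataset(genome, 30, False, cfg, pore)
        rev = [r for r in reads if r.strand == "-"]
        assert rev, "expect some reverse-strand reads"
        sub = ev[ev.read_name == rev[0].read_id]
        for _, row in sub.head(20).iterrows():
            ref_kmer = genome["chr1"][row.position : row.position + 6]
            assert row.reference_kmer == ref_kmer

    def test_rejects_bad_inputs(self, pore):
        with pytest.raises(ValueError):
            simulate_control_dataset({}, 5, False, SimConfig(), pore)
        with pytest.raises(ValueError):
            simulate_control_dataset({"c": "A" * 1000}, 0, False, SimConfig(),
                                     pore)


class TestChromatinDataset:
    def test_protected_zero_accessible_one_confines_mods_to_linkers(self, pore):
        genome = random_genome({"chr1": 12_000}, seed=6)
        cfg = SimConfig(seed=5, mod_rate_protected=0.0,
                        mod_rate_accessible=1.0, dyad_jitter_sd=0.0)
        reads, truths = simulate_chromatin_dataset(
            genome, [("chr1", 6000, "+", "g1")], 5, cfg, pore,
            molecule_flank=2000, emit_signal=False,
        )
        for read, truth in zip(reads, truths):
            L = len(read.sequence)
            for p in read.truth_mod_sites:
                ref = (read.start + p if read.strand == "+"
                       else read.start + L - 1 - p)
                for cs, ce in truth.core_intervals:
                    assert not (cs <= ref < ce)

    def test_zero_jitter_fixed_linker_gives_identical_cores(self, pore):
        genome = random_genome({"chr1": 12_000}, seed=6)
        cfg = SimConfig(seed=5, dyad_jitter_sd=0.0, linker_len_range=(30, 30))
        _, truths = simulate_chromatin_dataset(
            genome, [("chr1", 6000, "+", "g1")], 4, cfg, pore,
            emit_signal=False,
        )
        cores = {tuple(t.core_intervals) for t in truths}
        assert len(cores) == 1

    def test_dyad_outside_contig_skipped_with_warning(self, pore):
        genome = random_genome({"chr1": 3_000}, seed=6)
        with pytest.warns(UserWarning, match="outside contig"):
            reads, _ = simulate_chromatin_dataset(
                genome, [("chr1", 99_999, "+", "bad"),
                         ("chr1", 1500, "+", "ok")],
                2, SimConfig(seed=1), pore, molecule_flank=1000,
                emit_signal=False,
            )
        assert len(reads) == 2  # only the valid dyad

    def test_truth_autocorrelation_recovers_repeat_length(self, pore):
        """Aggregate truth accessibility of a fixed-NRL array has its first
        autocorrelation peak at the nucleosome repeat length."""
        nrl = 147 + 30
        genome = random_genome({"chr1": 30_000}, seed=10)
        cfg = SimConfig(seed=2, dyad_jitter_sd=0.0, linker_len_range=(30, 30))
        _, truths = simulate_chromatin_dataset(
            genome, [("chr1", 15_000, "+", "g1")], 200, cfg, pore,
            molecule_flank=2000, emit_signal=False,
        )
        acc = aggregate_truth_accessibility(truths, (13_200, 16_800))
        acc = acc[~np.isnan(acc)] - np.nanmean(acc)
        ac = np.correlate(acc, acc, mode="full")[len(acc) - 1 :]
        # oracle: direct autocorrelation peak in the plausible NRL range
        lag = 100 + int(np.argmax(ac[100:260]))
        assert abs(lag - nrl) <= 5


def test_raw_read_container_round_trip(pore, tmp_path, quiet_config):
    seq = "ACGTTATAGCATCGATCGTACGTAGCTTAAGG"
    reads = [simulate_read(seq, [modifiable_positions(seq)[0]], quiet_config,
                           pore, read_id="r1", contig="c", start=7,
                           strand="-")]
    path = tmp_path / "reads.npz"
    save_reads(reads, path)
    loaded = load_reads(path)
    assert loaded[0].read_id == "r1"
    assert loaded[0].strand == "-"
    assert loaded[0].truth_mod_sites == reads[0].truth_mod_sites
    assert np.array_equal(loaded[0].signal, reads[0].signal)
    assert np.array_equal(loaded[0].moves, reads[0].moves)


def test_revcomp():
    assert revcomp("ACGT") == "ACGT"
    assert revcomp("TTAC") == "GTAA"
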