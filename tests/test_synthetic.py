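import numpy as np
import pandas as pd
import pytest

from dmrscan.annotate import cpg_count
from dmrscan.synthetic import (
    CpGSegment,
    GenomeSpec,
    PlantedDMR,
    SimConfig,
    expand_clusters,
    generate_reads,
    simulate_counts,
    simulate_genes,
    simulate_genome,
    truth_from_frame,
    truth_to_frame,
    window_cpg_density,
)
from dmrscan.windows import count_matrix_from_reads, make_windows


class TestSimulateGenome:
    def test_reproducible_given_seed(self):
        g1 = simulate_genome({"chr1": 1000}, seed=1)
        g2 = simulate_genome({"chr1": 1000}, seed=1)
        g3 = simulate_genome({"chr1": 1000}, seed=2)
        assert g1.sequence["chr1"] == g2.sequence["chr1"]
        assert g1.sequence["chr1"] != g3.sequence["chr1"]
        assert len(g1.sequence["chr1"]) == 1000

    def test_forced_cpg_segment_density(self):
        seg = CpGSegment("chr1", 0, 100, 50.0)  # saturated: CG repeated
        g = simulate_genome({"chr1": 1000}, gc_profile=[seg], seed=1)
        assert cpg_count(g.sequence["chr1"][0:100]) == 50

    def test_background_density_near_target(self):
        g = simulate_genome({"chr1": 100_000}, seed=4, background_cpg_per_100=2.0)
        density = cpg_count(g.sequence["chr1"]) / 1000  # per 100 bp
        assert 1.6 <= density <= 2.4

    def test_empty_or_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            simulate_genome({}, seed=1)
        with pytest.raises(ValueError):
            simulate_genome({"chr1": 0}, seed=1)
        with pytest.raises(KeyError):
            simulate_genome({"chr1": 1000}, gc_profile=[CpGSegment("chrX", 0, 10, 5)], seed=1)

    def test_window_density_matches_substring_counts(self):
        seg = CpGSegment("chr1", 200, 400, 10.0)
        g = simulate_genome({"chr1": 1000}, gc_profile=[seg], seed=6)
        grid = make_windows({"chr1": 1000}, 100)
        dens = window_cpg_density(g, grid)
        for w, (s, e) in enumerate(zip(*grid.coords("chr1"))):
            assert dens[w] == pytest.approx(cpg_count(g.sequence["chr1"][s:e]))

    def test_fasta_roundtrip(self, tmp_path):
        g = simulate_genome({"chr1": 250, "chr2": 90}, seed=3)
        path = tmp_path / "genome.fa"
        g.write_fasta(path)
        back = GenomeSpec.from_fasta(path)
        assert back.sequence == dict(g.sequence)
        assert back.lengths == g.lengths


class TestSimulateCounts:
    def _setup(self, length=1_000_000):
        genome = GenomeSpec(((("chr1"), length),))
        grid = make_windows({"chr1": length}, 100)
        return genome, grid

    def test_bit_identical_given_seed(self):
        genome, grid = self._setup(10_000)
        cfg = SimConfig(seed=5)
        cm1, _ = simulate_counts(genome, grid, cfg)
        cm2, _ = simulate_counts(genome, grid, cfg)
        np.testing.assert_array_equal(cm1.counts, cm2.counts)
        cm3, _ = simulate_counts(genome, grid, SimConfig(seed=6))
        assert (cm1.counts != cm3.counts).any()

    def test_poisson_limit_variance_equals_mean(self):
        # phi=0 with equal size factors: across >= 1e4 windows the average
        # within-window sample variance matches the average mean (Poisson)
        genome, grid = self._setup(1_000_000)
        cfg = SimConfig(
            mean_depth_per_window=50, dispersion=0.0, seed=8, size_factor_range=(1.0, 1.0)
        )
        cm, _ = simulate_counts(genome, grid, cfg)
        mean = cm.counts.mean(axis=1)
        var = cm.counts.var(axis=1, ddof=1)
        assert var.mean() / mean.mean() == pytest.approx(1.0, abs=0.05)

    def test_nb_moments(self):
        genome, grid = self._setup(1_000_000)
        cfg = SimConfig(
            mean_depth_per_window=50, dispersion=0.5, seed=9, size_factor_range=(1.0, 1.0)
        )
        cm, _ = simulate_counts(genome, grid, cfg)
        mu = cm.counts.mean()
        expected_var = mu + 0.5 * mu**2
        assert cm.counts.var(ddof=1) / expected_var == pytest.approx(1.0, abs=0.1)

    def test_planted_fold_change_hits_group_b_only(self):
        genome, grid = self._setup(200_000)
        planted = tuple(PlantedDMR("chr1", s, 2, 3.0, "up") for s in range(0, 200_000, 4_000))
        cfg = SimConfig(
            mean_depth_per_window=100, dispersion=0.1, seed=10,
            size_factor_range=(1.0, 1.0), planted=planted,
        )
        cm, truth = simulate_counts(genome, grid, cfg)
        mask = np.zeros(grid.n_windows, dtype=bool)
        for d in truth:
            first = d.core_start // 100
            mask[first : first + d.n_core_windows] = True
        a = cm.counts[:, :3].mean()
        b_planted = cm.counts[mask, 3:].mean()
        b_null = cm.counts[~mask, 3:].mean()
        assert b_planted / a == pytest.approx(8.0, rel=0.1)
        assert b_null / a == pytest.approx(1.0, rel=0.05)

    def test_zero_fold_change_groups_exchangeable(self):
        genome, grid = self._setup(500_000)
        planted = (PlantedDMR("chr1", 1000, 2, 0.0, "up"),)
        cfg = SimConfig(seed=12, planted=planted, size_factor_range=(1.0, 1.0))
        cm, _ = simulate_counts(genome, grid, cfg)
        a, b = cm.counts[:, :3].mean(), cm.counts[:, 3:].mean()
        assert b / a == pytest.approx(1.0, abs=0.02)

    def test_invalid_planting_rejected(self):
        genome, grid = self._setup(10_000)
        bad_outside = SimConfig(planted=(PlantedDMR("chr1", 9_900, 2, 3.0),))
        with pytest.raises(ValueError, match="outside"):
            simulate_counts(genome, grid, bad_outside)
        bad_offgrid = SimConfig(planted=(PlantedDMR("chr1", 150, 1, 3.0),))
        with pytest.raises(ValueError, match="aligned"):
            simulate_counts(genome, grid, bad_offgrid)
        with pytest.raises(ValueError):
            SimConfig(dispersion=-0.1)

    def test_cpg_effect_scales_baseline(self):
        seg = CpGSegment("chr1", 0, 5_000, 8.0)
        genome = simulate_genome({"chr1": 100_000}, gc_profile=[seg], seed=2,
                                 background_cpg_per_100=0.0)
        grid = make_windows({"chr1": 100_000}, 100)
        cfg = SimConfig(mean_depth_per_window=50, dispersion=0.1, cpg_effect=1.2,
                        seed=3, size_factor_range=(1.0, 1.0))
        cm, _ = simulate_counts(genome, grid, cfg)
        dense = cm.counts[:50].mean()
        desert = cm.counts[50:].mean()
        assert dense / desert == pytest.approx(1.2**8, rel=0.1)


class TestClustersAndTruth:
    def test_expand_clusters_spacing_and_bounds(self):
        dmrs = expand_clusters([("chr1", 1_000_000, 5, 2_000_000)], window_size=100)
        assert len(dmrs) == 5
        assert all(d.core_start % 100 == 0 for d in dmrs)
        assert dmrs[0].core_start == 1_000_000
        assert max(d.core_end(100) for d in dmrs) <= 3_000_000
        with pytest.raises(ValueError, match="3-10"):
            expand_clusters([("chr1", 0, 2, 1_000_000)], 100)

    def test_truth_roundtrip_through_tsv(self, tmp_path):
        truth = [
            PlantedDMR("chr1", 1000, 3, 2.5, "up"),
            PlantedDMR("chr2", 0, 1, 1.0, "down"),
        ]
        path = tmp_path / "truth.tsv"
        truth_to_frame(truth).to_csv(path, sep="\t", index=False)
        back = truth_from_frame(pd.read_csv(path, sep="\t"))
        assert back == truth


class TestSimulateGenes:
    def test_single_gene_fits_in_bounds(self):
        genome = GenomeSpec((("chr1", 1000),))
        genes = simulate_genes(genome, 1, seed=1, length_range=(200, 500))
        assert len(genes) == 1
        assert 0 <= genes[0].start < genes[0].end <= 1000

    def test_zero_genes(self):
        assert simulate_genes(GenomeSpec((("chr1", 1000),)), 0) == []

    def test_reproducible_and_non_overlapping(self):
        genome = GenomeSpec((("chr1", 100_000), ("chr2", 50_000)))
        g1 = simulate_genes(genome, 40, seed=7)
        g2 = simulate_genes(genome, 40, seed=7)
        assert g1 == g2
        assert len(g1) == 40
        by_chrom: dict[str, list] = {}
        for g in g1:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for intervals in by_chrom.values():
            intervals.sort()
            assert all(a[1] <= b[0] for a, b in zip(intervals, intervals[1:]))

    def test_impossible_request_rejected(self):
        genome = GenomeSpec((("chr1", 1000),))
        with pytest.raises(ValueError):
            simulate_genes(genome, 100, seed=1, length_range=(200, 500))


class TestReadsMode:
    def test_counting_emitted_reads_recovers_matrix(self):
        genome = GenomeSpec((("chr1", 5_000),))
        grid = make_windows({"chr1": 5_000}, 100)
        cfg = SimConfig(mean_depth_per_window=5, seed=13)
        cm, _ = simulate_counts(genome, grid, cfg)
        reads = generate_reads(cm, read_len=50, seed=14)
        rebuilt = count_matrix_from_reads(
            reads, grid, {s.pool_id: s.group for s in cm.samples}, extension_bp=0
        )
        np.testing.assert_array_equal(rebuilt.counts, cm.counts)
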