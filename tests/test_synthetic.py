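"""Generators: genome CpG landscape, NB count emission, behavioral cohorts."""

import numpy as np
import pytest

from medipdmr.synthetic import (
    CountSimulationSpec,
    PhenotypeSimulationSpec,
    PlantedDMR,
    SyntheticGenomeSpec,
    generate_genome,
    simulate_phenotypes,
    simulate_reads,
    simulate_window_counts,
)
from medipdmr.windows import count_reads_in_windows, make_windows


class TestGenome:
    def test_zero_rate_genome_has_no_cpgs(self):
        spec = SyntheticGenomeSpec(chromosome_lengths=[("c", 10_000)],
                                   base_cpg_rate=0, cluster_fraction=0, seed=5)
        g = generate_genome(spec)
        assert "CG" not in g.sequences["c"]
        assert g.cpg_index["c"].size == 0

    def test_realized_density_matches_planted_rate(self):
        spec = SyntheticGenomeSpec(chromosome_lengths=[("c", 100_000)],
                                   base_cpg_rate=3, cluster_fraction=0, seed=7)
        g = generate_genome(spec)
        per_100bp = g.cpg_index["c"].size / 1000
        assert 2.5 <= per_100bp <= 3.5

    def test_cluster_windows_are_denser(self):
        spec = SyntheticGenomeSpec(chromosome_lengths=[("c", 200_000)],
                                   base_cpg_rate=2, cluster_rate=12,
                                   cluster_fraction=0.2, seed=8)
        g = generate_genome(spec)
        overall = g.cpg_index["c"].size / 2000
        assert overall > 2.5  # mixture mean 2 + 0.2*10 = 4

    def test_determinism_byte_identical(self, tmp_path):
        spec = SyntheticGenomeSpec(chromosome_lengths=[("c", 50_000)], seed=3)
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        generate_genome(spec).write_fasta(p1)
        generate_genome(spec).write_fasta(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_cpg_index_consistent_with_sequence(self):
        spec = SyntheticGenomeSpec(chromosome_lengths=[("c", 30_000)],
                                   repeat_arm=("c", 20_000, 30_000), seed=2)
        g = generate_genome(spec)
        seq = g.sequences["c"]
        assert all(seq[i:i + 2] == "CG" for i in g.cpg_index["c"][:200])
        # the repeat arm is high-GC
        arm = seq[20_000:30_000]
        gc = (arm.count("G") + arm.count("C")) / len(arm)
        assert gc > 0.6

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticGenomeSpec(chromosome_lengths=[("c", 0)])
        with pytest.raises(ValueError):
            SyntheticGenomeSpec(chromosome_lengths=[("c", 100)],
                                repeat_arm=("other", 0, 50))


class TestCounts:
    sizes = {"c": 1_000_000}  # 10^4 windows

    def test_poisson_limit_variance_equals_mean(self):
        sim = CountSimulationSpec(mean_depth=100, dispersion=0.0, seed=11)
        matrix, truth = simulate_window_counts(self.sizes, [], sim)
        ratio = matrix.counts[:, 0].var() / matrix.counts[:, 0].mean()
        assert 0.95 <= ratio <= 1.05
        assert len(truth) == 0

    def test_planted_fold_change_realized(self):
        planted = [PlantedDMR("c", 100_000, 200_000, fold_change=4.0)]
        sim = CountSimulationSpec(mean_depth=100, dispersion=0.05, seed=12)
        matrix, truth = simulate_window_counts(self.sizes, planted, sim)
        inside = (matrix.windows["start"] >= 100_000) & (matrix.windows["stop"] <= 200_000)
        control = matrix.counts[np.asarray(inside)][:, :3].mean()
        exposed = matrix.counts[np.asarray(inside)][:, 3:].mean()
        assert exposed / control == pytest.approx(4.0, rel=0.1)
        assert len(truth) == 1000  # every planted window listed exactly once
        assert not truth.duplicated(["chrom", "start"]).any()

    def test_hypo_direction_divides_mean(self):
        planted = [PlantedDMR("c", 0, 10_000, fold_change=4.0, direction="hypo")]
        sim = CountSimulationSpec(mean_depth=200, dispersion=0.0, seed=13)
        matrix, _ = simulate_window_counts(self.sizes, planted, sim)
        exposed = matrix.counts[:100, 3:].mean()
        assert exposed == pytest.approx(50, rel=0.1)

    def test_pool_count_shape(self):
        sim = CountSimulationSpec(n_pools_per_group=3, seed=1)
        matrix, _ = simulate_window_counts({"c": 10_000}, [], sim)
        assert matrix.counts.shape == (100, 6)
        assert matrix.pools_in_group("control") == [0, 1, 2]

    def test_off_chromosome_planting_rejected(self):
        sim = CountSimulationSpec(seed=1)
        with pytest.raises(ValueError):
            simulate_window_counts({"c": 1000}, [PlantedDMR("nope", 0, 100)], sim)
        with pytest.raises(ValueError):
            simulate_window_counts({"c": 1000}, [PlantedDMR("c", 900, 1100)], sim)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    def test_variance_grows_as_mu_plus_phi_mu_squared(self, phi):
        sim = CountSimulationSpec(mean_depth=100, dispersion=phi, seed=int(phi * 10))
        matrix, _ = simulate_window_counts(self.sizes, [], sim)
        col = matrix.counts[:, 0].astype(float)
        mu, var = col.mean(), col.var()
        assert var == pytest.approx(mu + phi * mu ** 2, rel=0.08)

    def test_determinism(self):
        sim = CountSimulationSpec(seed=9)
        m1, _ = simulate_window_counts({"c": 50_000}, [], sim)
        m2, _ = simulate_window_counts({"c": 50_000}, [], sim)
        np.testing.assert_array_equal(m1.counts, m2.counts)


class TestReadEmission:
    def test_midpoint_counting_recovers_matrix(self):
        sim = CountSimulationSpec(mean_depth=20, dispersion=0.1, seed=21)
        matrix, _ = simulate_window_counts({"c": 100_000}, [], sim)
        reads = simulate_reads(matrix, seed=22)
        windows = make_windows({"c": 100_000})
        recounted = count_reads_in_windows(reads, windows)
        np.testing.assert_array_equal(recounted.counts, matrix.counts)


class TestPhenotypes:
    def test_null_cohort_tail_rates_near_five_percent(self):
        spec = PhenotypeSimulationSpec(n_per_lineage=2000, lineage_shifts={"x": (0, 0)},
                                       seed=31)
        df = simulate_phenotypes(spec)
        from medipdmr.phenotypes import classify_abnormal

        calls, _ = classify_abnormal(df)
        shifted = calls[calls["lineage"] == "x"]
        assert shifted["visual_abnormal"].mean() == pytest.approx(0.05, abs=0.02)
        assert shifted["hyperactive"].mean() == pytest.approx(0.05, abs=0.02)

    def test_large_shift_fully_separates(self):
        spec = PhenotypeSimulationSpec(n_per_lineage=100, control_mean=20, control_sd=5,
                                       lineage_shifts={"hi": (50.0, 0.0)}, seed=32)
        df = simulate_phenotypes(spec)
        from medipdmr.phenotypes import classify_abnormal

        calls, _ = classify_abnormal(df)
        assert calls[calls["lineage"] == "hi"]["hyperactive"].all()

    def test_determinism_and_columns(self):
        spec = PhenotypeSimulationSpec(seed=33, lineage_shifts={"a": (1, -1)})
        d1, d2 = simulate_phenotypes(spec), simulate_phenotypes(spec)
        assert d1.equals(d2)
        assert {"fish_id", "lineage", "sex", "visual_startle", "locomotion",
                "fraction_time_moving"} <= set(d1.columns)
        assert d1["fraction_time_moving"].between(0, 1).all()
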