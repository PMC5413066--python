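"""Normalization, dispersion estimation and the conditional exact test."""

import numpy as np
import pandas as pd
import pytest

from conftest import binomial_exact_p

from medipdmr.difftest import (
    estimate_common_dispersion,
    nb_exact_test,
    normalize_library_sizes,
)
from medipdmr.difftest import test_all_windows as run_window_tests
from medipdmr.synthetic import CountSimulationSpec, simulate_window_counts
from medipdmr.windows import WindowCountMatrix, make_windows


def _matrix(counts, groups=("control", "control", "exposed", "exposed")):
    counts = np.asarray(counts)
    reps: dict[str, int] = {}
    labels = []
    for g in groups[: counts.shape[1]]:
        reps[g] = reps.get(g, 0) + 1
        labels.append((g, reps[g]))
    return WindowCountMatrix(windows=make_windows({"c": 100 * counts.shape[0]}),
                             counts=counts, pool_labels=labels)


class TestNormalization:
    def test_equal_libraries_give_unit_factors(self):
        m = _matrix([[10, 10, 10, 10]] * 5)
        np.testing.assert_allclose(normalize_library_sizes(m), 1.0)

    def test_geometric_mean_scaling_closed_form(self):
        m = _matrix(np.array([[1, 2]]) * 500, groups=("control", "exposed"))
        m.library_sizes = np.array([1e6, 2e6])
        np.testing.assert_allclose(normalize_library_sizes(m),
                                   [np.sqrt(2), 1 / np.sqrt(2)])

    def test_single_pool_per_group_finite(self):
        m = _matrix([[5, 9]], groups=("control", "exposed"))
        f = normalize_library_sizes(m)
        assert np.isfinite(f).all() and (f > 0).all()

    def test_all_zero_pool_rejected(self):
        m = _matrix([[0, 10, 10, 10]] * 3)
        with pytest.raises(ValueError, match="zero"):
            normalize_library_sizes(m)

    def test_tmm_matches_total_count_on_clean_data(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson([100, 200, 100, 200], size=(2000, 4))
        m = _matrix(counts)
        np.testing.assert_allclose(normalize_library_sizes(m, "tmm"),
                                   normalize_library_sizes(m), rtol=0.02)


class TestDispersion:
    def _sim(self, phi, seed):
        sim = CountSimulationSpec(mean_depth=100, dispersion=phi, seed=seed)
        matrix, _ = simulate_window_counts({"c": 1_000_000}, [], sim)
        return matrix

    def test_poisson_counts_give_near_zero_phi(self):
        est = estimate_common_dispersion(self._sim(0.0, 41))
        assert est.phi <= 0.02

    def test_recovers_planted_dispersion(self):
        est = estimate_common_dispersion(self._sim(0.2, 42))
        assert 0.1 <= est.phi <= 0.3

    def test_constant_counts_give_zero(self):
        m = _matrix([[50, 50, 50, 50]] * 20)
        assert estimate_common_dispersion(m).phi == 0.0

    def test_no_replicates_requires_fixed_phi(self):
        m = _matrix([[5, 9]], groups=("control", "exposed"))
        with pytest.raises(ValueError, match="fixed_phi"):
            estimate_common_dispersion(m)
        est = estimate_common_dispersion(m, fixed_phi=0.1)
        assert est.phi == 0.1 and est.method == "fixed"


class TestExactTest:
    def test_balanced_split_gives_p_one(self):
        for phi in (0.0, 0.1):
            assert nb_exact_test([10, 10], [10, 10], phi=phi) == 1.0

    def test_extreme_split_matches_binomial_tail(self):
        # sums (0, 20): both tails have the same pmf, so p = 2 * (1/2)^20
        p = nb_exact_test([0], [20], phi=0.0)
        assert p == pytest.approx(2 * 0.5 ** 20, rel=1e-12)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.integers(0, 50, 3)
            b = rng.integers(0, 50, 3)
            phi = rng.choice([0.0, 0.05, 0.3])
            assert nb_exact_test(a, b, phi=phi) == pytest.approx(
                nb_exact_test(b, a, phi=phi), rel=1e-9)

    def test_zero_total_gives_p_one(self):
        assert nb_exact_test([0, 0], [0, 0], phi=0.2) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test([-1], [3])

    def test_matches_rational_enumeration_to_1e12(self):
        # every (a, b) split of every total <= 50, equal effective libraries
        for n in range(1, 51):
            for a in range(n + 1):
                expected = binomial_exact_p(a, n)
                got = nb_exact_test([a], [n - a], phi=0.0)
                assert got == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_split_extremity(self):
        n = 60
        ps = [nb_exact_test([a], [n - a], phi=0.05) for a in range(0, 31)]
        assert all(ps[i] <= ps[i + 1] + 1e-15 for i in range(len(ps) - 1))

    def test_doubled_tail_rule_at_least_min_likelihood_for_symmetric_law(self):
        p_ml = nb_exact_test([3], [17], phi=0.0)
        p_dt = nb_exact_test([3], [17], phi=0.0, two_sided_rule="doubled-tail")
        assert p_ml == pytest.approx(p_dt, rel=1e-12)  # symmetric pmf: rules agree


class TestTestAllWindows:
    def test_all_zero_matrix_gives_unit_pvalues(self):
        m = _matrix(np.zeros((10, 4), dtype=int))
        m.library_sizes = np.ones(4)  # bypass the all-zero-library guard
        res = run_window_tests(m, phi=0.1, factors=np.ones(4))
        assert (res["p"] == 1.0).all()
        assert (res["direction"] == "none").all()

    def test_planted_window_attains_genomewide_minimum(self):
        from medipdmr.synthetic import PlantedDMR

        sim = CountSimulationSpec(mean_depth=100, dispersion=0.05, seed=51)
        planted = [PlantedDMR("c", 5000, 5100, fold_change=4.0)]
        matrix, _ = simulate_window_counts({"c": 100_000}, planted, sim)
        res = run_window_tests(matrix, phi=0.05)
        assert res["p"].idxmin() == 50
        assert res.loc[50, "direction"] == "hyper"

    def test_vectorized_path_agrees_with_scalar_calls(self):
        rng = np.random.default_rng(52)
        counts = rng.poisson(80, size=(200, 6))
        m = _matrix(counts, groups=("control",) * 3 + ("exposed",) * 3)
        for phi in (0.0, 0.07):
            res = run_window_tests(m, phi=phi, factors=np.ones(6))
            for i in rng.choice(200, 25, replace=False):
                scalar = nb_exact_test(counts[i, :3], counts[i, 3:], phi=phi)
                assert res["p"].iloc[i] == pytest.approx(scalar, rel=1e-9)

    @pytest.mark.parametrize("alpha", [0.01, 0.05])
    def test_type_i_error_controlled_under_null(self, null_run, alpha):
        p = null_run["results"]["p"].to_numpy()
        se = np.sqrt(alpha * (1 - alpha) / p.size)
        assert (p < alpha).mean() <= alpha + 2 * se

    def test_power_monotone_in_fold_change(self):
        from medipdmr.synthetic import PlantedDMR

        rates = []
        for fc in (1.5, 2.0, 4.0):
            # sparse planting (1% of windows) so normalization stays clean
            planted = [PlantedDMR("c", s, s + 100, fold_change=fc)
                       for s in range(0, 500_000, 10_000)]
            sim = CountSimulationSpec(mean_depth=100, dispersion=0.05, seed=53)
            matrix, truth = simulate_window_counts({"c": 500_000}, planted, sim)
            res = run_window_tests(matrix, phi=0.05)
            hit = res.loc[res["start"].isin(truth["start"]), "p"] < 1e-7
            rates.append(hit.mean())
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > 0.9
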