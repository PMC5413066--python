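"""Outlier filtering, abnormality classification and joint-phenotype test."""

import numpy as np
import pandas as pd
import pytest

from medipdmr.phenotypes import (
    classify_abnormal,
    filter_outliers,
    joint_independence_test,
    percent_change,
)
from medipdmr.synthetic import PhenotypeSimulationSpec, simulate_phenotypes


def _records(fracs, lineage="control"):
    n = len(fracs)
    return pd.DataFrame({
        "fish_id": [f"f{i}" for i in range(n)],
        "lineage": lineage,
        "sex": "M",
        "visual_startle": 20.0,
        "locomotion": 20.0,
        "fraction_time_moving": fracs,
    })


class TestOutlierFilter:
    def test_below_quarter_excluded_at_boundary(self):
        kept, excluded = filter_outliers(_records([0.24, 0.25, 0.6]))
        assert list(excluded["fish_id"]) == ["f0"]  # 0.24 out
        assert list(kept["fish_id"]) == ["f1", "f2"]  # 0.25 kept (strict <)

    def test_no_exclusions_when_all_moving(self):
        kept, excluded = filter_outliers(_records([0.5, 0.6, 0.7, 0.8]))
        assert len(excluded) == 0 and len(kept) == 4

    def test_four_sd_flag_is_reported_not_excluded(self):
        fracs = [0.6] * 50 + [0.30]  # 0.30 is far below in SD units but >= 0.25
        kept, excluded = filter_outliers(_records(fracs))
        assert len(excluded) == 0
        assert kept["low_fraction_flag"].sum() == 1

    def test_cap_warning_when_lineage_loses_many(self):
        with pytest.warns(UserWarning, match="audit cap"):
            filter_outliers(_records([0.1, 0.1, 0.1, 0.6]))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            filter_outliers(_records([1.2]))


class TestClassification:
    def test_control_distributed_cohort_flags_about_five_percent(self):
        spec = PhenotypeSimulationSpec(n_per_lineage=1000,
                                       lineage_shifts={"twin": (0.0, 0.0)}, seed=71)
        calls, bounds = classify_abnormal(simulate_phenotypes(spec))
        twin = calls[calls["lineage"] == "twin"]
        assert twin["visual_abnormal"].mean() == pytest.approx(0.05, abs=0.015)
        assert twin["hyperactive"].mean() == pytest.approx(0.05, abs=0.015)
        assert bounds.visual_p5 < bounds.locomotion_p95

    def test_value_exactly_at_bound_is_normal(self):
        control = _records([0.6] * 20)
        control["visual_startle"] = np.arange(20, dtype=float)
        control["locomotion"] = np.arange(20, dtype=float)
        calls, bounds = classify_abnormal(control)
        probe = control.iloc[[0]].copy()
        probe["lineage"] = "probe"
        probe["visual_startle"] = bounds.visual_p5
        probe["locomotion"] = bounds.locomotion_p95
        merged, _ = classify_abnormal(pd.concat([control, probe], ignore_index=True))
        row = merged[merged["lineage"] == "probe"].iloc[0]
        assert not row["visual_abnormal"] and not row["hyperactive"]

    def test_separated_cohort_fully_flagged(self):
        control = _records([0.6] * 20)
        control["locomotion"] = np.linspace(10, 30, 20)
        shifted = control.copy()
        shifted["lineage"] = "hi"
        shifted["locomotion"] = 100.0
        calls, _ = classify_abnormal(pd.concat([control, shifted], ignore_index=True))
        assert calls[calls["lineage"] == "hi"]["hyperactive"].all()

    def test_classification_ignores_other_exposure_lineages(self):
        control = _records([0.6] * 20)
        control["locomotion"] = np.linspace(10, 30, 20)
        probe = control.iloc[[0]].copy()
        probe["lineage"] = "probe"
        probe["locomotion"] = 25.0
        distractor = control.copy()
        distractor["lineage"] = "huge"
        distractor["locomotion"] = 1000.0
        with_d, _ = classify_abnormal(pd.concat([control, probe, distractor],
                                                ignore_index=True))
        without_d, _ = classify_abnormal(pd.concat([control, probe], ignore_index=True))
        call_with = with_d[with_d["lineage"] == "probe"]["hyperactive"].iloc[0]
        call_without = without_d[without_d["lineage"] == "probe"]["hyperactive"].iloc[0]
        assert call_with == call_without

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError):
            classify_abnormal(_records([0.6] * 3))


class TestJointIndependence:
    def _calls(self, n, p_vis, p_hyp, observed_both, lineage="10nM"):
        vis = np.zeros(n, dtype=bool)
        hyp = np.zeros(n, dtype=bool)
        n_vis, n_hyp = int(n * p_vis), int(n * p_hyp)
        both = observed_both
        vis[:n_vis] = True
        hyp[:both] = True
        hyp[n_vis:n_vis + (n_hyp - both)] = True
        return pd.DataFrame({"lineage": lineage, "visual_abnormal": vis,
                             "hyperactive": hyp})

    def test_observed_equals_expected_gives_zero_statistic(self):
        calls = self._calls(100, 0.5, 0.5, observed_both=25)
        res = joint_independence_test(calls).iloc[0]
        assert res["expected_both"] == 25
        assert res["chi_square"] == 0
        assert res["p"] == 1.0

    def test_p_decreases_with_deviation(self):
        ps = [joint_independence_test(self._calls(100, 0.5, 0.5, b)).iloc[0]["p"]
              for b in (25, 30, 35, 40)]
        assert all(ps[i] > ps[i + 1] for i in range(3))

    def test_degenerate_lineages_skipped(self):
        none_abnormal = pd.DataFrame({"lineage": "control",
                                      "visual_abnormal": [False] * 10,
                                      "hyperactive": [True] * 5 + [False] * 5})
        res = joint_independence_test(none_abnormal).iloc[0]
        assert np.isnan(res["chi_square"])
        assert "skipped" in res["note"]

    def test_full_penetrance_expectation(self):
        calls = pd.DataFrame({"lineage": "100nM",
                              "visual_abnormal": [True] * 8,
                              "hyperactive": [True] * 8})
        res = joint_independence_test(calls).iloc[0]
        assert res["expected_both"] == 8 and res["observed_both"] == 8


class TestPercentChange:
    @pytest.mark.parametrize(
        "treatment, control, expected",
        [
            (584, 382, 53),   # delayed-rectifier current, 10 nM lineage
            (914, 382, 139),  # 30 nM
            (561, 382, 47),   # 100 nM
            (734, 556, 32),   # transient outward current, 10 nM
            (936, 556, 68),   # 30 nM
            (597, 556, 7),    # 100 nM
        ],
    )
    def test_published_amplitude_table_reproduced(self, treatment, control, expected):
        assert percent_change(treatment, control) == expected

    def test_identity_and_sign(self):
        assert percent_change(382, 382) == 0
        assert percent_change(191, 382) == -50

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            percent_change(100, 0)
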