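"""Individual-level neurobehavioral classification and summary statistics.

Each fish carries a visual-startle response count and a spontaneous
locomotion distance.  Abnormality is defined against the control lineage
alone: a fish has a visual deficit when its startle value falls strictly
below the control 5th percentile, and is hyperactive when its locomotion
strictly exceeds the control 95th percentile.  Percentiles use linear
interpolation between order statistics (the common default; the choice
is exposed because different software disagrees at small n).

Fish that moved less than 25% of the recording time are excluded as
outliers before classification; a secondary flag marks values more than
4 SD below the cohort mean fraction-of-time-moving.  A chi-square test
with 1 df compares the observed number of fish abnormal in both assays
with the expectation under independent inheritance of the two phenotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_away

__all__ = ["AbnormalityBounds", "filter_outliers", "classify_abnormal",
           "joint_independence_test", "percent_change"]

MIN_FRACTION_MOVING = 0.25
SD_FLAG_MULTIPLIER = 4.0
MAX_OUTLIERS_PER_LINEAGE = 2


@dataclass
class AbnormalityBounds:
    """Control-lineage percentile cutoffs used for the calls."""

    visual_p5: float
    locomotion_p95: float


def filter_outliers(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into kept and excluded by the minimum-movement rule.

    Exclusion is strict: ``fraction_time_moving < 0.25`` (a fish at
    exactly 0.25 is kept).  Excluded rows carry a ``reason``.  Rows more
    than 4 SD below the cohort mean fraction are additionally flagged
    (``low_fraction_flag``) on the kept frame but not excluded by that
    criterion alone.  A warning is emitted if any lineage loses more than
    the audited maximum of 2 fish.
    """
    frac = records["fraction_time_moving"]
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError("fraction_time_moving must lie in [0, 1]")
    excluded_mask = frac < MIN_FRACTION_MOVING
    mean, sd = float(frac.mean()), float(frac.std(ddof=1))
    flag = frac < (mean - SD_FLAG_MULTIPLIER * sd) if sd > 0 else pd.Series(False, index=records.index)

    kept = records[~excluded_mask].copy()
    kept["low_fraction_flag"] = flag[~excluded_mask]
    excluded = records[excluded_mask].copy()
    excluded["reason"] = f"fraction_time_moving < {MIN_FRACTION_MOVING}"

    per_lineage = excluded.groupby("lineage").size() if len(excluded) else pd.Series(dtype=int)
    over = per_lineage[per_lineage > MAX_OUTLIERS_PER_LINEAGE]
    for lineage, n in over.items():
        warnings.warn(f"lineage {lineage!r}: {n} fish excluded as outliers "
                      f"(audit cap is {MAX_OUTLIERS_PER_LINEAGE})")
    return kept, excluded


def classify_abnormal(
    records: pd.DataFrame,
    control_lineage_label: str = "control",
    percentile_method: str = "linear",
) -> tuple[pd.DataFrame, AbnormalityBounds]:
    """Call each fish normal/abnormal per phenotype against control bounds.

    Adds boolean columns ``visual_abnormal`` (startle strictly below the
    control 5th percentile) and ``hyperactive`` (locomotion strictly
    above the control 95th percentile).  Bounds come from the control
    lineage only; classification of a fish depends on nothing but the
    control values and its own measurements.
    """
    control = records[records["lineage"] == control_lineage_label]
    if len(control) == 0:
        raise ValueError(f"no records in control lineage {control_lineage_label!r}")
    if len(control) < 5:
        raise ValueError("need >=5 control records for stable percentile bounds")
    visual_p5 = float(np.percentile(control["visual_startle"], 5, method=percentile_method))
    loco_p95 = float(np.percentile(control["locomotion"], 95, method=percentile_method))
    out = records.copy()
    out["visual_abnormal"] = out["visual_startle"] < visual_p5
    out["hyperactive"] = out["locomotion"] > loco_p95
    return out, AbnormalityBounds(visual_p5=visual_p5, locomotion_p95=loco_p95)


def joint_independence_test(calls: pd.DataFrame) -> pd.DataFrame:
    """Expected vs observed joint-abnormality counts per lineage.

    Under independent inheritance, the expected number of fish abnormal
    in both assays is ``n * P(visual abnormal) * P(hyperactive)``.  The
    chi-square statistic (1 df) contrasts the observed both/not-both
    split with that expectation.  Lineages whose expectation is zero (or
    n) are reported but not tested — with no fish abnormal in one assay
    the statistic is undefined, which is why the control group is
    excluded in practice.
    """
    rows = []
    for lineage, grp in calls.groupby("lineage", sort=False):
        n = len(grp)
        if n == 0:
            continue
        p_vis = grp["visual_abnormal"].mean()
        p_hyp = grp["hyperactive"].mean()
        expected = n * p_vis * p_hyp
        observed = int((grp["visual_abnormal"] & grp["hyperactive"]).sum())
        row = {"lineage": lineage, "n": n, "p_visual": p_vis, "p_hyperactive": p_hyp,
               "expected_both": expected, "observed_both": observed}
        if expected == 0 or expected == n:
            row["chi_square"] = np.nan
            row["p"] = np.nan
            row["note"] = "skipped: degenerate expectation"
        else:
            # both / not-both 1-df chi-square
            chi = (observed - expected) ** 2 * n / (expected * (n - expected))
            row["chi_square"] = chi
            row["p"] = float(stats.chi2.sf(chi, df=1))
            row["note"] = ""
        rows.append(row)
    return pd.DataFrame(rows)


def percent_change(mean_treatment: float, mean_control: float) -> int:
    """Integer percent change of a treatment mean from the control mean.

    Rounds half away from zero, matching how published amplitude tables
    round (e.g. 584 vs 382 pA -> 53).
    """
    if mean_control <= 0:
        raise ValueError("control mean must be positive")
    return round_half_away(100.0 * (mean_treatment - mean_control) / mean_control)
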