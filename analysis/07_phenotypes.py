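#!/usr/bin/env python
"""Neurobehavioral classification and joint-phenotype independence.

Filters low-movement outliers, calls visual deficit (below the control
5th percentile of startle) and hyperactivity (above the control 95th
percentile of locomotion) per fish, tests whether the two abnormalities
co-occur more often than independence predicts, and reproduces the
percent-change arithmetic on the published retinal amplitude means.
"""

import argparse
from pathlib import Path

import pandas as pd

from medipdmr.phenotypes import classify_abnormal, filter_outliers, joint_independence_test, percent_change


AMPLITUDE_MEANS = {  # published group means (pA), inputs to percent_change
    "Ik": {"control": 382, "10nM": 584, "30nM": 914, "100nM": 561},
    "Ia": {"control": 556, "10nM": 734, "30nM": 936, "100nM": 597},
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--study-dir", type=Path, default=Path("results/study"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    records = pd.read_csv(args.study_dir / "phenotypes.tsv", sep="\t")
    kept, excluded = filter_outliers(records)
    calls, bounds = classify_abnormal(kept)
    calls.to_csv(args.out / "phenotype_calls.tsv", sep="\t", index=False)
    summary = joint_independence_test(calls)
    summary.to_csv(args.out / "phenotype_summary.tsv", sep="\t", index=False)

    print(f"{len(excluded)} fish excluded (<25% of recording time moving); "
          f"bounds: startle p5={bounds.visual_p5:.1f}, locomotion p95={bounds.locomotion_p95:.1f}")
    for r in summary.itertuples():
        note = f" [{r.note}]" if r.note else f" chi2={r.chi_square:.2f}, p={r.p:.2f}"
        print(f"  {r.lineage}: visual {100 * r.p_visual:.0f}%, hyper {100 * r.p_hyperactive:.0f}%, "
              f"both obs/exp {r.observed_both}/{r.expected_both:.1f}{note}")

    print("percent change in peak amplitude from control:")
    for current, means in AMPLITUDE_MEANS.items():
        changes = {lin: percent_change(v, means["control"])
                   for lin, v in means.items() if lin != "control"}
        print(f"  {current}: " + ", ".join(f"{lin} {pc:+d}%" for lin, pc in changes.items()))


if __name__ == "__main__":
    main()
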