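#!/usr/bin/env python
"""Per-window differential testing: normalization, dispersion, exact test.

Reads the simulated count matrices, normalizes library sizes, estimates
the common NB dispersion from the replicate pools, and runs the
conditional exact test on every 100-bp window — for both the planted
comparison and the matched null.  Reports the dispersion estimate and
the null calibration of the p-values.
"""

import argparse
from pathlib import Path

from medipdmr.difftest import estimate_common_dispersion, normalize_library_sizes, test_all_windows
from medipdmr.windows import read_count_matrix


def run(counts_path: Path, out_path: Path) -> None:
    matrix = read_count_matrix(counts_path)
    factors = normalize_library_sizes(matrix)
    est = estimate_common_dispersion(matrix, factors=factors)
    results = test_all_windows(matrix, phi=est.phi, factors=factors)
    results.to_csv(out_path, sep="\t", index=False)
    frac05 = (results["p"] < 0.05).mean()
    print(f"{counts_path.name}: phi_hat={est.phi:.4f} ({est.method}), "
          f"{len(results):,} windows tested, fraction p<0.05 = {frac05:.4f}, "
          f"min p = {results['p'].min():.3e}")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--study-dir", type=Path, default=Path("results/study"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    run(args.study_dir / "window_counts.tsv", args.out / "window_tests.tsv")
    run(args.study_dir / "window_counts_null.tsv", args.out / "window_tests_null.tsv")


if __name__ == "__main__":
    main()
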