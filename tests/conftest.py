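"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive expected results from first
principles (exact rational arithmetic, literal fixpoint iteration) and
share no code with the implementation paths they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from medipdmr.difftest import (
    estimate_common_dispersion,
    normalize_library_sizes,
    test_all_windows,
)
from medipdmr.dmr import DMRCallParams, call_dmrs
from medipdmr.study import default_study, recovery_metrics
from medipdmr.synthetic import simulate_window_counts

STUDY_SEED = 1


# ---------------------------------------------------------------------------
# oracles

def binomial_exact_p(a: int, n: int) -> float:
    """Two-sided minimum-likelihood binomial(n, 1/2) p-value, exact rationals."""
    probs = [Fraction(comb(n, k), 2 ** n) for k in range(n + 1)]
    obs = probs[a]
    return float(sum(p for p in probs if p <= obs))


def grow_to_fixpoint_dmrs(p: np.ndarray, starts: np.ndarray, stops: np.ndarray,
                          params: DMRCallParams) -> list[tuple[int, int]]:
    """Literal seed-growth oracle for one chromosome.

    Every seed interval is repeatedly extended by absorbing any
    extension-candidate window within ``max_gap`` of the current region
    until nothing changes; overlapping/touching closures are then merged.
    Returns sorted (start, stop) spans.
    """
    cand = [i for i in range(len(p)) if p[i] < params.p_extend]
    seeds = [i for i in cand if p[i] < params.p_seed]
    regions = []
    for s in seeds:
        lo, hi = int(starts[s]), int(stops[s])
        absorbed = {s}
        changed = True
        while changed:
            changed = False
            for c in cand:
                if c in absorbed:
                    continue
                if stops[c] <= lo:
                    dist = lo - stops[c]
                elif starts[c] >= hi:
                    dist = starts[c] - hi
                else:
                    dist = 0
                if dist <= params.max_gap:
                    absorbed.add(c)
                    lo = min(lo, int(starts[c]))
                    hi = max(hi, int(stops[c]))
                    changed = True
        regions.append((lo, hi))
    regions.sort()
    merged: list[tuple[int, int]] = []
    for lo, hi in regions:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def random_p_vector(rng: np.random.Generator, n_windows: int) -> pd.DataFrame:
    """A window-result frame with a spiked p-value mixture.

    Mostly sqrt-uniform (few extension candidates), with a small
    log-uniform spike reaching far below the seed threshold so the
    closure rule is exercised across chaining regimes.
    """
    u = rng.random(n_windows)
    p = np.sqrt(u)
    spike = rng.random(n_windows) < 0.02
    p[spike] = 10 ** rng.uniform(-10, 0, spike.sum())
    starts = np.arange(n_windows, dtype=np.int64) * 100
    return pd.DataFrame({"chrom": "chr1", "start": starts, "stop": starts + 100, "p": p})


# ---------------------------------------------------------------------------
# session-scoped synthetic study (shared by recovery and acceptance tests)

@pytest.fixture(scope="session")
def study():
    return default_study(STUDY_SEED)


@pytest.fixture(scope="session")
def study_run(study):
    """Planted-signal run: matrix, truth, window tests, multi-site DMRs."""
    matrix, truth = simulate_window_counts(study.chromosome_sizes(), study.planted,
                                           study.count_spec)
    factors = normalize_library_sizes(matrix)
    phi = estimate_common_dispersion(matrix, factors=factors).phi
    results = test_all_windows(matrix, phi=phi, factors=factors)
    dmrs = call_dmrs(results, DMRCallParams())
    return {"matrix": matrix, "truth": truth, "results": results, "dmrs": dmrs,
            "phi": phi, "metrics": recovery_metrics(dmrs, study.planted)}


@pytest.fixture(scope="session")
def null_run(study):
    """Matched null run: same depth/dispersion/libraries, nothing planted."""
    matrix, _ = simulate_window_counts(study.chromosome_sizes(), [], study.null_count_spec)
    factors = normalize_library_sizes(matrix)
    phi = estimate_common_dispersion(matrix, factors=factors).phi
    results = test_all_windows(matrix, phi=phi, factors=factors)
    return {"matrix": matrix, "results": results, "phi": phi}
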