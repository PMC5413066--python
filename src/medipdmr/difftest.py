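"""Per-window two-group differential-coverage testing.

Coverage counts in a window are modelled as negative binomial with a
common dispersion phi (variance mu + phi * mu^2).  After library-size
normalization, replicate pools within a group are summed and the pair of
group sums is compared with a conditional exact test:

* conditional on the total ``n = a + b``, the control sum ``a`` follows
  Binomial(n, pi) when phi = 0, with pi set by the relative effective
  library sizes of the two groups;
* for phi > 0 the group sums are NB with sizes ``n_a/phi`` and
  ``n_b/phi``, and the conditional law of ``a`` is beta-binomial
  BetaBinomial(n, n_a/phi, n_b/phi).

The two-sided p-value is the sum of probabilities of all outcomes no more
probable than the observed one (minimum-likelihood rule); a
doubled-smaller-tail variant is available.  No window-level multiple
testing correction is applied — downstream region calling gates on raw
thresholds — but a Benjamini-Hochberg column is emitted for information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .windows import WindowCountMatrix

DEFAULT_FIXED_PHI = 0.1  # guard dispersion for no-replicate (1 vs 1) designs

__all__ = [
    "GroupDesign",
    "DispersionEstimate",
    "normalize_library_sizes",
    "estimate_common_dispersion",
    "nb_exact_test",
    "test_all_windows",
    "DEFAULT_FIXED_PHI",
]

_REL_TOL = 1 + 1e-12  # tolerance when comparing pmf values in the min-likelihood rule


@dataclass
class GroupDesign:
    """Assignment of count columns to the two comparison groups."""

    control: str = "control"
    exposed: str = "exposed"
    pairing: list[tuple[int, int]] | None = None

    def groups(self, matrix: WindowCountMatrix) -> tuple[list[int], list[int]]:
        a = matrix.pools_in_group(self.control)
        b = matrix.pools_in_group(self.exposed)
        if not a or not b:
            raise ValueError(
                f"matrix must contain pools for both groups "
                f"({self.control!r}: {len(a)}, {self.exposed!r}: {len(b)})"
            )
        return a, b


@dataclass
class DispersionEstimate:
    phi: float
    method: str
    n_windows_used: int

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("phi must be non-negative")


def normalize_library_sizes(
    matrix: WindowCountMatrix, method: str = "total-count"
) -> np.ndarray:
    """Per-pool scale factors bringing every library to a common effective size.

    ``total-count`` (default) scales each library to the geometric mean of
    the library sizes, i.e. factor_j = geomean(L) / L_j.  ``tmm`` is a
    trimmed-mean-of-ratios alternative behind the same contract: ratios of
    per-window proportions to the row geometric mean are trimmed (30% both
    sides) before averaging.
    """
    libs = np.asarray(matrix.library_sizes, dtype=float)
    if (libs <= 0).any():
        bad = [matrix.column_names()[i] for i in np.flatnonzero(libs <= 0)]
        raise ValueError(f"all-zero libraries cannot be normalized: {bad}")
    geomean = float(np.exp(np.log(libs).mean()))
    if method == "total-count":
        return geomean / libs
    if method == "tmm":
        base = geomean / libs
        props = matrix.counts / libs  # windows x pools, per-library proportions
        keep = (props > 0).all(axis=1)
        if not keep.any():
            return base
        p = props[keep]
        ref = np.exp(np.log(p).mean(axis=1, keepdims=True))  # row geometric mean
        ratios = p / ref
        lo, hi = np.quantile(ratios, [0.3, 0.7], axis=0)
        adjust = np.empty(matrix.n_pools)
        for j in range(matrix.n_pools):
            r = ratios[:, j]
            trimmed = r[(r >= lo[j]) & (r <= hi[j])]
            adjust[j] = 1.0 / np.exp(np.log(trimmed).mean())
        adjust /= np.exp(np.log(adjust).mean())  # keep the geometric-mean anchor
        return base * adjust
    raise ValueError(f"unknown normalization method {method!r}")


def estimate_common_dispersion(
    matrix: WindowCountMatrix,
    design: GroupDesign | None = None,
    factors: np.ndarray | None = None,
    fixed_phi: float | None = None,
    center: str = "mean",
) -> DispersionEstimate:
    """Method-of-moments common NB dispersion, pooled across windows.

    For every window and every group with >= 2 replicate pools, the
    normalized counts give a moment statistic ``(s^2 - mu) / mu^2`` whose
    expectation under NB(mu, phi) is phi.  The default estimate is the
    mean of these statistics over all windows with nonzero group mean,
    clamped at zero; with thousands of windows it is nearly unbiased even
    at 3 replicates.  ``center="median"`` gives a robust variant, but the
    small-sample variance distribution is right-skewed, so the median
    runs low at few replicates and makes the exact test anti-conservative
    — it is kept only for heavy-outlier data.

    For designs without replicates in either group, pass ``fixed_phi``.
    """
    design = design or GroupDesign()
    cols_a, cols_b = design.groups(matrix)
    if len(cols_a) < 2 and len(cols_b) < 2:
        if fixed_phi is not None:
            return DispersionEstimate(phi=float(fixed_phi), method="fixed", n_windows_used=0)
        raise ValueError(
            "need >=2 replicate pools in at least one group to estimate dispersion; "
            "pass fixed_phi for a no-replicate design"
        )
    if factors is None:
        factors = normalize_library_sizes(matrix)
    norm = matrix.counts * factors
    vals = []
    for cols in (cols_a, cols_b):
        if len(cols) < 2:
            continue
        g = norm[:, cols]
        mu = g.mean(axis=1)
        s2 = g.var(axis=1, ddof=1)
        ok = mu > 0
        vals.append(((s2[ok] - mu[ok]) / mu[ok] ** 2))
    pooled = np.concatenate(vals)
    if center not in ("mean", "median"):
        raise ValueError(f"unknown center {center!r}")
    agg = np.mean if center == "mean" else np.median
    phi = max(0.0, float(agg(pooled))) if pooled.size else 0.0
    return DispersionEstimate(phi=phi, method=f"mom-{center}", n_windows_used=int(pooled.size))


# ---------------------------------------------------------------------------
# conditional exact test

def _conditional_pmf(n: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """pmf of the control group sum conditional on the total ``n``.

    After normalization every pool has the same effective library size, so
    the null proportion for the control sum is ``n_a / (n_a + n_b)``.
    """
    k = np.arange(n + 1)
    if phi == 0:
        return stats.binom.pmf(k, n, n_a / (n_a + n_b))
    return stats.betabinom.pmf(k, n, n_a / phi, n_b / phi)


def _min_likelihood_p(pmf: np.ndarray, observed: int) -> float:
    include = pmf <= pmf[observed] * _REL_TOL
    if include.all():
        return 1.0  # observed outcome is the mode: the full law sums to 1 exactly
    return min(float(pmf[include].sum()), 1.0)


def _doubled_tail_p(pmf: np.ndarray, observed: int) -> float:
    lower = float(pmf[: observed + 1].sum())
    upper = float(pmf[observed:].sum())
    return min(1.0, 2 * min(lower, upper))


def nb_exact_test(
    control_counts,
    exposed_counts,
    factors=None,
    phi: float = 0.0,
    two_sided_rule: str = "min-likelihood",
) -> float:
    """Two-sided exact test for a difference in NB means between two groups.

    ``control_counts`` and ``exposed_counts`` are per-pool counts for one
    window; ``factors`` are the per-pool normalization factors (control
    pools first, matching the concatenated count order).  Counts are
    normalization-adjusted, summed within groups and rounded; the p-value
    comes from the conditional law described in the module docstring.
    Returns p in (0, 1].
    """
    a = np.atleast_1d(np.asarray(control_counts, dtype=float))
    b = np.atleast_1d(np.asarray(exposed_counts, dtype=float))
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    if phi < 0:
        raise ValueError("phi must be non-negative")
    if factors is not None:
        factors = np.asarray(factors, dtype=float)
        a = a * factors[: a.size]
        b = b * factors[a.size:]
    a_sum = int(np.rint(a.sum()))
    b_sum = int(np.rint(b.sum()))
    n = a_sum + b_sum
    if n == 0:
        return 1.0
    pmf = _conditional_pmf(n, a.size, b.size, phi)
    if two_sided_rule == "min-likelihood":
        return _min_likelihood_p(pmf, a_sum)
    if two_sided_rule == "doubled-tail":
        return _doubled_tail_p(pmf, a_sum)
    raise ValueError(f"unknown two_sided_rule {two_sided_rule!r}")


def _pvalues_grouped(
    a_sums: np.ndarray, totals: np.ndarray, n_a: int, n_b: int, phi: float,
    two_sided_rule: str = "min-likelihood",
) -> np.ndarray:
    """Vectorized exact p-values: one pmf evaluation per unique total."""
    p = np.ones(totals.size)
    order = np.argsort(totals, kind="stable")
    sorted_totals = totals[order]
    boundaries = np.flatnonzero(np.diff(sorted_totals)) + 1
    for block in np.split(order, boundaries):
        n = int(totals[block[0]])
        if n == 0:
            continue
        pmf = _conditional_pmf(n, n_a, n_b, phi)
        if two_sided_rule == "min-likelihood":
            # cumulative mass of outcomes with pmf <= each value, smallest first
            rank = np.argsort(pmf, kind="stable")
            cum = np.cumsum(pmf[rank])
            # map each possible observed value to its cumulative mass,
            # including ties (equal pmf values share the larger cumulative)
            pv = np.empty(n + 1)
            sorted_pmf = pmf[rank]
            # rightmost index whose pmf is <= pmf[obs] * tol
            idx = np.searchsorted(sorted_pmf, pmf * _REL_TOL, side="right") - 1
            pv = cum[np.clip(idx, 0, n)]
            pv[idx >= n] = 1.0  # mode: every outcome included, law sums to 1
            p[block] = np.minimum(pv[a_sums[block]], 1.0)
        else:
            cdf = np.cumsum(pmf)
            sf = pmf[::-1].cumsum()[::-1]
            obs = a_sums[block]
            p[block] = np.minimum(1.0, 2 * np.minimum(cdf[obs], sf[obs]))
    return p


def test_all_windows(
    matrix: WindowCountMatrix,
    design: GroupDesign | None = None,
    phi: float | None = None,
    factors: np.ndarray | None = None,
    two_sided_rule: str = "min-likelihood",
    with_bh: bool = True,
) -> pd.DataFrame:
    """Exact-test every window; returns a genome-ordered result table.

    Columns: ``chrom, start, stop, p, mean_control, mean_exposed,
    direction`` (+ ``p_bh`` unless disabled).  Windows with zero total
    count get p = 1 and direction ``none`` so downstream interval
    arithmetic never sees missing values.  ``phi=None`` estimates the
    common dispersion from the data.
    """
    design = design or GroupDesign()
    cols_a, cols_b = design.groups(matrix)
    if factors is None:
        factors = normalize_library_sizes(matrix)
    if phi is None:
        phi = estimate_common_dispersion(matrix, design, factors=factors).phi
    norm = matrix.counts * factors
    a_sums = np.rint(norm[:, cols_a].sum(axis=1)).astype(np.int64)
    b_sums = np.rint(norm[:, cols_b].sum(axis=1)).astype(np.int64)
    totals = a_sums + b_sums
    p = _pvalues_grouped(a_sums, totals, len(cols_a), len(cols_b), phi, two_sided_rule)

    mean_control = norm[:, cols_a].mean(axis=1)
    mean_exposed = norm[:, cols_b].mean(axis=1)
    direction = np.where(
        mean_exposed > mean_control, "hyper",
        np.where(mean_exposed < mean_control, "hypo", "none"),
    )
    out = matrix.windows[["chrom", "start", "stop"]].copy()
    out["p"] = p
    out["mean_control"] = mean_control
    out["mean_exposed"] = mean_exposed
    out["direction"] = direction
    if with_bh:
        out["p_bh"] = multipletests(p, method="fdr_bh")[1]
    return out
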