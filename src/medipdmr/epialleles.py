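"""Within-group pool-to-pool variability and DMR set overlap.

Pools of the same treatment group are compared pairwise (1 vs 1, fixed
dispersion) to flag hypervariable methylation regions — metastable
epialleles segregating within the population rather than induced by the
exposure.  A separate interval-overlap report compares any two DMR lists,
e.g. the direct-exposure and transgenerational generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .difftest import DEFAULT_FIXED_PHI, GroupDesign, test_all_windows
from .dmr import DMR, DMRCallParams, call_dmrs
from .windows import WindowCountMatrix

__all__ = ["PairwiseComparison", "OverlapReport", "hypervariable_dmrs", "overlap"]


@dataclass
class PairwiseComparison:
    group: str
    pool_a: int
    pool_b: int
    dmrs: list[DMR] = field(default_factory=list)


@dataclass
class OverlapReport:
    set_a_only: int
    set_b_only: int
    shared: int
    shared_pairs: list[tuple[str, str]] = field(default_factory=list)


def hypervariable_dmrs(
    matrix: WindowCountMatrix,
    group: str,
    params: DMRCallParams | None = None,
    phi: float = DEFAULT_FIXED_PHI,
) -> tuple[list[PairwiseComparison], list[DMR]]:
    """Call DMRs between every pair of pools within one group.

    Each of the C(n, 2) pool pairs is tested as a 1-vs-1 design with the
    fixed dispersion ``phi`` (no replicates, so dispersion cannot be
    estimated).  Returns the per-pair comparisons and the union of their
    DMRs with overlapping intervals merged; a region appearing in several
    pairs is counted once in the union.
    """
    params = params or DMRCallParams()
    cols = matrix.pools_in_group(group)
    if len(cols) < 2:
        raise ValueError(f"group {group!r} has {len(cols)} pool(s); >=2 required")
    comparisons = []
    for ia, ib in combinations(cols, 2):
        sub = matrix.subset_pools([ia, ib])
        # relabel the two pools as a throwaway 1-vs-1 design
        sub.pool_labels = [("a", 1), ("b", 1)]
        results = test_all_windows(sub, GroupDesign("a", "b"), phi=phi, with_bh=False)
        dmrs = call_dmrs(results, params)
        rep_a = matrix.pool_labels[ia][1]
        rep_b = matrix.pool_labels[ib][1]
        comparisons.append(PairwiseComparison(group=group, pool_a=rep_a, pool_b=rep_b, dmrs=dmrs))

    union = _merge_union([d for c in comparisons for d in c.dmrs])
    return comparisons, union


def _merge_union(dmrs: list[DMR]) -> list[DMR]:
    """Merge overlapping intervals from different pairwise comparisons."""
    out: list[DMR] = []
    for d in sorted(dmrs, key=lambda d: (d.chromosome, d.start, d.stop)):
        if out and d.chromosome == out[-1].chromosome and d.start < out[-1].stop:
            prev = out[-1]
            prev.stop = max(prev.stop, d.stop)
            prev.min_p = min(prev.min_p, d.min_p)
            prev.n_significant_windows = max(prev.n_significant_windows, d.n_significant_windows)
        else:
            out.append(DMR(
                name=d.name, chromosome=d.chromosome, start=d.start, stop=d.stop,
                n_windows_total=d.n_windows_total,
                n_significant_windows=d.n_significant_windows, min_p=d.min_p,
            ))
    return out


def overlap(dmrs_a: list[DMR], dmrs_b: list[DMR]) -> OverlapReport:
    """Count DMRs shared between two lists by >=1 bp interval intersection.

    ``shared`` counts intersecting (a, b) pairs, so it is symmetric in the
    argument order; the exclusive counts treat each DMR once even when it
    intersects several partners.  Both lists must be on the same genome.
    """
    hit_a: set[int] = set()
    hit_b: set[int] = set()
    pairs: list[tuple[str, str]] = []
    by_chrom_b: dict[str, list[tuple[int, DMR]]] = {}
    for j, d in enumerate(dmrs_b):
        by_chrom_b.setdefault(d.chromosome, []).append((j, d))
    for i, da in enumerate(dmrs_a):
        for j, db in by_chrom_b.get(da.chromosome, []):
            if da.start < db.stop and db.start < da.stop:
                hit_a.add(i)
                hit_b.add(j)
                pairs.append((da.name, db.name))
    return OverlapReport(
        set_a_only=len(dmrs_a) - len(hit_a),
        set_b_only=len(dmrs_b) - len(hit_b),
        shared=len(pairs),
        shared_pairs=pairs,
    )
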