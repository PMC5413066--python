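"""DMR assembly from per-window p-values.

A window with p below the seed threshold (default 1e-7) nucleates a DMR.
Edges are then extended: any window with p below the extension threshold
(default 0.1) lying within ``max_gap`` (default 1000 bp) of the growing
region is absorbed and itself extends the search frontier, iterated to a
fixpoint.  Regions whose closures touch are merged, and regions with
fewer than ``min_significant_windows`` seed windows (2 for the stringent
"multiple-site" set) are filtered out.

Because absorption is transitive, the fixpoint of the grow-and-merge
procedure over one chromosome equals the partition of extension-candidate
windows into chains in which consecutive candidates are separated by at
most ``max_gap``; a chain survives iff it contains a seed.  The
implementation uses this chain formulation; an independent literal
grow-to-fixpoint oracle is kept in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["DMR", "DMRCallParams", "call_dmrs", "threshold_sweep",
           "sites_histogram", "attach_cpg_profiles", "dmrs_to_frame", "write_dmr_table"]


@dataclass
class DMRCallParams:
    """Thresholds of the seed/extend/filter region-calling rule."""

    p_seed: float = 1e-7
    p_extend: float = 0.1
    max_gap: int = 1000
    min_significant_windows: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.p_seed <= self.p_extend <= 1):
            raise ValueError("require 0 < p_seed <= p_extend <= 1")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.min_significant_windows < 1:
            raise ValueError("min_significant_windows must be >= 1")


@dataclass
class DMR:
    """An assembled differentially methylated region.

    Coordinates are 0-based half-open and snap to window boundaries
    (lengths are multiples of the window width except at chromosome ends).
    """

    name: str
    chromosome: str
    start: int
    stop: int
    n_windows_total: int
    n_significant_windows: int
    min_p: float
    cpg_count: int | None = None
    cpg_density: float | None = None
    genes: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.stop - self.start


def _check_sorted(results: pd.DataFrame) -> None:
    for _, grp in results.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        if (np.diff(starts) <= 0).any():
            raise ValueError("window results must be genome-ordered within chromosomes")


def call_dmrs(results: pd.DataFrame, params: DMRCallParams | None = None) -> list[DMR]:
    """Assemble DMRs from a genome-ordered window result table.

    ``results`` needs columns ``chrom, start, stop, p``.  Every window
    with p < p_seed ends up in exactly one returned DMR (before the
    multi-site filter); no window with p < p_extend remains within
    ``max_gap`` of any returned DMR boundary.
    """
    params = params or DMRCallParams()
    _check_sorted(results)
    dmrs: list[DMR] = []
    for chrom, grp in results.groupby("chrom", sort=False):
        p = grp["p"].to_numpy()
        starts = grp["start"].to_numpy()
        stops = grp["stop"].to_numpy()
        cand = np.flatnonzero(p < params.p_extend)
        if cand.size == 0:
            continue
        seed_mask = p[cand] < params.p_seed
        if not seed_mask.any():
            continue
        # chain break where the gap between consecutive candidate windows
        # exceeds max_gap
        gaps = starts[cand[1:]] - stops[cand[:-1]]
        chain_id = np.concatenate([[0], np.cumsum(gaps > params.max_gap)])
        for cid in np.unique(chain_id[seed_mask]):
            members = cand[chain_id == cid]
            lo, hi = members[0], members[-1]
            region_start, region_stop = int(starts[lo]), int(stops[hi])
            in_span = slice(lo, hi + 1)
            span_p = p[in_span]
            n_sig = int((span_p < params.p_seed).sum())
            min_p = float(span_p.min())
            dmrs.append(DMR(
                name="",  # ordinal assigned after filtering
                chromosome=chrom,
                start=region_start,
                stop=region_stop,
                n_windows_total=hi - lo + 1,
                n_significant_windows=n_sig,
                min_p=min_p,
            ))
    kept = [d for d in dmrs if d.n_significant_windows >= params.min_significant_windows]
    counters: dict[str, int] = {}
    named = []
    for d in kept:
        counters[d.chromosome] = counters.get(d.chromosome, 0) + 1
        named.append(replace(d, name=f"{d.chromosome}:{counters[d.chromosome]}"))
    return named


def threshold_sweep(results: pd.DataFrame, thresholds, params: DMRCallParams | None = None) -> pd.DataFrame:
    """DMR counts over a range of seed thresholds, for all and multi-site sets.

    Reproduces the structure of the headline DMR-number table: per seed
    threshold, the number of regions containing >=1 seed window ("all")
    and >=2 seed windows ("multiple").  The extension threshold and gap
    stay fixed, so tightening the seed threshold can only shrink both
    counts.
    """
    params = params or DMRCallParams()
    rows = []
    for thr in thresholds:
        base = DMRCallParams(p_seed=thr, p_extend=max(thr, params.p_extend),
                             max_gap=params.max_gap, min_significant_windows=1)
        all_dmrs = call_dmrs(results, base)
        n_multi = sum(1 for d in all_dmrs if d.n_significant_windows >= 2)
        rows.append({"p_seed": thr, "n_all_dmrs": len(all_dmrs), "n_multiple_dmrs": n_multi})
    return pd.DataFrame(rows)


def sites_histogram(dmrs: list[DMR], cap: int = 10) -> pd.DataFrame:
    """DMR counts per number of significant windows (1, 2, ..., >cap)."""
    buckets: dict[str, int] = {}
    for d in dmrs:
        key = f">{cap}" if d.n_significant_windows > cap else str(d.n_significant_windows)
        buckets[key] = buckets.get(key, 0) + 1
    order = [str(i) for i in range(1, cap + 1)] + [f">{cap}"]
    rows = [{"n_significant_windows": k, "n_dmrs": buckets[k]} for k in order if k in buckets]
    return pd.DataFrame(rows, columns=["n_significant_windows", "n_dmrs"])


def attach_cpg_profiles(dmrs: list[DMR], reference) -> list[DMR]:
    """Fill each DMR's CpG count and density from the reference genome."""
    from .windows import cpg_profile

    out = []
    for d in dmrs:
        count, density = cpg_profile(reference, d.chromosome, d.start, d.stop)
        out.append(replace(d, cpg_count=count, cpg_density=density))
    return out


def dmrs_to_frame(dmrs: list[DMR], one_based: bool = True) -> pd.DataFrame:
    """Tabulate DMRs in the supplementary-table layout.

    ``start`` is written 1-based inclusive (the table convention); use
    ``one_based=False`` for 0-based half-open coordinates.
    """
    rows = []
    for d in dmrs:
        rows.append({
            "name": d.name,
            "chromosome": d.chromosome,
            "start": d.start + 1 if one_based else d.start,
            "length": d.length,
            "n_significant_windows": d.n_significant_windows,
            "min_p": d.min_p,
            "cpg_count": d.cpg_count if d.cpg_count is not None else "NA",
            "cpg_density": d.cpg_density if d.cpg_density is not None else "NA",
            "genes": ";".join(d.genes) if d.genes else "NA",
        })
    cols = ["name", "chromosome", "start", "length", "n_significant_windows",
            "min_p", "cpg_count", "cpg_density", "genes"]
    return pd.DataFrame(rows, columns=cols)


def write_dmr_table(dmrs: list[DMR], path) -> None:
    dmrs_to_frame(dmrs).to_csv(path, sep="\t", index=False)
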