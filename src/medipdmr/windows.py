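"""Fixed-width genome windowing, read counting and CpG content.

The analysis operates on a tiling of the genome into fixed 100-bp windows;
MeDIP read coverage per window is the unit of differential testing.  All
internal coordinates are 0-based half-open; written DMR tables use 1-based
inclusive starts and BED output stays 0-based (converted at the boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

WINDOW_WIDTH = 100

__all__ = [
    "WINDOW_WIDTH",
    "WindowCountMatrix",
    "make_windows",
    "count_reads_in_windows",
    "cpg_profile",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "read_count_matrix",
    "write_count_matrix",
]


@dataclass
class WindowCountMatrix:
    """Per-pool read counts over an ordered genome-window tiling.

    Attributes
    ----------
    windows:
        DataFrame with columns ``chrom``, ``start``, ``stop`` (0-based
        half-open), one row per window, genome-ordered.
    counts:
        Integer array of shape ``(n_windows, n_pools)``.
    pool_labels:
        One ``(group, replicate)`` tuple per column, e.g. ``("control", 1)``.
    library_sizes:
        Per-pool total counts (column sums when built from reads).
    skipped:
        Reads discarded because their chromosome was absent from the
        window set (kept so that assigned + skipped = input).
    """

    windows: pd.DataFrame
    counts: np.ndarray
    pool_labels: list[tuple[str, int]]
    library_sizes: np.ndarray = field(default=None)  # type: ignore[assignment]
    skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != len(self.windows):
            raise ValueError("counts must be (n_windows, n_pools)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.pool_labels) != self.counts.shape[1]:
            raise ValueError("one pool label per count column required")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_pools(self) -> int:
        return self.counts.shape[1]

    def pools_in_group(self, group: str) -> list[int]:
        return [i for i, (g, _) in enumerate(self.pool_labels) if g == group]

    def column_names(self) -> list[str]:
        return [f"{g}_pool{r}" for g, r in self.pool_labels]

    def subset_pools(self, columns: Sequence[int]) -> "WindowCountMatrix":
        return WindowCountMatrix(
            windows=self.windows,
            counts=self.counts[:, list(columns)],
            pool_labels=[self.pool_labels[i] for i in columns],
            library_sizes=self.library_sizes[list(columns)],
        )


def make_windows(
    chromosome_sizes: Mapping[str, int] | Iterable[tuple[str, int]],
    window_width: int = WINDOW_WIDTH,
) -> pd.DataFrame:
    """Tile each chromosome with non-overlapping fixed-width windows.

    Every chromosome is split into ``ceil(size / window_width)`` windows;
    the terminal window is shortened so the tiling covers exactly
    ``[0, size)`` with no gaps or overlaps.
    """
    if window_width <= 0:
        raise ValueError("window_width must be positive")
    items = list(chromosome_sizes.items()) if isinstance(chromosome_sizes, Mapping) else list(chromosome_sizes)
    frames = []
    for chrom, size in items:
        size = int(size)
        if size <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")
        starts = np.arange(0, size, window_width, dtype=np.int64)
        stops = np.minimum(starts + window_width, size)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "stop": stops}))
    return pd.concat(frames, ignore_index=True)


def _read_midpoints(starts: np.ndarray, stops: np.ndarray, extension: int) -> np.ndarray:
    # optional fixed fragment extension from the read start (default off);
    # MeDIP fragments are longer than the sequenced read, so callers may
    # extend before midpoint assignment
    if extension:
        stops = starts + extension
    return (starts + stops) // 2


def count_reads_in_windows(
    reads_by_pool: Mapping[str, pd.DataFrame | str | Path],
    windows: pd.DataFrame,
    extension: int = 0,
    window_width: int = WINDOW_WIDTH,
) -> WindowCountMatrix:
    """Count reads into windows by the read-midpoint rule.

    Each read is assigned to exactly one window: the one containing its
    midpoint ``floor((start + stop) / 2)``.  A midpoint landing exactly on
    a window boundary goes to the left window, so no read is ever counted
    twice.  Strand is ignored (MeDIP coverage is unstranded).  Reads on
    chromosomes absent from ``windows`` are tallied in ``skipped``.

    ``reads_by_pool`` maps pool names like ``control_pool1`` to BED paths
    or DataFrames with columns ``chrom``, ``start``, ``stop``.
    """
    offsets: dict[str, tuple[int, int]] = {}
    pos = 0
    for chrom, grp in windows.groupby("chrom", sort=False):
        offsets[chrom] = (pos, int(grp["stop"].iloc[-1]))
        pos += len(grp)

    n_win = len(windows)
    pool_names = list(reads_by_pool)
    counts = np.zeros((n_win, len(pool_names)), dtype=np.int64)
    skipped = 0
    for j, name in enumerate(pool_names):
        reads = reads_by_pool[name]
        if not isinstance(reads, pd.DataFrame):
            reads = read_bed(reads)
        for chrom, grp in reads.groupby("chrom", sort=False):
            if chrom not in offsets:
                skipped += len(grp)
                continue
            base, chrom_len = offsets[chrom]
            mid = _read_midpoints(grp["start"].to_numpy(), grp["stop"].to_numpy(), extension)
            mid = np.clip(mid, 0, chrom_len - 1)
            idx = mid // window_width
            on_boundary = (mid % window_width == 0) & (mid > 0)
            idx[on_boundary] -= 1
            np.add.at(counts[:, j], base + idx, 1)
    labels = [_parse_pool_name(n) for n in pool_names]
    return WindowCountMatrix(windows=windows, counts=counts, pool_labels=labels, skipped=skipped)


def _parse_pool_name(name: str) -> tuple[str, int]:
    """``control_pool2`` -> ``("control", 2)``; unlabelled names get rep 1."""
    if "_pool" in name:
        group, rep = name.rsplit("_pool", 1)
        return group, int(rep)
    return name, 1


def cpg_profile(reference, chrom: str, start: int, stop: int) -> tuple[int, float]:
    """Count CpG dinucleotides fully inside ``[start, stop)``.

    Returns ``(cpg_count, cpg_density)`` with density in CpGs per 100 bp.
    Matching is case-insensitive; a CG whose G falls on or beyond ``stop``
    is not counted (both bases must lie inside the interval).  Any N at a
    candidate position fails the match.  ``reference`` may be a
    ``pyfaidx.Fasta``, a dict of sequences, or anything indexable as
    ``reference[chrom][start:stop]``.
    """
    if start < 0 or stop <= start:
        raise ValueError("interval must satisfy 0 <= start < stop")
    seq_obj = reference[chrom]
    chrom_len = len(seq_obj)
    if stop > chrom_len:
        raise ValueError(f"interval [{start}, {stop}) beyond end of {chrom} ({chrom_len} bp)")
    seq = str(seq_obj[start:stop]).upper()
    count = seq.count("CG")
    density = 100.0 * count / (stop - start)
    return count, density


# ---------------------------------------------------------------------------
# plain-text I/O

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def read_alignments_bam(path: str | Path) -> pd.DataFrame:
    """Load aligned reads from BAM/SAM into the same frame ``read_bed`` gives.

    Requires pysam (the ``bam`` extra); unmapped reads are dropped.
    """
    import pysam  # optional dependency

    rows = []
    with pysam.AlignmentFile(str(path)) as fh:
        for read in fh.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            rows.append((read.reference_name, read.reference_start, read.reference_end))
    return pd.DataFrame(rows, columns=["chrom", "start", "stop"])


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
                     names=["chrom", "start", "stop"])
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "stop"]].to_csv(path, sep="\t", header=False, index=False)


def write_count_matrix(matrix: WindowCountMatrix, path: str | Path) -> None:
    out = matrix.windows[["chrom", "start", "stop"]].copy()
    for j, name in enumerate(matrix.column_names()):
        out[name] = matrix.counts[:, j]
    out.to_csv(path, sep="\t", index=False)


def read_count_matrix(path: str | Path) -> WindowCountMatrix:
    df = pd.read_csv(path, sep="\t")
    pool_cols = [c for c in df.columns if c not in ("chrom", "start", "stop")]
    return WindowCountMatrix(
        windows=df[["chrom", "start", "stop"]].copy(),
        counts=df[pool_cols].to_numpy(dtype=np.int64),
        pool_labels=[_parse_pool_name(c) for c in pool_cols],
    )
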