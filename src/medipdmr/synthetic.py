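"""Synthetic genomes, window counts and behavioral cohorts with planted truth.

Everything downstream of alignment is testable against these generators:
a toy multi-chromosome genome whose CpG landscape mimics a CpG desert
(low background density with scattered dense clusters and one repeat-rich
high-GC arm), negative-binomial window counts for three pools per group
with unequal library sizes and planted fold-change regions, and
control-anchored behavioral cohorts with shifted exposure lineages.

The sequence model is deliberately simple: i.i.d. bases with CpG
dinucleotides suppressed in the background and injected at a specified
per-window Poisson rate, so the realized CpG density is exactly the
planted rate up to sampling noise.  No generative model exists for the
real data; these emission choices are stand-ins whose parameters are the
study conditions, not fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import substream
from .windows import WINDOW_WIDTH, WindowCountMatrix, make_windows

__all__ = [
    "SyntheticGenomeSpec", "PlantedDMR", "CountSimulationSpec",
    "PhenotypeSimulationSpec", "SyntheticGenome",
    "generate_genome", "simulate_window_counts", "simulate_phenotypes",
    "simulate_reads",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
# tandem repeat unit for the high-GC arm: 72% GC, one CpG per 25-mer
_REPEAT_UNIT = "GGCCAGGCTGGCAGGCCTGGCGTCA"


@dataclass
class SyntheticGenomeSpec:
    """Layout of the toy genome's chromosomes and CpG landscape."""

    chromosome_lengths: Sequence[tuple[str, int]] = (("chr1", 1_000_000),)
    base_cpg_rate: float = 3.0        # CpGs per 100 bp in the desert background
    cluster_rate: float = 12.0        # CpGs per 100 bp inside clusters
    cluster_fraction: float = 0.05    # fraction of windows that are clusters
    repeat_arm: tuple[str, int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = dict(self.chromosome_lengths)
        for name, size in lengths.items():
            if size <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        if self.base_cpg_rate < 0 or self.cluster_rate < 0:
            raise ValueError("CpG rates must be non-negative")
        if not 0 <= self.cluster_fraction <= 1:
            raise ValueError("cluster_fraction must be in [0, 1]")
        if self.repeat_arm is not None:
            chrom, start, stop = self.repeat_arm
            if chrom not in lengths:
                raise ValueError(f"repeat_arm chromosome {chrom!r} not in genome")
            if not (0 <= start < stop <= lengths[chrom]):
                raise ValueError("repeat_arm must lie within its chromosome")


@dataclass
class PlantedDMR:
    """Ground-truth differential region (0-based half-open)."""

    chromosome: str
    start: int
    stop: int
    fold_change: float = 4.0
    direction: str = "hyper"

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("stop must exceed start")
        if self.fold_change <= 0 or self.fold_change == 1:
            raise ValueError("fold_change must be positive and != 1")
        if self.direction not in ("hyper", "hypo"):
            raise ValueError("direction must be 'hyper' or 'hypo'")

    @property
    def multiplier(self) -> float:
        """Mean multiplier applied to exposed-group counts."""
        return self.fold_change if self.direction == "hyper" else 1.0 / self.fold_change


@dataclass
class CountSimulationSpec:
    """Emission model for per-pool window counts."""

    n_pools_per_group: int = 3
    mean_depth: float = 100.0          # expected reads per window at factor 1
    dispersion: float = 0.05           # NB phi; 0 gives Poisson
    library_size_factors: Sequence[float] | None = None  # control pools then exposed
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pools_per_group < 1:
            raise ValueError("n_pools_per_group must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        n = 2 * self.n_pools_per_group
        if self.library_size_factors is None:
            self.library_size_factors = (1.0,) * n
        self.library_size_factors = tuple(float(f) for f in self.library_size_factors)
        if len(self.library_size_factors) != n:
            raise ValueError(f"need {n} library size factors (control pools first)")
        if any(f <= 0 for f in self.library_size_factors):
            raise ValueError("library size factors must be positive")


@dataclass
class PhenotypeSimulationSpec:
    """Control-anchored behavioral cohorts with per-lineage shifts.

    ``lineage_shifts`` maps lineage label to ``(locomotion_shift,
    startle_shift)`` in assay units; hyperactive lineages shift
    locomotion up, visually impaired lineages shift startle down.
    """

    n_per_lineage: int = 20
    control_mean: float = 20.0
    control_sd: float = 5.0
    lineage_shifts: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    fraction_time_moving_params: tuple[float, float] = (0.6, 0.08)  # mean, sd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_lineage < 1:
            raise ValueError("n_per_lineage must be >= 1")
        if self.control_sd <= 0:
            raise ValueError("control_sd must be positive")


@dataclass
class SyntheticGenome:
    """Generated sequences plus the realized CpG-position index."""

    sequences: dict[str, str]
    cpg_index: dict[str, np.ndarray]
    spec: SyntheticGenomeSpec

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def chromosome_sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def write_fasta(self, path: str | Path, line_width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i:i + line_width] + "\n")


def _background_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    """i.i.d. bases with every accidental CG dinucleotide broken."""
    seq = rng.choice(_BASES, size=length)
    is_c = seq[:-1] == b"C"
    is_g = seq[1:] == b"G"
    hits = np.flatnonzero(is_c & is_g)
    seq[hits + 1] = b"T"  # T after C never creates a new CG on either side
    return seq


def _find_cpgs(seq: np.ndarray) -> np.ndarray:
    return np.flatnonzero((seq[:-1] == b"C") & (seq[1:] == b"G"))


def generate_genome(spec: SyntheticGenomeSpec) -> SyntheticGenome:
    """Generate the toy genome described by ``spec``.

    Per 100-bp window the CpG count is Poisson with the desert or cluster
    rate; CpGs are injected at even in-window offsets so injected sites
    never overlap each other or window boundaries.  The optional repeat
    arm is tiled with copies of a fixed high-GC 25-mer.  The returned CpG
    index is re-scanned from the final sequence, so every indexed
    position is guaranteed to hold "CG".
    """
    sequences: dict[str, str] = {}
    cpg_index: dict[str, np.ndarray] = {}
    for name, length in spec.chromosome_lengths:
        rng = substream(spec.seed, f"genome/{name}")
        seq = _background_sequence(rng, length)

        n_windows = int(np.ceil(length / WINDOW_WIDTH))
        starts = np.arange(n_windows, dtype=np.int64) * WINDOW_WIDTH
        widths = np.minimum(starts + WINDOW_WIDTH, length) - starts
        is_cluster = rng.random(n_windows) < spec.cluster_fraction
        rates = np.where(is_cluster, spec.cluster_rate, spec.base_cpg_rate)
        n_cpg = rng.poisson(rates * widths / WINDOW_WIDTH)
        for w_start, width, k in zip(starts, widths, n_cpg):
            if k == 0:
                continue
            n_slots = (int(width) - 1) // 2  # even offsets leaving room for the G
            k = min(int(k), n_slots)
            offsets = rng.choice(n_slots, size=k, replace=False) * 2
            pos = int(w_start) + offsets
            seq[pos] = b"C"
            seq[pos + 1] = b"G"

        if spec.repeat_arm is not None and spec.repeat_arm[0] == name:
            _, arm_start, arm_stop = spec.repeat_arm
            unit = np.frombuffer(_REPEAT_UNIT.encode(), dtype="S1")
            reps = int(np.ceil((arm_stop - arm_start) / len(unit)))
            seq[arm_start:arm_stop] = np.tile(unit, reps)[: arm_stop - arm_start]

        sequences[name] = seq.tobytes().decode()
        cpg_index[name] = _find_cpgs(seq)
    return SyntheticGenome(sequences=sequences, cpg_index=cpg_index, spec=spec)


def _planted_window_mask(windows: pd.DataFrame, planted: Sequence[PlantedDMR]) -> np.ndarray:
    """Per-window exposed-group mean multiplier from the planted regions."""
    mult = np.ones(len(windows))
    starts = windows["start"].to_numpy()
    stops = windows["stop"].to_numpy()
    chroms = windows["chrom"].to_numpy()
    for p in planted:
        inside = (chroms == p.chromosome) & (starts >= p.start) & (stops <= p.stop)
        mult[inside] = p.multiplier
    return mult


def simulate_window_counts(
    chromosome_sizes: Mapping[str, int],
    planted: Sequence[PlantedDMR],
    sim: CountSimulationSpec,
    window_width: int = WINDOW_WIDTH,
) -> tuple[WindowCountMatrix, pd.DataFrame]:
    """Simulate per-pool NB window counts with planted differential regions.

    Counts for pool j in window w are NB with mean
    ``mean_depth * factor_j * multiplier(w)`` where the multiplier is the
    planted fold change for exposed-group pools in windows fully inside a
    planted region, and 1 elsewhere; variance is ``mu + phi * mu**2``.
    Returns the count matrix and a truth table with one row per planted
    window.
    """
    for p in planted:
        if p.chromosome not in chromosome_sizes:
            raise ValueError(f"planted DMR on unknown chromosome {p.chromosome!r}")
        if p.stop > chromosome_sizes[p.chromosome]:
            raise ValueError(f"planted DMR [{p.start}, {p.stop}) beyond end of {p.chromosome}")
    windows = make_windows(chromosome_sizes, window_width)
    mult = _planted_window_mask(windows, planted)
    rng = substream(sim.seed, "counts")
    n_pools = 2 * sim.n_pools_per_group
    counts = np.empty((len(windows), n_pools), dtype=np.int64)
    phi = sim.dispersion
    ones = np.ones(len(windows))
    for j in range(n_pools):
        exposed = j >= sim.n_pools_per_group
        mu = sim.mean_depth * sim.library_size_factors[j] * (mult if exposed else ones)
        if phi == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / phi
            counts[:, j] = rng.negative_binomial(r, r / (r + mu))
    labels = [("control", i + 1) for i in range(sim.n_pools_per_group)] + \
             [("exposed", i + 1) for i in range(sim.n_pools_per_group)]
    matrix = WindowCountMatrix(windows=windows, counts=counts, pool_labels=labels)

    truth_rows = windows[mult != 1.0].copy()
    truth_rows["multiplier"] = mult[mult != 1.0]
    truth = truth_rows.reset_index(drop=True)
    return matrix, truth


def simulate_reads(
    matrix: WindowCountMatrix,
    read_length: int = 50,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Emit per-pool BED-style reads whose midpoints realize the counts.

    Exists solely to exercise the read-counting path: for every window
    and pool, ``count`` reads are placed with midpoints uniform inside
    the window (clipped so reads stay on-chromosome), so midpoint
    counting recovers the matrix exactly.
    """
    rng = substream(seed, "reads")
    half = read_length // 2
    chrom_stop = matrix.windows.groupby("chrom", sort=False)["stop"].max().to_dict()
    out: dict[str, pd.DataFrame] = {}
    win_chrom = matrix.windows["chrom"].to_numpy()
    win_start = matrix.windows["start"].to_numpy()
    win_stop = matrix.windows["stop"].to_numpy()
    chrom_len = np.vectorize(chrom_stop.__getitem__)(win_chrom)
    for j, name in enumerate(matrix.column_names()):
        c = matrix.counts[:, j]
        rep_idx = np.repeat(np.arange(len(win_chrom)), c)
        lo = win_start[rep_idx]
        hi = win_stop[rep_idx]
        # midpoints strictly inside the window (a midpoint on the left
        # boundary would be assigned to the previous window by the tie
        # rule), clipped so the full read stays on-chromosome
        mids = lo + 1 + (rng.random(rep_idx.size) * (hi - lo - 1)).astype(np.int64)
        mids = np.clip(mids, half, chrom_len[rep_idx] - (read_length - half))
        starts = mids - half
        out[name] = pd.DataFrame({
            "chrom": win_chrom[rep_idx],
            "start": starts,
            "stop": starts + read_length,
        })
    return out


def simulate_phenotypes(spec: PhenotypeSimulationSpec) -> pd.DataFrame:
    """Simulate one behavioral cohort per lineage.

    The control lineage draws both assays from N(control_mean,
    control_sd) truncated at zero; exposure lineages add their stated
    shifts.  Fraction-of-time-moving is normal, clipped to [0, 1], shared
    across lineages (the outlier filter is not a treatment effect here).
    """
    rng = substream(spec.seed, "phenotypes")
    lineages = ["control"] + list(spec.lineage_shifts)
    frames = []
    frac_mean, frac_sd = spec.fraction_time_moving_params
    for lineage in lineages:
        loco_shift, startle_shift = (0.0, 0.0) if lineage == "control" else spec.lineage_shifts[lineage]
        n = spec.n_per_lineage
        visual = rng.normal(spec.control_mean + startle_shift, spec.control_sd, n)
        loco = rng.normal(spec.control_mean + loco_shift, spec.control_sd, n)
        frac = np.clip(rng.normal(frac_mean, frac_sd, n), 0.0, 1.0)
        frames.append(pd.DataFrame({
            "fish_id": [f"{lineage}_{i + 1}" for i in range(n)],
            "lineage": lineage,
            "sex": np.where(np.arange(n) % 2 == 0, "M", "F"),
            "visual_startle": np.maximum(visual, 0.0),
            "locomotion": np.maximum(loco, 0.0),
            "fraction_time_moving": frac,
        }))
    return pd.concat(frames, ignore_index=True)
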