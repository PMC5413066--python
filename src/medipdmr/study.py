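"""The canonical synthetic study: conditions, truth and evaluation helpers.

This module fixes the study conditions under which the pipeline is
exercised end-to-end: a 5-chromosome x 2-Mb genome in a CpG-desert
regime, 50 planted 3-window hypermethylated regions at 4-fold change,
three pools per group at 100 reads per window with NB dispersion 0.05
and mildly unequal library sizes, and behavioral cohorts for a control
plus five exposure lineages whose locomotion shifts up and visual
startle shifts down with dose.  The analysis scripts, the acceptance
harness and the recovery tests all draw from here, so the conditions are
defined exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._util import substream
from .dmr import DMR
from .synthetic import (
    CountSimulationSpec,
    PhenotypeSimulationSpec,
    PlantedDMR,
    SyntheticGenomeSpec,
)
from .windows import WINDOW_WIDTH

__all__ = ["StudyConditions", "default_study", "plant_dmrs", "recovery_metrics",
           "synthetic_gene_table", "synthetic_pathway_map"]

N_CHROMOSOMES = 5
CHROM_LENGTH = 2_000_000
N_PLANTED = 50
PLANTED_WINDOWS = 3
FOLD_CHANGE = 4.0
MEAN_DEPTH = 100.0
DISPERSION = 0.05
N_POOLS = 3
LIBRARY_FACTORS = (1.0, 0.9, 1.1, 1.05, 0.95, 1.0)
N_PER_LINEAGE = 20
LINEAGE_SHIFTS = {  # locomotion up, startle down, growing with ancestral dose
    "1nM": (4.0, -4.0),
    "3nM": (6.0, -6.0),
    "10nM": (8.0, -8.0),
    "30nM": (10.0, -10.0),
    "100nM": (14.0, -14.0),
}


@dataclass
class StudyConditions:
    genome_spec: SyntheticGenomeSpec
    planted: list[PlantedDMR]
    count_spec: CountSimulationSpec
    null_count_spec: CountSimulationSpec
    phenotype_spec: PhenotypeSimulationSpec

    def chromosome_sizes(self) -> dict[str, int]:
        return dict(self.genome_spec.chromosome_lengths)


def plant_dmrs(
    chromosome_sizes: dict[str, int],
    n_dmrs: int = N_PLANTED,
    n_windows: int = PLANTED_WINDOWS,
    fold_change: float = FOLD_CHANGE,
    seed: int = 0,
    min_separation: int = 20_000,
) -> list[PlantedDMR]:
    """Place window-aligned ground-truth regions, well separated.

    Regions are spread across chromosomes round-robin and positioned on a
    grid of ``min_separation`` so no two planted regions fall within the
    extension reach of one another.
    """
    rng = substream(seed, "plant")
    chroms = list(chromosome_sizes)
    span = n_windows * WINDOW_WIDTH
    planted: list[PlantedDMR] = []
    slots_by_chrom = {
        c: list(range(1, (chromosome_sizes[c] - span) // min_separation))
        for c in chroms
    }
    for i in range(n_dmrs):
        chrom = chroms[i % len(chroms)]
        slots = slots_by_chrom[chrom]
        if not slots:
            raise ValueError("not enough room to separate planted regions")
        slot = slots.pop(int(rng.integers(len(slots))))
        start = slot * min_separation
        planted.append(PlantedDMR(chromosome=chrom, start=start, stop=start + span,
                                  fold_change=fold_change, direction="hyper"))
    planted.sort(key=lambda p: (p.chromosome, p.start))
    return planted


def default_study(seed: int = 0) -> StudyConditions:
    """The study conditions at their defaults, reseeded as one unit."""
    sizes = [(f"chr{i + 1}", CHROM_LENGTH) for i in range(N_CHROMOSOMES)]
    genome_spec = SyntheticGenomeSpec(
        chromosome_lengths=sizes,
        base_cpg_rate=3.0,
        cluster_rate=12.0,
        cluster_fraction=0.05,
        repeat_arm=("chr4", 1_400_000, 2_000_000),
        seed=seed,
    )
    planted = plant_dmrs(dict(sizes), seed=seed)
    count_spec = CountSimulationSpec(
        n_pools_per_group=N_POOLS,
        mean_depth=MEAN_DEPTH,
        dispersion=DISPERSION,
        library_size_factors=LIBRARY_FACTORS,
        seed=seed,
    )
    null_count_spec = CountSimulationSpec(
        n_pools_per_group=N_POOLS,
        mean_depth=MEAN_DEPTH,
        dispersion=DISPERSION,
        library_size_factors=LIBRARY_FACTORS,
        seed=seed + 1,
    )
    phenotype_spec = PhenotypeSimulationSpec(
        n_per_lineage=N_PER_LINEAGE,
        control_mean=20.0,
        control_sd=5.0,
        lineage_shifts=LINEAGE_SHIFTS,
        fraction_time_moving_params=(0.6, 0.08),
        seed=seed,
    )
    return StudyConditions(
        genome_spec=genome_spec,
        planted=planted,
        count_spec=count_spec,
        null_count_spec=null_count_spec,
        phenotype_spec=phenotype_spec,
    )


def recovery_metrics(called: list[DMR], planted: list[PlantedDMR]) -> dict[str, float]:
    """Sensitivity and precision of called DMRs against the planted truth.

    A planted region is recovered when at least one called DMR intersects
    it; a called DMR is a true positive when it intersects any planted
    region.
    """
    def hits(dmr: DMR) -> bool:
        return any(p.chromosome == dmr.chromosome and dmr.start < p.stop and p.start < dmr.stop
                   for p in planted)

    recovered = sum(
        1 for p in planted
        if any(d.chromosome == p.chromosome and d.start < p.stop and p.start < d.stop
               for d in called)
    )
    true_pos = sum(1 for d in called if hits(d))
    sensitivity = recovered / len(planted) if planted else float("nan")
    precision = true_pos / len(called) if called else float("nan")
    return {
        "sensitivity": sensitivity,
        "precision": precision,
        "n_called": len(called),
        "n_planted": len(planted),
    }


def synthetic_gene_table(
    chromosome_sizes: dict[str, int],
    planted: list[PlantedDMR],
    n_background_genes: int = 60,
    seed: int = 0,
) -> pd.DataFrame:
    """A toy gene annotation: some genes near planted regions, rest scattered.

    Every other planted region receives a gene 5 kb downstream so the
    10-kb association rule has positives and negatives; background genes
    are placed uniformly with round-robin functional categories.
    """
    from .annotate import CATEGORIES

    rng = substream(seed, "genes")
    rows = []
    for i, p in enumerate(planted):
        if i % 2 == 0:
            start = p.stop + 5_000
            rows.append({
                "symbol": f"g{i + 1:03d}", "chrom": p.chromosome,
                "start": start, "stop": start + 2_000, "strand": "+",
                "category": CATEGORIES[i % (len(CATEGORIES) - 1)],
            })
    chroms = list(chromosome_sizes)
    for i in range(n_background_genes):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, chromosome_sizes[chrom] - 3_000))
        rows.append({
            "symbol": f"bg{i + 1:03d}", "chrom": chrom,
            "start": start, "stop": start + 2_000,
            "strand": "+" if rng.random() < 0.5 else "-",
            "category": CATEGORIES[int(rng.integers(len(CATEGORIES)))],
        })
    return pd.DataFrame(rows, columns=["symbol", "chrom", "start", "stop", "strand", "category"])


def synthetic_pathway_map(gene_table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Assign a subset of genes to a few toy pathway ids."""
    rng = substream(seed, "pathways")
    pathways = ["path:metabolic", "path:neuroactive", "path:actin", "path:adhesion", "path:mapk"]
    rows = []
    for sym in gene_table["symbol"]:
        for pid in pathways:
            if rng.random() < 0.15:
                rows.append({"pathway_id": pid, "symbol": sym})
    return pd.DataFrame(rows, columns=["pathway_id", "symbol"])
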