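"""Distance-bounded DMR-to-gene association and functional rollups.

Annotation is entirely file-driven: a gene table (symbol, chromosome,
interval, strand, functional category) and an optional pathway map
(pathway id, symbol).  A gene is associated with a DMR when the gap
between the two intervals is at most ``max_distance`` (default 10 kb,
zero when they overlap), measured interval-edge to interval-edge in both
directions and ignoring strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .dmr import DMR

__all__ = ["GeneRecord", "associate_genes", "category_summary", "pathway_rollup",
           "read_gene_table", "read_pathway_map", "CATEGORIES"]

# controlled (extensible) vocabulary of functional gene classes
CATEGORIES = (
    "signaling", "metabolism", "receptor", "protease", "transcription",
    "translation", "cytoskeleton", "development", "transport", "immune",
    "unknown",
)


@dataclass
class GeneRecord:
    symbol: str
    chromosome: str
    start: int
    stop: int
    strand: str = "+"
    category: str = "unknown"

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError(f"gene {self.symbol}: stop must exceed start")


def _gap(a_start: int, a_stop: int, b_start: int, b_stop: int) -> int:
    """bp separating two half-open intervals; 0 when they overlap."""
    return max(0, b_start - a_stop, a_start - b_stop)


def associate_genes(
    dmrs: list[DMR], genes: list[GeneRecord], max_distance: int = 10_000
) -> list[DMR]:
    """Attach to each DMR all genes within ``max_distance``, nearest first.

    Ties in distance break by symbol so the ordering is deterministic.
    DMRs with no qualifying gene keep an empty list (rendered NA in
    written tables).
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    out = []
    for d in dmrs:
        hits = []
        for g in by_chrom.get(d.chromosome, []):
            gap = _gap(d.start, d.stop, g.start, g.stop)
            if gap <= max_distance:
                hits.append((gap, g.symbol))
        hits.sort()
        out.append(replace(d, genes=[s for _, s in hits]))
    return out


def category_summary(annotated_dmrs: list[DMR], genes: list[GeneRecord]) -> pd.DataFrame:
    """Count DMRs per functional gene category.

    A DMR associated with k genes increments each gene's category once,
    so category totals may exceed the number of annotated DMRs; DMRs with
    no association are reported under ``NA``.
    """
    cat_of = {g.symbol: g.category for g in genes}
    counts: dict[str, int] = {}
    for d in annotated_dmrs:
        if not d.genes:
            counts["NA"] = counts.get("NA", 0) + 1
            continue
        for cat in {cat_of.get(sym, "unknown") for sym in d.genes}:
            counts[cat] = counts.get(cat, 0) + 1
    rows = [{"category": c, "n_dmrs": n} for c, n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["category", "n_dmrs"])


def pathway_rollup(annotated_dmrs: list[DMR], pathway_map: pd.DataFrame) -> pd.DataFrame:
    """Count unique associated gene symbols per pathway id.

    ``pathway_map`` has columns ``pathway_id`` and ``symbol``; a gene in
    several pathways counts in each, but multiple DMRs near the same gene
    contribute that gene only once.  Symbols in the map that never occur
    in the annotation are fine; associated symbols missing from the map
    are ignored with a warning.
    """
    associated = {sym for d in annotated_dmrs for sym in d.genes}
    mapped = set(pathway_map["symbol"]) if len(pathway_map) else set()
    unknown = associated - mapped
    if unknown:
        warnings.warn(f"{len(unknown)} associated gene symbol(s) absent from the pathway map")
    if not len(pathway_map):
        return pd.DataFrame(columns=["pathway_id", "n_genes"])
    hits = pathway_map[pathway_map["symbol"].isin(associated)]
    rollup = (hits.drop_duplicates(["pathway_id", "symbol"])
                  .groupby("pathway_id").size().rename("n_genes").reset_index())
    return rollup.sort_values(["n_genes", "pathway_id"], ascending=[False, True]).reset_index(drop=True)


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t")
    return [GeneRecord(symbol=r.symbol, chromosome=r.chrom, start=int(r.start),
                       stop=int(r.stop), strand=getattr(r, "strand", "+"),
                       category=getattr(r, "category", "unknown"))
            for r in df.itertuples(index=False)]


def read_pathway_map(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")[["pathway_id", "symbol"]]
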