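#!/usr/bin/env python
"""DMR-to-gene association within 10 kb, category and pathway rollups."""

import argparse
from pathlib import Path

import pandas as pd

from medipdmr.annotate import associate_genes, category_summary, pathway_rollup, read_gene_table, read_pathway_map
from medipdmr.dmr import DMRCallParams, call_dmrs, write_dmr_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--study-dir", type=Path, default=Path("results/study"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    results = pd.read_csv(args.out / "window_tests.tsv", sep="\t")
    dmrs = call_dmrs(results, DMRCallParams())
    genes = read_gene_table(args.study_dir / "genes.tsv")
    annotated = associate_genes(dmrs, genes)
    write_dmr_table(annotated, args.out / "dmrs_annotated.tsv")

    summary = category_summary(annotated, genes)
    summary.to_csv(args.out / "gene_categories.tsv", sep="\t", index=False)
    rollup = pathway_rollup(annotated, read_pathway_map(args.study_dir / "pathways.tsv"))
    rollup.to_csv(args.out / "pathway_rollup.tsv", sep="\t", index=False)

    n_assoc = sum(1 for d in annotated if d.genes)
    print(f"{n_assoc}/{len(annotated)} DMRs have a gene within 10 kb "
          f"(the rest are NA, as expected in a CpG-desert landscape)")
    print("category rollup:", dict(zip(summary["category"], summary["n_dmrs"])))
    if len(rollup):
        top = rollup.iloc[0]
        print(f"top pathway: {top.pathway_id} ({top.n_genes} genes)")


if __name__ == "__main__":
    main()
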