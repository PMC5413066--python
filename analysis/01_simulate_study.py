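#!/usr/bin/env python
"""Generate the synthetic study: genome, window counts, truth, annotation, cohorts.

Writes every downstream input under results/study/ and reports the study
dimensions.  All later analysis steps read from that directory, so the
whole analysis chain is reproducible from one seed.
"""

import argparse
from pathlib import Path

import pandas as pd

from medipdmr.study import default_study, synthetic_gene_table, synthetic_pathway_map
from medipdmr.synthetic import generate_genome, simulate_phenotypes, simulate_window_counts
from medipdmr.windows import write_count_matrix


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/study"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    study = default_study(args.seed)
    genome = generate_genome(study.genome_spec)
    genome.write_fasta(args.out / "genome.fa")
    sizes = genome.chromosome_sizes()
    pd.DataFrame(sizes.items()).to_csv(args.out / "genome.chrom.sizes",
                                       sep="\t", header=False, index=False)

    matrix, truth = simulate_window_counts(sizes, study.planted, study.count_spec)
    write_count_matrix(matrix, args.out / "window_counts.tsv")
    null_matrix, _ = simulate_window_counts(sizes, [], study.null_count_spec)
    write_count_matrix(null_matrix, args.out / "window_counts_null.tsv")
    truth.to_csv(args.out / "planted_truth.tsv", sep="\t", index=False)

    genes = synthetic_gene_table(sizes, study.planted, seed=args.seed)
    genes.to_csv(args.out / "genes.tsv", sep="\t", index=False)
    synthetic_pathway_map(genes, seed=args.seed).to_csv(
        args.out / "pathways.tsv", sep="\t", index=False)
    simulate_phenotypes(study.phenotype_spec).to_csv(
        args.out / "phenotypes.tsv", sep="\t", index=False)

    n_cpg = sum(v.size for v in genome.cpg_index.values())
    total_bp = sum(sizes.values())
    print(f"genome: {len(sizes)} chromosomes, {total_bp:,} bp, "
          f"{100 * n_cpg / total_bp:.2f} CpG per 100 bp overall")
    print(f"counts: {matrix.n_windows:,} windows x {matrix.n_pools} pools "
          f"(depth {study.count_spec.mean_depth:.0f}, phi {study.count_spec.dispersion})")
    print(f"truth: {len(truth)} planted windows in {len(study.planted)} regions "
          f"(fold change {study.planted[0].fold_change:.0f})")


if __name__ == "__main__":
    main()
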