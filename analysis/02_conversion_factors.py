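"""Estimate cluster-to-species conversion factors and the species census.

For each marker gene, genome-derived sequences are rarefied along a log
grid and the zero-intercept slope of species on clusters gives the
conversion factor; cluster counts times factors give per-marker species
estimates, summarized as the cross-marker median.
"""

import pandas as pd

import microcensus as mc
from microcensus.io import read_sequences_tsv, write_tsv

OUT = "results/analysis"
SEED = 42


def main() -> None:
    table = read_sequences_tsv(f"{OUT}/sequences.tsv")
    labels = dict(
        pd.read_csv(f"{OUT}/species_labels.tsv", sep="\t", dtype=str).values
    )
    rows, fits, cluster_counts = [], {}, {}
    for marker in table.markers:
        fit = mc.estimate_conversion_factor(table, labels, marker, seed=SEED)
        fits[marker] = fit
        cluster_counts[marker] = table.subset(marker)["cluster_id"].nunique()
        rows.append(
            {
                "marker_gene": marker,
                "factor": fit.factor,
                "std_error": fit.std_error,
                "n_points": fit.n_points,
                "clusters": cluster_counts[marker],
            }
        )
        print(f"{marker}: factor {fit.factor:.3f} +- {fit.std_error:.4f} "
              f"({cluster_counts[marker]} clusters)")
    write_tsv(pd.DataFrame(rows), f"{OUT}/conversion_fits.tsv")

    summary = mc.estimate_species_counts(cluster_counts, fits)
    print(f"estimated species: median {summary['median']:.0f} "
          f"+- {summary['sd']:.0f} across {summary['n_markers']} markers")
    kept = mc.filter_marker_genes(summary["per_marker"])
    print(f"markers within 20% of the median: {sorted(kept)}")


if __name__ == "__main__":
    main()
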