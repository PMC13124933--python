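"""Map significant SNPs to genes (+-10 kb) and count direct pleiotropy.

Reads the study files written by 01_simulate.py; writes the gene-trait
association table and the per-gene ARD-/ARC-pleiotropy profile.
"""

import argparse
from pathlib import Path

import pandas as pd

from agenet.mapping import compute_pleiotropy, map_snps_to_genes


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
    ap.add_argument("--flank", type=int, default=10_000)
    args = ap.parse_args()
    d = args.outdir / "study"

    snps = pd.read_csv(d / "snp_table.tsv", sep="\t", dtype={"chrom": str})
    ranges = pd.read_csv(d / "gene_ranges.tsv", sep="\t", dtype={"chrom": str})
    arc_map = dict(pd.read_csv(d / "arc_map.tsv", sep="\t").values)

    assoc = map_snps_to_genes(snps, ranges, flank=args.flank, arc_map=arc_map)
    pleiotropy = compute_pleiotropy(assoc)
    assoc.to_frame().to_csv(args.outdir / "associations.tsv", sep="\t", index=False)
    pleiotropy.to_csv(args.outdir / "pleiotropy.tsv", sep="\t", index=False)

    high = pleiotropy[pleiotropy["pleiotropy_class"] == "high"]
    print(f"{len(assoc.genes)} genes associated with at least one ARD")
    print(f"{len(high)} genes with high ARC-pleiotropy (>= 4 clusters)")
    print(pleiotropy["arc_pleiotropy"].value_counts().sort_index().to_string())


if __name__ == "__main__":
    main()
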