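"""Position of gene groups in the pathway DAG hierarchy.

Computes per-gene mean finite distances to roots and leaves (plus degrees and
betweenness) and prints where each analysis group sits between regulatory
roots and terminal leaves.
"""

import argparse
from pathlib import Path

import pandas as pd

from agenet.hierarchy import hierarchy_distances
from agenet.mapping import associations_from_frame
from agenet.synthetic import read_study


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    study = read_study(args.outdir / "study")
    assoc = associations_from_frame(pd.read_csv(args.outdir / "associations.tsv", sep="\t"))
    pleio = pd.read_csv(args.outdir / "pleiotropy.tsv", sep="\t")
    table = hierarchy_distances(study.kegg_dag)
    table.to_csv(args.outdir / "hierarchy.tsv", sep="\t")

    groups = {"GenAgeHum": study.ageing_like,
              "Diseases": set(assoc.genes),
              "HighPleio": set(pleio.loc[pleio["pleiotropy_class"] == "high", "gene"])}
    print(f"DAG: {len(table)} genes, "
          f"{int((table['in_degree'] == 0).sum())} roots, "
          f"{int((table['out_degree'] == 0).sum())} leaves")
    for label, members in groups.items():
        sub = table[table.index.isin(members)]
        print(f"{label}: root_mean {sub['root_mean'].mean():.2f}, "
              f"leaf_mean {sub['leaf_mean'].mean():.2f} (n={len(sub)})")


if __name__ == "__main__":
    main()
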