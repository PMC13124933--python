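"""Coexpression coherence and tissue specificity of the gene groups.

Computes the group x group mean absolute-coexpression matrix (diagonal =
intra-set coherence) and per-gene Tau, then prints the coherence/specificity
polarity between ageing-like and pleiotropic-like genes.
"""

import argparse
from pathlib import Path

import pandas as pd

from agenet.coexpression import group_mean_matrix
from agenet.mapping import associations_from_frame
from agenet.synthetic import read_study
from agenet.tissue import compute_tau


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    study = read_study(args.outdir / "study")
    assoc = associations_from_frame(pd.read_csv(args.outdir / "associations.tsv", sep="\t"))
    pleio = pd.read_csv(args.outdir / "pleiotropy.tsv", sep="\t")
    groups = {"GenAgeHum": study.ageing_like,
              "Diseases": set(assoc.genes),
              "HighPleio": set(pleio.loc[pleio["pleiotropy_class"] == "high", "gene"])}
    for arc in sorted(set(assoc.arc_map.values())):
        groups[arc] = assoc.genes_for_arc(arc)

    cox = group_mean_matrix(study.coexpr, groups)
    cox.to_csv(args.outdir / "coexpression_groups.tsv", sep="\t")
    tau = compute_tau(study.expression)
    tau.to_csv(args.outdir / "tau.tsv", sep="\t")

    print("intra-set coexpression (diagonal):")
    print(cox.round(3).to_string())
    for label, members in (("ageing-like", study.ageing_like),
                           ("pleio-like", study.pleio_like),
                           ("diseases", set(assoc.genes))):
        sub = tau[tau.index.isin(members)]
        print(f"mean Tau {label}: {sub.mean():.3f} (n={len(sub)})")


if __name__ == "__main__":
    main()
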