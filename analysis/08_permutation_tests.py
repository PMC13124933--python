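"""Size-matched permutation tests of the group contrasts.

Tests, against 10,000 size-matched random gene sets: ARC-interaction means
per group per layer (Bonferroni family 16 = 4 groups x 4 layers), mean Tau
per group (family 4), and mean leaf-distance in the pathway DAG (family 4).
Writes one results table mirroring observed / null mean / null sd /
difference / p / p_adj.
"""

import argparse
from pathlib import Path

import pandas as pd

from agenet.hierarchy import hierarchy_distances
from agenet.mapping import associations_from_frame
from agenet.permutation import permutation_null_mean
from agenet.synthetic import read_study
from agenet.tissue import compute_tau


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
    ap.add_argument("--n-perm", type=int, default=10_000)
    ap.add_argument("--seed", type=int, default=42)
    args = ap.parse_args()

    study = read_study(args.outdir / "study")
    assoc = associations_from_frame(pd.read_csv(args.outdir / "associations.tsv", sep="\t"))
    pleio = pd.read_csv(args.outdir / "pleiotropy.tsv", sep="\t")
    groups = {"GenAgeHum": study.ageing_like,
              "Diseases": set(assoc.genes),
              "HighPleio": set(pleio.loc[pleio["pleiotropy_class"] == "high", "gene"]),
              "PleioLike": study.pleio_like}
    rows = []

    inter = pd.read_csv(args.outdir / "arc_interactions.tsv", sep="\t", index_col=0)
    for layer in inter.columns:
        values = inter[layer].dropna().astype(float)
        for label in ("GenAgeHum", "Diseases", "HighPleio"):
            members = set(groups[label]) & set(values.index)
            if len(members) < 2:
                continue
            res = permutation_null_mean(values, members, n_perm=args.n_perm,
                                        seed=args.seed, family_size=16,
                                        label=f"arc_interactions:{layer}:{label}")
            rows.append({"metric": "arc_interactions", "network": layer,
                         "group": label, **res.to_dict()})

    tau = compute_tau(study.expression)
    for label in ("GenAgeHum", "Diseases", "HighPleio", "PleioLike"):
        members = set(groups[label]) & set(tau.index)
        res = permutation_null_mean(tau, members, n_perm=args.n_perm, seed=args.seed,
                                    family_size=4, label=f"tau:{label}")
        rows.append({"metric": "tau", "network": "-", "group": label, **res.to_dict()})

    leaf = hierarchy_distances(study.kegg_dag)["leaf_mean"].dropna()
    for label in ("GenAgeHum", "Diseases", "HighPleio", "PleioLike"):
        members = set(groups[label]) & set(leaf.index)
        if len(members) < 2:
            continue
        res = permutation_null_mean(leaf, members, n_perm=args.n_perm, seed=args.seed,
                                    family_size=4, label=f"leaf_mean:{label}")
        rows.append({"metric": "leaf_mean", "network": "KEGG-DAG", "group": label,
                     **res.to_dict()})

    out = pd.DataFrame(rows).drop(columns="label")
    out.to_csv(args.outdir / "permutation_results.tsv", sep="\t", index=False)
    sig = out[out["p_adj"] < 0.05]
    print(out[["metric", "network", "group", "observed", "null_mean",
               "difference", "p", "p_adj"]].round(4).to_string(index=False))
    print(f"\n{len(sig)}/{len(out)} contrasts significant after Bonferroni")


if __name__ == "__main__":
    main()
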