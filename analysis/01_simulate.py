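"""Generate the synthetic study: the inputs every later stage reads.

Writes gene ranges, the per-disease significant-SNP table, the disease->cluster
map, the four network layers, the pathway DAG, the coexpression and expression
matrices, and the two planted gene sets under <outdir>/study/.
"""

import argparse
from pathlib import Path

import yaml

from agenet.synthetic import StudyConfig, generate_study, write_study


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--config", type=Path, default=None,
                    help="optional YAML with StudyConfig fields")
    args = ap.parse_args()

    fields = yaml.safe_load(args.config.read_text()) if args.config else {}
    fields.setdefault("seed", args.seed)
    study = generate_study(StudyConfig(**fields))
    paths = write_study(study, args.outdir / "study")

    print(f"study written to {args.outdir / 'study'} ({len(paths)} files)")
    print(f"genes: {len(study.genes)}, ARDs: {study.config.n_ards}, "
          f"ARCs: {study.config.n_arcs}, SNPs: {len(study.snp_table)}")
    for name, g in study.layers.items():
        print(f"layer {name}: {g.number_of_nodes()} nodes, {g.number_of_edges()} edges")
    print(f"planted: {len(study.ageing_like)} ageing-like, "
          f"{len(study.pleio_like)} pleiotropic-like genes")


if __name__ == "__main__":
    main()
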