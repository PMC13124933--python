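"""Summarise the four network layers and gene-set coverage on each.

Reads the study and the association/pleiotropy tables; writes a JSON summary
(node/edge counts plus how many genes of each analysis set each layer holds).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from agenet.layers import NetworkLayer, layer_summary, neighbours_of_set
from agenet.synthetic import read_study


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    study = read_study(args.outdir / "study")
    pleio = pd.read_csv(args.outdir / "pleiotropy.tsv", sep="\t")
    assoc = pd.read_csv(args.outdir / "associations.tsv", sep="\t")
    diseases = set(assoc["gene"])
    ppi = NetworkLayer("PPI", study.layers["PPI"])
    groups = {
        "GenAgeHum": study.ageing_like,
        "Diseases": diseases,
        "Neighbours": neighbours_of_set(ppi, diseases),
        "HighPleio": set(pleio.loc[pleio["pleiotropy_class"] == "high", "gene"]),
    }
    summaries = [layer_summary(NetworkLayer(n, g), groups)
                 for n, g in study.layers.items()]
    out = args.outdir / "layer_summary.json"
    out.write_text(json.dumps(summaries, indent=2))
    for s in summaries:
        print(f"{s['name']}: {s['nodes']} nodes / {s['edges']} edges; "
              f"coverage {s['coverage']}")


if __name__ == "__main__":
    main()
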