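"""SNP-to-gene mapping and direct pleiotropy.

Significant SNPs are assigned to every gene whose body (plus a symmetric
flank, 10 kb by default, boundaries inclusive) contains the SNP position;
coordinates are 1-based inclusive throughout.  Gene-level disease (ARD)
associations are aggregated to disease clusters (ARCs) through the cluster
map, and pleiotropy is counted at both levels: a gene associated with four or
more distinct ARCs is classed as high ARC-pleiotropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HIGH_PLEIOTROPY_MIN_ARCS = 4

__all__ = [
    "GeneTraitAssociations",
    "map_snps_to_genes",
    "associations_from_frame",
    "compute_pleiotropy",
    "HIGH_PLEIOTROPY_MIN_ARCS",
]


@dataclass
class GeneTraitAssociations:
    """gene -> {ARD} with the derived gene -> {ARC} view.

    Only genes with at least one association are stored; the ARC set of a
    gene is exactly the image of its ARD set under ``arc_map``.
    """

    ards: dict  # gene -> set of ard ids
    arc_map: dict  # ard -> arc
    arcs: dict = field(init=False)

    def __post_init__(self) -> None:
        self.ards = {g: set(a) for g, a in self.ards.items() if a}
        self.arcs = {g: {self.arc_map[a] for a in ards} for g, ards in self.ards.items()}

    @property
    def genes(self) -> set:
        return set(self.ards)

    def genes_for_ard(self, ard: str) -> set:
        return {g for g, ards in self.ards.items() if ard in ards}

    def genes_for_arc(self, arc: str) -> set:
        return {g for g, arcs in self.arcs.items() if arc in arcs}

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, a, self.arc_map[a]) for g in sorted(self.ards) for a in sorted(self.ards[g])]
        return pd.DataFrame(rows, columns=["gene", "ard_id", "arc_id"])


def _check_coordinates(ranges: pd.DataFrame) -> pd.DataFrame:
    required = {"gene", "chrom", "start", "end"}
    if not required <= set(ranges.columns):
        raise ValueError(f"gene range table must have columns {sorted(required)}")
    ranges = ranges.drop_duplicates(subset=["gene", "chrom", "start", "end"])
    if (ranges["start"] > ranges["end"]).any():
        raise ValueError("malformed gene range: start > end")
    if (ranges["start"] < 1).any():
        raise ValueError("coordinates are 1-based; start must be >= 1")
    return ranges


def map_snps_to_genes(
    snps: pd.DataFrame,
    ranges: pd.DataFrame,
    flank: int = 10_000,
    arc_map: Mapping[str, str] | None = None,
) -> GeneTraitAssociations:
    """Assign each SNP to all genes within the body or +-``flank`` bp.

    A SNP at position ``pos`` on a matching chromosome is assigned to gene
    ``g`` iff ``start - flank <= pos <= end + flank`` (both bounds inclusive);
    a SNP overlapping k genes contributes to all k.  The gene then carries the
    ARD of every one of its SNPs.  SNPs on chromosomes absent from the range
    table are skipped with a warning; duplicate (gene, ARD) pairs collapse.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    if not {"snp", "chrom", "pos", "ard_id"} <= set(snps.columns):
        raise ValueError("SNP table must have columns snp, chrom, pos, ard_id")
    if (pd.to_numeric(snps["pos"], errors="coerce").isna()).any():
        raise ValueError("malformed SNP coordinate")
    ranges = _check_coordinates(ranges)
    if arc_map is None:
        arc_map = {}
    arc_map = dict(arc_map)

    assoc: dict = {}
    known_chroms = set(ranges["chrom"].astype(str))
    for chrom, chunk in snps.groupby(snps["chrom"].astype(str)):
        if chrom not in known_chroms:
            logger.warning("skipping %d SNPs on unknown chromosome %r", len(chunk), chrom)
            continue
        sub = ranges[ranges["chrom"].astype(str) == chrom]
        starts = sub["start"].to_numpy(dtype=np.int64) - flank
        ends = sub["end"].to_numpy(dtype=np.int64) + flank
        names = sub["gene"].to_numpy()
        pos = chunk["pos"].to_numpy(dtype=np.int64)
        ards = chunk["ard_id"].to_numpy()
        # broadcast overlap test; desk-scale tables make this cheap
        hits = (pos[:, None] >= starts[None, :]) & (pos[:, None] <= ends[None, :])
        si, gi = np.nonzero(hits)
        for s, g in zip(si, gi):
            assoc.setdefault(str(names[g]), set()).add(str(ards[s]))

    missing = {a for ards in assoc.values() for a in ards} - set(arc_map)
    for a in sorted(missing):
        arc_map[a] = a  # identity cluster for unmapped ARDs
    if missing:
        logger.warning("%d ARDs missing from arc_map; mapped to themselves", len(missing))
    return GeneTraitAssociations(ards=assoc, arc_map=arc_map)


def associations_from_frame(df: pd.DataFrame, arc_map: Mapping[str, str] | None = None) -> GeneTraitAssociations:
    """Rebuild associations from a (gene, ard_id[, arc_id]) long table."""
    ards: dict = {}
    for g, a in zip(df["gene"], df["ard_id"]):
        ards.setdefault(str(g), set()).add(str(a))
    if arc_map is None:
        arc_map = dict(zip(df["ard_id"].astype(str), df["arc_id"].astype(str)))
    return GeneTraitAssociations(ards=ards, arc_map=dict(arc_map))


def compute_pleiotropy(assoc: GeneTraitAssociations) -> pd.DataFrame:
    """Per-gene direct pleiotropy at ARD and ARC level.

    Returns columns ``gene, ard_pleiotropy, arc_pleiotropy, pleiotropy_class``
    where class is ``high`` iff the gene is associated with at least
    ``HIGH_PLEIOTROPY_MIN_ARCS`` (four) distinct ARCs.
    """
    rows = []
    for g in sorted(assoc.ards):
        n_ard = len(assoc.ards[g])
        n_arc = len(assoc.arcs[g])
        assert n_arc <= n_ard
        rows.append((g, n_ard, n_arc,
                     "high" if n_arc >= HIGH_PLEIOTROPY_MIN_ARCS else "low"))
    return pd.DataFrame(rows, columns=["gene", "ard_pleiotropy", "arc_pleiotropy",
                                       "pleiotropy_class"])
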