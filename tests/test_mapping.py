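"""SNP-to-gene mapping semantics and direct pleiotropy counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from agenet.mapping import GeneTraitAssociations, compute_pleiotropy, map_snps_to_genes

RANGES = pd.DataFrame({
    "gene": ["A", "B", "C"],
    "chrom": ["1", "1", "2"],
    "start": [100_000, 150_000, 100_000],
    "end": [120_000, 170_000, 130_000],
})

ARC_MAP = {"stroke": "Cardiovascular", "hypertension": "Cardiovascular",
           "arthritis": "Musculoskeletal", "diabetes": "Endocrine"}


def _snps(rows):
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "ard_id"])


def test_snp_in_gene_body_is_assigned():
    assoc = map_snps_to_genes(_snps([("s1", "1", 110_000, "stroke")]), RANGES,
                              arc_map=ARC_MAP)
    assert assoc.ards == {"A": {"stroke"}}


@pytest.mark.parametrize("pos,hit", [
    (90_000, True),    # exactly 10 kb upstream: boundary inclusive
    (89_999, False),   # one bp beyond the flank
    (130_000, True),   # exactly 10 kb downstream
    (130_001, False),
])
def test_flank_boundary_inclusive(pos, hit):
    assoc = map_snps_to_genes(_snps([("s1", "1", pos, "stroke")]), RANGES.iloc[[0]],
                              flank=10_000, arc_map=ARC_MAP)
    assert ("A" in assoc.ards) == hit


def test_snp_overlapping_two_genes_assigned_to_both():
    overlapping = pd.DataFrame({"gene": ["A", "B"], "chrom": ["1", "1"],
                                "start": [100_000, 140_000],
                                "end": [150_000, 180_000]})
    assoc = map_snps_to_genes(_snps([("s1", "1", 145_000, "stroke")]), overlapping,
                              flank=10_000, arc_map=ARC_MAP)
    assert set(assoc.ards) == {"A", "B"}
    assert assoc.ards["A"] == assoc.ards["B"] == {"stroke"}


def test_unknown_chromosome_skipped_with_warning(caplog):
    with caplog.at_level("WARNING"):
        assoc = map_snps_to_genes(_snps([("s1", "7", 110_000, "stroke")]), RANGES,
                                  arc_map=ARC_MAP)
    assert assoc.ards == {}
    assert "unknown chromosome" in caplog.text


def test_malformed_coordinate_raises():
    with pytest.raises(ValueError):
        map_snps_to_genes(_snps([("s1", "1", "oops", "stroke")]), RANGES, arc_map=ARC_MAP)


def test_mapping_matches_intervaltree_oracle():
    """Random SNPs/genes against an independent interval-overlap oracle."""
    from intervaltree import IntervalTree
    rng = np.random.default_rng(0)
    genes = pd.DataFrame({
        "gene": [f"g{i}" for i in range(40)],
        "chrom": rng.choice(["1", "2"], size=40),
        "start": rng.integers(1, 500_000, size=40),
    })
    genes["end"] = genes["start"] + rng.integers(1_000, 40_000, size=40)
    snps = pd.DataFrame({
        "snp": [f"s{i}" for i in range(300)],
        "chrom": rng.choice(["1", "2"], size=300),
        "pos": rng.integers(1, 550_000, size=300),
        "ard_id": rng.choice(["d1", "d2", "d3"], size=300),
    })
    flank = 10_000
    trees = {}
    for _, r in genes.iterrows():
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start - flank, r.end + flank + 1, r.gene)
    expected: dict = {}
    for _, s in snps.iterrows():
        for iv in trees.get(s.chrom, IntervalTree())[s.pos]:
            expected.setdefault(iv.data, set()).add(s.ard_id)
    assoc = map_snps_to_genes(snps, genes, flank=flank, arc_map={})
    assert assoc.ards == expected


@given(st.integers(0, 20_000), st.integers(0, 20_000))
def test_increasing_flank_never_removes_associations(f1, f2):
    lo, hi = sorted((f1, f2))
    snps = _snps([("s1", "1", 95_000, "stroke"), ("s2", "1", 132_500, "diabetes"),
                  ("s3", "2", 99_000, "arthritis")])
    small = map_snps_to_genes(snps, RANGES, flank=lo, arc_map=ARC_MAP).ards
    large = map_snps_to_genes(snps, RANGES, flank=hi, arc_map=ARC_MAP).ards
    for g, ards in small.items():
        assert ards <= large.get(g, set())


def test_pleiotropy_worked_examples():
    assoc = GeneTraitAssociations(
        ards={"X": {"stroke", "hypertension"},
              "Y": {"stroke", "hypertension", "arthritis"},
              "Z": {"stroke", "arthritis", "diabetes", "gout"}},
        arc_map={**ARC_MAP, "gout": "Renal"})
    table = compute_pleiotropy(assoc).set_index("gene")
    assert table.at["X", "ard_pleiotropy"] == 2
    assert table.at["Y", "arc_pleiotropy"] == 2  # two ARDs share Cardiovascular
    assert table.at["Z", "arc_pleiotropy"] == 4
    assert table.at["Z", "pleiotropy_class"] == "high"
    assert table.at["X", "pleiotropy_class"] == "low"
    assert (table["arc_pleiotropy"] <= table["ard_pleiotropy"]).all()


def test_roundtrip_recovers_planted_truth(small_study, small_assoc):
    truth = {g: set(v) for g, v in small_study.truth.items()}
    assert small_assoc.ards == truth
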