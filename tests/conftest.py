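"""Shared fixtures: reconstructed pedigrees, small panels, prioritised-variant rows."""

from __future__ import annotations

import numpy as np
import pytest

from consangmap import (
    GenotypeMatrix,
    Individual,
    Marker,
    Pedigree,
    VariantRecord,
    family_fixtures,
)
from consangmap.pedigree import CD, FEMALE, MALE, UC, UNAFFECTED


@pytest.fixture(scope="session")
def families() -> dict[str, Pedigree]:
    return family_fixtures()


def make_individual(iid, fam="F", father=None, mother=None, sex=MALE, aff=UNAFFECTED):
    return Individual(id=iid, family_id=fam, father_id=father, mother_id=mother,
                      sex=sex, affection=aff)


@pytest.fixture(scope="session")
def first_cousin_pedigree() -> Pedigree:
    """Grandparents, two sib-parents with founder spouses, a cousin couple
    and their child (F = 1/16)."""
    i = make_individual
    return Pedigree([
        i("G1"), i("G2", sex=FEMALE),
        i("P1", father="G1", mother="G2"),
        i("S1", sex=FEMALE),
        i("P2", father="G1", mother="G2", sex=FEMALE),
        i("S2"),
        i("C1", father="P1", mother="S1"),
        i("C2", father="S2", mother="P2", sex=FEMALE),
        i("K", father="C1", mother="C2"),
    ])


@pytest.fixture(scope="session")
def double_first_cousin_pedigree() -> Pedigree:
    """Two founder couples, cross-married sibs, double first cousins and
    their child (F = 1/8)."""
    i = make_individual
    return Pedigree([
        i("F1"), i("F2", sex=FEMALE), i("F3"), i("F4", sex=FEMALE),
        i("A1", father="F1", mother="F2"),
        i("A2", father="F1", mother="F2", sex=FEMALE),
        i("B1", father="F3", mother="F4", sex=FEMALE),
        i("B2", father="F3", mother="F4"),
        i("C1", father="A1", mother="B1"),
        i("C2", father="B2", mother="A2", sex=FEMALE),
        i("D", father="C1", mother="C2"),
    ])


def pedigree_parent_map(ped: Pedigree) -> dict[str, tuple[str | None, str | None]]:
    return {ind.id: (ind.father_id, ind.mother_id) for ind in ped}


def single_sample_matrix(calls, spacing_bp=25_000, chrom="1", maf=0.3,
                         sample="S1") -> GenotypeMatrix:
    """One-sample matrix with evenly spaced markers for detector tests."""
    markers = [
        Marker(id=f"m{k}", chrom=chrom, bp=1 + k * spacing_bp, ref_maf=maf)
        for k in range(len(calls))
    ]
    return GenotypeMatrix([sample], markers, np.array([calls], dtype=np.int8))


def multi_sample_matrix(rows: dict[str, list[int]], spacing_bp=25_000, chrom="1",
                        maf=0.3) -> GenotypeMatrix:
    n = len(next(iter(rows.values())))
    markers = [
        Marker(id=f"m{k}", chrom=chrom, bp=1 + k * spacing_bp, ref_maf=maf)
        for k in range(n)
    ]
    return GenotypeMatrix(
        list(rows), markers, np.array(list(rows.values()), dtype=np.int8)
    )


# The 19 prioritised homozygous variants, re-encoded as records:
# (gene, consequence, sift, polyphen, cadd, primary-population MAF,
#  population-specific MAF); None = absent from the reference data set.
PRIORITISED_ROWS = [
    ("FGFR2", "missense", "tolerated", "benign", 22.4, 0.0049, 0.0065),
    ("DMBT1", "missense", "deleterious", "unknown", 12.66, 0.015, None),
    ("DENND3", "missense", "deleterious", "possibly_damaging", 18.83, None, None),
    ("PTGS1", "missense", "deleterious", "benign", 23.3, 0.0072, 0.0146),
    ("WDR38", "missense", "deleterious", "possibly_damaging", 28.4, None, None),
    ("CERCAM", "missense", "deleterious", "probably_damaging", 22.9, 0.0006, 0.0005),
    ("AAGAB", "missense", "tolerated", "possibly_damaging", 25.8, None, None),
    ("MAP4K3", "missense", "tolerated", "benign", 23.9, 0.0008, None),
    ("MAP4K4", "missense", "tolerated_lc", "possibly_damaging", 23.3, 0.0002, 0.0005),
    ("NIPSNAP3B", "missense", "deleterious", "possibly_damaging", 27.7, 0.0267, 0.0347),
    ("WHAMM", "missense", "deleterious", "possibly_damaging", 29.5, 4.47e-05, None),
    ("ADAMTSL3", "missense", "tolerated", "probably_damaging", 24.4, 0.0163, 0.0091),
    ("AKAP13", "missense", "deleterious_lc", "benign", 16.55, 0.0415, 0.0267),
    ("LRRK1", "missense", "deleterious", "probably_damaging", 29.8, 0.0044, 0.0171),
    ("COQ2", "stop_gained", "unknown", "unknown", 23.0, 0.0166, 0.0304),
    ("IL36B", "missense", "deleterious_lc", "benign", 3.083, 0.013, 0.0222),
    ("C5", "missense", "deleterious", "possibly_damaging", 25.0, 0.0054, 0.0044),
    ("PALM3", "missense", "deleterious", "possibly_damaging", 26.8, 0.0245, 0.0319),
    ("MYO9B", "missense", "deleterious", "benign", 23.9, 0.0014, 0.0024),
]


def prioritised_variant_records() -> list[VariantRecord]:
    out = []
    for k, (gene, csq, sift, polyphen, cadd, maf1, maf2) in enumerate(PRIORITISED_ROWS):
        out.append(
            VariantRecord(
                chrom="1", pos=1000 + k, ref="A", alt="G", gene=gene,
                consequence=csq, sift=sift, polyphen=polyphen, cadd_phred=cadd,
                tranche_sensitivity=99.0,
                maf={"primary": maf1, "secondary": maf2},
            )
        )
    return out
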