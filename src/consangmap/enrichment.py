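"""Exact 2x2 gene-set association and homozygous-burden summaries.

The enrichment question: are the protein-coding genes inside case-shared
runs of homozygosity over-represented in a curated disease gene list,
relative to the genome-wide gene universe? The test conditions on the
margins of the 2x2 table (in ROH / not, in list / not) and reports the
one-sided upper hypergeometric tail P(X >= a) — the enrichment direction —
together with the raw cross-product odds ratio. No multiple-testing
correction is applied.

Zero-cell convention: the odds ratio is reported as 0.0 (empty overlap
numerator) or ``inf`` (empty denominator cell) with ``zero_cell=True``;
no Haldane-Anscombe correction is used.

Burden comparisons of homozygous variant counts are restricted to full
siblings, who expect an equal fraction of their genome in the homozygous
state — comparisons across pedigree positions would confound inbreeding
level with genotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from .pedigree import Pedigree
from .variants import (
    HOM_ALT,
    FilterThresholds,
    VariantRecord,
    frequency_class,
    is_damaging,
)

__all__ = [
    "EnrichmentResult",
    "exact_2x2",
    "roh_gene_enrichment",
    "sibling_homozygous_burden",
    "DEFAULT_GENE_UNIVERSE",
]

#: Default protein-coding gene universe size for the enrichment test.
DEFAULT_GENE_UNIVERSE = 19_528


@dataclass(frozen=True)
class EnrichmentResult:
    table: tuple[int, int, int, int]  # (a, b, c, d)
    odds_ratio: float
    p_one_sided: float
    zero_cell: bool = False


def exact_2x2(a: int, b: int, c: int, d: int) -> EnrichmentResult:
    """Exact one-sided association test for a 2x2 table.

    ``a`` counts the joint category whose excess is tested (e.g. genes both
    in ROH and in the disease list). P = P(X >= a) for X hypergeometric with
    the table's margins fixed.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("table counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("a table margin is zero")
    zero_cell = (a * d == 0) or (b * c == 0)
    if b * c == 0:
        odds_ratio = 0.0 if a * d == 0 else math.inf
    else:
        odds_ratio = (a * d) / (b * c)
    p = float(stats.hypergeom.sf(a - 1, n, a + b, a + c))
    return EnrichmentResult(
        table=(a, b, c, d), odds_ratio=odds_ratio, p_one_sided=min(1.0, p),
        zero_cell=zero_cell,
    )


def roh_gene_enrichment(
    roh_genes: set[str],
    list_genes: set[str],
    genome_gene_total: int = DEFAULT_GENE_UNIVERSE,
) -> EnrichmentResult:
    """Enrichment of a disease gene list among genes contained in ROH."""
    a = len(roh_genes & list_genes)
    b = len(list_genes - roh_genes)
    c = len(roh_genes - list_genes)
    d = genome_gene_total - a - b - c
    if d < 0:
        raise ValueError(
            "genome_gene_total smaller than the union of ROH and list genes"
        )
    return exact_2x2(a, b, c, d)


def sibling_homozygous_burden(
    variants: Sequence[VariantRecord],
    sibling_ids: Sequence[str],
    ped: Pedigree,
    populations: Sequence[str],
    t: FilterThresholds = FilterThresholds(),
) -> pd.DataFrame:
    """Homozygous-alternate variant counts per sibling, stratified by class.

    Strata: ``any`` (all frequencies), ``uncommon`` (combined MAF below 5%,
    i.e. uncommon or rarer), ``rare`` (below 1%), and ``rare_damaging``.
    Raises unless all listed individuals share both recorded parents.
    """
    if len(sibling_ids) < 2:
        raise ValueError("need at least two siblings")
    parents = {
        (ped.individual(s).father_id, ped.individual(s).mother_id) for s in sibling_ids
    }
    if len(parents) != 1 or None in next(iter(parents)):
        raise ValueError("listed individuals are not full siblings")
    rows = []
    for s in sibling_ids:
        counts = {"sibling": s, "any": 0, "uncommon": 0, "rare": 0, "rare_damaging": 0}
        for v in variants:
            call = v.genotypes.get(s)
            if call is None or call.gt != HOM_ALT:
                continue
            counts["any"] += 1
            cls = frequency_class(v, populations, t)
            if cls == "common":
                continue
            counts["uncommon"] += 1
            if cls in ("rare", "very_rare"):
                counts["rare"] += 1
                if is_damaging(v, t):
                    counts["rare_damaging"] += 1
        rows.append(counts)
    return pd.DataFrame(rows).set_index("sibling")
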