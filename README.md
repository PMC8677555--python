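# consangmap

Family-based genetic analysis of consanguineous multiplex pedigrees:
homozygosity mapping complemented by exome variant prioritisation, as used
to hunt rare, high-impact homozygous variants in families with several
cases of a complex disease (the motivating application is inflammatory
bowel disease — Crohn's disease and ulcerative colitis — in families with
first-cousin matings).

Offspring of consanguineous matings carry long runs of homozygosity (ROH):
chromosomal stretches where both haplotypes descend from a single ancestral
haplotype (autozygosity). If a recessive high-impact variant drives disease
in such a family, affected relatives should share an identical autozygous
segment containing it. `consangmap` implements the full analysis path:

- **`pedigree` / `genotypes`** — validated pedigree graphs (loops from
  consanguinity welcome) with exact kinship φ and inbreeding F by the
  classical recursion; PLINK-style FAM / text `.ped`+`.map` / TSV-dosage I/O.
- **`qc`** — array QC in the canonical order (samples by missingness, then
  markers by missingness and an exact Hardy–Weinberg test at P < 5×10⁻⁸),
  X-homozygosity sex checks, robust pairwise kinship verification, and
  array–exome concordance.
- **`roh`** — run-of-homozygosity detection on common markers
  (≥ 50 homozygous SNPs, ≥ 1 Mb, zero tolerated heterozygotes by default)
  and case-shared *identical* ROH mapping, with control-overlap, gene and
  GWAS-locus annotation.
- **`genedrop`** — gene-dropping simulation of meiosis (Haldane model,
  1 cM/Mb default map) to estimate the pedigree-based probability of
  observed shared autozygosity.
- **`variants`** — exome filter cascade: recalibration-tranche site filter,
  genotype-quality rules (GQ ≥ 30, het allele balance χ² P ≥ 0.001, alt
  depth ≥ 3), no-call-rate filter, dual-population frequency classes,
  permissive damaging definition, proband candidate selection, sibling
  segregation and deceased-parent genotype inference.
- **`enrichment`** — exact one-sided 2×2 gene-set enrichment of ROH gene
  content and sibling homozygous-burden summaries.
- **`synth`** — reconstructions of the four study pedigrees and fully
  synthetic genotype/variant generators with planted ROH, planted
  candidates and single-violation decoys, so the whole pipeline is testable
  offline.

## Worked example

How unlikely is it that the two Crohn's disease cases of the reconstructed
Druze pedigree — the proband V-1 and her uncle III-2, the offspring of a
first-cousin mating — are identically homozygous by descent across a
specific 1 cM window on chromosome 16 (the NOD2 region their shared ROH
covers)?

```python
from consangmap import (DropConfig, default_autosome_map, family_fixtures,
                        shared_autozygosity_probability)

ped = family_fixtures()["DR"]
print(ped.inbreeding("III-2"))          # 0.0625  (first-cousin offspring)
cfg = DropConfig(n_reps=10_000, seed=1, window=("16", 50.2, 51.2))
p, se = shared_autozygosity_probability(ped, ("V-1", "III-2"), cfg,
                                        default_autosome_map())
print(f"{p:.4f} +/- {se:.4f}")          # 0.0037 +/- 0.0006
```

Each replicate drops founder haplotypes through the pedigree with
recombination; the estimate is the fraction of replicates in which all four
haplotypes of the two cases carry one and the same founder haplotype across
the whole window. A probability of a few parts per thousand says that a
shared identical ROH at a prespecified window is a rare event under the
pedigree alone — which is what makes an observed one informative.

The `examples/` directory holds one short script per capability (QC and
kinship verification, homozygosity mapping with a planted region, the
simulation above, variant prioritisation with decoys, and gene-set
enrichment); each prints the numbers it computes and what they mean.

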