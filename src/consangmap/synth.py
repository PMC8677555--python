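"""Synthetic family data: pedigrees, array genotypes and exome variant tables.

Everything the pipeline consumes can be generated here without any
download: reconstructed study pedigrees, marker panels with founder
genotypes transmitted by simulated meiosis, planted case-shared runs of
homozygosity, and annotated variant tables in which planted candidates
survive the full filter cascade while decoy variants each violate exactly
one named criterion.

Genotype model: founder haplotype alleles are drawn independently per
marker (Bernoulli at the marker's minor allele frequency) and transmitted
through the pedigree by gene dropping, so founders conform to
Hardy-Weinberg and relatives share alleles exactly as the pedigree
dictates. Markers are generated without linkage disequilibrium — run-based
ROH detection and the analyses here do not model LD, so LD realism would
add nothing to the tests. Genotyping error is modelled as replacement with
a random population genotype; error and missingness are applied outside
planted regions only, and the markers immediately flanking a planted
region are forced heterozygous in the carriers so that planted region
boundaries are exactly recoverable.

The default panel is a fast desk-scale profile (20,000 markers over four
synthetic chromosomes); :func:`paper_scale_config` gives a ~250,000-marker
panel over the 22 GRCh37 autosomes.

The bundled pedigrees are *reconstructions*: the published pedigree
figures are anonymised, so topologies here are plausible reconstructions
consistent with the described relationships (proband, siblings, uncles,
aunt, first-cousin matings), not ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genedrop import GeneticMap, _drop_once
from .genome import GRCH37_AUTOSOME_BP
from .genotypes import MISSING, GenotypeMatrix, Marker
from .pedigree import CD, FEMALE, MALE, UC, UNAFFECTED, Individual, Pedigree
from .roh import GeneInterval
from .variants import GenotypeCall, VariantRecord, HOM_REF, HET, HOM_ALT, NO_CALL

__all__ = [
    "SynthConfig",
    "PlantSpec",
    "CandidateSpec",
    "DecoySpec",
    "DECOY_KINDS",
    "family_fixtures",
    "paper_scale_config",
    "generate_family_genotypes",
    "generate_variant_table",
    "tiled_gene_panel",
]


@dataclass(frozen=True)
class SynthConfig:
    n_markers: int = 20_000
    chrom_lengths: tuple[tuple[str, int], ...] = (
        ("1", 120_000_000),
        ("2", 100_000_000),
        ("3", 90_000_000),
        ("4", 80_000_000),
    )
    #: Array-marker MAF distribution: uniform on [maf_min, maf_max].
    maf_min: float = 0.05
    maf_max: float = 0.5
    genotype_error_rate: float = 0.002
    missing_rate: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        for rate in (self.genotype_error_rate, self.missing_rate):
            if not 0.0 <= rate < 1.0:
                raise ValueError("rates must be in [0, 1)")
        if not 0.0 < self.maf_min <= self.maf_max <= 0.5:
            raise ValueError("MAF bounds must satisfy 0 < min <= max <= 0.5")

    def genetic_map(self, cm_per_mb: float = 1.0) -> GeneticMap:
        return GeneticMap(
            {c: bp / 1e6 * cm_per_mb for c, bp in self.chrom_lengths}, cm_per_mb
        )


def paper_scale_config(seed: int = 0) -> SynthConfig:
    """A ~250k-marker autosomal panel over the GRCh37 autosomes."""
    return SynthConfig(
        n_markers=250_000,
        chrom_lengths=tuple(GRCH37_AUTOSOME_BP.items()),
        seed=seed,
    )


@dataclass(frozen=True)
class PlantSpec:
    """A structure to plant into generated genotypes.

    ``mode="shared_identical_roh"`` forces every carrier homozygous for the
    same per-marker allele across the region.
    """

    region: tuple[str, int, int]  # (chrom, start_bp, end_bp), 1-based inclusive
    carriers: tuple[str, ...]
    mode: str = "shared_identical_roh"

    def __post_init__(self):
        if self.mode != "shared_identical_roh":
            raise ValueError(f"unknown plant mode {self.mode!r}")
        if not self.carriers:
            raise ValueError("plant needs at least one carrier")


# -- reconstructed study pedigrees ----------------------------------------------------


def _ind(fam, iid, father=None, mother=None, sex=MALE, aff=UNAFFECTED):
    return Individual(
        id=iid, family_id=fam, father_id=father, mother_id=mother, sex=sex,
        affection=aff, generation_label=iid,
    )


def _aj_pedigree() -> Pedigree:
    """Ashkenazi family reconstruction: three affected siblings (all CD)
    born to a consanguineous couple, one living unaffected sibling, and two
    deceased unaffected siblings each represented by two genotyped
    descendants (used for deceased-parent genotype inference)."""
    f = "AJ"
    inds = [
        _ind(f, "I-1"), _ind(f, "I-2", sex=FEMALE),
        _ind(f, "II-1", "I-1", "I-2"),
        _ind(f, "II-2", sex=FEMALE),
        _ind(f, "II-3", "I-1", "I-2", sex=FEMALE),
        _ind(f, "II-4"),
        _ind(f, "III-1", "II-1", "II-2"),
        _ind(f, "III-2", "II-4", "II-3", sex=FEMALE),
        _ind(f, "IV-1", "III-1", "III-2", aff=CD),
        _ind(f, "IV-2", "III-1", "III-2", aff=CD),
        _ind(f, "IV-3", "III-1", "III-2", sex=FEMALE, aff=CD),
        _ind(f, "IV-4", "III-1", "III-2"),
        _ind(f, "IV-5", "III-1", "III-2"),          # deceased, not genotyped
        _ind(f, "IV-6", "III-1", "III-2", sex=FEMALE),  # deceased, not genotyped
        _ind(f, "IV-7", sex=FEMALE),
        _ind(f, "IV-8"),
        _ind(f, "V-1", "IV-5", "IV-7"),
        _ind(f, "V-2", "IV-5", "IV-7", sex=FEMALE),
        _ind(f, "V-3", "IV-8", "IV-6"),
        _ind(f, "V-4", "IV-8", "IV-6", sex=FEMALE),
    ]
    return Pedigree(inds, proband_id="IV-1")


def _dr_pedigree() -> Pedigree:
    """Druze family reconstruction.

    III-2 (CD) is the offspring of a first-cousin mating (II-5 x II-6).
    The proband V-1 (CD) descends from III-2's sibship on both sides: her
    parents IV-1 (UC) and IV-2 are first cousins, children of III-2's
    brother III-4 and sister III-5. III-3 is an uncle with UC.
    """
    f = "DR"
    inds = [
        _ind(f, "I-1"), _ind(f, "I-2", sex=FEMALE),
        _ind(f, "II-1", "I-1", "I-2"),
        _ind(f, "II-2", sex=FEMALE),
        _ind(f, "II-3", "I-1", "I-2", sex=FEMALE),
        _ind(f, "II-4"),
        _ind(f, "II-5", "II-1", "II-2"),
        _ind(f, "II-6", "II-4", "II-3", sex=FEMALE),
        _ind(f, "III-1", "II-5", "II-6"),
        _ind(f, "III-2", "II-5", "II-6", aff=CD),
        _ind(f, "III-3", "II-5", "II-6", aff=UC),
        _ind(f, "III-4", "II-5", "II-6"),
        _ind(f, "III-5", "II-5", "II-6", sex=FEMALE),
        _ind(f, "III-6", sex=FEMALE),
        _ind(f, "III-7"),
        _ind(f, "IV-1", "III-4", "III-6", sex=FEMALE, aff=UC),
        _ind(f, "IV-2", "III-7", "III-5"),
        _ind(f, "V-1", "IV-2", "IV-1", sex=FEMALE, aff=CD),
        _ind(f, "V-2", "IV-2", "IV-1"),
        _ind(f, "V-3", "IV-2", "IV-1", sex=FEMALE),
        _ind(f, "V-4", "IV-2", "IV-1"),
    ]
    return Pedigree(inds, proband_id="V-1")


def _am_cd_pedigree() -> Pedigree:
    """Arab Muslim family (CD) reconstruction: two affected brothers born
    to first cousins, with unaffected siblings as family controls."""
    f = "AM-CD"
    inds = [
        _ind(f, "II-1"), _ind(f, "II-2", sex=FEMALE),
        _ind(f, "III-1", "II-1", "II-2"),
        _ind(f, "III-2", sex=FEMALE),
        _ind(f, "III-3", "II-1", "II-2", sex=FEMALE),
        _ind(f, "III-4"),
        _ind(f, "IV-1", "III-1", "III-2"),
        _ind(f, "IV-2", "III-4", "III-3", sex=FEMALE),
        _ind(f, "V-1", "IV-1", "IV-2", aff=CD),
        _ind(f, "V-2", "IV-1", "IV-2", sex=FEMALE),
        _ind(f, "V-3", "IV-1", "IV-2", aff=CD),
        _ind(f, "V-4", "IV-1", "IV-2"),
    ]
    return Pedigree(inds, proband_id="V-1")


def _am_uc_pedigree() -> Pedigree:
    """Arab Muslim family (UC) reconstruction: two affected sisters born to
    first cousins, plus an affected aunt (IV-16, CD) and a larger set of
    unaffected relatives serving as family controls."""
    f = "AM-UC"
    inds = [
        _ind(f, "II-1"), _ind(f, "II-2", sex=FEMALE),
        _ind(f, "III-1", "II-1", "II-2"),
        _ind(f, "III-2", sex=FEMALE),
        _ind(f, "III-3", "II-1", "II-2", sex=FEMALE),
        _ind(f, "III-4"),
        _ind(f, "IV-9", "III-1", "III-2"),
        _ind(f, "IV-13", "III-4", "III-3", sex=FEMALE),
        _ind(f, "IV-14", "III-1", "III-2"),
        _ind(f, "IV-15", "III-4", "III-3", sex=FEMALE),
        _ind(f, "IV-16", "III-4", "III-3", sex=FEMALE, aff=CD),
        _ind(f, "V-1", "IV-14", "IV-15", sex=FEMALE, aff=UC),
        _ind(f, "V-2", "IV-14", "IV-15"),
        _ind(f, "V-3", "IV-14", "IV-15", sex=FEMALE),
        _ind(f, "V-5", "IV-14", "IV-15", sex=FEMALE, aff=UC),
        _ind(f, "V-9", "IV-14", "IV-15"),
        _ind(f, "V-10", "IV-14", "IV-15", sex=FEMALE),
    ]
    return Pedigree(inds, proband_id="V-1")


def family_fixtures() -> dict[str, Pedigree]:
    """Reconstructions of the four consanguineous study families.

    Keys: ``AJ``, ``DR``, ``AM-CD``, ``AM-UC``. See the individual builders
    for the topology each reconstruction encodes.
    """
    return {
        "AJ": _aj_pedigree(),
        "DR": _dr_pedigree(),
        "AM-CD": _am_cd_pedigree(),
        "AM-UC": _am_uc_pedigree(),
    }


# -- genotype generation --------------------------------------------------------------


def _allocate_markers(cfg: SynthConfig, rng: np.random.Generator) -> list[Marker]:
    total_bp = sum(bp for _, bp in cfg.chrom_lengths)
    markers: list[Marker] = []
    remaining = cfg.n_markers
    for k, (chrom, bp) in enumerate(cfg.chrom_lengths):
        n = remaining if k == len(cfg.chrom_lengths) - 1 else round(
            cfg.n_markers * bp / total_bp
        )
        n = min(n, remaining)
        remaining -= n
        # Distinct uniform positions without materialising the full range.
        positions = np.unique(rng.integers(1, bp + 1, size=max(1, int(n * 1.2))))
        while positions.size < n:
            positions = np.unique(
                np.concatenate([positions, rng.integers(1, bp + 1, size=n)])
            )
        positions = np.sort(rng.choice(positions, size=n, replace=False))
        mafs = rng.uniform(cfg.maf_min, cfg.maf_max, size=n)
        for j, (pos, maf) in enumerate(zip(positions, mafs)):
            markers.append(
                Marker(
                    id=f"c{chrom}_m{j}", chrom=chrom, bp=int(pos),
                    alleles=("A", "B"), ref_maf=float(maf),
                )
            )
    return markers


def _labels_at(hap, cm_positions: np.ndarray) -> np.ndarray:
    ends = np.array([seg[1] for seg in hap])
    labels = np.array([seg[2] for seg in hap])
    idx = np.minimum(np.searchsorted(ends, cm_positions, side="right"), len(labels) - 1)
    return labels[idx]


def generate_family_genotypes(
    ped: Pedigree,
    cfg: SynthConfig = SynthConfig(),
    plants: Sequence[PlantSpec] = (),
) -> GenotypeMatrix:
    """Simulate an array genotype matrix for every pedigree member.

    Founder haplotypes are sampled per marker from the panel MAFs and
    transmitted by gene dropping; planted regions are then imposed, and
    finally genotyping error and missingness outside planted markers.
    Fixed ``cfg.seed`` gives bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    markers = _allocate_markers(cfg, rng)
    gmap = cfg.genetic_map()
    state = _drop_once(ped, gmap, rng)

    n_labels = 1 + max(
        seg[2]
        for per_chrom in state.values()
        for haps in per_chrom.values()
        for hap in haps
        for seg in hap
    )
    mafs = np.array([m.ref_maf for m in markers])
    hap_alleles = (rng.random((n_labels, len(markers))) < mafs).astype(np.int8)

    sample_ids = [ind.id for ind in ped]
    calls = np.zeros((len(sample_ids), len(markers)), dtype=np.int8)
    chrom_index: dict[str, np.ndarray] = {}
    cm_index: dict[str, np.ndarray] = {}
    marker_chroms = np.array([m.chrom for m in markers])
    marker_cm = np.array([gmap.bp_to_cm(m.chrom, m.bp) for m in markers])
    for chrom, _ in cfg.chrom_lengths:
        sel = np.flatnonzero(marker_chroms == chrom)
        chrom_index[chrom] = sel
        cm_index[chrom] = marker_cm[sel]
    for si, s in enumerate(sample_ids):
        for chrom, sel in chrom_index.items():
            hap_a, hap_b = state[s][chrom]
            la = _labels_at(hap_a, cm_index[chrom])
            lb = _labels_at(hap_b, cm_index[chrom])
            calls[si, sel] = hap_alleles[la, sel] + hap_alleles[lb, sel]

    # Plant shared identical ROH and note the protected marker indices.
    protected = np.zeros(len(markers), dtype=bool)
    bps = np.array([m.bp for m in markers])
    for plant in plants:
        chrom, start_bp, end_bp = plant.region
        in_region = (marker_chroms == chrom) & (bps >= start_bp) & (bps <= end_bp)
        idx = np.flatnonzero(in_region)
        if idx.size == 0:
            raise ValueError(f"plant region {plant.region} contains no markers")
        planted_allele = (rng.random(idx.size) < mafs[idx]).astype(np.int8)
        for c in plant.carriers:
            ped.individual(c)  # raises PedigreeError on unknown carriers
        rows = [sample_ids.index(c) for c in plant.carriers]
        for r in rows:
            calls[r, idx] = 2 * planted_allele
        protected[idx] = True
        # Insulate the region so the planted run ends exactly at its
        # boundary markers: the nearest flanking marker on each side (same
        # chromosome) is made heterozygous in every carrier.
        chrom_sel = chrom_index[chrom]
        for flank in (idx[0] - 1, idx[-1] + 1):
            if flank in chrom_sel:
                for r in rows:
                    calls[r, flank] = 1
                protected[flank] = True

    # Genotyping error: replacement with a random population genotype.
    if cfg.genotype_error_rate > 0:
        err = (rng.random(calls.shape) < cfg.genotype_error_rate) & ~protected
        if err.any():
            u = rng.random(calls.shape)
            p_hom_ref = (1 - mafs) ** 2
            p_het = 2 * mafs * (1 - mafs)
            resampled = np.where(
                u < p_hom_ref, 0, np.where(u < p_hom_ref + p_het, 1, 2)
            ).astype(np.int8)
            calls = np.where(err, resampled, calls)
    if cfg.missing_rate > 0:
        miss = (rng.random(calls.shape) < cfg.missing_rate) & ~protected
        calls = np.where(miss, np.int8(MISSING), calls)
    return GenotypeMatrix(sample_ids, markers, calls)


# -- variant-table generation ---------------------------------------------------------


@dataclass(frozen=True)
class CandidateSpec:
    """A variant planted to survive the full prioritisation cascade."""

    gene: str
    case_ids: tuple[str, ...]


@dataclass(frozen=True)
class DecoySpec:
    """A variant violating exactly one named filter criterion."""

    kind: str
    case_ids: tuple[str, ...]

    def __post_init__(self):
        if self.kind not in DECOY_KINDS:
            raise ValueError(f"unknown decoy kind {self.kind!r}")


DECOY_KINDS = (
    "site_tranche",
    "genotype_gq",
    "genotype_alt_depth",
    "genotype_allele_balance",
    "no_call_rate",
    "not_damaging",
    "common_primary",
    "common_secondary",
    "case_not_hom",
    "control_hom",
)

_CLEAN_HOM_ALT = dict(gq=99, ref_depth=0, alt_depth=40)
_CLEAN_HOM_REF = dict(gq=99, ref_depth=40, alt_depth=0)


def _clean_genotypes(sample_ids, case_ids) -> dict[str, GenotypeCall]:
    cases = set(case_ids)
    return {
        s: GenotypeCall(gt=HOM_ALT, **_CLEAN_HOM_ALT)
        if s in cases
        else GenotypeCall(gt=HOM_REF, **_CLEAN_HOM_REF)
        for s in sample_ids
    }


def generate_variant_table(
    ped: Pedigree,
    cfg: SynthConfig,
    planted_candidates: Sequence[CandidateSpec],
    decoys: Sequence[DecoySpec],
    control_ids: Sequence[str] = (),
    n_background: int = 60,
    populations: Sequence[str] = ("gnomad", "gmev"),
    sample_ids: Optional[Sequence[str]] = None,
) -> tuple[list[VariantRecord], pd.DataFrame, dict]:
    """Annotated exome variants with planted candidates and decoys.

    Returns ``(records, annotation_table, truth)`` where ``truth`` maps
    ``"planted"`` to the planted variant keys and ``"decoys"`` to a
    {kind: key} dict. Background variants carry a realistic mix of
    consequences and frequency classes and clean genotypes drawn from
    Hardy-Weinberg at the combined frequency.
    """
    rng = np.random.default_rng(cfg.seed + 7)
    if sample_ids is None:
        sample_ids = [ind.id for ind in ped]
    chroms = [c for c, _ in cfg.chrom_lengths]
    records: list[VariantRecord] = []
    truth: dict = {"planted": [], "decoys": {}}
    pos_counter = {c: 1_000_000 for c in chroms}

    def next_site(k: int) -> tuple[str, int]:
        chrom = chroms[k % len(chroms)]
        pos_counter[chrom] += int(rng.integers(5_000, 50_000))
        return chrom, pos_counter[chrom]

    def base_candidate(k: int, gene: str, case_ids) -> VariantRecord:
        chrom, pos = next_site(k)
        return VariantRecord(
            chrom=chrom, pos=pos, ref="G", alt="T", gene=gene,
            consequence="missense", sift="deleterious", polyphen="probably_damaging",
            cadd_phred=28.0, tranche_sensitivity=99.0,
            maf={populations[0]: 0.004, populations[1]: 0.003},
            genotypes=_clean_genotypes(sample_ids, case_ids),
        )

    k = 0
    for spec in planted_candidates:
        v = base_candidate(k, spec.gene, spec.case_ids)
        records.append(v)
        truth["planted"].append(v.key)
        k += 1

    n_samples = len(sample_ids)
    n_quarter = math.ceil(0.25 * n_samples)
    for spec in decoys:
        v = base_candidate(k, f"DECOY_{spec.kind.upper()}", spec.case_ids)
        g = dict(v.genotypes)
        non_cases = [s for s in sample_ids if s not in spec.case_ids]
        if spec.kind == "site_tranche":
            v = VariantRecord(**{**v.__dict__, "tranche_sensitivity": 99.9})
        elif spec.kind == "genotype_gq":
            for s in spec.case_ids:
                g[s] = GenotypeCall(gt=HOM_ALT, gq=25, ref_depth=0, alt_depth=40)
            v = VariantRecord(**{**v.__dict__, "genotypes": g})
        elif spec.kind == "genotype_alt_depth":
            for s in spec.case_ids:
                g[s] = GenotypeCall(gt=HOM_ALT, gq=99, ref_depth=0, alt_depth=2)
            v = VariantRecord(**{**v.__dict__, "genotypes": g})
        elif spec.kind == "genotype_allele_balance":
            # A systematic allelic-imbalance artefact: a quarter of the
            # cohort carries strongly skewed het calls (GQ and alt depth
            # clean), so only the balance rule no-calls them.
            for s in non_cases[:n_quarter]:
                g[s] = GenotypeCall(gt=HET, gq=99, ref_depth=60, alt_depth=4)
            v = VariantRecord(**{**v.__dict__, "genotypes": g})
        elif spec.kind == "no_call_rate":
            for s in non_cases[:n_quarter]:
                g[s] = GenotypeCall(gt=NO_CALL)
            v = VariantRecord(**{**v.__dict__, "genotypes": g})
        elif spec.kind == "not_damaging":
            v = VariantRecord(**{**v.__dict__, "sift": "tolerated",
                                 "polyphen": "benign", "cadd_phred": 10.0})
        elif spec.kind == "common_primary":
            v = VariantRecord(**{**v.__dict__,
                                 "maf": {populations[0]: 0.08, populations[1]: 0.004}})
        elif spec.kind == "common_secondary":
            v = VariantRecord(**{**v.__dict__,
                                 "maf": {populations[0]: 0.004, populations[1]: 0.08}})
        elif spec.kind == "case_not_hom":
            g[spec.case_ids[0]] = GenotypeCall(gt=HET, gq=99, ref_depth=20, alt_depth=22)
            v = VariantRecord(**{**v.__dict__, "genotypes": g})
        elif spec.kind == "control_hom":
            for s in control_ids:
                g[s] = GenotypeCall(gt=HOM_ALT, **_CLEAN_HOM_ALT)
            v = VariantRecord(**{**v.__dict__, "genotypes": g})
        records.append(v)
        truth["decoys"][spec.kind] = v.key
        k += 1

    consequences = np.array(
        ["synonymous", "missense", "intronic", "other"], dtype=object
    )
    for j in range(n_background):
        chrom, pos = next_site(k)
        maf0 = float(rng.choice([rng.uniform(0.05, 0.5), rng.uniform(0.001, 0.05)]))
        maf1 = float(np.clip(maf0 * rng.uniform(0.5, 2.0), 1e-5, 0.5))
        genotypes = {}
        for s in sample_ids:
            u = rng.random()
            if u < (1 - maf0) ** 2:
                gt = HOM_REF
            elif u < (1 - maf0) ** 2 + 2 * maf0 * (1 - maf0):
                gt = HET
            else:
                gt = HOM_ALT
            depths = {HOM_REF: (40, 0), HET: (20, 20), HOM_ALT: (0, 40)}[gt]
            genotypes[s] = GenotypeCall(gt=gt, gq=99, ref_depth=depths[0],
                                        alt_depth=depths[1])
        records.append(
            VariantRecord(
                chrom=chrom, pos=pos, ref="A", alt="C", gene=f"BG{j}",
                consequence=str(rng.choice(consequences, p=[0.4, 0.35, 0.15, 0.1])),
                sift=str(rng.choice(["tolerated", "unknown"])),
                polyphen=str(rng.choice(["benign", "unknown"])),
                cadd_phred=float(rng.uniform(0, 15)),
                tranche_sensitivity=99.0,
                maf={populations[0]: maf0, populations[1]: maf1},
                genotypes=genotypes,
            )
        )
        k += 1

    ann_rows = []
    for v in records:
        row = {
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "gene": v.gene, "consequence": v.consequence, "sift": v.sift,
            "polyphen": v.polyphen, "cadd_phred": v.cadd_phred,
        }
        for p in populations:
            row[f"maf_{p}"] = v.maf.get(p)
        ann_rows.append(row)
    return records, pd.DataFrame(ann_rows), truth


def tiled_gene_panel(
    chrom: str, start_bp: int, end_bp: int, n: int, prefix: str = "G"
) -> list[GeneInterval]:
    """``n`` equal, non-overlapping synthetic gene intervals tiling a span."""
    width = (end_bp - start_bp) // n
    out = []
    for k in range(n):
        a = start_bp + k * width
        out.append(GeneInterval(symbol=f"{prefix}{k}", chrom=chrom,
                                start_bp=a, end_bp=a + width - 1))
    return out
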