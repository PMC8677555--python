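"""Exome variant quality filtering, classification and family prioritisation.

The cascade is order-fixed and idempotent:

1. **site filter** — keep SNPs with a recalibration truth-tranche
   sensitivity <= 99.5 and indels <= 99.0 (pass-flagged records are kept);
2. **genotype filter** — individual calls failing quality rules become
   no-calls: genotype quality < 30; heterozygous calls whose allele depths
   diverge from 50:50 (chi-squared P < 0.001); heterozygous or
   homozygous-alternate calls with alternate-allele depth < 3;
3. **no-call filter** — drop variants with a no-call rate >= 0.25;
4. **classification** — population-frequency class (dual-population rule:
   the combined class is the *least rare* across the required reference
   populations, an absent frequency meaning "not present in that data
   set", hence 0) and a deliberately permissive "damaging" definition
   (any protein-truncating/splice consequence; missense if *any* of SIFT,
   PolyPhen or CADD > 20 calls it deleterious);
5. **candidate selection and segregation** — homozygous-alternate in the
   proband, damaging, uncommon or rarer; then kept if homozygous in the
   required number of affected siblings, with homozygous-control counts
   annotated.

Frequency-class boundaries: MAF >= 5% is common; a MAF of exactly 1% is
rare and exactly 0.1% is very rare (boundary points join the rarer class);
only the 5% boundary joins the commoner class.

Recalibration is consumed, not computed: input VCFs must carry a
``TRANCHE`` INFO value (percent sensitivity) or a PASS filter flag.
In-silico predictions and population frequencies arrive via a TSV
annotation table keyed by (chrom, pos, ref, alt) with columns
``gene consequence sift polyphen cadd_phred`` and one ``maf_<population>``
column per reference population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "VariantRecord",
    "GenotypeCall",
    "FilterThresholds",
    "SegregationRule",
    "site_filter",
    "allele_balance_p",
    "genotype_filter",
    "apply_genotype_filters",
    "no_call_filter",
    "frequency_class",
    "is_damaging",
    "proband_candidates",
    "segregation_filter",
    "parent_genotype_constraint",
    "known_variant_screen",
    "read_vcf",
    "write_vcf",
    "read_annotations",
    "attach_annotations",
    "candidate_table",
]

HOM_REF, HET, HOM_ALT, NO_CALL = "hom_ref", "het", "hom_alt", "no_call"

TRUNCATING_CONSEQUENCES = frozenset(
    {"frameshift", "stop_gained", "stop_lost", "start_lost", "splice_acceptor", "splice_donor"}
)
DELETERIOUS_SIFT = frozenset({"deleterious", "deleterious_lc"})
DAMAGING_POLYPHEN = frozenset({"probably_damaging", "possibly_damaging"})

CLASS_ORDER = ("very_rare", "rare", "uncommon", "common")


@dataclass(frozen=True)
class GenotypeCall:
    gt: str = NO_CALL
    gq: Optional[int] = None
    ref_depth: Optional[int] = None
    alt_depth: Optional[int] = None

    def __post_init__(self):
        for d in (self.ref_depth, self.alt_depth):
            if d is not None and d < 0:
                raise ValueError("read depths must be non-negative")


@dataclass
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    rsid: str = ""
    consequence: str = "other"
    sift: str = "unknown"
    polyphen: str = "unknown"
    cadd_phred: Optional[float] = None
    tranche_sensitivity: Optional[float] = None
    filter_pass: bool = False
    maf: dict[str, Optional[float]] = field(default_factory=dict)
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based)")
        for pop, f in self.maf.items():
            if f is not None and not 0.0 <= f <= 1.0:
                raise ValueError(f"MAF for {pop!r} outside [0, 1]")

    @property
    def vtype(self) -> str:
        return "snp" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterThresholds:
    snp_tranche_max: float = 99.5
    indel_tranche_max: float = 99.0
    min_gq: int = 30
    ab_p_min: float = 0.001
    min_alt_depth: int = 3
    max_no_call_rate: float = 0.25
    cadd_damaging: float = 20.0
    common_maf: float = 0.05
    uncommon_maf: float = 0.01
    rare_maf: float = 0.001

    def __post_init__(self):
        if not 0.0 < self.rare_maf < self.uncommon_maf < self.common_maf < 1.0:
            raise ValueError("frequency-class bounds must be ordered and nested")


@dataclass(frozen=True)
class SegregationRule:
    """How candidates must segregate in the family.

    ``required_hom_cases``: "all" or a minimum count of homozygous-alternate
    cases. ``control_exclusion``: "none" keeps every variant (controls are
    only counted), "any" drops variants homozygous in any control,
    "majority" drops those homozygous in more than half of the controls
    (the "also common in unaffected family controls" exclusion).
    """

    required_hom_cases: object = "all"
    control_exclusion: str = "none"

    def __post_init__(self):
        if self.required_hom_cases != "all" and int(self.required_hom_cases) < 1:
            raise ValueError("required_hom_cases must be 'all' or a positive count")
        if self.control_exclusion not in ("none", "any", "majority"):
            raise ValueError("control_exclusion must be none/any/majority")


# -- stage 1: site-level filter -------------------------------------------------------


def site_filter(
    variants: Sequence[VariantRecord], t: FilterThresholds = FilterThresholds()
) -> list[VariantRecord]:
    out = []
    for v in variants:
        if v.filter_pass:
            out.append(v)
            continue
        if v.tranche_sensitivity is None:
            continue
        limit = t.snp_tranche_max if v.vtype == "snp" else t.indel_tranche_max
        if v.tranche_sensitivity <= limit:
            out.append(v)
    return out


# -- stage 2: genotype-level filter ---------------------------------------------------


def allele_balance_p(ref_depth: int, alt_depth: int) -> float:
    """Upper-tail chi-squared (1 df) P for departure from 50:50 allele depths."""
    total = ref_depth + alt_depth
    if total <= 0:
        raise ValueError("zero total read depth")
    chi2 = (ref_depth - alt_depth) ** 2 / total
    return float(stats.chi2.sf(chi2, df=1))


def genotype_filter(
    call: GenotypeCall, vtype: str, t: FilterThresholds = FilterThresholds()
) -> GenotypeCall:
    """Return the call unchanged, or a bare no-call if any quality rule fails.

    Metrics that are absent are treated as uninformative rather than
    failing: a rule only fires on an observed value.
    """
    no_call = GenotypeCall(gt=NO_CALL, gq=call.gq, ref_depth=call.ref_depth,
                           alt_depth=call.alt_depth)
    if call.gt == NO_CALL:
        return call
    if call.gq is not None and call.gq < t.min_gq:
        return no_call
    if call.gt == HET and call.ref_depth is not None and call.alt_depth is not None:
        if allele_balance_p(call.ref_depth, call.alt_depth) < t.ab_p_min:
            return no_call
    if call.gt in (HET, HOM_ALT) and call.alt_depth is not None:
        if call.alt_depth < t.min_alt_depth:
            return no_call
    return call


def apply_genotype_filters(
    variants: Sequence[VariantRecord], t: FilterThresholds = FilterThresholds()
) -> list[VariantRecord]:
    out = []
    for v in variants:
        new_calls = {s: genotype_filter(c, v.vtype, t) for s, c in v.genotypes.items()}
        out.append(replace(v, genotypes=new_calls))
    return out


# -- stage 3: no-call-rate filter -----------------------------------------------------


def no_call_filter(
    variants: Sequence[VariantRecord], t: FilterThresholds = FilterThresholds()
) -> list[VariantRecord]:
    out = []
    for v in variants:
        if not v.genotypes:
            continue
        rate = sum(c.gt == NO_CALL for c in v.genotypes.values()) / len(v.genotypes)
        if rate < t.max_no_call_rate:
            out.append(v)
    return out


# -- stage 4: classification ----------------------------------------------------------


def _single_population_class(maf: Optional[float], t: FilterThresholds) -> str:
    f = 0.0 if maf is None else maf  # absent from the data set -> frequency 0
    if f >= t.common_maf:
        return "common"
    if f > t.uncommon_maf:
        return "uncommon"
    if f > t.rare_maf:
        return "rare"
    return "very_rare"


def frequency_class(
    v: VariantRecord,
    populations: Sequence[str],
    t: FilterThresholds = FilterThresholds(),
) -> str:
    """Combined frequency class under the dual-population rule.

    Every required population must satisfy a class's bound, so the combined
    class is the least rare across populations; a rarer frequency in one
    population never rescues a commoner one in another.
    """
    if not populations:
        raise ValueError("at least one reference population required")
    classes = [_single_population_class(v.maf.get(p), t) for p in populations]
    return max(classes, key=CLASS_ORDER.index)


def is_damaging(v: VariantRecord, t: FilterThresholds = FilterThresholds()) -> bool:
    """Permissive deleteriousness call (any predictor suffices for missense)."""
    if v.consequence in TRUNCATING_CONSEQUENCES:
        return True
    if v.consequence != "missense":
        return False
    if v.sift in DELETERIOUS_SIFT:
        return True
    if v.polyphen in DAMAGING_POLYPHEN:
        return True
    return v.cadd_phred is not None and v.cadd_phred > t.cadd_damaging


# -- stage 5: candidate selection and segregation -------------------------------------


def proband_candidates(
    variants: Sequence[VariantRecord],
    proband_id: str,
    populations: Sequence[str],
    t: FilterThresholds = FilterThresholds(),
) -> list[VariantRecord]:
    """Homozygous-alternate, damaging, uncommon-or-rarer variants in the proband."""
    out = []
    for v in variants:
        call = v.genotypes.get(proband_id)
        if call is None:
            raise KeyError(f"proband {proband_id!r} has no genotype for {v.key}")
        if call.gt != HOM_ALT:
            continue
        if not is_damaging(v, t):
            continue
        if frequency_class(v, populations, t) == "common":
            continue
        out.append(v)
    return out


def segregation_filter(
    candidates: Sequence[VariantRecord],
    rule: SegregationRule,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
) -> list[tuple[VariantRecord, str]]:
    """Keep candidates homozygous in enough cases; annotate control homozygotes.

    Returns (variant, "k/n") pairs where k of n genotyped controls are
    homozygous-alternate. Unknown sample ids raise.
    """
    out = []
    for v in candidates:
        for s in (*case_ids, *control_ids):
            if s not in v.genotypes:
                raise KeyError(f"sample {s!r} has no genotype for {v.key}")
        hom_cases = sum(v.genotypes[s].gt == HOM_ALT for s in case_ids)
        needed = len(case_ids) if rule.required_hom_cases == "all" else int(
            rule.required_hom_cases
        )
        if hom_cases < needed:
            continue
        hom_controls = sum(v.genotypes[s].gt == HOM_ALT for s in control_ids)
        if rule.control_exclusion == "any" and hom_controls > 0:
            continue
        if rule.control_exclusion == "majority" and control_ids and (
            hom_controls > len(control_ids) / 2
        ):
            continue
        out.append((v, f"{hom_controls}/{len(control_ids)}"))
    return out


def parent_genotype_constraint(offspring_calls: Sequence[GenotypeCall]) -> str:
    """Infer whether an ungenotyped parent could be homozygous-alternate.

    Any homozygous-reference offspring must have received a reference allele
    from that parent, excluding parental homozygosity for the alternate.
    """
    if not offspring_calls:
        raise ValueError("at least one offspring genotype required")
    if any(c.gt == HOM_REF for c in offspring_calls):
        return "hom_alt_excluded"
    return "hom_alt_possible"


def known_variant_screen(
    variants: Sequence[VariantRecord],
    panel: Sequence[tuple[str, int, str, str, str]],
    sample_ids: Sequence[str],
) -> pd.DataFrame:
    """Genotype table for a panel of known risk variants.

    ``panel`` rows are (chrom, pos, ref, alt, label). Panel variants missing
    from the callset report "absent" for every sample.
    """
    by_key = {v.key: v for v in variants}
    rows = []
    for chrom, pos, ref, alt, label in panel:
        v = by_key.get((chrom, pos, ref, alt))
        for s in sample_ids:
            if v is None:
                gt = "absent"
            else:
                call = v.genotypes.get(s)
                gt = call.gt if call is not None else NO_CALL
            rows.append({"variant": label, "chrom": chrom, "pos": pos, "sample": s,
                         "genotype": gt})
    return pd.DataFrame(rows, columns=["variant", "chrom", "pos", "sample", "genotype"])


# -- reporting ------------------------------------------------------------------------


def candidate_table(
    prioritised: Sequence[tuple[VariantRecord, str]],
    populations: Sequence[str],
    t: FilterThresholds = FilterThresholds(),
) -> pd.DataFrame:
    """Per-variant report in the prioritised-variant layout."""
    rows = []
    for v, controls in prioritised:
        row = {
            "chrom": v.chrom,
            "pos": v.pos,
            "rsid": v.rsid or "-",
            "gene": v.gene,
            "consequence": v.consequence,
            "sift": v.sift,
            "polyphen": v.polyphen,
            "cadd_phred": v.cadd_phred,
            "frequency_class": frequency_class(v, populations, t),
            "hom_in_controls": controls,
        }
        for p in populations:
            f = v.maf.get(p)
            row[f"maf_{p}"] = "-" if f is None else f
        rows.append(row)
    return pd.DataFrame(rows)


# -- VCF and annotation I/O -----------------------------------------------------------

_GT_TO_TUPLE = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), NO_CALL: (None, None)}


def read_vcf(path, annotations: Optional[pd.DataFrame] = None) -> list[VariantRecord]:
    """Read biallelic records with GT/AD/GQ genotypes from a VCF (4.x).

    ``TRANCHE`` INFO (percent sensitivity) populates the recalibration
    annotation; a PASS filter sets ``filter_pass``. When ``annotations``
    is given it is joined immediately (see :func:`attach_annotations`).
    """
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"record {rec.chrom}:{rec.pos} is not biallelic")
            genotypes = {}
            for sample, sample_rec in rec.samples.items():
                gt_tuple = sample_rec.get("GT")
                if gt_tuple is None or None in gt_tuple:
                    gt = NO_CALL
                else:
                    gt = {0: HOM_REF, 1: HET, 2: HOM_ALT}[sum(gt_tuple)]
                ad = sample_rec.get("AD")
                gq = sample_rec.get("GQ")
                genotypes[sample] = GenotypeCall(
                    gt=gt,
                    gq=None if gq is None else int(gq),
                    ref_depth=None if ad is None or ad[0] is None else int(ad[0]),
                    alt_depth=None if ad is None or len(ad) < 2 or ad[1] is None
                    else int(ad[1]),
                )
            tranche = rec.info.get("TRANCHE")
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    rsid=rec.id or "",
                    tranche_sensitivity=None if tranche is None else float(tranche),
                    filter_pass="PASS" in rec.filter.keys(),
                    genotypes=genotypes,
                )
            )
    if annotations is not None:
        records = attach_annotations(records, annotations)
    return records


def write_vcf(records: Sequence[VariantRecord], path, sample_ids: Sequence[str]) -> None:
    """Write records as an uncompressed VCF with GT:AD:GQ genotype fields."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=TRANCHE,Number=1,Type=Float,'
                    'Description="Recalibration truth-tranche sensitivity (percent)">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    for chrom in dict.fromkeys(v.chrom for v in records):
        max_pos = max(v.pos for v in records if v.chrom == chrom)
        header.add_line(f"##contig=<ID={chrom},length={max_pos + 1000}>")
    for s in sample_ids:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in sorted(records, key=lambda r: (r.chrom, r.pos)):
            rec = vf.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt),
                id=v.rsid or None,
            )
            if v.tranche_sensitivity is not None:
                rec.info["TRANCHE"] = float(v.tranche_sensitivity)
            if v.filter_pass:
                rec.filter.add("PASS")
            for s in sample_ids:
                call = v.genotypes.get(s, GenotypeCall())
                rec.samples[s]["GT"] = _GT_TO_TUPLE[call.gt]
                if call.ref_depth is not None and call.alt_depth is not None:
                    rec.samples[s]["AD"] = (call.ref_depth, call.alt_depth)
                if call.gq is not None:
                    rec.samples[s]["GQ"] = call.gq
            vf.write(rec)


def read_annotations(path) -> pd.DataFrame:
    """Read the annotation TSV (keyed by chrom, pos, ref, alt)."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_annotations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="")


def attach_annotations(
    records: Sequence[VariantRecord], annotations: pd.DataFrame
) -> list[VariantRecord]:
    """Join consequence/prediction/frequency columns onto VCF records.

    Population frequencies come from every ``maf_<population>`` column; an
    empty cell means the variant is absent from that reference data set.
    Unannotated records keep their defaults.
    """
    maf_cols = [c for c in annotations.columns if c.startswith("maf_")]
    idx = {}
    for row in annotations.itertuples(index=False):
        idx[(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))] = row
    out = []
    for v in records:
        row = idx.get(v.key)
        if row is None:
            out.append(v)
            continue
        maf = {}
        for c in maf_cols:
            val = getattr(row, c)
            maf[c[len("maf_"):]] = None if pd.isna(val) else float(val)
        cadd = getattr(row, "cadd_phred", None)
        out.append(
            replace(
                v,
                gene=str(getattr(row, "gene", v.gene) or ""),
                consequence=str(getattr(row, "consequence", v.consequence)),
                sift=str(getattr(row, "sift", v.sift)),
                polyphen=str(getattr(row, "polyphen", v.polyphen)),
                cadd_phred=None if cadd is None or pd.isna(cadd) else float(cadd),
                maf=maf,
            )
        )
    return out
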