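"""Array-genotype quality control.

Filters mirror a standard one-shot SNP-array QC for small family cohorts:
samples are removed first (missingness > 5%), then markers (missingness
> 5%, Hardy-Weinberg exact P below a genome-wide threshold, duplicate
ids). The filter order matters and is fixed: a failing sample's missing
calls must not count against markers.

The Hardy-Weinberg test is the exact conditional test on heterozygote
counts given the allele counts (the test universally applied to array
HWE QC), two-sided by probability-mass ordering: P is the total
probability of all heterozygote configurations whose conditional
probability does not exceed that of the observed one.

Relatedness verification uses a robust pairwise kinship estimator built
from shared-heterozygosity and opposite-homozygote counts,

    phi_hat = (N_het,het - 2 * N_opp-hom) / (N_het(i) + N_het(j)),

which is insensitive to population structure because it conditions on the
two samples' own heterozygosity rather than on cohort allele frequencies.
Observed and pedigree-expected kinship are compared on the standard
relationship-degree ladder (boundaries 0.0442 / 0.0884 / 0.177 / 0.354).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genotypes import MISSING, GenotypeMatrix
from .pedigree import FEMALE, MALE, Pedigree

__all__ = [
    "QcThresholds",
    "SexCheckResult",
    "KinshipResult",
    "filter_samples_by_missingness",
    "hwe_exact_test",
    "filter_markers",
    "infer_sex",
    "verify_relatedness",
    "genotype_concordance",
]


@dataclass(frozen=True)
class QcThresholds:
    max_sample_missing: float = 0.05
    max_marker_missing: float = 0.05
    hwe_alpha: float = 5e-8
    common_maf: float = 0.05
    #: X-homozygosity cutoffs for sex inference; the gap is deliberate and
    #: rates falling inside it are reported as ambiguous.
    male_x_homozygosity_min: float = 0.9
    female_x_homozygosity_max: float = 0.8

    def __post_init__(self):
        for name in ("max_sample_missing", "max_marker_missing", "hwe_alpha", "common_maf"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass(frozen=True)
class SexCheckResult:
    sample_id: str
    x_homozygosity_rate: float
    inferred_sex: str  # "male" / "female" / "ambiguous"


@dataclass(frozen=True)
class KinshipResult:
    pair: tuple[str, str]
    expected_kinship: float
    observed_kinship: Optional[float] = None
    discordant: bool = False


class EmptyResultError(ValueError):
    """All samples (or markers) were removed by a filter."""


def filter_samples_by_missingness(
    gm: GenotypeMatrix, t: QcThresholds = QcThresholds()
) -> tuple[GenotypeMatrix, list[str]]:
    """Remove samples missing more than ``t.max_sample_missing`` of calls.

    Must run before any marker filter. Returns the filtered matrix and the
    removed sample ids; raises :class:`EmptyResultError` if nothing is left.
    """
    if gm.n_samples == 0 or gm.n_markers == 0:
        raise ValueError("empty genotype matrix")
    rates = gm.sample_missing_rate()
    removed = [s for s, r in zip(gm.sample_ids, rates) if r > t.max_sample_missing]
    kept = [s for s in gm.sample_ids if s not in set(removed)]
    if not kept:
        raise EmptyResultError("all samples exceed the missingness threshold")
    return gm.subset(samples=kept), removed


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact two-sided Hardy-Weinberg P for one biallelic marker.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose conditional probability is less than or
    equal to that of the observed configuration.
    """
    for c in (n_hom1, n_het, n_hom2):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("no genotyped samples")
    rare = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    if rare == 0:
        return 1.0

    # log P(n_het | n, rare) up to a constant: multinomial pedigree-free
    # sampling probability of the genotype configuration given allele counts.
    def logprob(het: int) -> float:
        r_hom = (rare - het) // 2
        c_hom = n - het - r_hom
        return (
            het * math.log(2.0)
            - math.lgamma(r_hom + 1)
            - math.lgamma(het + 1)
            - math.lgamma(c_hom + 1)
        )

    hets = range(rare % 2, rare + 1, 2)
    logs = {h: logprob(h) for h in hets}
    m = max(logs.values())
    probs = {h: math.exp(v - m) for h, v in logs.items()}
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    p = sum(v / total for v in probs.values() if v / total <= p_obs * (1.0 + 1e-12))
    return min(1.0, p)


def filter_markers(
    gm: GenotypeMatrix,
    t: QcThresholds = QcThresholds(),
    founders_only: Optional[Sequence[str]] = None,
) -> tuple[GenotypeMatrix, list[str]]:
    """Remove markers by missingness, HWE deviation and duplicated ids.

    Assumes the sample filter has already run. HWE is computed on all
    retained samples by default (the cohort is a handful of small families);
    pass ``founders_only`` with founder ids to restrict the test to them.
    Duplicate marker ids keep their first occurrence.
    """
    keep = np.ones(gm.n_markers, dtype=bool)
    removed: list[str] = []

    seen: set[str] = set()
    for k, m in enumerate(gm.markers):
        if m.id in seen:
            keep[k] = False
            removed.append(m.id)
        seen.add(m.id)

    miss = gm.marker_missing_rate()
    hwe_gm = gm if founders_only is None else gm.subset(samples=list(founders_only))
    for k, m in enumerate(gm.markers):
        if not keep[k]:
            continue
        if miss[k] > t.max_marker_missing:
            keep[k] = False
            removed.append(m.id)
            continue
        n0, n1, n2 = hwe_gm.genotype_counts(k)
        if n0 + n1 + n2 > 0 and hwe_exact_test(n0, n1, n2) < t.hwe_alpha:
            keep[k] = False
            removed.append(m.id)
    return gm.subset(marker_mask=keep), removed


def infer_sex(gm_x: GenotypeMatrix, t: QcThresholds = QcThresholds()) -> list[SexCheckResult]:
    """Call sample sex from the X-homozygosity rate of common markers.

    ``gm_x`` must contain only non-pseudoautosomal X markers; markers with
    a known ``ref_maf`` at or below ``t.common_maf`` are excluded here,
    markers without a ``ref_maf`` are used as given. Hemizygous male calls
    are assumed to be coded homozygous, as array callers do.
    """
    mask = np.array(
        [m.ref_maf is None or m.ref_maf > t.common_maf for m in gm_x.markers], dtype=bool
    )
    if not mask.any():
        raise ValueError("no qualifying X markers (all below the common-MAF cutoff)")
    sub = gm_x.subset(marker_mask=mask)
    out = []
    for s in sub.sample_ids:
        calls = sub.sample_calls(s)
        called = calls != MISSING
        if not called.any():
            raise ValueError(f"sample {s!r} has no called X genotypes")
        rate = float(((calls == 0) | (calls == 2))[called].mean())
        if rate >= t.male_x_homozygosity_min:
            sex = MALE
        elif rate <= t.female_x_homozygosity_max:
            sex = FEMALE
        else:
            sex = "ambiguous"
        out.append(SexCheckResult(sample_id=s, x_homozygosity_rate=rate, inferred_sex=sex))
    return out


# Kinship degree-class boundaries (monozygotic/duplicate, 1st, 2nd, 3rd degree,
# unrelated): the standard powers-of-two ladder at 2^(-k-1.5). The smallest
# boundary is the ladder's resolution limit: pairs whose observed kinship
# deviates from expectation by more than it have effectively changed degree.
_DEGREE_BOUNDS = (0.0442, 0.0884, 0.177, 0.354)
_DISCORDANCE_LIMIT = _DEGREE_BOUNDS[0]


def robust_kinship(calls_i: np.ndarray, calls_j: np.ndarray) -> tuple[float, int]:
    """Pairwise robust kinship estimate and the informative-marker count.

    phi_hat = (N_het,het - 2 * N_opposite-hom) / (N_het(i) + N_het(j)),
    computed over markers called in both samples.
    """
    both = (calls_i != MISSING) & (calls_j != MISSING)
    ci, cj = calls_i[both], calls_j[both]
    het_i = int((ci == 1).sum())
    het_j = int((cj == 1).sum())
    het_het = int(((ci == 1) & (cj == 1)).sum())
    opp = int((((ci == 0) & (cj == 2)) | ((ci == 2) & (cj == 0))).sum())
    denom = het_i + het_j
    phi = float("nan") if denom == 0 else (het_het - 2.0 * opp) / denom
    return phi, int(both.sum())


def verify_relatedness(
    gm: GenotypeMatrix,
    ped: Pedigree,
    min_informative: int = 200,
) -> list[KinshipResult]:
    """Compare observed pairwise kinship against pedigree expectation.

    A pair is flagged discordant when |observed - expected| exceeds the
    degree-class boundary 0.0442 — a full degree-class shift. (The robust
    estimator is mildly biased downward for inbred pairs, so an absolute
    band is preferred over comparing hard degree assignments.) Raises if any
    pair has fewer than ``min_informative`` jointly called markers.
    """
    shared = [s for s in gm.sample_ids if s in ped]
    if len(shared) < 2:
        raise ValueError("need at least two samples present in both genotypes and pedigree")
    out = []
    for a_idx in range(len(shared)):
        for b_idx in range(a_idx + 1, len(shared)):
            a, b = shared[a_idx], shared[b_idx]
            expected = ped.kinship(a, b)
            phi, n_inf = robust_kinship(gm.sample_calls(a), gm.sample_calls(b))
            if n_inf < min_informative:
                raise ValueError(
                    f"pair ({a}, {b}): only {n_inf} informative markers "
                    f"(minimum {min_informative})"
                )
            out.append(
                KinshipResult(
                    pair=(a, b),
                    expected_kinship=expected,
                    observed_kinship=phi,
                    discordant=abs(phi - expected) > _DISCORDANCE_LIMIT,
                )
            )
    return out


def genotype_concordance(gm: GenotypeMatrix, variants) -> float:
    """Fraction of agreeing non-missing calls at shared (sample, position) pairs.

    ``variants`` is a sequence of exome :class:`~consangmap.variants.VariantRecord`
    objects; a variant matches an array marker on (chrom, pos). Raises on
    zero overlap.
    """
    pos_index = {(m.chrom, m.bp): k for k, m in enumerate(gm.markers)}
    gt_dosage = {"hom_ref": 0, "het": 1, "hom_alt": 2}
    agree = 0
    total = 0
    for v in variants:
        k = pos_index.get((v.chrom, v.pos))
        if k is None:
            continue
        for s, call in v.genotypes.items():
            if s not in gm._sample_index or call.gt not in gt_dosage:
                continue
            array_call = gm.calls[gm.sample_index(s), k]
            if array_call == MISSING:
                continue
            total += 1
            agree += int(array_call == gt_dosage[call.gt])
    if total == 0:
        raise ValueError("no overlapping (sample, position) calls between array and exome")
    return agree / total
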