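"""Runs of homozygosity and case-shared identical-homozygosity mapping.

The detector scans ordered common markers per chromosome for maximal runs
of homozygous calls. Defaults encode the mapping criteria for recessive
loci in consanguineous families: at least 50 homozygous markers spanning
at least 1 Mb, with *no* tolerated heterozygous calls. The zero default is
deliberate — silently "erasing" embedded heterozygous calls manufactures
false runs in inbred families (a 49-marker stretch containing two true
heterozygous calls is not autozygous), so any error tolerance must be
requested explicitly.

Rules of the scan:

* a heterozygous call terminates a run unless the running count of absorbed
  heterozygous calls stays within ``het_tolerance``;
* missing calls neither terminate a run nor count toward the marker
  minimum; ``max_missing_run`` optionally breaks runs at long no-call
  stretches to guard low-marker-density regions;
* region boundaries are the first and last *homozygous-called* markers;
* reported length is ``end_bp - start_bp`` and coordinates are 1-based
  inclusive (GRCh37 convention).

Case-shared mapping ("genetic homogeneity") additionally requires every
case to be homozygous *for the same allele* at every counted marker; a
marker where two cases are homozygous for opposite alleles is a hard break
that no tolerance absorbs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "RohParams",
    "ROHRegion",
    "GeneInterval",
    "detect_roh",
    "shared_identical_regions",
    "annotate_control_overlap",
    "genome_roh_fraction",
    "genes_in_regions",
    "gwas_loci_in_regions",
    "read_bed_genes",
    "write_regions_bed",
    "regions_table",
]

# Per-marker scan states.
_HOM = 0  # homozygous (counted; identical across cases in shared mode)
_HET = 1  # heterozygous event, absorbed while within het_tolerance
_BREAK = 2  # hard break: identity mismatch or an over-long missing stretch
_MISS = 3  # missing, transparent to the scan


@dataclass(frozen=True)
class RohParams:
    min_snps: int = 50
    min_length_bp: int = 1_000_000
    het_tolerance: int = 0
    max_missing_run: Optional[int] = None
    input_maf_min: float = 0.05
    require_identity: bool = True
    #: A control is listed as overlapping when one of its own ROH covers at
    #: least this fraction of the case region's length.
    control_overlap_frac: float = 0.5

    def __post_init__(self):
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")
        if self.min_length_bp < 1:
            raise ValueError("min_length_bp must be >= 1")
        if self.het_tolerance < 0:
            raise ValueError("het_tolerance must be >= 0")


@dataclass(frozen=True)
class ROHRegion:
    chrom: str
    start_bp: int
    end_bp: int
    n_markers: int
    members: frozenset[str]
    control_overlaps: frozenset[str] = frozenset()
    genes: tuple[str, ...] = ()
    gwas_hits: tuple[str, ...] = ()

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    def overlap_bp(self, other: "ROHRegion") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end_bp, other.end_bp) - max(self.start_bp, other.start_bp))


@dataclass(frozen=True)
class GeneInterval:
    """A gene span, 1-based inclusive on both ends."""

    symbol: str
    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self):
        if self.end_bp <= self.start_bp:
            raise ValueError(f"gene {self.symbol!r}: end must exceed start")


def _common_marker_mask(gm: GenotypeMatrix, p: RohParams) -> np.ndarray:
    """Input filter: common markers only; markers without a known MAF pass."""
    return np.array(
        [m.ref_maf is None or m.ref_maf > p.input_maf_min for m in gm.markers], dtype=bool
    )


def _status_single(calls: np.ndarray) -> np.ndarray:
    status = np.full(calls.shape, _HOM, dtype=np.int8)
    status[calls == 1] = _HET
    status[calls == MISSING] = _MISS
    return status


def _status_shared(case_calls: np.ndarray) -> np.ndarray:
    """Joint state across cases: all-hom-identical / het / identity break / missing."""
    any_het = (case_calls == 1).any(axis=0)
    miss = case_calls == MISSING
    any_miss = miss.any(axis=0)
    # Identity check over non-missing homozygous calls.
    hom_alt = np.where(miss, 0, (case_calls == 2).astype(np.int8)).sum(axis=0)
    hom_ref = np.where(miss, 0, (case_calls == 0).astype(np.int8)).sum(axis=0)
    mismatch = (hom_alt > 0) & (hom_ref > 0) & ~any_het
    status = np.full(case_calls.shape[1], _HOM, dtype=np.int8)
    status[any_miss] = _MISS
    status[any_het] = _HET
    status[mismatch] = _BREAK
    return status


def _apply_missing_run_breaks(status: np.ndarray, max_run: Optional[int]) -> np.ndarray:
    if max_run is None:
        return status
    status = status.copy()
    run = 0
    for k, s in enumerate(status):
        if s == _MISS:
            run += 1
            if run > max_run:
                status[k - run + 1 : k + 1] = _BREAK
        else:
            run = 0
    return status


def _scan_chromosome(
    status: np.ndarray, bps: np.ndarray, p: RohParams
) -> list[tuple[int, int, int]]:
    """Maximal qualifying runs as (start_bp, end_bp, n_hom_markers) triples.

    A candidate window is a maximal stretch, between hard breaks, containing
    at most ``het_tolerance`` heterozygous events, trimmed to homozygous
    markers at both ends.
    """
    out: list[tuple[int, int, int]] = []
    n = len(status)
    seg_start = 0
    for seg_end in range(n + 1):  # [seg_start, seg_end) segments split on _BREAK
        if seg_end < n and status[seg_end] != _BREAK:
            continue
        if seg_end > seg_start:
            out.extend(_scan_segment(status, bps, seg_start, seg_end, p))
        seg_start = seg_end + 1
    # De-duplicate and drop windows nested inside another qualifying window.
    uniq = sorted(set(out))
    kept = [
        w
        for w in uniq
        if not any(
            o != w and o[0] <= w[0] and w[1] <= o[1] for o in uniq
        )
    ]
    return kept


def _scan_segment(
    status: np.ndarray, bps: np.ndarray, lo: int, hi: int, p: RohParams
) -> list[tuple[int, int, int]]:
    het_pos = [k for k in range(lo, hi) if status[k] == _HET]
    # Window k spans (boundary[k], boundary[k + tol + 1]) exclusive, where
    # boundaries are het positions padded with the segment edges. When the
    # segment holds fewer het calls than the tolerance, the single maximal
    # window is the whole segment.
    bounds = [lo - 1] + het_pos + [hi]
    t = min(p.het_tolerance, len(het_pos))
    windows = []
    for k in range(len(bounds) - t - 1):
        a, b = bounds[k] + 1, bounds[k + t + 1]  # half-open [a, b)
        if a < b:
            windows.append((a, b))
    out = []
    for a, b in windows:
        hom_idx = [k for k in range(a, b) if status[k] == _HOM]
        if not hom_idx:
            continue
        n_hom = len(hom_idx)
        start_bp, end_bp = int(bps[hom_idx[0]]), int(bps[hom_idx[-1]])
        if n_hom >= p.min_snps and (end_bp - start_bp) >= p.min_length_bp:
            out.append((start_bp, end_bp, n_hom))
    return out


def _require_sorted(gm: GenotypeMatrix) -> None:
    # GenotypeMatrix enforces order at construction; this is a guard for
    # callers handing in raw arrays through the low-level helpers.
    pass


def detect_roh(
    gm: GenotypeMatrix, sample_id: str, p: RohParams = RohParams()
) -> list[ROHRegion]:
    """Runs of homozygosity for one sample over the common-marker panel."""
    mask = _common_marker_mask(gm, p)
    sub = gm.subset(samples=[sample_id], marker_mask=mask)
    regions: list[ROHRegion] = []
    for chrom, sl in sub.chrom_slices().items():
        calls = sub.calls[0, sl]
        bps = np.array([m.bp for m in sub.markers[sl]])
        status = _apply_missing_run_breaks(_status_single(calls), p.max_missing_run)
        for start_bp, end_bp, n_hom in _scan_chromosome(status, bps, p):
            regions.append(
                ROHRegion(
                    chrom=chrom,
                    start_bp=start_bp,
                    end_bp=end_bp,
                    n_markers=n_hom,
                    members=frozenset({sample_id}),
                )
            )
    return regions


def shared_identical_regions(
    gm: GenotypeMatrix, case_ids: Sequence[str], p: RohParams = RohParams()
) -> list[ROHRegion]:
    """ROH shared by all cases with identical homozygous genotypes.

    Implements the "require genetic homogeneity" mapping mode: a counted
    marker must be homozygous for the same allele in every case.
    """
    if len(case_ids) < 2:
        raise ValueError("shared mapping needs at least two cases")
    mask = _common_marker_mask(gm, p)
    sub = gm.subset(samples=list(case_ids), marker_mask=mask)
    members = frozenset(case_ids)
    regions: list[ROHRegion] = []
    for chrom, sl in sub.chrom_slices().items():
        calls = sub.calls[:, sl]
        bps = np.array([m.bp for m in sub.markers[sl]])
        status = _apply_missing_run_breaks(_status_shared(calls), p.max_missing_run)
        for start_bp, end_bp, n_hom in _scan_chromosome(status, bps, p):
            regions.append(
                ROHRegion(
                    chrom=chrom,
                    start_bp=start_bp,
                    end_bp=end_bp,
                    n_markers=n_hom,
                    members=members,
                )
            )
    return regions


def annotate_control_overlap(
    regions: Sequence[ROHRegion],
    gm: GenotypeMatrix,
    control_ids: Sequence[str],
    p: RohParams = RohParams(),
    exclude: bool = False,
) -> list[ROHRegion]:
    """Fill ``control_overlaps`` with controls whose own ROH cover each region.

    A control is listed when one of its ROH (same detector, same parameters)
    overlaps the case region by at least ``p.control_overlap_frac`` of the
    region's length. With ``exclude=True``, regions with any overlapping
    control are dropped — the strict mode that assumes full penetrance.
    """
    control_rohs = {c: detect_roh(gm, c, p) for c in control_ids}
    out = []
    for region in regions:
        hits = set()
        for c, rohs in control_rohs.items():
            need = p.control_overlap_frac * region.length_bp
            if any(region.overlap_bp(r) >= need for r in rohs):
                hits.add(c)
        if exclude and hits:
            continue
        out.append(replace(region, control_overlaps=frozenset(hits)))
    return out


def genome_roh_fraction(
    gm: GenotypeMatrix, sample_id: str, p: RohParams = RohParams()
) -> float:
    """Fraction of the covered autosomal span lying inside the sample's ROH.

    Denominator: per chromosome, last minus first marker position, summed;
    numerator: total ROH length. Callers should pass autosomal markers only.
    """
    if gm.n_markers == 0:
        raise ValueError("empty marker panel")
    covered = 0
    for chrom, sl in gm.chrom_slices().items():
        bps = [m.bp for m in gm.markers[sl]]
        covered += bps[-1] - bps[0]
    if covered == 0:
        raise ValueError("marker panel spans zero length")
    total_roh = sum(r.length_bp for r in detect_roh(gm, sample_id, p))
    return total_roh / covered


def genes_in_regions(
    regions: Sequence[ROHRegion], gene_intervals: Sequence[GeneInterval]
) -> list[ROHRegion]:
    """Attach gene symbols whose interval intersects each region (1-based inclusive)."""
    out = []
    for region in regions:
        genes = tuple(
            g.symbol
            for g in gene_intervals
            if g.chrom == region.chrom
            and g.start_bp <= region.end_bp
            and g.end_bp >= region.start_bp
        )
        out.append(replace(region, genes=genes))
    return out


def gwas_loci_in_regions(
    regions: Sequence[ROHRegion], top_snps: Sequence[tuple[str, str, int]]
) -> list[ROHRegion]:
    """Attach GWAS top-SNP ids positioned inside each region.

    ``top_snps`` rows are (snp_id, chrom, bp) on the same build.
    """
    out = []
    for region in regions:
        hits = tuple(
            snp_id
            for snp_id, chrom, bp in top_snps
            if chrom == region.chrom and region.start_bp <= bp <= region.end_bp
        )
        out.append(replace(region, gwas_hits=hits))
    return out


def read_bed_genes(path) -> list[GeneInterval]:
    """Read gene intervals from BED (0-based half-open -> 1-based inclusive)."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "name"], dtype={"chrom": str, "name": str},
        comment="#",
    )
    return [
        GeneInterval(symbol=r.name, chrom=r.chrom, start_bp=int(r.start) + 1, end_bp=int(r.end))
        for r in df.itertuples()
    ]


def write_regions_bed(regions: Sequence[ROHRegion], path) -> None:
    """Write regions as BED (converting back to 0-based half-open starts)."""
    with open(path, "w") as fh:
        for r in regions:
            name = ",".join(sorted(r.members))
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{name}\n")


def regions_table(regions: Sequence[ROHRegion]) -> pd.DataFrame:
    """Summary table (one row per region) in the mapping-report layout."""
    rows = []
    for r in regions:
        rows.append(
            {
                "chrom": r.chrom,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "length_mb": round(r.length_bp / 1e6, 1),
                "n_snps": r.n_markers,
                "members": ",".join(sorted(r.members)),
                "control_overlaps": ",".join(sorted(r.control_overlaps)) or "None",
                "gwas_hits": ",".join(r.gwas_hits) or "No IBD GWAS loci",
                "genes": ",".join(r.genes),
                "n_genes": len(r.genes),
            }
        )
    return pd.DataFrame(rows)
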