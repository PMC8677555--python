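"""Gene-dropping simulation of meiosis with recombination through pedigrees.

Founder chromosomes receive distinct integer labels (two per founder) and
are transmitted through the pedigree in topological order. Each meiosis
follows the Haldane (no-interference) model: the crossover count on a
chromosome is Poisson with mean equal to the map length in Morgans and
breakpoints fall uniformly on the centimorgan scale; the starting parental
haplotype is chosen with probability 1/2.

The resulting per-individual founder-label mosaics answer identity-by-
descent questions directly: an individual is *autozygous* wherever its two
haplotypes carry the same founder label, and two individuals are
*identically homozygous by descent* over a window when all four of their
haplotypes carry one and the same founder label across the entire window.
The Monte-Carlo probability of that event over many replicates is the
quantity homozygosity mapping implicitly conditions on.

The default genetic map is uniform at 1 cM/Mb over the GRCh37 autosomes;
sex chromosomes are excluded. All haplotype coordinates are centimorgans.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional, Sequence

import numpy as np

from .genome import GRCH37_AUTOSOME_BP
from .pedigree import Pedigree

__all__ = [
    "GeneticMap",
    "DropConfig",
    "default_autosome_map",
    "simulate_gamete",
    "gene_drop",
    "iter_gene_drops",
    "realized_autozygosity",
    "shared_autozygosity_probability",
]

#: One haplotype: ordered, tiling (start_cM, end_cM, founder_label) segments.
Haplotype = list[tuple[float, float, int]]
#: One replicate: individual id -> chromosome -> (haplotype, haplotype).
DropState = dict[str, dict[str, tuple[Haplotype, Haplotype]]]


@dataclass(frozen=True)
class GeneticMap:
    """Per-chromosome map lengths with a physical-to-genetic position mapping.

    ``cm_per_mb`` gives the uniform density used by :meth:`bp_to_cm`;
    replace the instance (or subclass) for a non-uniform map.
    """

    lengths_cm: dict[str, float]
    cm_per_mb: float = 1.0

    def __post_init__(self):
        if not self.lengths_cm:
            raise ValueError("genetic map has no chromosomes")
        for chrom, length in self.lengths_cm.items():
            if length < 0:
                raise ValueError(f"chromosome {chrom}: negative map length")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths_cm)

    def length_cm(self, chrom: str) -> float:
        return self.lengths_cm[chrom]

    def bp_to_cm(self, chrom: str, bp: int) -> float:
        cm = bp / 1e6 * self.cm_per_mb
        return min(cm, self.lengths_cm[chrom])

    def restrict(self, chroms: Sequence[str]) -> "GeneticMap":
        return GeneticMap({c: self.lengths_cm[c] for c in chroms}, self.cm_per_mb)


def default_autosome_map() -> GeneticMap:
    """Uniform 1 cM/Mb map over the 22 GRCh37 autosomes."""
    return GeneticMap({c: bp / 1e6 for c, bp in GRCH37_AUTOSOME_BP.items()})


@dataclass(frozen=True)
class DropConfig:
    n_reps: int = 10_000
    seed: int = 0
    #: Optional query window (chrom, start_cM, end_cM).
    window: Optional[tuple[str, float, float]] = None

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.window is not None and not self.window[2] > self.window[1]:
            raise ValueError("window length must be positive")


def _slice_haplotype(hap: Haplotype, a: float, b: float) -> Haplotype:
    """Segments of ``hap`` restricted to [a, b)."""
    out: Haplotype = []
    for start, end, label in hap:
        if end <= a:
            continue
        if start >= b:
            break
        out.append((max(start, a), min(end, b), label))
    return out


def simulate_gamete(
    hap_pair: tuple[Haplotype, Haplotype], length_cm: float, rng: np.random.Generator
) -> Haplotype:
    """One recombinant gamete from a parental haplotype pair.

    Haldane model: crossover count ~ Poisson(length_cm / 100), breakpoints
    uniform on (0, length_cm), starting haplotype equiprobable. A zero-length
    chromosome is transmitted without recombination.
    """
    cur = int(rng.integers(2))
    n_x = rng.poisson(length_cm / 100.0) if length_cm > 0 else 0
    if n_x == 0:
        return list(hap_pair[cur])
    cuts = np.sort(rng.uniform(0.0, length_cm, size=n_x))
    out: Haplotype = []
    pos = 0.0
    for cut in [*cuts.tolist(), length_cm]:
        if cut > pos:
            out.extend(_slice_haplotype(hap_pair[cur], pos, cut))
        cur ^= 1
        pos = cut
    # Merge adjacent segments that carry the same label.
    merged: Haplotype = []
    for seg in out:
        if merged and merged[-1][2] == seg[2] and merged[-1][1] == seg[0]:
            merged[-1] = (merged[-1][0], seg[1], seg[2])
        else:
            merged.append(seg)
    return merged


def _drop_once(
    ped: Pedigree, gmap: GeneticMap, rng: np.random.Generator
) -> DropState:
    founders = sorted(ind.id for ind in ped.founders())
    labels = {fid: (2 * k, 2 * k + 1) for k, fid in enumerate(founders)}
    next_phantom = 2 * len(founders)  # labels for recorded-absent parents
    state: DropState = {}
    for iid in ped.topological_order():
        ind = ped.individual(iid)
        per_chrom: dict[str, tuple[Haplotype, Haplotype]] = {}
        if ind.is_founder:
            la, lb = labels[iid]
            for chrom in gmap.chromosomes:
                length = gmap.length_cm(chrom)
                per_chrom[chrom] = ([(0.0, length, la)], [(0.0, length, lb)])
        else:
            parent_haps = []
            for pid in (ind.father_id, ind.mother_id):
                if pid is None:
                    # Unrecorded parent: a phantom founder with fresh labels.
                    la, lb = next_phantom, next_phantom + 1
                    next_phantom += 2
                    phantom = {
                        chrom: (
                            [(0.0, gmap.length_cm(chrom), la)],
                            [(0.0, gmap.length_cm(chrom), lb)],
                        )
                        for chrom in gmap.chromosomes
                    }
                    parent_haps.append(phantom)
                else:
                    if pid not in state:
                        raise ValueError(f"parent {pid!r} of {iid!r} has no simulated state")
                    parent_haps.append(state[pid])
            for chrom in gmap.chromosomes:
                length = gmap.length_cm(chrom)
                paternal = simulate_gamete(parent_haps[0][chrom], length, rng)
                maternal = simulate_gamete(parent_haps[1][chrom], length, rng)
                per_chrom[chrom] = (paternal, maternal)
        state[iid] = per_chrom
    return state


def iter_gene_drops(
    ped: Pedigree, gmap: GeneticMap, cfg: DropConfig
) -> Iterator[DropState]:
    """Stream replicate founder-label states (fixed seed => identical stream)."""
    rng = np.random.default_rng(cfg.seed)
    for _ in range(cfg.n_reps):
        yield _drop_once(ped, gmap, rng)


def gene_drop(ped: Pedigree, gmap: GeneticMap, cfg: DropConfig) -> list[DropState]:
    """All replicate states as a list; prefer :func:`iter_gene_drops` for large runs."""
    return list(iter_gene_drops(ped, gmap, cfg))


def realized_autozygosity(state: DropState, individual_id: str, gmap: GeneticMap) -> float:
    """Fraction of the map where the individual's two labels coincide."""
    total = sum(gmap.length_cm(c) for c in gmap.chromosomes)
    if total == 0:
        raise ValueError("zero-length genetic map")
    ibd = 0.0
    for chrom in gmap.chromosomes:
        hap_a, hap_b = state[individual_id][chrom]
        ia = ib = 0
        pos = 0.0
        end_cm = gmap.length_cm(chrom)
        while pos < end_cm and ia < len(hap_a) and ib < len(hap_b):
            sa, ea, la = hap_a[ia]
            sb, eb, lb = hap_b[ib]
            nxt = min(ea, eb)
            if la == lb:
                ibd += nxt - pos
            pos = nxt
            if ea <= nxt:
                ia += 1
            if eb <= nxt:
                ib += 1
    return ibd / total


def _window_labels(
    state: DropState, individual_id: str, chrom: str, a: float, b: float
) -> Optional[set[int]]:
    """Set of founder labels covering [a, b) on both haplotypes, or None if
    either haplotype switches labels inside the window."""
    labels: set[int] = set()
    for hap in state[individual_id][chrom]:
        segs = _slice_haplotype(hap, a, b)
        if len(segs) != 1:
            return None
        labels.add(segs[0][2])
    return labels


def shared_autozygosity_probability(
    ped: Pedigree,
    pair: tuple[str, str],
    cfg: DropConfig,
    gmap: Optional[GeneticMap] = None,
    identical: bool = True,
) -> tuple[float, float]:
    """Monte-Carlo probability that a pair is autozygous across a window.

    With ``identical=True`` (default, the strict reading of "identically
    homozygous"): success in a replicate requires both individuals to carry
    *one and the same* founder-haplotype label on *both* chromosomes across
    the entire window. With ``identical=False`` each individual must merely
    be autozygous over the window, possibly to different founders — the
    relaxed mode for sensitivity analysis.

    Only the window's chromosome is simulated: under the no-interference
    model the window statistic is independent of all other chromosomes.
    The pair may name one individual twice, in which case the estimate
    converges on that individual's window-autozygosity probability (its
    point-window limit is the inbreeding coefficient).

    Returns ``(estimate, monte_carlo_se)`` with
    ``se = sqrt(p * (1 - p) / n_reps)``.
    """
    if cfg.window is None:
        raise ValueError("DropConfig.window must be set")
    for iid in pair:
        ped.individual(iid)  # raises PedigreeError on unknown ids
    gmap = gmap or default_autosome_map()
    chrom, a, b = cfg.window
    if chrom not in gmap.lengths_cm:
        raise ValueError(f"window chromosome {chrom!r} not in genetic map")
    if b > gmap.length_cm(chrom):
        raise ValueError("window extends beyond the chromosome map length")
    sub_map = gmap.restrict([chrom])
    hits = 0
    for state in iter_gene_drops(ped, sub_map, cfg):
        labels: set[int] = set()
        ok = True
        for iid in dict.fromkeys(pair):  # deduplicate, preserve order
            lab = _window_labels(state, iid, chrom, a, b)
            if lab is None or len(lab) != 1:
                ok = False
                break
            labels |= lab
        if not ok:
            continue
        if identical:
            if len(labels) == 1:
                hits += 1
        else:
            hits += 1
    p_hat = hits / cfg.n_reps
    se = math.sqrt(p_hat * (1.0 - p_hat) / cfg.n_reps)
    return p_hat, se
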