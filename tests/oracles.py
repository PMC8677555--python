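"""Independent brute-force oracles used to validate the implementations.

Each oracle computes its quantity by exhaustive enumeration or a closed
form, sharing no code with the package implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import product
from math import comb, factorial


def enumeration_kinship(parents: dict[str, tuple[str | None, str | None]],
                        i: str, j: str) -> Fraction:
    """Exact kinship by enumerating every inheritance vector.

    ``parents`` maps each individual to (father, mother), ``None`` for a
    founder's absent parents. Each founder contributes two distinct allele
    labels; each non-founder meiosis independently picks one of the parent's
    two alleles, and kinship is the average probability that one allele
    drawn from each of *i* and *j* is the same founder allele.
    """
    founders = [k for k, (f, m) in parents.items() if f is None and m is None]
    nonfounders = [k for k in parents if k not in founders]
    # Topological order of nonfounders.
    ordered: list[str] = []
    while len(ordered) < len(nonfounders):
        for k in nonfounders:
            if k in ordered:
                continue
            f, m = parents[k]
            if all(p in founders or p in ordered for p in (f, m)):
                ordered.append(k)
    total = Fraction(0)
    n_vec = 0
    for bits in product((0, 1), repeat=2 * len(ordered)):
        labels: dict[str, tuple] = {f: ((f, 0), (f, 1)) for f in founders}
        for k, ind in enumerate(ordered):
            f, m = parents[ind]
            pat = labels[f][bits[2 * k]]
            mat = labels[m][bits[2 * k + 1]]
            labels[ind] = (pat, mat)
        same = sum(
            labels[i][a] == labels[j][b] for a in (0, 1) for b in (0, 1)
        )
        total += Fraction(same, 4)
        n_vec += 1
    return total / n_vec


def hwe_enumeration(n_hom1: int, n_het: int, n_hom2: int) -> Fraction:
    """Exact two-sided HWE P by full enumeration with rational arithmetic."""
    n = n_hom1 + n_het + n_hom2
    rare = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    if rare == 0:
        return Fraction(1)

    def weight(het: int) -> Fraction:
        r_hom = (rare - het) // 2
        c_hom = n - het - r_hom
        return Fraction(2**het, factorial(r_hom) * factorial(het) * factorial(c_hom))

    weights = {h: weight(h) for h in range(rare % 2, rare + 1, 2)}
    total = sum(weights.values())
    p_obs = weights[n_het] / total
    return sum(w / total for w in weights.values() if w / total <= p_obs)


def hypergeom_upper_tail(a: int, b: int, c: int, d: int) -> Fraction:
    """P(X >= a) for X hypergeometric with the 2x2 table's margins fixed."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = comb(n, col1)
    hi = min(row1, col1)
    return Fraction(
        sum(comb(row1, x) * comb(n - row1, col1 - x) for x in range(a, hi + 1)), denom
    )


# -- brute-force ROH scan -------------------------------------------------------------

_MISSING = -1


def _single_status(call: int) -> str:
    if call == _MISSING:
        return "miss"
    return "het" if call == 1 else "hom"


def _shared_status(column) -> str:
    calls = list(column)
    if any(c == 1 for c in calls):
        return "het"
    non_missing = [c for c in calls if c != _MISSING]
    if len(set(non_missing)) > 1:
        return "break"
    if len(non_missing) < len(calls):
        return "miss"
    return "hom"


def _missing_run_lengths(statuses: list[str]) -> list[int]:
    """For each position, the length of the missing-run containing it (0 if called)."""
    out = [0] * len(statuses)
    k = 0
    while k < len(statuses):
        if statuses[k] == "miss":
            j = k
            while j < len(statuses) and statuses[j] == "miss":
                j += 1
            for t in range(k, j):
                out[t] = j - k
            k = j
        else:
            k += 1
    return out


def brute_force_roh(statuses: list[str], bps, min_snps: int, min_length_bp: int,
                    het_tolerance: int, max_missing_run=None) -> list[tuple[int, int, int]]:
    """All-substrings scan: maximal valid runs as (start_bp, end_bp, n_hom).

    An interval [i, j] (both endpoints homozygous) is valid when it holds no
    hard break, at most ``het_tolerance`` heterozygous events, no marker
    inside a missing-run longer than ``max_missing_run``, at least
    ``min_snps`` homozygous markers and a span of at least ``min_length_bp``.
    Only intervals not strictly contained in another valid interval are kept.
    """
    n = len(statuses)
    runlens = _missing_run_lengths(statuses)
    valid = []
    for i in range(n):
        if statuses[i] != "hom":
            continue
        for j in range(i, n):
            if statuses[j] != "hom":
                continue
            inner = statuses[i : j + 1]
            if "break" in inner:
                continue
            if inner.count("het") > het_tolerance:
                continue
            if max_missing_run is not None and any(
                r > max_missing_run for r in runlens[i : j + 1]
            ):
                continue
            n_hom = inner.count("hom")
            if n_hom >= min_snps and (bps[j] - bps[i]) >= min_length_bp:
                valid.append((i, j, n_hom))
    maximal = [
        (int(bps[i]), int(bps[j]), n_hom)
        for (i, j, n_hom) in valid
        if not any((i2 <= i and j <= j2) and (i2, j2) != (i, j) for (i2, j2, _) in valid)
    ]
    return sorted(set(maximal))
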