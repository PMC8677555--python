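"""Pedigree data model, PLINK-style FAM I/O and identity-by-descent coefficients.

A :class:`Pedigree` is a validated directed acyclic graph of
:class:`Individual` records. Consanguinity loops (marriages between
relatives) are expected and fully supported — "acyclic" refers only to the
parent-child relation.

Kinship and inbreeding follow the classical recursive definition: the
kinship coefficient ``phi(i, j)`` is the probability that one allele drawn
at random from *i* and one from *j* are identical by descent, computed by
recursing onto the parents of the individual farther from the founders.
Founders are assumed mutually unrelated and non-inbred; deeper relatedness
is modelled by adding ancestors to the pedigree rather than by assigning
founder kinship. The inbreeding coefficient ``F(i)`` is the kinship of
*i*'s parents.

Affection status is three-state (Crohn's disease, ulcerative colitis,
unaffected) so case sets can be restricted by IBD subtype. The FAM dialect
encodes it in the sixth column: 1 unaffected, 2 CD, 3 UC, 0/-9 unknown;
parent code ``0`` means "absent".
"""

from __future__ import annotations

from dataclasses import dataclass
from graphlib import CycleError, TopologicalSorter
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

__all__ = [
    "MALE",
    "FEMALE",
    "SEX_UNKNOWN",
    "UNAFFECTED",
    "CD",
    "UC",
    "AFFECTION_UNKNOWN",
    "Individual",
    "Pedigree",
    "PedigreeError",
    "load_pedigree",
    "read_fam",
    "write_fam",
    "kinship_coefficient",
    "inbreeding_coefficient",
]

MALE = "male"
FEMALE = "female"
SEX_UNKNOWN = "unknown"

UNAFFECTED = "unaffected"
CD = "CD"
UC = "UC"
AFFECTION_UNKNOWN = "unknown"

_SEX_FROM_CODE = {"1": MALE, "2": FEMALE, "0": SEX_UNKNOWN, "-9": SEX_UNKNOWN}
_SEX_TO_CODE = {MALE: "1", FEMALE: "2", SEX_UNKNOWN: "0"}
_AFF_FROM_CODE = {
    "1": UNAFFECTED,
    "2": CD,
    "3": UC,
    "0": AFFECTION_UNKNOWN,
    "-9": AFFECTION_UNKNOWN,
}
_AFF_TO_CODE = {UNAFFECTED: "1", CD: "2", UC: "3", AFFECTION_UNKNOWN: "0"}

#: Affection values counted as "affected" for case-set construction.
IBD_SUBTYPES = (CD, UC)


class PedigreeError(ValueError):
    """Structural pedigree problem: unresolved parent, cycle, bad sex, unknown id."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``generation_label`` carries the conventional pedigree-figure label
    (e.g. ``"V-1"``) when the individual id itself is not of that form.
    """

    id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = SEX_UNKNOWN
    affection: str = AFFECTION_UNKNOWN
    generation_label: Optional[str] = None

    @property
    def is_founder(self) -> bool:
        """Founder iff both parent ids are absent."""
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """A validated family graph with memoised kinship computation."""

    def __init__(self, individuals: Iterable[Individual], proband_id: Optional[str] = None):
        self._members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._members:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self._members[ind.id] = ind
        if not self._members:
            raise PedigreeError("pedigree is empty")
        if proband_id is not None and proband_id not in self._members:
            raise PedigreeError(f"proband {proband_id!r} not in pedigree")
        self.proband_id = proband_id
        self._validate()
        self._depth_cache: dict[str, int] = {}
        self._phi_cache: dict[tuple[str, str], float] = {}

    # -- construction / validation ------------------------------------------------

    def _validate(self) -> None:
        for ind in self._members.values():
            for pid, role, bad_sex in (
                (ind.father_id, "father", FEMALE),
                (ind.mother_id, "mother", MALE),
            ):
                if pid is None:
                    continue
                parent = self._members.get(pid)
                if parent is None:
                    raise PedigreeError(f"{role} {pid!r} of {ind.id!r} not in pedigree")
                if parent.sex == bad_sex:
                    raise PedigreeError(
                        f"{role} {pid!r} of {ind.id!r} has inconsistent sex {parent.sex}"
                    )
        # Parent graph must be acyclic (consanguinity loops are fine; a cycle
        # would mean someone is their own ancestor).
        ts = TopologicalSorter(
            {
                ind.id: [p for p in (ind.father_id, ind.mother_id) if p is not None]
                for ind in self._members.values()
            }
        )
        try:
            self._topo_order = tuple(ts.static_order())
        except CycleError as exc:
            raise PedigreeError(f"cycle detected in pedigree: {exc.args}") from exc
        if not any(ind.is_founder for ind in self._members.values()):
            raise PedigreeError("pedigree has no founder")

    # -- basic access ---------------------------------------------------------------

    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._members

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._members.values())

    @property
    def members(self) -> dict[str, Individual]:
        return dict(self._members)

    def individual(self, individual_id: str) -> Individual:
        try:
            return self._members[individual_id]
        except KeyError:
            raise PedigreeError(f"individual {individual_id!r} not in pedigree") from None

    def founders(self) -> list[Individual]:
        return [ind for ind in self._members.values() if ind.is_founder]

    def cases(self, subtype: Optional[str] = None) -> list[Individual]:
        """Affected members, optionally restricted to one IBD subtype.

        ``subtype=None`` returns any-IBD cases (CD or UC), matching the
        "all affected members with any IBD subtype" analysis mode.
        """
        if subtype is None:
            return [i for i in self._members.values() if i.affection in IBD_SUBTYPES]
        return [i for i in self._members.values() if i.affection == subtype]

    def unaffected(self) -> list[Individual]:
        return [i for i in self._members.values() if i.affection == UNAFFECTED]

    def topological_order(self) -> tuple[str, ...]:
        """Individual ids with every parent before its children."""
        return self._topo_order

    # -- identity-by-descent coefficients -------------------------------------------

    def depth(self, individual_id: str) -> int:
        """Longest parent-chain from a founder to the individual (founders: 0)."""
        if individual_id not in self._depth_cache:
            ind = self.individual(individual_id)
            if ind.is_founder:
                self._depth_cache[individual_id] = 0
            else:
                self._depth_cache[individual_id] = 1 + max(
                    self.depth(p) for p in (ind.father_id, ind.mother_id) if p is not None
                )
        return self._depth_cache[individual_id]

    def kinship(self, i: str, j: str) -> float:
        """Kinship coefficient phi(i, j).

        Recursion: for i != j, recurse onto the parents of the deeper
        individual (a parent is always shallower than its child, so the
        deeper of the pair cannot be an ancestor of the other); two distinct
        founders have phi = 0; phi(i, i) = (1 + F(i)) / 2.
        """
        self.individual(i)
        self.individual(j)
        return self._phi(i, j)

    def inbreeding(self, i: str) -> float:
        """Inbreeding coefficient F(i) = phi(father(i), mother(i)); 0 for founders."""
        ind = self.individual(i)
        return self._phi_parents(ind)

    def _phi(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        cached = self._phi_cache.get(key)
        if cached is not None:
            return cached
        if a == b:
            val = 0.5 * (1.0 + self._phi_parents(self._members[a]))
        else:
            if self.depth(a) < self.depth(b):
                a, b = b, a
            ind = self._members[a]
            if ind.is_founder:
                val = 0.0
            else:
                val = 0.5 * (
                    self._phi_or_zero(ind.father_id, b) + self._phi_or_zero(ind.mother_id, b)
                )
        self._phi_cache[key] = val
        return val

    def _phi_or_zero(self, parent_id: Optional[str], other: str) -> float:
        # A recorded-absent parent behaves as a unique unrelated founder.
        return 0.0 if parent_id is None else self._phi(parent_id, other)

    def _phi_parents(self, ind: Individual) -> float:
        if ind.father_id is None or ind.mother_id is None:
            return 0.0
        return self._phi(ind.father_id, ind.mother_id)


def kinship_coefficient(ped: Pedigree, i: str, j: str) -> float:
    """Functional alias for :meth:`Pedigree.kinship`."""
    return ped.kinship(i, j)


def inbreeding_coefficient(ped: Pedigree, i: str) -> float:
    """Functional alias for :meth:`Pedigree.inbreeding`."""
    return ped.inbreeding(i)


# -- file I/O -------------------------------------------------------------------------


def _clean_parent(value: object) -> Optional[str]:
    s = str(value).strip()
    return None if s in {"0", "", "nan", "-9"} else s


def load_pedigree(source, proband_id: Optional[str] = None) -> Pedigree:
    """Build a validated :class:`Pedigree` from a table.

    ``source`` is a path to a whitespace-separated FAM file (six columns,
    no header: family, id, father, mother, sex, affection) or a DataFrame
    with columns ``family, id, father, mother, sex, affection``. Sex and
    affection may be given either as PLINK numeric codes or as the string
    values used by this package.
    """
    if isinstance(source, (str, Path)):
        df = pd.read_csv(
            source,
            sep=r"\s+",
            header=None,
            names=["family", "id", "father", "mother", "sex", "affection"],
            dtype=str,
        )
    else:
        df = source.copy()
        missing = {"family", "id", "father", "mother", "sex", "affection"} - set(df.columns)
        if missing:
            raise PedigreeError(f"pedigree table missing columns: {sorted(missing)}")
    individuals = []
    for row in df.itertuples(index=False):
        sex = str(row.sex).strip()
        aff = str(row.affection).strip()
        individuals.append(
            Individual(
                id=str(row.id).strip(),
                family_id=str(row.family).strip(),
                father_id=_clean_parent(row.father),
                mother_id=_clean_parent(row.mother),
                sex=_SEX_FROM_CODE.get(sex, sex),
                affection=_AFF_FROM_CODE.get(aff, aff),
            )
        )
    for ind in individuals:
        if ind.sex not in (MALE, FEMALE, SEX_UNKNOWN):
            raise PedigreeError(f"unrecognised sex {ind.sex!r} for {ind.id!r}")
        if ind.affection not in (UNAFFECTED, CD, UC, AFFECTION_UNKNOWN):
            raise PedigreeError(f"unrecognised affection {ind.affection!r} for {ind.id!r}")
    return Pedigree(individuals, proband_id=proband_id)


def read_fam(path) -> Pedigree:
    """Read a PLINK-style FAM file (see module docstring for the dialect)."""
    return load_pedigree(path)


def write_fam(ped: Pedigree, path) -> None:
    """Write a pedigree as a PLINK-style FAM file (tab-separated)."""
    with open(path, "w") as fh:
        for ind in ped:
            fh.write(
                "\t".join(
                    [
                        ind.family_id,
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_TO_CODE[ind.sex],
                        _AFF_TO_CODE[ind.affection],
                    ]
                )
                + "\n"
            )
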