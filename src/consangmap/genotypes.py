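"""Marker panels and the sample-by-marker genotype matrix.

Genotypes are stored as alt-allele dosage: 0 (homozygous first allele),
1 (heterozygous), 2 (homozygous second allele), or -1 for a missing call.
Markers are held in a fixed order, grouped by chromosome with strictly
increasing physical position (1-based, GRCh37 convention).

Two text dialects are supported:

* PLINK text ``.ped``/``.map`` pairs — one sample per ``.ped`` row (six
  pedigree columns then two allele columns per marker, ``0 0`` missing);
  ``.map`` rows are ``chrom id cM bp``.
* A TSV dosage matrix — one marker per row with columns
  ``marker chrom bp a1 a2 ref_maf`` followed by one dosage column per
  sample (``NA`` for missing).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["Marker", "GenotypeMatrix", "MISSING"]

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1


@dataclass(frozen=True)
class Marker:
    """A biallelic array marker.

    ``ref_maf`` is the reference-population minor allele frequency used for
    "common SNP" input filters; ``None`` when unknown.
    """

    id: str
    chrom: str
    bp: int
    alleles: tuple[str, str] = ("A", "B")
    ref_maf: Optional[float] = None

    def __post_init__(self):
        if self.bp < 1:
            raise ValueError(f"marker {self.id!r}: bp must be >= 1")
        if self.ref_maf is not None and not 0.0 <= self.ref_maf <= 1.0:
            raise ValueError(f"marker {self.id!r}: ref_maf outside [0, 1]")


class GenotypeMatrix:
    """Samples x ordered biallelic markers with dosage calls."""

    def __init__(
        self,
        sample_ids: Sequence[str],
        markers: Sequence[Marker],
        calls: np.ndarray,
    ):
        self.sample_ids = list(sample_ids)
        self.markers = list(markers)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(self.sample_ids), len(self.markers)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("calls contain values outside {-1, 0, 1, 2}")
        self.calls = calls
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self._check_marker_order()
        self._sample_index = {s: k for k, s in enumerate(self.sample_ids)}

    def _check_marker_order(self) -> None:
        seen_chroms: set[str] = set()
        prev_chrom: Optional[str] = None
        prev_bp = 0
        for m in self.markers:
            if m.chrom != prev_chrom:
                if m.chrom in seen_chroms:
                    raise ValueError(f"chromosome {m.chrom} appears in non-contiguous blocks")
                seen_chroms.add(m.chrom)
                prev_chrom = m.chrom
                prev_bp = 0
            if m.bp <= prev_bp:
                raise ValueError(
                    f"markers on chromosome {m.chrom} not strictly increasing at {m.id!r}"
                )
            prev_bp = m.bp

    # -- shape and access ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for m in self.markers:
            if not out or out[-1] != m.chrom:
                out.append(m.chrom)
        return out

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not in genotype matrix") from None

    def sample_calls(self, sample_id: str) -> np.ndarray:
        return self.calls[self.sample_index(sample_id)]

    def positions(self) -> np.ndarray:
        return np.array([m.bp for m in self.markers], dtype=np.int64)

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous marker slice per chromosome, in panel order."""
        out: dict[str, slice] = {}
        start = 0
        for k in range(1, self.n_markers + 1):
            if k == self.n_markers or self.markers[k].chrom != self.markers[start].chrom:
                out[self.markers[start].chrom] = slice(start, k)
                start = k
        return out

    def subset(
        self,
        samples: Optional[Sequence[str]] = None,
        marker_mask: Optional[np.ndarray] = None,
    ) -> "GenotypeMatrix":
        """Return a sub-matrix keeping panel order for both axes."""
        rows = (
            np.arange(self.n_samples)
            if samples is None
            else np.array([self.sample_index(s) for s in samples])
        )
        if marker_mask is None:
            marker_mask = np.ones(self.n_markers, dtype=bool)
        marker_mask = np.asarray(marker_mask, dtype=bool)
        markers = [m for m, keep in zip(self.markers, marker_mask) if keep]
        return GenotypeMatrix(
            [self.sample_ids[r] for r in rows],
            markers,
            self.calls[np.ix_(rows, np.flatnonzero(marker_mask))],
        )

    def restrict_chrom(self, chrom: str) -> "GenotypeMatrix":
        mask = np.array([m.chrom == chrom for m in self.markers])
        if not mask.any():
            raise ValueError(f"no markers on chromosome {chrom!r}")
        return self.subset(marker_mask=mask)

    # -- summaries ----------------------------------------------------------------

    def sample_missing_rate(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=1)

    def marker_missing_rate(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def genotype_counts(self, marker_idx: int) -> tuple[int, int, int]:
        """(n hom-first-allele, n het, n hom-second-allele) over non-missing calls."""
        col = self.calls[:, marker_idx]
        return int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())

    def marker_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": [m.id for m in self.markers],
                "chrom": [m.chrom for m in self.markers],
                "bp": [m.bp for m in self.markers],
                "a1": [m.alleles[0] for m in self.markers],
                "a2": [m.alleles[1] for m in self.markers],
                "ref_maf": [m.ref_maf for m in self.markers],
            }
        )

    # -- I/O ----------------------------------------------------------------------

    @classmethod
    def from_plink(cls, ped_path, map_path) -> "GenotypeMatrix":
        mp = pd.read_csv(
            map_path,
            sep=r"\s+",
            header=None,
            names=["chrom", "id", "cm", "bp"],
            dtype={"chrom": str, "id": str, "cm": float, "bp": int},
        )
        markers = [Marker(id=r.id, chrom=r.chrom, bp=int(r.bp)) for r in mp.itertuples()]
        sample_ids: list[str] = []
        rows: list[np.ndarray] = []
        with open(ped_path) as fh:
            for line in fh:
                fields = line.split()
                if not fields:
                    continue
                sample_ids.append(fields[1])
                alleles = fields[6:]
                if len(alleles) != 2 * len(markers):
                    raise ValueError(
                        f"sample {fields[1]!r}: {len(alleles)} allele fields for "
                        f"{len(markers)} markers"
                    )
                a = np.array(alleles).reshape(-1, 2)
                # Dosage counts the second allele of each marker.
                second = np.array([m.alleles[1] for m in markers])
                dosage = np.where(
                    (a == "0").any(axis=1), MISSING, (a == second[:, None]).sum(axis=1)
                )
                rows.append(dosage.astype(np.int8))
        return cls(sample_ids, markers, np.vstack(rows))

    def to_plink(self, ped_path, map_path, pedigree=None) -> None:
        """Write a PLINK text pair.

        When ``pedigree`` is given, its parent/sex/affection columns are
        used for the first six ``.ped`` fields; otherwise placeholders.
        """
        with open(map_path, "w") as fh:
            for m in self.markers:
                fh.write(f"{m.chrom}\t{m.id}\t0\t{m.bp}\n")
        a1 = np.array([m.alleles[0] for m in self.markers])
        a2 = np.array([m.alleles[1] for m in self.markers])
        from .pedigree import _AFF_TO_CODE, _SEX_TO_CODE  # local import, avoids cycle

        with open(ped_path, "w") as fh:
            for s in self.sample_ids:
                if pedigree is not None and s in pedigree:
                    ind = pedigree.individual(s)
                    head = [
                        ind.family_id,
                        s,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_TO_CODE[ind.sex],
                        _AFF_TO_CODE[ind.affection],
                    ]
                else:
                    head = ["FAM", s, "0", "0", "0", "0"]
                calls = self.sample_calls(s)
                first = np.where(calls == MISSING, "0", np.where(calls == 2, a2, a1))
                second = np.where(calls == MISSING, "0", np.where(calls >= 1, a2, a1))
                pairs = np.char.add(np.char.add(first, " "), second)
                fh.write(" ".join(head) + " " + " ".join(pairs) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        meta_cols = ["marker", "chrom", "bp", "a1", "a2", "ref_maf"]
        sample_cols = [c for c in df.columns if c not in meta_cols]
        markers = [
            Marker(
                id=str(r.marker),
                chrom=str(r.chrom),
                bp=int(r.bp),
                alleles=(str(r.a1), str(r.a2)),
                ref_maf=None if pd.isna(r.ref_maf) else float(r.ref_maf),
            )
            for r in df.itertuples()
        ]
        calls = df[sample_cols].to_numpy(dtype=float).T
        calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
        return cls(sample_cols, markers, calls)

    def to_tsv(self, path) -> None:
        df = self.marker_table()
        for k, s in enumerate(self.sample_ids):
            col = self.calls[k].astype(float)
            col[col == MISSING] = np.nan
            df[s] = col
        df.to_csv(path, sep="\t", index=False, na_rep="NA")
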