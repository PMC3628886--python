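"""Tabular containers for multi-SNP family genotype datasets.

A dataset couples a per-family frame (ids, child sex, case status, member
presence) with int8 dose matrices of shape (n_families, n_snps): the number
of A2 copies, or -1 for missing.  These are the objects the QC, inference
and I/O layers operate on; :class:`~xlinkrr.core.DyadRecord` /
:class:`~xlinkrr.core.TriadRecord` views are available per SNP for the
record-level algebra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Union

import numpy as np
import pandas as pd

from .core import (
    FEMALE,
    MALE,
    MISSING,
    DyadRecord,
    TriadRecord,
    XGenotype,
)

__all__ = ["DyadDataset", "TriadDataset", "default_snp_table"]


def default_snp_table(n_snps: int, prefix: str = "snp") -> pd.DataFrame:
    """A minimal SNP metadata table: ids, X chromosome, dummy positions, A/G alleles."""
    return pd.DataFrame(
        {
            "snp": [f"{prefix}{i + 1}" for i in range(n_snps)],
            "chrom": ["X"] * n_snps,
            "pos": np.arange(1, n_snps + 1) * 10_000,
            "a1": ["A"] * n_snps,
            "a2": ["G"] * n_snps,
        }
    )


def _check_matrix(name: str, arr: np.ndarray, n_fam: int, n_snp: int, hi: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.int8)
    if arr.shape != (n_fam, n_snp):
        raise ValueError(f"{name} matrix shape {arr.shape} != ({n_fam}, {n_snp})")
    bad = (arr < MISSING) | (arr > hi[:, None])
    if bad.any():
        raise ValueError(f"{name} matrix contains out-of-range dose codes")
    return arr


@dataclass
class DyadDataset:
    """Mother-child pairs genotyped at a panel of X SNPs.

    ``families`` columns: family_id, child_sex ('male'/'female'),
    status ('case'/'control').  Row i of the dose matrices corresponds to
    families row i; column j to snps row j.
    """

    families: pd.DataFrame
    snps: pd.DataFrame
    mother_gt: np.ndarray
    child_gt: np.ndarray

    def __post_init__(self) -> None:
        self.families = self.families.reset_index(drop=True)
        self.snps = self.snps.reset_index(drop=True)
        n_fam, n_snp = len(self.families), len(self.snps)
        male = (self.families["child_sex"] == MALE).to_numpy()
        child_hi = np.where(male, 1, 2).astype(np.int8)
        self.mother_gt = _check_matrix(
            "mother", self.mother_gt, n_fam, n_snp, np.full(n_fam, 2, dtype=np.int8)
        )
        self.child_gt = _check_matrix("child", self.child_gt, n_fam, n_snp, child_hi)

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_index(self, snp: Union[str, int]) -> int:
        if isinstance(snp, (int, np.integer)):
            return int(snp)
        idx = self.snps.index[self.snps["snp"] == snp]
        if len(idx) == 0:
            raise KeyError(f"unknown SNP {snp!r}")
        return int(idx[0])

    def records(self, snp: Union[str, int]) -> List[DyadRecord]:
        """Record-level view of one SNP."""
        j = self.snp_index(snp)
        out = []
        for i, row in self.families.iterrows():
            sex = row["child_sex"]
            out.append(
                DyadRecord(
                    family_id=str(row["family_id"]),
                    mother=XGenotype(FEMALE, int(self.mother_gt[i, j])),
                    child=XGenotype(sex, int(self.child_gt[i, j])),
                    child_sex=sex,
                    status=row["status"],
                )
            )
        return out

    @classmethod
    def from_records(
        cls, records: List[DyadRecord], snps: Optional[pd.DataFrame] = None
    ) -> "DyadDataset":
        """Build a single-SNP dataset from dyad records."""
        fam = pd.DataFrame(
            {
                "family_id": [r.family_id for r in records],
                "child_sex": [r.child_sex for r in records],
                "status": [r.status for r in records],
            }
        )
        mother = np.array([[r.mother.dose] for r in records], dtype=np.int8)
        child = np.array([[r.child.dose] for r in records], dtype=np.int8)
        return cls(fam, snps if snps is not None else default_snp_table(1), mother, child)

    def subset_families(self, mask: np.ndarray) -> "DyadDataset":
        mask = np.asarray(mask)
        return DyadDataset(
            self.families.loc[mask].copy(),
            self.snps.copy(),
            self.mother_gt[mask],
            self.child_gt[mask],
        )

    def subset_snps(self, mask: np.ndarray) -> "DyadDataset":
        mask = np.asarray(mask)
        return DyadDataset(
            self.families.copy(),
            self.snps.loc[mask].copy(),
            self.mother_gt[:, mask],
            self.child_gt[:, mask],
        )


@dataclass
class TriadDataset:
    """Case families (affected individual + both parents) at a panel of X SNPs.

    ``families`` columns: family_id, child_sex, design ('fetal_triad' or
    'maternal_triad'), and boolean presence flags father_present,
    mother_present, child_present — an absent member (a dyad family within a
    triad study) has all-missing genotypes and is marginalized in the
    likelihood.  Several children of one family occupy several rows sharing
    family_id.
    """

    families: pd.DataFrame
    snps: pd.DataFrame
    father_gt: np.ndarray
    mother_gt: np.ndarray
    child_gt: np.ndarray

    def __post_init__(self) -> None:
        self.families = self.families.reset_index(drop=True)
        self.snps = self.snps.reset_index(drop=True)
        for col, default in (
            ("father_present", True),
            ("mother_present", True),
            ("child_present", True),
        ):
            if col not in self.families.columns:
                self.families[col] = default
        n_fam, n_snp = len(self.families), len(self.snps)
        male = (self.families["child_sex"] == MALE).to_numpy()
        child_hi = np.where(male, 1, 2).astype(np.int8)
        self.father_gt = _check_matrix(
            "father", self.father_gt, n_fam, n_snp, np.full(n_fam, 1, dtype=np.int8)
        )
        self.mother_gt = _check_matrix(
            "mother", self.mother_gt, n_fam, n_snp, np.full(n_fam, 2, dtype=np.int8)
        )
        self.child_gt = _check_matrix("child", self.child_gt, n_fam, n_snp, child_hi)

    @property
    def n_families(self) -> int:
        return self.families["family_id"].nunique()

    @property
    def n_rows(self) -> int:
        return len(self.families)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_index(self, snp: Union[str, int]) -> int:
        if isinstance(snp, (int, np.integer)):
            return int(snp)
        idx = self.snps.index[self.snps["snp"] == snp]
        if len(idx) == 0:
            raise KeyError(f"unknown SNP {snp!r}")
        return int(idx[0])

    def records(self, snp: Union[str, int]) -> List[TriadRecord]:
        j = self.snp_index(snp)
        out = []
        for i, row in self.families.iterrows():
            sex = row["child_sex"]
            out.append(
                TriadRecord(
                    family_id=str(row["family_id"]),
                    father=XGenotype(MALE, int(self.father_gt[i, j])),
                    mother=XGenotype(FEMALE, int(self.mother_gt[i, j])),
                    child=XGenotype(sex, int(self.child_gt[i, j])),
                    child_sex=sex,
                    design=row.get("design", "fetal_triad"),
                )
            )
        return out

    def subset_families(self, mask: np.ndarray) -> "TriadDataset":
        mask = np.asarray(mask)
        return TriadDataset(
            self.families.loc[mask].copy(),
            self.snps.copy(),
            self.father_gt[mask],
            self.mother_gt[mask],
            self.child_gt[mask],
        )
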