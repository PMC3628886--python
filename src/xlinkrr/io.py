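"""PLINK-style PED/MAP text I/O for X-linked family datasets.

The PED dialect is the classic 6 pedigree columns (family, individual,
father, mother, sex, phenotype) followed by two allele columns per SNP.
Male X genotypes are written as homozygous pairs, per PLINK convention, and
decoded back to hemizygous doses on read; "0 0" is missing.  A heterozygous
male X genotype is impossible data: it is decoded to missing and counted so
QC can see it.  The MAP file carries chrom/snp/cM/pos and, as an extension,
two extra columns naming the A1 and A2 allele so that dose codes round-trip
losslessly even for monomorphic SNPs.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .containers import DyadDataset, TriadDataset
from .core import FEMALE, MALE

__all__ = ["read_pedmap", "write_pedmap", "PedParseError"]

_X_CHROMS = {"23", "X", "x", "chrX", "chrx"}


class PedParseError(ValueError):
    """Malformed PED/MAP input, with the offending line number."""


def _geno_string(dose: int, sex: str, a1: str, a2: str) -> str:
    if dose < 0:
        return "0 0"
    if sex == MALE:
        a = a2 if dose == 1 else a1
        return f"{a} {a}"
    return {0: f"{a1} {a1}", 1: f"{a1} {a2}", 2: f"{a2} {a2}"}[dose]


def write_pedmap(
    dataset: Union[DyadDataset, TriadDataset],
    ped_path: Union[str, Path],
    map_path: Union[str, Path],
) -> None:
    """Write a dataset as PED/MAP text.

    Dyads produce a mother line (founder, sex 2) and a child line whose
    phenotype is 2 for case and 1 for control.  Triad families produce
    father/mother/child lines; non-case siblings get phenotype 0 and absent
    members are simply not written.
    """
    snps = dataset.snps
    a1 = snps["a1"].tolist()
    a2 = snps["a2"].tolist()
    n_snp = len(snps)
    triad = isinstance(dataset, TriadDataset)

    def genos(doses: np.ndarray, sex: str) -> str:
        return "\t".join(
            _geno_string(int(doses[j]), sex, a1[j], a2[j]) for j in range(n_snp)
        )

    lines: List[str] = []
    if not triad:
        for i, row in dataset.families.iterrows():
            fid = str(row["family_id"])
            sex_code = "1" if row["child_sex"] == MALE else "2"
            pheno = "2" if row["status"] == "case" else "1"
            lines.append(
                f"{fid}\t{fid}_mo\t0\t0\t2\t0\t" + genos(dataset.mother_gt[i], FEMALE)
            )
            lines.append(
                f"{fid}\t{fid}_ch\t0\t{fid}_mo\t{sex_code}\t{pheno}\t"
                + genos(dataset.child_gt[i], row["child_sex"])
            )
    else:
        written_parents = set()
        child_n: Dict[str, int] = {}
        for i, row in dataset.families.iterrows():
            fid = str(row["family_id"])
            fa_id, mo_id = f"{fid}_fa", f"{fid}_mo"
            if fid not in written_parents:
                if row["father_present"]:
                    lines.append(
                        f"{fid}\t{fa_id}\t0\t0\t1\t0\t" + genos(dataset.father_gt[i], MALE)
                    )
                if row["mother_present"]:
                    lines.append(
                        f"{fid}\t{mo_id}\t0\t0\t2\t0\t" + genos(dataset.mother_gt[i], FEMALE)
                    )
                written_parents.add(fid)
            k = child_n.get(fid, 0) + 1
            child_n[fid] = k
            sex_code = "1" if row["child_sex"] == MALE else "2"
            is_case = bool(row.get("is_case", True))
            pheno = "2" if is_case else "0"
            pat = fa_id if row["father_present"] else "0"
            mat = mo_id if row["mother_present"] else "0"
            lines.append(
                f"{fid}\t{fid}_ch{k}\t{pat}\t{mat}\t{sex_code}\t{pheno}\t"
                + genos(dataset.child_gt[i], row["child_sex"])
            )

    Path(ped_path).write_text("\n".join(lines) + ("\n" if lines else ""))

    map_lines = [
        f"{snps['chrom'].iloc[j]}\t{snps['snp'].iloc[j]}\t0\t{snps['pos'].iloc[j]}"
        f"\t{a1[j]}\t{a2[j]}"
        for j in range(n_snp)
    ]
    Path(map_path).write_text("\n".join(map_lines) + ("\n" if map_lines else ""))


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _read_map(map_path: Union[str, Path]) -> pd.DataFrame:
    rows = []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) not in (4, 6):
            raise PedParseError(
                f"{map_path}: line {ln}: expected 4 or 6 fields, got {len(parts)}"
            )
        chrom, snp, _cm, pos = parts[:4]
        if chrom not in _X_CHROMS:
            raise PedParseError(
                f"{map_path}: line {ln}: SNP {snp} is on chromosome {chrom}, "
                f"not the X; this analysis handles non-pseudoautosomal X SNPs only"
            )
        a1, a2 = (parts[4], parts[5]) if len(parts) == 6 else ("", "")
        rows.append({"snp": snp, "chrom": "X", "pos": int(pos), "a1": a1, "a2": a2})
    if not rows:
        raise PedParseError(f"{map_path}: empty MAP file")
    return pd.DataFrame(rows)


def _decode_doses(
    alleles_a: List[str],
    alleles_b: List[str],
    sexes: List[str],
    snps: pd.DataFrame,
) -> Tuple[np.ndarray, pd.DataFrame, int]:
    """Decode allele-pair strings to dose codes; returns (doses, snps with
    resolved a1/a2, count of male-het genotypes set to missing)."""
    n_ind, n_snp = len(sexes), len(snps)
    a = np.array(alleles_a, dtype=object).reshape(n_ind, n_snp)
    b = np.array(alleles_b, dtype=object).reshape(n_ind, n_snp)
    snps = snps.copy()
    male_het = 0
    doses = np.full((n_ind, n_snp), -1, dtype=np.int8)
    male = np.array([s == MALE for s in sexes])
    for j in range(n_snp):
        col_a, col_b = a[:, j], b[:, j]
        observed = sorted(set(col_a) | set(col_b) - {"0"} - {"0"})
        observed = [x for x in observed if x != "0"]
        a1, a2 = snps["a1"].iloc[j], snps["a2"].iloc[j]
        if not a1 or not a2:
            # no allele metadata in the MAP: take the minor observed allele as A2
            if len(observed) > 2:
                raise PedParseError(
                    f"SNP {snps['snp'].iloc[j]}: more than two alleles observed "
                    f"({observed}); only biallelic SNPs are supported"
                )
            counts = {x: int((col_a == x).sum() + (col_b == x).sum()) for x in observed}
            ordered = sorted(counts, key=lambda x: (counts[x], x), reverse=True)
            a1 = ordered[0] if ordered else "A"
            a2 = ordered[1] if len(ordered) > 1 else ("G" if a1 != "G" else "A")
            snps.loc[j, ["a1", "a2"]] = [a1, a2]
        known = {a1, a2, "0"}
        strange = [x for x in observed if x not in known]
        if strange:
            raise PedParseError(
                f"SNP {snps['snp'].iloc[j]}: unexpected allele(s) {strange}; "
                f"MAP declares {a1}/{a2}"
            )
        miss = (col_a == "0") | (col_b == "0")
        dose = (col_a == a2).astype(np.int8) + (col_b == a2).astype(np.int8)
        dose[miss] = -1
        het = male & (col_a != col_b) & ~miss
        if het.any():
            male_het += int(het.sum())
            dose[het] = -1
        dose[male & (dose == 2)] = 1
        doses[:, j] = dose
    return doses, snps, male_het


def read_pedmap(
    ped_path: Union[str, Path],
    map_path: Union[str, Path],
    design: str = "auto",
) -> Tuple[Union[DyadDataset, TriadDataset], Dict[str, int]]:
    """Read PED/MAP into a dataset, resolving pedigree roles.

    Children are the individuals with a parent reference; their mother/father
    rows are matched by id within the family.  With ``design='auto'`` the
    result is a :class:`TriadDataset` when any father appears and a
    :class:`DyadDataset` otherwise; pass ``design='maternal_triad'`` to mark
    an all-female triad study of case mothers and their parents.

    Returns the dataset and a small report dict including
    ``n_male_het_set_missing``, the count of impossible heterozygous male X
    genotypes decoded to missing.
    """
    if design not in ("auto", "dyad", "fetal_triad", "maternal_triad"):
        raise ValueError(f"unknown design {design!r}")
    snps = _read_map(map_path)
    n_snp = len(snps)
    expected = 6 + 2 * n_snp

    ind_rows = []
    alleles_a: List[str] = []
    alleles_b: List[str] = []
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != expected:
            raise PedParseError(
                f"{ped_path}: line {ln}: expected {expected} fields "
                f"(6 + 2 x {n_snp} SNPs), got {len(parts)}"
            )
        fid, iid, pat, mat, sex_code, pheno = parts[:6]
        if sex_code not in ("1", "2"):
            raise PedParseError(f"{ped_path}: line {ln}: sex must be 1 or 2, got {sex_code}")
        ind_rows.append(
            {
                "fid": fid, "iid": iid, "pat": pat, "mat": mat,
                "sex": MALE if sex_code == "1" else FEMALE, "pheno": pheno, "line": ln,
            }
        )
        alleles_a.extend(parts[6::2])
        alleles_b.extend(parts[7::2])
    if not ind_rows:
        raise PedParseError(f"{ped_path}: empty PED file")

    ind = pd.DataFrame(ind_rows)
    doses, snps, male_het = _decode_doses(
        alleles_a, alleles_b, ind["sex"].tolist(), snps
    )
    by_iid = {(r["fid"], r["iid"]): i for i, r in ind.iterrows()}

    children = ind[(ind["pat"] != "0") | (ind["mat"] != "0")]
    if children.empty:
        raise PedParseError(f"{ped_path}: no child rows (no parent references) found")
    any_father = (children["pat"] != "0").any()

    if design == "auto":
        design = "fetal_triad" if any_father else "dyad"

    report = {"n_male_het_set_missing": male_het, "n_individuals": len(ind)}

    if design == "dyad":
        fam_rows, mo_g, ch_g = [], [], []
        for _, ch in children.iterrows():
            key = (ch["fid"], ch["mat"])
            if ch["mat"] == "0" or key not in by_iid:
                raise PedParseError(
                    f"{ped_path}: line {ch['line']}: dyad child without a genotyped mother"
                )
            mi = by_iid[key]
            if ind["sex"].iloc[mi] != FEMALE:
                raise PedParseError(f"{ped_path}: mother {ch['mat']} is not female")
            status = {"2": "case", "1": "control"}.get(ch["pheno"])
            if status is None:
                raise PedParseError(
                    f"{ped_path}: line {ch['line']}: dyad child phenotype must be "
                    f"1 (control) or 2 (case), got {ch['pheno']}"
                )
            fam_rows.append(
                {"family_id": ch["fid"], "child_sex": ch["sex"], "status": status}
            )
            mo_g.append(doses[mi])
            ch_g.append(doses[ch.name])
        fam = pd.DataFrame(fam_rows)
        return (
            DyadDataset(fam, snps, np.array(mo_g, np.int8), np.array(ch_g, np.int8)),
            report,
        )

    fam_rows, fa_g, mo_g, ch_g = [], [], [], []
    for _, ch in children.iterrows():
        fid = ch["fid"]
        fa_i = by_iid.get((fid, ch["pat"])) if ch["pat"] != "0" else None
        mo_i = by_iid.get((fid, ch["mat"])) if ch["mat"] != "0" else None
        if ch["pat"] != "0" and fa_i is None:
            raise PedParseError(f"{ped_path}: line {ch['line']}: father {ch['pat']} not in file")
        if ch["mat"] != "0" and mo_i is None:
            raise PedParseError(f"{ped_path}: line {ch['line']}: mother {ch['mat']} not in file")
        if design == "maternal_triad" and ch["sex"] != FEMALE:
            raise PedParseError(
                f"{ped_path}: line {ch['line']}: maternal_triad affected individuals "
                f"must be female"
            )
        fam_rows.append(
            {
                "family_id": fid,
                "child_sex": ch["sex"],
                "design": design,
                "father_present": fa_i is not None,
                "mother_present": mo_i is not None,
                "child_present": True,
                "is_case": ch["pheno"] == "2",
            }
        )
        fa_g.append(doses[fa_i] if fa_i is not None else np.full(n_snp, -1, np.int8))
        mo_g.append(doses[mo_i] if mo_i is not None else np.full(n_snp, -1, np.int8))
        ch_g.append(doses[ch.name])
    fam = pd.DataFrame(fam_rows)
    return (
        TriadDataset(
            fam, snps,
            np.array(fa_g, np.int8), np.array(mo_g, np.int8), np.array(ch_g, np.int8),
        ),
        report,
    )
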