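"""SNP- and individual-level quality control for X-linked family data.

Filter order is fixed: (1) individuals (and with them, their whole dyads)
whose genotype call rate falls below the individual threshold are dropped;
(2) SNPs failing call rate, Mendelian-error count or minor allele frequency
are dropped, with all SNP statistics recomputed on the surviving
individuals.  Exclusion thresholds are strict inequalities — a value exactly
at the threshold is retained.  Female Hardy-Weinberg equilibrium is computed
and reported but never filters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DyadDataset, TriadDataset
from .core import MALE

__all__ = [
    "QCThresholds",
    "QCReport",
    "compute_maf",
    "count_mendelian_errors",
    "hwe_test_females",
    "apply_filters",
]


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion thresholds; defaults follow common dyad-study practice:
    SNP call rate < 95%, individual call rate < 97%, MAF < 1%, and more than
    five Mendelian inconsistencies per SNP."""

    snp_call_rate_min: float = 0.95
    individual_call_rate_min: float = 0.97
    maf_min: float = 0.01
    max_mendelian_errors_per_snp: int = 5
    hwe_alpha: float = 1e-6  # report-only flag level; HWE never filters

    def __post_init__(self) -> None:
        for name in ("snp_call_rate_min", "individual_call_rate_min", "maf_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.max_mendelian_errors_per_snp < 0:
            raise ValueError("max_mendelian_errors_per_snp must be non-negative")


@dataclass
class QCReport:
    """Everything the filters measured and decided.

    ``snp_table`` columns: snp, call_rate, maf, mendel_errors, hwe_p_females,
    dropped, reason.  ``individual_table`` columns: individual_id, family_id,
    role, call_rate, dropped, reason.  Dropped + retained partition the
    input, and every drop carries exactly one primary reason.
    """

    snp_table: pd.DataFrame
    individual_table: pd.DataFrame
    n_dyads_in: int
    n_dyads_out: int
    thresholds: QCThresholds

    @property
    def dropped_snps(self) -> list:
        return self.snp_table.loc[self.snp_table["dropped"], "snp"].tolist()

    @property
    def dropped_individuals(self) -> list:
        return self.individual_table.loc[
            self.individual_table["dropped"], "individual_id"
        ].tolist()

    def summary(self) -> dict:
        return {
            "n_dyads_in": int(self.n_dyads_in),
            "n_dyads_out": int(self.n_dyads_out),
            "n_snps_in": int(len(self.snp_table)),
            "n_snps_out": int((~self.snp_table["dropped"]).sum()),
            "n_individuals_dropped": int(self.individual_table["dropped"].sum()),
            "snp_drop_reasons": self.snp_table.loc[self.snp_table["dropped"], "reason"]
            .value_counts()
            .to_dict(),
            "thresholds": {
                "snp_call_rate_min": self.thresholds.snp_call_rate_min,
                "individual_call_rate_min": self.thresholds.individual_call_rate_min,
                "maf_min": self.thresholds.maf_min,
                "max_mendelian_errors_per_snp": self.thresholds.max_mendelian_errors_per_snp,
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)

    def to_tsv(self, snp_path, individual_path=None) -> None:
        self.snp_table.to_csv(snp_path, sep="\t", index=False)
        if individual_path is not None:
            self.individual_table.to_csv(individual_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# per-SNP statistics
# ---------------------------------------------------------------------------

def _allele_counts(dataset: DyadDataset, j: int) -> Tuple[float, float]:
    """(A2 allele count, total called alleles): 2 per female, 1 per male."""
    male_child = (dataset.families["child_sex"] == MALE).to_numpy()
    m = dataset.mother_gt[:, j]
    c = dataset.child_gt[:, j]
    a2 = float(m[m >= 0].sum()) + float(c[c >= 0].sum())
    total = 2.0 * float((m >= 0).sum())
    total += 1.0 * float(((c >= 0) & male_child).sum())
    total += 2.0 * float(((c >= 0) & ~male_child).sum())
    return a2, total


def compute_maf(dataset: DyadDataset, snp: Union[str, int]) -> float:
    """Minor allele frequency with females contributing two X alleles and
    hemizygous males one.  Undefined (NaN) for an all-missing SNP."""
    j = dataset.snp_index(snp)
    a2, total = _allele_counts(dataset, j)
    if total == 0:
        return float("nan")
    f = a2 / total
    return min(f, 1.0 - f)


def count_mendelian_errors(
    dataset: Union[DyadDataset, TriadDataset], snp: Union[str, int]
) -> int:
    """Families whose non-missing members are impossible under X-linked
    inheritance at this SNP.  Heterozygous-male input encodings are set to
    missing at parse time and counted by the reader, not here."""
    j = dataset.snp_index(snp)
    male = (dataset.families["child_sex"] == MALE).to_numpy()
    m = dataset.mother_gt[:, j].astype(np.int64)
    c = dataset.child_gt[:, j].astype(np.int64)
    if isinstance(dataset, TriadDataset):
        fa = dataset.father_gt[:, j].astype(np.int64)
    else:
        fa = np.full(len(m), -1, dtype=np.int64)

    obs_mc = (m >= 0) & (c >= 0)
    # boys: mother must carry the transmitted allele (father's X irrelevant)
    boy_err = male & obs_mc & ((m == 0) & (c == 1) | (m == 2) & (c == 0))
    # girls: one maternal + one paternal allele
    girl = ~male
    err_mo = girl & obs_mc & ((m == 0) & (c == 2) | (m == 2) & (c == 0))
    obs_fc = (fa >= 0) & (c >= 0)
    err_fa = girl & obs_fc & ((fa == 0) & (c == 2) | (fa == 1) & (c == 0))
    # both parents observed: child dose must equal a transmissible t + father
    obs_all = obs_mc & (fa >= 0)
    t_lo = np.where(m == 1, 0, m // 2)
    t_hi = np.where(m == 1, 1, m // 2)
    err_both = girl & obs_all & ((c < t_lo + fa) | (c > t_hi + fa))
    return int((boy_err | err_mo | err_fa | err_both).sum())


def hwe_test_females(dataset: DyadDataset, snp: Union[str, int]) -> float:
    """Pearson chi-square (1 df) Hardy-Weinberg test on female genotype
    counts only (mothers and daughters); males are excluded.  Report-only.
    Monomorphic SNPs return p = 1."""
    j = dataset.snp_index(snp)
    male = (dataset.families["child_sex"] == MALE).to_numpy()
    doses = np.concatenate(
        [dataset.mother_gt[:, j], dataset.child_gt[~male, j]]
    ).astype(np.int64)
    doses = doses[doses >= 0]
    if doses.size == 0:
        return float("nan")
    counts = np.bincount(doses, minlength=3).astype(float)
    n = counts.sum()
    q = (counts[1] + 2 * counts[2]) / (2 * n)
    if q == 0.0 or q == 1.0:
        return 1.0
    p = 1.0 - q
    expected = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _individual_call_rates(dataset: DyadDataset) -> pd.DataFrame:
    n_snp = dataset.n_snps
    rows = []
    for role, gt in (("mother", dataset.mother_gt), ("child", dataset.child_gt)):
        rate = (gt >= 0).sum(axis=1) / max(n_snp, 1)
        for i, fid in enumerate(dataset.families["family_id"]):
            rows.append(
                {
                    "individual_id": f"{fid}_{'mo' if role == 'mother' else 'ch'}",
                    "family_id": fid,
                    "role": role,
                    "call_rate": float(rate[i]),
                }
            )
    return pd.DataFrame(rows)


def _snp_stats(dataset: DyadDataset) -> pd.DataFrame:
    n_ind = 2 * dataset.n_families
    rows = []
    for j in range(dataset.n_snps):
        called = int((dataset.mother_gt[:, j] >= 0).sum() + (dataset.child_gt[:, j] >= 0).sum())
        rows.append(
            {
                "snp": dataset.snps["snp"].iloc[j],
                "call_rate": called / n_ind if n_ind else float("nan"),
                "maf": compute_maf(dataset, j),
                "mendel_errors": count_mendelian_errors(dataset, j),
                "hwe_p_females": hwe_test_females(dataset, j),
            }
        )
    return pd.DataFrame(rows)


def apply_filters(
    dataset: DyadDataset, thresholds: QCThresholds = QCThresholds()
) -> Tuple[DyadDataset, QCReport]:
    """Apply individual-level then SNP-level filters; report everything.

    A dropped individual removes the whole dyad.  SNP statistics are computed
    on the surviving dyads.  Primary drop reasons are assigned in threshold
    order: call rate, then Mendelian errors, then MAF.
    """
    n_in = dataset.n_families

    ind = _individual_call_rates(dataset)
    ind["dropped"] = ind["call_rate"] < thresholds.individual_call_rate_min
    ind["reason"] = np.where(ind["dropped"], "call_rate", "")
    bad_families = set(ind.loc[ind["dropped"], "family_id"])
    keep = ~dataset.families["family_id"].isin(bad_families).to_numpy()
    survivors = dataset.subset_families(keep)

    snp = _snp_stats(survivors)
    low_cr = snp["call_rate"] < thresholds.snp_call_rate_min
    many_me = snp["mendel_errors"] > thresholds.max_mendelian_errors_per_snp
    low_maf = (snp["maf"] < thresholds.maf_min) | snp["maf"].isna()
    snp["dropped"] = low_cr | many_me | low_maf
    snp["reason"] = ""
    snp.loc[low_maf, "reason"] = "maf"
    snp.loc[many_me, "reason"] = "mendelian_errors"
    snp.loc[low_cr, "reason"] = "call_rate"

    filtered = survivors.subset_snps((~snp["dropped"]).to_numpy())
    report = QCReport(
        snp_table=snp,
        individual_table=ind,
        n_dyads_in=n_in,
        n_dyads_out=filtered.n_families,
        thresholds=thresholds,
    )
    return filtered, report
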