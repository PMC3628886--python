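"""Fixed-effects meta-analysis of per-study X-linked relative risks.

Per SNP, the combined log RR is the inverse-variance-weighted average of
the study log RRs, with each study's SE recovered from its printed 95% CI
as (ln U - ln L) / (2 x 1.959964) when raw SEs are unavailable; overall
p-values are additionally combined with Fisher's method (-2 sum ln p ~
chi-square, 2k df), which is direction-agnostic.  Bonferroni thresholds and
QQ-plot quantile tables round out the scan-level diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Z95",
    "StudyResult",
    "MetaResult",
    "inverse_variance_combine",
    "fisher_combine",
    "bonferroni_threshold",
    "qq_data",
    "meta_scan",
]

Z95 = 1.959964

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyResult:
    """One study's estimate for one SNP: RR with 95% CI and overall p."""

    snp: str
    rr: float
    ci_low: float
    ci_high: float
    p_overall: Optional[float] = None
    study: str = ""
    alleles: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.ci_low <= self.rr <= self.ci_high):
            raise ValueError(
                f"invalid CI for {self.snp}: need 0 < low <= RR <= high, "
                f"got {self.rr} ({self.ci_low}, {self.ci_high})"
            )

    @property
    def se_log_rr(self) -> float:
        """SE of log RR recovered from the 95% CI width."""
        return (np.log(self.ci_high) - np.log(self.ci_low)) / (2.0 * Z95)

    def flipped(self) -> "StudyResult":
        """The same estimate oriented to the other allele (RR -> 1/RR)."""
        alleles = None
        if self.alleles:
            a, b = _parse_alleles(self.alleles)
            alleles = f"{b.swapcase()}/{a.swapcase()}" if a else self.alleles
        return StudyResult(
            snp=self.snp,
            rr=1.0 / self.rr,
            ci_low=1.0 / self.ci_high,
            ci_high=1.0 / self.ci_low,
            p_overall=self.p_overall,
            study=self.study,
            alleles=alleles,
        )


@dataclass(frozen=True)
class MetaResult:
    """Fixed-effects combination across studies for one SNP."""

    snp: str
    rr: float
    ci_low: float
    ci_high: float
    se_log_rr: float
    p_rr: float
    p_fisher: Optional[float]
    weights: Tuple[float, ...]


def inverse_variance_combine(results: Sequence[StudyResult]) -> MetaResult:
    """Precision-weighted fixed-effects combination of study log RRs.

    Weights are 1/SE_i^2 with SE_i recovered from each 95% CI; the combined
    SE is 1/sqrt(sum of weights) and p_rr is the two-sided Wald p on the
    combined log RR.  Needs at least two studies with non-degenerate CIs.
    """
    if len(results) < 2:
        raise ValueError("need at least two studies to combine")
    log_rr = np.array([np.log(r.rr) for r in results])
    ses = np.array([r.se_log_rr for r in results])
    if np.any(ses <= 0):
        bad = [r.snp for r, s in zip(results, ses) if s <= 0]
        raise ValueError(f"degenerate CI (upper == lower) for {bad}")
    w = 1.0 / ses**2
    combined = float((w @ log_rr) / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    ps = [r.p_overall for r in results]
    p_fisher = fisher_combine(ps) if all(p is not None for p in ps) else None
    return MetaResult(
        snp=results[0].snp,
        rr=float(np.exp(combined)),
        ci_low=float(np.exp(combined - Z95 * se)),
        ci_high=float(np.exp(combined + Z95 * se)),
        se_log_rr=se,
        p_rr=float(2.0 * stats.norm.sf(abs(combined / se))),
        p_fisher=p_fisher,
        weights=tuple(float(x) for x in w / w.sum()),
    )


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's method: -2 sum ln p ~ chi-square with 2k degrees of freedom."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    x2 = -2.0 * float(np.log(p).sum())
    return float(stats.chi2.sf(x2, df=2 * p.size))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m for m tests."""
    if m < 1:
        raise ValueError("m must be at least 1")
    return alpha / m


def qq_data(p_values: Sequence[float]) -> pd.DataFrame:
    """Expected-vs-observed quantile table for a QQ plot of p-values.

    Observed p sorted ascending against expected quantiles (i - 0.5)/m, with
    -log10 columns ready for plotting.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    if p.size == 0:
        raise ValueError("no p-values")
    m = p.size
    expected = (np.arange(1, m + 1) - 0.5) / m
    return pd.DataFrame(
        {
            "expected": expected,
            "observed": p,
            "neg_log10_expected": -np.log10(expected),
            "neg_log10_observed": -np.log10(np.clip(p, np.finfo(float).tiny, None)),
        }
    )


# ---------------------------------------------------------------------------
# scan-level combination
# ---------------------------------------------------------------------------

_REQUIRED = ("snp", "rr", "ci_low", "ci_high")


def _parse_alleles(alleles: Optional[str]) -> Tuple[str, str]:
    if not alleles or "/" not in str(alleles):
        return "", ""
    a, b = str(alleles).split("/", 1)
    return a.strip(), b.strip()


def _minor_allele(alleles: Optional[str]) -> str:
    """Lower-case letter in an 'A/g'-style allele pair marks the minor/risk
    allele the RR refers to."""
    a, b = _parse_alleles(alleles)
    for x in (a, b):
        if x and x == x.lower():
            return x.upper()
    return ""


def meta_scan(
    study_tables: Sequence[pd.DataFrame],
    study_labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Combine two or more per-study scan tables SNP by SNP.

    Input tables need columns snp, rr, ci_low, ci_high and optionally
    alleles and p_overall.  SNPs absent from any study are dropped (logged).
    When studies orient a SNP to opposite alleles (e.g. 'A/g' vs 'a/G'),
    the discordant study's RR is inverted before combining and the flip is
    logged.  Output is sorted by the combined Wald p.
    """
    if len(study_tables) < 2:
        raise ValueError("need at least two study tables")
    labels = list(study_labels) if study_labels else [f"study{i+1}" for i in range(len(study_tables))]
    tables = []
    for lab, t in zip(
        study_labels or [f"study{i+1}" for i in range(len(study_tables))], study_tables
    ):
        missing = [c for c in _REQUIRED if c not in t.columns]
        if missing:
            raise ValueError(f"study table lacks columns {missing}")
        vals = t[["rr", "ci_low", "ci_high"]].to_numpy(dtype=float)
        usable = (
            np.isfinite(vals).all(axis=1)
            & (vals[:, 1] > 0)
            & (vals[:, 1] <= vals[:, 0])
            & (vals[:, 0] <= vals[:, 2])
            & (vals[:, 1] < vals[:, 2])
        )
        if (~usable).any():
            logger.info(
                "meta_scan: dropping %d SNPs with unusable estimates "
                "(boundary or non-finite CI) from %s", int((~usable).sum()), lab
            )
        tables.append(t.loc[usable].set_index("snp", drop=False))

    shared = set(tables[0].index)
    for t in tables[1:]:
        shared &= set(t.index)
    for lab, t in zip(labels, tables):
        dropped = set(t.index) - shared
        if dropped:
            logger.info("meta_scan: %d SNPs absent from other studies dropped (%s)", len(dropped), lab)

    rows = []
    for snp in sorted(shared):
        per_study: List[StudyResult] = []
        ref_minor = ""
        for lab, t in zip(labels, tables):
            rec = t.loc[snp]
            sr = StudyResult(
                snp=str(snp),
                rr=float(rec["rr"]),
                ci_low=float(rec["ci_low"]),
                ci_high=float(rec["ci_high"]),
                p_overall=float(rec["p_overall"]) if "p_overall" in rec and pd.notna(rec["p_overall"]) else None,
                study=lab,
                alleles=str(rec["alleles"]) if "alleles" in rec and pd.notna(rec["alleles"]) else None,
            )
            minor = _minor_allele(sr.alleles)
            if not ref_minor:
                ref_minor = minor
            elif minor and ref_minor and minor != ref_minor:
                logger.info("meta_scan: flipping allele orientation of %s in %s", snp, lab)
                sr = sr.flipped()
            per_study.append(sr)
        combined = inverse_variance_combine(per_study)
        rows.append(
            {
                "snp": snp,
                "alleles": per_study[0].alleles,
                "rr": combined.rr,
                "ci_low": combined.ci_low,
                "ci_high": combined.ci_high,
                "p_rr": combined.p_rr,
                "p_fisher": combined.p_fisher,
            }
        )
    out = pd.DataFrame(
        rows, columns=["snp", "alleles", "rr", "ci_low", "ci_high", "p_rr", "p_fisher"]
    )
    return out.sort_values("p_rr", kind="mergesort").reset_index(drop=True)
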