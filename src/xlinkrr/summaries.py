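"""Cohort descriptive statistics: group comparison tables and family rosters."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .containers import TriadDataset

__all__ = ["chisq_2x2", "family_roster_summary", "CohortSummary", "cohort_summary"]


def chisq_2x2(counts) -> float:
    """Two-sided Pearson chi-square p-value (1 df, no continuity correction)
    for a 2x2 contingency table of non-negative integer counts."""
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"need a 2x2 table, got shape {t.shape}")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("both margins must be positive")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(p)


def family_roster_summary(dataset: TriadDataset) -> Dict[str, object]:
    """Tally triad-study families by composition.

    Families are grouped by id: full triads (both parents + one child),
    mother-infant and father-infant dyads, and larger families (both parents
    with several genotyped children), plus totals of families and
    individuals.  An absent parent does not count as an individual.
    """
    fam = dataset.families
    full = mo_dyad = fa_dyad = 0
    larger: Dict[int, int] = {}
    n_individuals = 0
    if len(fam) == 0:
        return {
            "full_triads": 0, "mother_infant_dyads": 0, "father_infant_dyads": 0,
            "larger_families": {}, "n_families": 0, "n_individuals": 0,
        }
    for _, grp in fam.groupby("family_id", sort=False):
        n_children = int(grp["child_present"].sum())
        father = bool(grp["father_present"].any())
        mother = bool(grp["mother_present"].any())
        members = n_children + int(father) + int(mother)
        n_individuals += members
        if father and mother and n_children == 1:
            full += 1
        elif mother and not father and n_children == 1:
            mo_dyad += 1
        elif father and not mother and n_children == 1:
            fa_dyad += 1
        else:
            larger[members] = larger.get(members, 0) + 1
    return {
        "full_triads": full,
        "mother_infant_dyads": mo_dyad,
        "father_infant_dyads": fa_dyad,
        "larger_families": larger,
        "n_families": int(fam["family_id"].nunique()),
        "n_individuals": n_individuals,
    }


@dataclass
class CohortSummary:
    """Two-group descriptive table: continuous variables as median (range),
    categorical as count (%), with chi-square p for binary categoricals.
    Percentages use non-missing denominators; missing counts are reported."""

    group_sizes: Dict[str, int]
    table: pd.DataFrame


def _fmt_median_range(x: pd.Series) -> str:
    x = x.dropna()
    if x.empty:
        return "-"
    return f"{x.median():g} ({x.min():g}–{x.max():g})"


def cohort_summary(
    frame: pd.DataFrame,
    group_col: str = "status",
    continuous: Sequence[str] = (),
    categorical: Sequence[str] = (),
) -> CohortSummary:
    """Table-1-style summary of a per-family covariate frame.

    ``frame`` holds one row per family with a two-level ``group_col``.
    Binary categorical variables get a Pearson chi-square p-value (no
    continuity correction); continuous variables are described but not
    tested (the appropriate test depends on the variable's distribution).
    """
    groups = list(pd.unique(frame[group_col]))
    if len(groups) != 2:
        raise ValueError(f"{group_col} must have exactly two levels, got {groups}")
    g0 = frame[frame[group_col] == groups[0]]
    g1 = frame[frame[group_col] == groups[1]]

    rows: List[Dict[str, object]] = []
    for var in continuous:
        rows.append(
            {
                "variable": var,
                str(groups[0]): _fmt_median_range(g0[var]),
                str(groups[1]): _fmt_median_range(g1[var]),
                "p": np.nan,
                "n_missing": int(frame[var].isna().sum()),
            }
        )
    for var in categorical:
        levels = [lv for lv in pd.unique(frame[var].dropna())]
        if len(levels) != 2:
            raise ValueError(f"categorical variable {var!r} must be binary, got {levels}")
        lv = sorted(map(str, levels))[0]
        cells = []
        shown = []
        for g in (g0, g1):
            x = g[var].dropna().astype(str)
            k, n = int((x == lv).sum()), len(x)
            cells.append([k, n - k])
            shown.append(f"{k} ({100.0 * k / n:.1f}%)" if n else "-")
        p = chisq_2x2(np.array(cells).T) if all(sum(c) for c in cells) else np.nan
        rows.append(
            {
                "variable": f"{var}={lv}",
                str(groups[0]): shown[0],
                str(groups[1]): shown[1],
                "p": p,
                "n_missing": int(frame[var].isna().sum()),
            }
        )
    return CohortSummary(
        group_sizes={str(groups[0]): len(g0), str(groups[1]): len(g1)},
        table=pd.DataFrame(rows),
    )
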