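"""X-chromosome genotype algebra for family-based association designs.

Biallelic X-linked SNPs are coded by the number of copies of the designated
risk allele ``A2``: females carry 0, 1 or 2 copies, hemizygous males carry
0 or 1.  Everything downstream (simulation, QC, likelihoods) works on these
dose codes; :class:`XGenotype` is the record-level wrapper.

The population model is Hardy-Weinberg equilibrium in mothers with random
mating and a common male/female allele frequency ``q`` for A2.  Disease risk
is multiplicative on a sex-specific baseline: boys carrying A2 and girls
homozygous for A2 have their baseline multiplied by the relative risk R,
while heterozygous girls get the average of the baseline and the full-risk
rate, ``(1+R)/2`` times baseline — the X-inactivation dosage model.  A purely
multiplicative female dose (het R, hom R^2) is available as an option.
Baseline risks never enter the cell probabilities used here: conditioning on
case status within a sex stratum cancels them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "A1",
    "A2",
    "MALE",
    "FEMALE",
    "MISSING",
    "X_INACTIVATION",
    "MULTIPLICATIVE",
    "XGenotype",
    "DyadRecord",
    "TriadRecord",
    "RiskModel",
    "enumerate_dyad_cells",
    "enumerate_triad_cells",
    "dyad_population_prob",
    "mendelian_consistent",
    "risk_multiplier",
    "dyad_cell_table",
    "triad_cell_table",
    "hwe_probs",
    "female_dose_multipliers",
    "male_dose_multipliers",
]

#: The two allele symbols per SNP. A2 is the designated risk/minor allele.
A1 = "A1"
A2 = "A2"

MALE = "male"
FEMALE = "female"

#: Dose code for a missing genotype.
MISSING = -1

X_INACTIVATION = "x_inactivation_average"
MULTIPLICATIVE = "multiplicative"

Sex = Literal["male", "female"]


def _dose_from_alleles(sex: Sex, alleles: Sequence[str]) -> int:
    n2 = sum(1 for a in alleles if a == A2)
    if any(a not in (A1, A2) for a in alleles):
        raise ValueError(f"unknown allele symbols in {alleles!r}")
    return n2


@dataclass(frozen=True)
class XGenotype:
    """Genotype of one individual at one X-linked SNP.

    ``dose`` is the number of A2 copies: 0..2 for females, 0..1 for males,
    or :data:`MISSING` (-1).  Female genotypes are unordered (A1A2 == A2A1).
    """

    sex: Sex
    dose: int = MISSING

    def __post_init__(self) -> None:
        if self.sex not in (MALE, FEMALE):
            raise ValueError(f"sex must be {MALE!r} or {FEMALE!r}, got {self.sex!r}")
        hi = 1 if self.sex == MALE else 2
        if not (self.dose == MISSING or 0 <= self.dose <= hi):
            raise ValueError(
                f"invalid dose {self.dose} for a {self.sex} X genotype "
                f"(a male never carries two alleles)"
            )

    @classmethod
    def from_alleles(cls, sex: Sex, alleles: Optional[Sequence[str]]) -> "XGenotype":
        """Build from allele symbols: a pair for females, one allele for males."""
        if alleles is None:
            return cls(sex, MISSING)
        expected = 1 if sex == MALE else 2
        if len(alleles) != expected:
            raise ValueError(
                f"a {sex} X genotype carries exactly {expected} allele(s), got {len(alleles)}"
            )
        return cls(sex, _dose_from_alleles(sex, alleles))

    @property
    def missing(self) -> bool:
        return self.dose == MISSING

    @property
    def alleles(self) -> Optional[Tuple[str, ...]]:
        """Allele symbols, sorted (A1 first), or None when missing."""
        if self.missing:
            return None
        n = 1 if self.sex == MALE else 2
        return tuple([A1] * (n - self.dose) + [A2] * self.dose)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.missing:
            return f"{self.sex}:?"
        return f"{self.sex}:{''.join(a[-1] for a in self.alleles)}"


@dataclass(frozen=True)
class DyadRecord:
    """One mother-child pair at one SNP, with the child's case status."""

    family_id: str
    mother: XGenotype
    child: XGenotype
    child_sex: Sex
    status: Literal["case", "control"]

    def __post_init__(self) -> None:
        if self.mother.sex != FEMALE:
            raise ValueError("dyad mother must be female")
        if self.child.sex != self.child_sex:
            raise ValueError("child genotype sex must match child_sex")
        if self.status not in ("case", "control"):
            raise ValueError(f"status must be 'case' or 'control', got {self.status!r}")


@dataclass(frozen=True)
class TriadRecord:
    """One case family at one SNP: affected individual plus both parents.

    In the ``maternal_triad`` design the "child" slot holds the case mother
    (always female) and the parent slots hold her own parents.
    """

    family_id: str
    father: XGenotype
    mother: XGenotype
    child: XGenotype
    child_sex: Sex
    design: Literal["fetal_triad", "maternal_triad"] = "fetal_triad"

    def __post_init__(self) -> None:
        if self.father.sex != MALE:
            raise ValueError("triad father must be male")
        if self.mother.sex != FEMALE:
            raise ValueError("triad mother must be female")
        if self.child.sex != self.child_sex:
            raise ValueError("child genotype sex must match child_sex")
        if self.design == "maternal_triad" and self.child_sex != FEMALE:
            raise ValueError("in the maternal_triad design the affected individual is female")


@dataclass(frozen=True)
class RiskModel:
    """Multiplicative X-linked disease-risk model with sex-specific baselines.

    Parameters
    ----------
    q
        Population frequency of the risk allele A2, strictly inside (0, 1).
    rr_fetal, rr_maternal
        Relative risks attached to the child's and the mother's own genotype.
    baseline_male, baseline_female
        Baseline disease risks for boys (B_B) and girls (B_G) carrying no risk
        allele.  They scale absolute risks (and hence the case sex ratio) but
        cancel out of all within-sex conditional probabilities.
    female_dose_mode
        ``"x_inactivation_average"`` (default): heterozygous females get
        multiplier (1+R)/2.  ``"multiplicative"``: het R, hom R^2.
    """

    q: float
    rr_fetal: float = 1.0
    rr_maternal: float = 1.0
    baseline_male: float = 0.0636
    baseline_female: float = 0.055
    female_dose_mode: str = X_INACTIVATION

    def __post_init__(self) -> None:
        if not (0.0 < self.q < 1.0):
            raise ValueError(f"q must be strictly inside (0, 1), got {self.q}")
        if self.rr_fetal <= 0 or self.rr_maternal <= 0:
            raise ValueError("relative risks must be positive")
        if not (0.0 < self.baseline_male < 1.0 and 0.0 < self.baseline_female < 1.0):
            raise ValueError("baseline risks must lie in (0, 1)")
        if self.female_dose_mode not in (X_INACTIVATION, MULTIPLICATIVE):
            raise ValueError(f"unknown female dose mode {self.female_dose_mode!r}")


# ---------------------------------------------------------------------------
# dose-level helpers (vectorized; the building blocks for likelihoods)
# ---------------------------------------------------------------------------

def hwe_probs(q: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities (p^2, 2pq, q^2) for doses 0,1,2."""
    p = 1.0 - q
    return np.array([p * p, 2.0 * p * q, q * q])


def _transmission_prob(mother_dose: int, transmitted: int) -> float:
    """P(mother with given A2 dose transmits `transmitted` A2 copies (0/1))."""
    if mother_dose == 1:
        return 0.5
    return 1.0 if transmitted == (mother_dose // 2) else 0.0


def female_dose_multipliers(rr: float, mode: str = X_INACTIVATION) -> np.ndarray:
    """Risk multipliers for female doses (0, 1, 2) under the chosen dose model."""
    if mode == X_INACTIVATION:
        return np.array([1.0, (1.0 + rr) / 2.0, rr])
    if mode == MULTIPLICATIVE:
        return np.array([1.0, rr, rr * rr])
    raise ValueError(f"unknown female dose mode {mode!r}")


def male_dose_multipliers(rr: float) -> np.ndarray:
    """Risk multipliers for hemizygous male doses (0, 1)."""
    return np.array([1.0, rr])


# Mendelian-consistent dyad cells as (mother_dose, child_dose) arrays.
_BOY_CELLS = (np.array([0, 1, 1, 2]), np.array([0, 0, 1, 1]))
_GIRL_CELLS = (
    np.array([0, 0, 1, 1, 1, 2, 2]),
    np.array([0, 1, 0, 1, 2, 1, 2]),
)


def dyad_cell_table(child_sex: Sex) -> Tuple[np.ndarray, np.ndarray]:
    """Mendelian-consistent (mother_dose, child_dose) cells for one child sex.

    Boys: 4 cells (the mother must transmit an allele she carries).  Girls:
    7 cells, the unobserved father allele marginalized out.
    """
    if child_sex == MALE:
        return _BOY_CELLS
    return _GIRL_CELLS


def dyad_cell_probs(child_sex: Sex, q: float) -> np.ndarray:
    """Population probability of each dyad cell under HWE + random mating."""
    m, c = dyad_cell_table(child_sex)
    hwe = hwe_probs(q)
    out = np.empty(len(m))
    for i, (mi, ci) in enumerate(zip(m, c)):
        if child_sex == MALE:
            out[i] = hwe[mi] * _transmission_prob(mi, ci)
        else:
            # child dose = maternal transmitted + paternal allele ~ Bernoulli(q)
            tot = 0.0
            for t in (0, 1):
                f = ci - t
                if f in (0, 1):
                    pat = q if f == 1 else 1.0 - q
                    tot += _transmission_prob(mi, t) * pat
            out[i] = hwe[mi] * tot
    return out


def dyad_cell_multipliers(
    child_sex: Sex,
    rr_fetal: float,
    rr_maternal: float,
    mode: str = X_INACTIVATION,
) -> np.ndarray:
    """Case risk multiplier for each dyad cell: fetal part x maternal part."""
    m, c = dyad_cell_table(child_sex)
    mat = female_dose_multipliers(rr_maternal, mode)[m]
    if child_sex == MALE:
        fet = male_dose_multipliers(rr_fetal)[c]
    else:
        fet = female_dose_multipliers(rr_fetal, mode)[c]
    return fet * mat


def _triad_cells(child_sex: Sex) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mendelian-consistent (father_dose, mother_dose, child_dose) triad cells."""
    cells = []
    for fa in (0, 1):
        for m in (0, 1, 2):
            transmissible = {m // 2} if m != 1 else {0, 1}
            for t in transmissible:
                if child_sex == MALE:
                    cells.append((fa, m, t))
                else:
                    cells.append((fa, m, t + fa))
    arr = np.array(sorted(set(cells)))
    return arr[:, 0], arr[:, 1], arr[:, 2]


def triad_cell_table(child_sex: Sex) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    return _triad_cells(child_sex)


def triad_cell_probs(child_sex: Sex, q: float) -> np.ndarray:
    """Population probability of each triad cell: Bernoulli(q) father x HWE
    mother x Mendelian transmission."""
    fa, m, c = triad_cell_table(child_sex)
    hwe = hwe_probs(q)
    out = np.empty(len(fa))
    for i in range(len(fa)):
        pf = q if fa[i] == 1 else 1.0 - q
        if child_sex == MALE:
            trans = _transmission_prob(m[i], c[i])
        else:
            t = c[i] - fa[i]
            trans = _transmission_prob(m[i], t) if t in (0, 1) else 0.0
        out[i] = pf * hwe[m[i]] * trans
    return out


def triad_cell_multipliers(
    child_sex: Sex,
    rr_fetal: float,
    rr_maternal: float,
    mode: str = X_INACTIVATION,
    design: str = "fetal_triad",
) -> np.ndarray:
    """Case risk multiplier per triad cell.

    ``fetal_triad``: the affected child's genotype carries rr_fetal and the
    mother's carries rr_maternal.  ``maternal_triad``: the affected individual
    in the child slot is the case mother herself; only her own genotype
    carries a risk multiplier (rr_maternal).
    """
    fa, m, c = triad_cell_table(child_sex)
    if design == "maternal_triad":
        if child_sex != FEMALE:
            raise ValueError("maternal_triad cells are all-female in the child slot")
        return female_dose_multipliers(rr_maternal, mode)[c]
    mat = female_dose_multipliers(rr_maternal, mode)[m]
    if child_sex == MALE:
        fet = male_dose_multipliers(rr_fetal)[c]
    else:
        fet = female_dose_multipliers(rr_fetal, mode)[c]
    return fet * mat


# ---------------------------------------------------------------------------
# record-level operations
# ---------------------------------------------------------------------------

def enumerate_dyad_cells(child_sex: Sex) -> list[Tuple[XGenotype, XGenotype]]:
    """All Mendelian-consistent non-missing (mother, child) genotype pairs."""
    m, c = dyad_cell_table(child_sex)
    return [
        (XGenotype(FEMALE, int(mi)), XGenotype(child_sex, int(ci)))
        for mi, ci in zip(m, c)
    ]


def enumerate_triad_cells(child_sex: Sex) -> list[Tuple[XGenotype, XGenotype, XGenotype]]:
    """All Mendelian-consistent non-missing (father, mother, child) triples."""
    fa, m, c = triad_cell_table(child_sex)
    return [
        (XGenotype(MALE, int(f)), XGenotype(FEMALE, int(mi)), XGenotype(child_sex, int(ci)))
        for f, mi, ci in zip(fa, m, c)
    ]


def dyad_population_prob(
    mother: XGenotype, child: XGenotype, child_sex: Sex, q: float
) -> float:
    """Population probability of a non-missing dyad cell.

    Mothers follow HWE; boys inherit one maternal allele; girls additionally
    receive an independent paternal allele with A2 frequency q.  Mendelian-
    inconsistent cells have probability zero.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must be strictly inside (0, 1)")
    if mother.missing or child.missing:
        raise ValueError("dyad_population_prob requires non-missing genotypes")
    m, c = dyad_cell_table(child_sex)
    probs = dyad_cell_probs(child_sex, q)
    match = (m == mother.dose) & (c == child.dose)
    if not match.any():
        return 0.0
    return float(probs[match][0])


def mendelian_consistent(
    mother: XGenotype,
    child: XGenotype,
    child_sex: Sex,
    father: Optional[XGenotype] = None,
) -> bool:
    """True iff some X-linked transmission pattern explains the child.

    Missing genotypes (or an absent father) are compatible with anything.
    Boys carry one maternal allele and no paternal X contribution; girls
    carry one maternal and the paternal allele.
    """
    md = mother.dose if (mother is not None and not mother.missing) else None
    cd = child.dose if (child is not None and not child.missing) else None
    fd = father.dose if (father is not None and not father.missing) else None
    if cd is None:
        return True
    maternal_options = {0, 1} if md is None else ({0, 1} if md == 1 else {md // 2})
    if child_sex == MALE:
        return cd in maternal_options
    paternal_options = {0, 1} if fd is None else {fd}
    return any(t + f == cd for t in maternal_options for f in paternal_options)


def risk_multiplier(
    mother: XGenotype,
    child: XGenotype,
    child_sex: Sex,
    model: RiskModel,
) -> float:
    """Joint fetal x maternal risk multiplier for one dyad cell.

    The full disease risk is B_sex times this factor; baselines live outside
    this operation.  Raises on missing genotypes — the caller must marginalize
    those inside the likelihood instead.
    """
    if mother.missing or child.missing:
        raise ValueError(
            "risk_multiplier is undefined for missing genotypes; "
            "marginalize over completions in the likelihood"
        )
    mat = float(female_dose_multipliers(model.rr_maternal, model.female_dose_mode)[mother.dose])
    if child_sex == MALE:
        fet = float(male_dose_multipliers(model.rr_fetal)[child.dose])
    else:
        fet = float(female_dose_multipliers(model.rr_fetal, model.female_dose_mode)[child.dose])
    return fet * mat
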