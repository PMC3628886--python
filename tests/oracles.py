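"""Independent brute-force oracles used across the test suite.

Everything here is computed from first principles (HWE, fair transmission,
Bernoulli paternal alleles, explicit enumeration of completions) without
calling the package's cell-table or likelihood code, so that agreement is a
real cross-check rather than a tautology.
"""

from __future__ import annotations

import itertools
import math
from typing import List, Optional, Sequence, Tuple

MALE, FEMALE = "male", "female"


def hwe(dose: int, q: float) -> float:
    p = 1.0 - q
    return {0: p * p, 1: 2 * p * q, 2: q * q}[dose]


def bern(allele: int, q: float) -> float:
    return q if allele == 1 else 1.0 - q


def transmit(mother_dose: int, t: int) -> float:
    if mother_dose == 1:
        return 0.5
    return 1.0 if t == mother_dose // 2 else 0.0


def female_mult(dose: int, rr: float, mode: str = "x_inactivation_average") -> float:
    if mode == "x_inactivation_average":
        return [1.0, (1.0 + rr) / 2.0, rr][dose]
    return [1.0, rr, rr * rr][dose]


def male_mult(dose: int, rr: float) -> float:
    return [1.0, rr][dose]


def dyad_cell_space(sex: str) -> List[Tuple[int, int]]:
    child_range = (0, 1) if sex == MALE else (0, 1, 2)
    return [(m, c) for m in (0, 1, 2) for c in child_range]


def dyad_pop_prob(m: int, c: int, sex: str, q: float) -> float:
    """Population dyad probability by explicit sum over transmissions."""
    if sex == MALE:
        return hwe(m, q) * transmit(m, c)
    tot = 0.0
    for t in (0, 1):
        f = c - t
        if f in (0, 1):
            tot += transmit(m, t) * bern(f, q)
    return hwe(m, q) * tot


def dyad_case_weight(
    m: int, c: int, sex: str, q: float, rr_f: float, rr_m: float, mode: str
) -> float:
    fet = male_mult(c, rr_f) if sex == MALE else female_mult(c, rr_f, mode)
    return dyad_pop_prob(m, c, sex, q) * fet * female_mult(m, rr_m, mode)


def dyad_loglik_oracle(
    records: Sequence[Tuple[int, int, str, str]],
    q: float,
    rr_f: float,
    rr_m: float,
    mode: str = "x_inactivation_average",
) -> float:
    """Log-likelihood by enumerating every completion of every dyad.

    ``records``: (mother_dose, child_dose, sex, status) with -1 for missing.
    """
    ll = 0.0
    for m_obs, c_obs, sex, status in records:
        m_opts = (0, 1, 2) if m_obs < 0 else (m_obs,)
        c_opts = ((0, 1) if sex == MALE else (0, 1, 2)) if c_obs < 0 else (c_obs,)
        if status == "control":
            prob = sum(dyad_pop_prob(m, c, sex, q) for m in m_opts for c in c_opts)
        else:
            num = sum(
                dyad_case_weight(m, c, sex, q, rr_f, rr_m, mode)
                for m in m_opts
                for c in c_opts
            )
            den = sum(
                dyad_case_weight(m, c, sex, q, rr_f, rr_m, mode)
                for m, c in dyad_cell_space(sex)
            )
            prob = num / den
        ll += math.log(prob)
    return ll


# --- triads ----------------------------------------------------------------

def triad_cell_space(sex: str) -> List[Tuple[int, int, int]]:
    child_range = (0, 1) if sex == MALE else (0, 1, 2)
    return [
        (fa, m, c) for fa in (0, 1) for m in (0, 1, 2) for c in child_range
    ]


def triad_pop_prob(fa: int, m: int, c: int, sex: str, q: float) -> float:
    if sex == MALE:
        trans = transmit(m, c)
    else:
        t = c - fa
        trans = transmit(m, t) if t in (0, 1) else 0.0
    return bern(fa, q) * hwe(m, q) * trans


def triad_case_weight(
    fa: int, m: int, c: int, sex: str, q: float,
    rr_f: float, rr_m: float, mode: str, design: str,
) -> float:
    pop = triad_pop_prob(fa, m, c, sex, q)
    if design == "maternal_triad":
        return pop * female_mult(c, rr_m, mode)
    fet = male_mult(c, rr_f) if sex == MALE else female_mult(c, rr_f, mode)
    return pop * fet * female_mult(m, rr_m, mode)


def triad_loglik_oracle(
    records: Sequence[Tuple[int, int, int, str]],
    q: float,
    rr_f: float,
    rr_m: float,
    mode: str = "x_inactivation_average",
    design: str = "fetal_triad",
) -> float:
    """records: (father_dose, mother_dose, child_dose, sex), -1 missing; all case."""
    ll = 0.0
    for fa_obs, m_obs, c_obs, sex in records:
        fa_opts = (0, 1) if fa_obs < 0 else (fa_obs,)
        m_opts = (0, 1, 2) if m_obs < 0 else (m_obs,)
        c_opts = ((0, 1) if sex == MALE else (0, 1, 2)) if c_obs < 0 else (c_obs,)
        num = sum(
            triad_case_weight(fa, m, c, sex, q, rr_f, rr_m, mode, design)
            for fa in fa_opts for m in m_opts for c in c_opts
        )
        den = sum(
            triad_case_weight(fa, m, c, sex, q, rr_f, rr_m, mode, design)
            for fa, m, c in triad_cell_space(sex)
        )
        ll += math.log(num / den)
    return ll


# --- Mendelian brute force -------------------------------------------------

def mendelian_consistent_bruteforce(
    m_dose: Optional[int], c_dose: Optional[int], sex: str, fa_dose: Optional[int]
) -> bool:
    """Enumerate every assignment of unordered parental alleles and every
    transmission; True iff some assignment reproduces the child."""
    if c_dose is None:
        return True
    m_options = [m_dose] if m_dose is not None else [0, 1, 2]
    fa_options = [fa_dose] if fa_dose is not None else [0, 1]
    for m in m_options:
        mother_alleles = [1] * m + [0] * (2 - m)
        for fa in fa_options:
            for t in set(mother_alleles):
                child = t if sex == MALE else t + fa
                if child == c_dose:
                    return True
    return False
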