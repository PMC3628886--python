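"""Synthetic family genotype data with the sampling structure of a hybrid
case-mother/control-mother dyad study of an X-linked disease.

Case dyads are drawn exactly from the case-conditional cell law
P(cell | case, sex) proportional to population probability x risk multiplier;
control dyads from the population law (the rare-disease approximation for a
~5-6% prevalence outcome — an ``exact`` control mode weighting cells by
1 - B_sex x multiplier is available).  The child's sex among cases follows
the baseline-risk ratio B_B/B_G, which with the default baselines gives the
~54-55% male excess typical of spontaneous preterm delivery; controls follow
the live-birth sex ratio.  Missingness is injected per genotype, missing
completely at random.

Default sizes mirror a large dyad study: about 1,000 case + 1,000 control
dyads per cohort for the larger study and 500+500 for the smaller one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .containers import DyadDataset, TriadDataset, default_snp_table
from .core import (
    FEMALE,
    MALE,
    RiskModel,
    dyad_cell_multipliers,
    dyad_cell_probs,
    dyad_cell_table,
    triad_cell_multipliers,
    triad_cell_probs,
    triad_cell_table,
)

__all__ = [
    "SimulationConfig",
    "simulate_dyads",
    "simulate_triads",
    "simulate_null_panel",
    "case_male_fraction",
]

#: Live-birth fraction of boys used for control dyads and sibling draws.
POPULATION_MALE_FRACTION = 0.512


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for one simulated dataset.

    The same seed and config always produce the identical dataset.
    ``case_male_fraction`` overrides the sex ratio among cases implied by the
    model's baselines; leave None to let B_B/B_G determine it.
    """

    n_case_dyads: int = 1000
    n_control_dyads: int = 1000
    model: RiskModel = field(default_factory=lambda: RiskModel(q=0.3))
    missing_rate: float = 0.02
    case_male_fraction: Optional[float] = None
    control_male_fraction: float = POPULATION_MALE_FRACTION
    control_mode: str = "population"  # or "exact"
    seed: int = 0
    n_snps: int = 1
    maf_bounds: Tuple[float, float] = (0.01, 0.5)

    def __post_init__(self) -> None:
        if self.n_case_dyads < 0 or self.n_control_dyads < 0:
            raise ValueError("dyad counts must be non-negative")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.control_mode not in ("population", "exact"):
            raise ValueError("control_mode must be 'population' or 'exact'")
        lo, hi = self.maf_bounds
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_bounds must satisfy 0 < low <= high <= 0.5")


def _check_model(model: RiskModel) -> None:
    if model.q < 1e-4 or model.q > 1 - 1e-4:
        raise ValueError(f"degenerate allele frequency q={model.q}; nothing to simulate")


def _sex_weights(model: RiskModel, pop_male_fraction: float) -> Tuple[float, float]:
    """Unnormalized case probabilities of (male, female) child sex."""
    w = []
    for sex, base in ((MALE, model.baseline_male), (FEMALE, model.baseline_female)):
        probs = dyad_cell_probs(sex, model.q)
        mult = dyad_cell_multipliers(
            sex, model.rr_fetal, model.rr_maternal, model.female_dose_mode
        )
        frac = pop_male_fraction if sex == MALE else 1.0 - pop_male_fraction
        w.append(frac * base * float(probs @ mult))
    return w[0], w[1]


def case_male_fraction(
    model: RiskModel, pop_male_fraction: float = POPULATION_MALE_FRACTION
) -> float:
    """P(male | case) implied by the sex-specific baselines and the risk model."""
    wm, wf = _sex_weights(model, pop_male_fraction)
    return wm / (wm + wf)


def _case_cell_dist(sex: str, model: RiskModel) -> np.ndarray:
    probs = dyad_cell_probs(sex, model.q)
    mult = dyad_cell_multipliers(
        sex, model.rr_fetal, model.rr_maternal, model.female_dose_mode
    )
    w = probs * mult
    return w / w.sum()

def _control_cell_dist(sex: str, model: RiskModel, mode: str) -> np.ndarray:
    probs = dyad_cell_probs(sex, model.q)
    if mode == "exact":
        base = model.baseline_male if sex == MALE else model.baseline_female
        mult = dyad_cell_multipliers(
            sex, model.rr_fetal, model.rr_maternal, model.female_dose_mode
        )
        probs = probs * (1.0 - base * mult)
    return probs / probs.sum()


def _draw_dyad_doses(
    rng: np.random.Generator, sex: str, dist: np.ndarray, n: int
) -> Tuple[np.ndarray, np.ndarray]:
    m, c = dyad_cell_table(sex)
    idx = rng.choice(len(dist), size=n, p=dist)
    return m[idx].astype(np.int8), c[idx].astype(np.int8)


def _inject_missing(rng: np.random.Generator, gt: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return gt
    mask = rng.random(gt.shape) < rate
    out = gt.copy()
    out[mask] = -1
    return out


def simulate_dyads(config: SimulationConfig) -> DyadDataset:
    """Simulate one SNP's worth of case- and control-mother dyads.

    Cases are drawn from the exact case-conditional cell law within child
    sex; controls from the population (or exact low-prevalence) law.
    """
    model = config.model
    _check_model(model)
    rng = np.random.default_rng(config.seed)

    p_male_case = (
        config.case_male_fraction
        if config.case_male_fraction is not None
        else case_male_fraction(model, config.control_male_fraction)
    )

    rows = []
    mothers = []
    children = []
    for status, n, p_male in (
        ("case", config.n_case_dyads, p_male_case),
        ("control", config.n_control_dyads, config.control_male_fraction),
    ):
        n_male = int(rng.binomial(n, p_male)) if n > 0 else 0
        for sex, n_sex in ((MALE, n_male), (FEMALE, n - n_male)):
            if n_sex == 0:
                continue
            if status == "case":
                dist = _case_cell_dist(sex, model)
            else:
                dist = _control_cell_dist(sex, model, config.control_mode)
            m, c = _draw_dyad_doses(rng, sex, dist, n_sex)
            mothers.append(m)
            children.append(c)
            rows.append(
                pd.DataFrame(
                    {"child_sex": [sex] * n_sex, "status": [status] * n_sex}
                )
            )

    if rows:
        fam = pd.concat(rows, ignore_index=True)
        mother_gt = np.concatenate(mothers)[:, None]
        child_gt = np.concatenate(children)[:, None]
    else:
        fam = pd.DataFrame({"child_sex": [], "status": []})
        mother_gt = np.empty((0, 1), dtype=np.int8)
        child_gt = np.empty((0, 1), dtype=np.int8)
    fam.insert(0, "family_id", [f"F{i + 1:06d}" for i in range(len(fam))])

    mother_gt = _inject_missing(rng, mother_gt, config.missing_rate)
    child_gt = _inject_missing(rng, child_gt, config.missing_rate)
    return DyadDataset(fam, default_snp_table(1), mother_gt, child_gt)


# ---------------------------------------------------------------------------
# triads
# ---------------------------------------------------------------------------

def _case_triad_dist(sex: str, model: RiskModel, design: str) -> np.ndarray:
    probs = triad_cell_probs(sex, model.q)
    mult = triad_cell_multipliers(
        sex, model.rr_fetal, model.rr_maternal, model.female_dose_mode, design
    )
    w = probs * mult
    return w / w.sum()


def simulate_triads(
    config: SimulationConfig,
    design: str = "fetal_triad",
    roster: Optional[Dict[str, object]] = None,
) -> TriadDataset:
    """Simulate case-parent triad families.

    ``fetal_triad``: the affected child plus both parents, child sex drawn
    like the dyad cases.  ``maternal_triad``: the affected individual is the
    case mother (always female) genotyped with her own parents; only her
    genotype carries a risk multiplier (rr_maternal).

    ``roster`` optionally fixes the family composition, e.g.::

        {"full_triads": 182, "mother_child_dyads": 66,
         "father_child_dyads": 14, "extra_children": {2: 4, 3: 1}}

    ``extra_children`` maps number-of-children to number of full families
    with that many genotyped siblings (the first child is the case; siblings
    are plain Mendelian transmissions).  Without a roster all
    ``n_case_dyads`` families are full triads.
    """
    if design not in ("fetal_triad", "maternal_triad"):
        raise ValueError(f"unknown triad design {design!r}")
    model = config.model
    _check_model(model)
    rng = np.random.default_rng(config.seed)

    if roster is None:
        roster = {"full_triads": config.n_case_dyads}
    full = int(roster.get("full_triads", 0))
    modyads = int(roster.get("mother_child_dyads", 0))
    fadyads = int(roster.get("father_child_dyads", 0))
    extra = dict(roster.get("extra_children", {}))

    p_male_case = (
        0.0
        if design == "maternal_triad"
        else (
            config.case_male_fraction
            if config.case_male_fraction is not None
            else case_male_fraction(model, config.control_male_fraction)
        )
    )

    fam_rows = []
    fa_g, mo_g, ch_g = [], [], []
    fam_counter = 0

    def _draw_case_cell(sex: str) -> Tuple[int, int, int]:
        fa, m, c = triad_cell_table(sex)
        dist = _case_triad_dist(sex, model, design)
        i = rng.choice(len(dist), p=dist)
        return int(fa[i]), int(m[i]), int(c[i])

    def _add_family(n_children: int, father_present: bool, mother_present: bool) -> None:
        nonlocal fam_counter
        fam_counter += 1
        fid = f"T{fam_counter:06d}"
        sex = MALE if (design == "fetal_triad" and rng.random() < p_male_case) else FEMALE
        fa, m, c = _draw_case_cell(sex)
        members = [(sex, c)]
        for _ in range(n_children - 1):
            sib_sex = MALE if rng.random() < POPULATION_MALE_FRACTION else FEMALE
            t = rng.integers(0, 2) if m == 1 else m // 2
            sib_c = int(t) if sib_sex == MALE else int(t) + fa
            members.append((sib_sex, sib_c))
        for k, (child_sex, child_dose) in enumerate(members):
            fam_rows.append(
                {
                    "family_id": fid,
                    "child_sex": child_sex,
                    "design": design,
                    "father_present": father_present,
                    "mother_present": mother_present,
                    "child_present": True,
                    "is_case": k == 0,
                }
            )
            fa_g.append(fa if father_present else -1)
            mo_g.append(m if mother_present else -1)
            ch_g.append(child_dose)

    for _ in range(full):
        _add_family(1, True, True)
    for _ in range(modyads):
        _add_family(1, False, True)
    for _ in range(fadyads):
        _add_family(1, True, False)
    for n_children, n_fams in sorted(extra.items()):
        for _ in range(n_fams):
            _add_family(int(n_children), True, True)

    fam = pd.DataFrame(
        fam_rows,
        columns=[
            "family_id",
            "child_sex",
            "design",
            "father_present",
            "mother_present",
            "child_present",
            "is_case",
        ],
    )
    father_gt = np.array(fa_g, dtype=np.int8)[:, None] if fa_g else np.empty((0, 1), np.int8)
    mother_gt = np.array(mo_g, dtype=np.int8)[:, None] if mo_g else np.empty((0, 1), np.int8)
    child_gt = np.array(ch_g, dtype=np.int8)[:, None] if ch_g else np.empty((0, 1), np.int8)

    present_fa = fam["father_present"].to_numpy() if len(fam) else np.empty(0, bool)
    present_mo = fam["mother_present"].to_numpy() if len(fam) else np.empty(0, bool)
    father_gt[present_fa] = _inject_missing(rng, father_gt[present_fa], config.missing_rate)
    mother_gt[present_mo] = _inject_missing(rng, mother_gt[present_mo], config.missing_rate)
    child_gt = _inject_missing(rng, child_gt, config.missing_rate)
    return TriadDataset(fam, default_snp_table(1), father_gt, mother_gt, child_gt)


# ---------------------------------------------------------------------------
# multi-SNP panels
# ---------------------------------------------------------------------------

def simulate_null_panel(
    config: SimulationConfig,
    signal_snps: Optional[Dict[int, Tuple[float, float]]] = None,
) -> Tuple[DyadDataset, pd.DataFrame]:
    """Simulate a panel of independent X SNPs on one set of dyad families.

    MAFs are drawn uniformly within ``config.maf_bounds``; every SNP is null
    (RR = 1) unless listed in ``signal_snps`` as {snp_index: (rr_fetal,
    rr_maternal)}.  Returns the dataset and a per-SNP truth table
    (snp, maf, rr_fetal, rr_maternal).
    """
    if config.n_snps < 1:
        raise ValueError("panel needs n_snps >= 1")
    rng = np.random.default_rng(config.seed)
    signal_snps = signal_snps or {}

    lo, hi = config.maf_bounds
    mafs = rng.uniform(lo, hi, size=config.n_snps)

    # family roster drawn once; genotypes per SNP are independent given
    # sex and status under the multiplicative model
    base = config.model
    p_male_case = (
        config.case_male_fraction
        if config.case_male_fraction is not None
        else case_male_fraction(base, config.control_male_fraction)
    )
    n_case, n_ctrl = config.n_case_dyads, config.n_control_dyads
    sexes = np.concatenate(
        [
            np.where(rng.random(n_case) < p_male_case, MALE, FEMALE),
            np.where(rng.random(n_ctrl) < config.control_male_fraction, MALE, FEMALE),
        ]
    )
    status = np.array(["case"] * n_case + ["control"] * n_ctrl)
    fam = pd.DataFrame(
        {
            "family_id": [f"F{i + 1:06d}" for i in range(n_case + n_ctrl)],
            "child_sex": sexes,
            "status": status,
        }
    )

    n_fam = len(fam)
    mother_gt = np.empty((n_fam, config.n_snps), dtype=np.int8)
    child_gt = np.empty((n_fam, config.n_snps), dtype=np.int8)
    truth_rows = []
    for j in range(config.n_snps):
        rr_f, rr_m = signal_snps.get(j, (1.0, 1.0))
        model = replace(base, q=float(mafs[j]), rr_fetal=rr_f, rr_maternal=rr_m)
        for sex in (MALE, FEMALE):
            for st in ("case", "control"):
                sel = (sexes == sex) & (status == st)
                n_sel = int(sel.sum())
                if n_sel == 0:
                    continue
                if st == "case":
                    dist = _case_cell_dist(sex, model)
                else:
                    dist = _control_cell_dist(sex, model, config.control_mode)
                m, c = _draw_dyad_doses(rng, sex, dist, n_sel)
                mother_gt[sel, j] = m
                child_gt[sel, j] = c
        truth_rows.append(
            {"snp": f"snp{j + 1}", "maf": float(mafs[j]), "rr_fetal": rr_f, "rr_maternal": rr_m}
        )

    mother_gt = _inject_missing(rng, mother_gt, config.missing_rate)
    child_gt = _inject_missing(rng, child_gt, config.missing_rate)
    snps = default_snp_table(config.n_snps)
    return DyadDataset(fam, snps, mother_gt, child_gt), pd.DataFrame(truth_rows)
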