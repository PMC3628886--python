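"""Maximum-likelihood relative-risk estimation for X-linked family designs.

The hybrid dyad likelihood conditions on child sex and case status, so the
sex-specific baseline risks cancel and only the allele frequency ``q`` and
the relative risks remain.  Within a sex stratum, a case dyad falling in
genotype cell ``j`` contributes ``f_j(q) m_j(R) / sum_k f_k(q) m_k(R)`` and a
control dyad ``f_j(q)``, with ``f`` the Hardy-Weinberg/random-mating cell law
and ``m`` the fetal x maternal risk multiplier.  Case-parent triads (and
maternal triads, where the affected individual is the case mother) use the
analogous normalized law over (father allele, mother genotype, child
genotype) cells.

Missing genotypes are handled by exact summation over all Mendelian-
compatible completions inside the likelihood, which yields the same maximum
as expectation-maximization but is deterministic and needs no convergence
loop of its own.  Optimization runs over (logit q, log R) from fixed starts,
so estimates are reproducible; standard errors come from the numerically
differentiated observed information, confidence intervals are Wald intervals
on log RR, and the overall p-value is a likelihood-ratio test against RR=1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import DyadDataset, TriadDataset
from .core import (
    FEMALE,
    MALE,
    X_INACTIVATION,
    dyad_cell_probs,
    dyad_cell_table,
    triad_cell_probs,
    triad_cell_table,
    dyad_cell_multipliers,
    triad_cell_multipliers,
)

__all__ = [
    "FitSpec",
    "FitResult",
    "JointFitResult",
    "MonomorphicSNPError",
    "dyad_loglik",
    "triad_loglik",
    "fit",
    "scan",
    "sex_stratified_scan",
]

#: z for a 95% CI, fixed for consistency with the meta-analysis layer.
Z95 = 1.959964


class MonomorphicSNPError(ValueError):
    """Raised when a SNP carries no copies of one allele in the fitted stratum."""


@dataclass(frozen=True)
class FitSpec:
    """What to estimate and how.

    ``effect``: which genotype carries the free relative risk — the child's
    (fetal), the mother's own (maternal), or both (joint).  ``sex_stratum``
    restricts to male or female affected individuals; 'both' shares q and RR
    across sexes with per-sex normalization.  ``design`` picks the family
    structure.  The maternal_triad design forces effect='maternal' and an
    all-female affected set.
    """

    effect: str = "fetal"
    sex_stratum: str = "both"
    design: str = "hybrid_dyad"
    ci_level: float = 0.95
    female_dose_mode: str = X_INACTIVATION
    gtol: float = 1e-8
    max_iter: int = 200
    min_families: int = 10

    def __post_init__(self) -> None:
        if self.effect not in ("fetal", "maternal", "joint"):
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.sex_stratum not in ("both", "male_only", "female_only"):
            raise ValueError(f"unknown sex stratum {self.sex_stratum!r}")
        if self.design not in ("hybrid_dyad", "fetal_triad", "maternal_triad"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.design == "maternal_triad" and self.effect != "maternal":
            raise ValueError("maternal_triad design estimates the maternal effect only")
        if self.design == "maternal_triad" and self.sex_stratum == "male_only":
            raise ValueError("maternal_triad affected individuals are all female")


@dataclass
class FitResult:
    """One relative-risk estimate with its uncertainty and diagnostics."""

    snp: str
    effect: str
    stratum: str
    rr: float
    se_log_rr: float
    ci_low: float
    ci_high: float
    p_wald: float
    p_overall: float
    q_hat: float
    loglik: float
    converged: bool
    n_families: int
    n_cases: int
    n_controls: int
    n_excluded: int = 0
    flags: Tuple[str, ...] = ()


@dataclass
class JointFitResult:
    """Joint fetal + maternal fit: two Wald summaries sharing one 2-df LRT."""

    fetal: FitResult
    maternal: FitResult
    p_overall: float
    loglik: float
    q_hat: float


# ---------------------------------------------------------------------------
# pattern tables: observed (possibly missing) configurations -> counts and
# compatibility with the complete-data cells
# ---------------------------------------------------------------------------


@dataclass
class _StratumPatterns:
    sex: str
    case_counts: np.ndarray       # per observed case pattern
    case_compat: np.ndarray       # (n_case_patterns, n_cells) 0/1
    control_counts: np.ndarray
    control_compat: np.ndarray
    n_cases: int
    n_controls: int


def _compat_matrix(obs: np.ndarray, cells: Sequence[np.ndarray]) -> np.ndarray:
    """obs: (n_patterns, k) observed codes with -1 missing; cells: k arrays."""
    n_cells = len(cells[0])
    out = np.ones((len(obs), n_cells), dtype=float)
    for k, cell_vals in enumerate(cells):
        col = obs[:, k][:, None]
        out *= (col < 0) | (col == cell_vals[None, :])
    return out


def _pattern_counts(obs: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    uniq, counts = np.unique(obs, axis=0, return_counts=True)
    return uniq, counts.astype(float)


def _prepare_dyads(
    dataset: DyadDataset, snp: Union[str, int], spec: FitSpec
) -> Tuple[List[_StratumPatterns], int]:
    j = dataset.snp_index(snp)
    fam = dataset.families
    m = dataset.mother_gt[:, j].astype(np.int64)
    c = dataset.child_gt[:, j].astype(np.int64)
    sexes = fam["child_sex"].to_numpy()
    status = fam["status"].to_numpy()

    wanted = {"both": (MALE, FEMALE), "male_only": (MALE,), "female_only": (FEMALE,)}[
        spec.sex_stratum
    ]
    strata: List[_StratumPatterns] = []
    n_excluded = 0
    for sex in wanted:
        cells = dyad_cell_table(sex)
        sel = sexes == sex
        entries = {}
        for st in ("case", "control"):
            obs = np.stack([m[sel & (status == st)], c[sel & (status == st)]], axis=1)
            uniq, counts = _pattern_counts(obs)
            compat = _compat_matrix(uniq, cells)
            # a pattern compatible with no cell is Mendelian-impossible
            ok = compat.sum(axis=1) > 0
            n_excluded += int(counts[~ok].sum())
            entries[st] = (counts[ok], compat[ok])
        strata.append(
            _StratumPatterns(
                sex=sex,
                case_counts=entries["case"][0],
                case_compat=entries["case"][1],
                control_counts=entries["control"][0],
                control_compat=entries["control"][1],
                n_cases=int(entries["case"][0].sum()),
                n_controls=int(entries["control"][0].sum()),
            )
        )
    return strata, n_excluded


def _prepare_triads(
    dataset: TriadDataset, snp: Union[str, int], spec: FitSpec
) -> Tuple[List[_StratumPatterns], int]:
    j = dataset.snp_index(snp)
    fam = dataset.families
    use = fam["is_case"].to_numpy() if "is_case" in fam.columns else np.ones(len(fam), bool)
    use = use & fam["child_present"].to_numpy()
    f = dataset.father_gt[use, j].astype(np.int64)
    m = dataset.mother_gt[use, j].astype(np.int64)
    c = dataset.child_gt[use, j].astype(np.int64)
    sexes = fam.loc[use, "child_sex"].to_numpy()

    wanted = {"both": (MALE, FEMALE), "male_only": (MALE,), "female_only": (FEMALE,)}[
        spec.sex_stratum
    ]
    if spec.design == "maternal_triad":
        wanted = (FEMALE,)
    strata: List[_StratumPatterns] = []
    n_excluded = 0
    for sex in wanted:
        cells = triad_cell_table(sex)
        sel = sexes == sex
        obs = np.stack([f[sel], m[sel], c[sel]], axis=1)
        uniq, counts = _pattern_counts(obs)
        compat = _compat_matrix(uniq, cells)
        ok = compat.sum(axis=1) > 0
        n_excluded += int(counts[~ok].sum())
        strata.append(
            _StratumPatterns(
                sex=sex,
                case_counts=counts[ok],
                case_compat=compat[ok],
                control_counts=np.empty(0),
                control_compat=np.empty((0, len(cells[0]))),
                n_cases=int(counts[ok].sum()),
                n_controls=0,
            )
        )
    return strata, n_excluded


# ---------------------------------------------------------------------------
# log-likelihood
# ---------------------------------------------------------------------------


def _effect_rrs(params: Sequence[float], effect: str) -> Tuple[float, float]:
    if effect == "fetal":
        return float(params[0]), 1.0
    if effect == "maternal":
        return 1.0, float(params[0])
    return float(params[0]), float(params[1])


def _dyad_ll(
    strata: List[_StratumPatterns],
    q: float,
    rr_f: float,
    rr_m: float,
    mode: str,
) -> float:
    ll = 0.0
    for s in strata:
        f = dyad_cell_probs(s.sex, q)
        if s.n_controls:
            probs = s.control_compat @ f
            ll += float(s.control_counts @ np.log(probs))
        if s.n_cases:
            w = f * dyad_cell_multipliers(s.sex, rr_f, rr_m, mode)
            probs = s.case_compat @ w
            ll += float(s.case_counts @ np.log(probs)) - s.n_cases * np.log(w.sum())
    return ll


def _triad_ll(
    strata: List[_StratumPatterns],
    q: float,
    rr_f: float,
    rr_m: float,
    mode: str,
    design: str,
) -> float:
    ll = 0.0
    for s in strata:
        f = triad_cell_probs(s.sex, q)
        if s.n_cases:
            w = f * triad_cell_multipliers(s.sex, rr_f, rr_m, mode, design)
            probs = s.case_compat @ w
            ll += float(s.case_counts @ np.log(probs)) - s.n_cases * np.log(w.sum())
    return ll


def dyad_loglik(
    params: Sequence[float],
    dataset: DyadDataset,
    spec: FitSpec = FitSpec(),
    snp: Union[str, int] = 0,
) -> float:
    """Hybrid-design log-likelihood at natural-scale parameters.

    ``params`` is (q, RR) for a single-effect spec or (q, RR_fetal,
    RR_maternal) for effect='joint'.  Dyads with missing genotypes contribute
    the sum over all Mendelian-compatible completions; dyads compatible with
    no completion are excluded (with a warning at fit time).
    """
    strata, _ = _prepare_dyads(dataset, snp, spec)
    q = float(params[0])
    rr_f, rr_m = _effect_rrs(params[1:], spec.effect)
    return _dyad_ll(strata, q, rr_f, rr_m, spec.female_dose_mode)


def triad_loglik(
    params: Sequence[float],
    dataset: TriadDataset,
    spec: FitSpec = FitSpec(design="fetal_triad"),
    snp: Union[str, int] = 0,
) -> float:
    """Case-parent-triad log-likelihood at natural-scale parameters.

    Cells are (father allele, mother genotype, child genotype) under
    HWE + random mating, weighted by the risk multiplier and normalized
    within sex stratum; absent or missing members are marginalized exactly.
    In the maternal_triad design the "child" slot holds the affected case
    mother and the multiplier applies to her own genotype.
    """
    if spec.design == "hybrid_dyad":
        raise ValueError("triad_loglik requires a triad design spec")
    strata, _ = _prepare_triads(dataset, snp, spec)
    q = float(params[0])
    rr_f, rr_m = _effect_rrs(params[1:], spec.effect)
    return _triad_ll(strata, q, rr_f, rr_m, spec.female_dose_mode, spec.design)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _numerical_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for k in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ek = np.zeros(n); ek[k] = eps
            H[i, k] = H[k, i] = (
                f(x + ei + ek) - f(x + ei - ek) - f(x - ei + ek) + f(x - ei - ek)
            ) / (4 * eps * eps)
    return H


def _stratum_allele_counts(
    dataset, snp: Union[str, int], spec: FitSpec, triad: bool
) -> Tuple[float, float]:
    j = dataset.snp_index(snp)
    fam = dataset.families
    sexes = fam["child_sex"].to_numpy()
    wanted = {"both": (MALE, FEMALE), "male_only": (MALE,), "female_only": (FEMALE,)}[
        spec.sex_stratum
    ]
    if spec.design == "maternal_triad":
        wanted = (FEMALE,)
    sel = np.isin(sexes, wanted)
    a2 = 0.0
    total = 0.0
    mats = [("mother", dataset.mother_gt), ("child", dataset.child_gt)]
    if triad:
        mats.append(("father", dataset.father_gt))
    for role, gt in mats:
        g = gt[sel, j].astype(np.int64)
        obs = g >= 0
        a2 += float(g[obs].sum())
        if role == "mother":
            total += 2.0 * obs.sum()
        elif role == "father":
            total += 1.0 * obs.sum()
        else:
            male = (sexes[sel] == MALE) & obs
            female = (sexes[sel] == FEMALE) & obs
            total += 1.0 * male.sum() + 2.0 * female.sum()
    return a2, total


def _logit(x: float) -> float:
    return float(np.log(x / (1.0 - x)))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def fit(
    dataset: Union[DyadDataset, TriadDataset],
    snp: Union[str, int] = 0,
    spec: FitSpec = FitSpec(),
) -> Union[FitResult, JointFitResult]:
    """Maximum-likelihood relative-risk fit for one SNP.

    Optimizes the design's log-likelihood over (logit q, log RR) — or
    (logit q, log RR_fetal, log RR_maternal) for effect='joint' — from the
    fixed start q = observed allele frequency, RR = 1.  Returns a
    :class:`FitResult` (or :class:`JointFitResult` for the joint effect)
    with Wald CI/p on log RR and a likelihood-ratio overall p against RR=1.

    Raises :class:`MonomorphicSNPError` when one allele is absent from the
    stratum, and ValueError when the stratum holds no case families.
    """
    triad = spec.design in ("fetal_triad", "maternal_triad")
    if triad and not isinstance(dataset, TriadDataset):
        raise TypeError("triad designs need a TriadDataset")
    if not triad and not isinstance(dataset, DyadDataset):
        raise TypeError("the hybrid_dyad design needs a DyadDataset")

    if triad:
        strata, n_excluded = _prepare_triads(dataset, snp, spec)
    else:
        strata, n_excluded = _prepare_dyads(dataset, snp, spec)
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} families inconsistent with any X-linked "
            f"transmission at SNP {snp!r}",
            stacklevel=2,
        )

    n_cases = sum(s.n_cases for s in strata)
    n_controls = sum(s.n_controls for s in strata)
    n_families = n_cases + n_controls
    snp_id = str(dataset.snps["snp"].iloc[dataset.snp_index(snp)])

    if n_families < spec.min_families:
        raise ValueError(
            f"stratum has {n_families} families, fewer than min_families={spec.min_families}"
        )
    if n_cases == 0:
        raise ValueError("no case families in stratum; relative risk not identifiable")

    a2, total = _stratum_allele_counts(dataset, snp, spec, triad)
    if total == 0 or a2 == 0 or a2 == total:
        raise MonomorphicSNPError(f"monomorphic SNP {snp_id!r} in fitted stratum")
    q0 = a2 / total

    n_rr = 2 if spec.effect == "joint" else 1
    mode, design = spec.female_dose_mode, spec.design

    def nll(theta: np.ndarray) -> float:
        q = float(_expit(np.asarray([theta[0]]))[0])
        q = min(max(q, 1e-12), 1 - 1e-12)
        rrs = np.exp(theta[1:])
        rr_f, rr_m = _effect_rrs(rrs, spec.effect)
        if triad:
            return -_triad_ll(strata, q, rr_f, rr_m, mode, design)
        return -_dyad_ll(strata, q, rr_f, rr_m, mode)

    x0 = np.array([_logit(q0)] + [0.0] * n_rr)
    res = optimize.minimize(
        nll, x0, method="BFGS", options={"gtol": spec.gtol, "maxiter": spec.max_iter}
    )
    # polish with Nelder-Mead if the gradient-based step stalled
    if not res.success:
        res2 = optimize.minimize(
            nll, res.x, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        if res2.fun <= res.fun:
            res = res2
    theta_hat = res.x
    loglik = -float(res.fun)
    q_hat = float(_expit(np.asarray([theta_hat[0]]))[0])

    # null fit (all RR = 1) for the likelihood-ratio test
    def nll_null(t0: np.ndarray) -> float:
        return nll(np.concatenate([t0, np.zeros(n_rr)]))

    res0 = optimize.minimize(
        nll_null, np.array([_logit(q0)]), method="BFGS",
        options={"gtol": spec.gtol, "maxiter": spec.max_iter},
    )
    lrt = max(0.0, 2.0 * (-float(res.fun) + float(res0.fun)))
    p_overall = float(stats.chi2.sf(lrt, df=n_rr)) if lrt > 0 else 1.0

    H = _numerical_hessian(nll, theta_hat)
    flags: List[str] = []
    try:
        cov = np.linalg.inv(H)
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        ses = np.full(len(theta_hat), np.nan)
        flags.append("singular_information")

    converged = bool(res.success or np.linalg.norm(res.x - x0) < 1e-12 or res.fun <= nll(x0))
    grad_norm = float(np.linalg.norm(optimize.approx_fprime(theta_hat, nll, 1e-7)))
    converged = converged and np.isfinite(loglik)
    if grad_norm > 1e-3 * max(1.0, abs(loglik)):
        flags.append("large_gradient")
        converged = False

    z = stats.norm.ppf(0.5 + spec.ci_level / 2.0) if spec.ci_level != 0.95 else Z95

    def _one(effect_name: str, idx: int, p_ov: float) -> FitResult:
        log_rr = float(theta_hat[1 + idx])
        se = float(ses[1 + idx])
        rr = float(np.exp(log_rr))
        fl = list(flags)
        if rr < 1e-3 or rr > 1e3:
            fl.append("boundary")
        if se > 0 and np.isfinite(se):
            ci_low, ci_high = float(np.exp(log_rr - z * se)), float(np.exp(log_rr + z * se))
            p_wald = float(2.0 * stats.norm.sf(abs(log_rr / se)))
        else:
            ci_low = ci_high = p_wald = float("nan")
        return FitResult(
            snp=snp_id,
            effect=effect_name,
            stratum=spec.sex_stratum,
            rr=rr,
            se_log_rr=se,
            ci_low=ci_low,
            ci_high=ci_high,
            p_wald=p_wald,
            p_overall=p_ov,
            q_hat=q_hat,
            loglik=loglik,
            converged=converged and "boundary" not in fl,
            n_families=n_families,
            n_cases=n_cases,
            n_controls=n_controls,
            n_excluded=n_excluded,
            flags=tuple(fl),
        )

    if spec.effect == "joint":
        fetal = _one("fetal", 0, p_overall)
        maternal = _one("maternal", 1, p_overall)
        return JointFitResult(
            fetal=fetal, maternal=maternal, p_overall=p_overall,
            loglik=loglik, q_hat=q_hat,
        )
    return _one(spec.effect, 0, p_overall)


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

_SCAN_COLUMNS = [
    "snp", "alleles", "stratum", "effect", "maf", "rr", "ci_low", "ci_high",
    "p_rr", "p_overall", "q_hat", "n_families", "converged", "error",
]


def scan(
    dataset: Union[DyadDataset, TriadDataset],
    spec: FitSpec = FitSpec(),
) -> pd.DataFrame:
    """Fit every SNP in the panel under one spec; per-SNP failures are
    recorded in the ``error`` column instead of aborting the scan."""
    from .qc import compute_maf  # local import to avoid a cycle

    rows = []
    for j in range(dataset.n_snps):
        meta = dataset.snps.iloc[j]
        alleles = f"{meta['a1']}/{meta['a2']}"
        maf = compute_maf(dataset, j) if isinstance(dataset, DyadDataset) else float("nan")
        base = {
            "snp": meta["snp"], "alleles": alleles, "stratum": spec.sex_stratum,
            "effect": spec.effect, "maf": maf,
        }
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = fit(dataset, j, spec)
            if isinstance(result, JointFitResult):
                result = result.fetal
            rows.append(
                base | {
                    "rr": result.rr, "ci_low": result.ci_low, "ci_high": result.ci_high,
                    "p_rr": result.p_wald, "p_overall": result.p_overall,
                    "q_hat": result.q_hat, "n_families": result.n_families,
                    "converged": result.converged, "error": "",
                }
            )
        except (MonomorphicSNPError, ValueError, TypeError) as exc:
            rows.append(
                base | {
                    "rr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                    "p_rr": np.nan, "p_overall": np.nan, "q_hat": np.nan,
                    "n_families": 0, "converged": False, "error": str(exc),
                }
            )
    return pd.DataFrame(rows, columns=_SCAN_COLUMNS)


def sex_stratified_scan(
    dataset: Union[DyadDataset, TriadDataset],
    spec: FitSpec = FitSpec(),
) -> pd.DataFrame:
    """Run the scan separately on male and female affected individuals."""
    frames = []
    for stratum in ("male_only", "female_only"):
        frames.append(scan(dataset, replace(spec, sex_stratum=stratum)))
    return pd.concat(frames, ignore_index=True)
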