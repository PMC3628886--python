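"""Likelihood core: oracle equivalence, hand-computed values, invariances,
degenerate inputs, and the sex-stratified scan."""

import numpy as np
import pytest
from scipy import optimize

from xlinkrr import (
    DyadDataset,
    DyadRecord,
    FEMALE,
    FitSpec,
    MALE,
    MonomorphicSNPError,
    RiskModel,
    SimulationConfig,
    TriadDataset,
    XGenotype,
    default_snp_table,
    dyad_loglik,
    fit,
    scan,
    sex_stratified_scan,
    simulate_dyads,
    simulate_triads,
    triad_loglik,
)
from xlinkrr.core import dyad_cell_multipliers, dyad_cell_probs, dyad_cell_table

from oracles import dyad_loglik_oracle, triad_loglik_oracle


def _random_dyads(rng, n, missing=0.2):
    """Random (possibly inconsistent-free) dyads with missingness."""
    records = []
    rows = []
    for i in range(n):
        sex = MALE if rng.random() < 0.5 else FEMALE
        status = "case" if rng.random() < 0.5 else "control"
        m = int(rng.binomial(2, 0.4))
        t = int(rng.integers(0, 2)) if m == 1 else m // 2
        c = t if sex == MALE else t + int(rng.binomial(1, 0.4))
        if rng.random() < missing:
            m = -1
        if rng.random() < missing:
            c = -1
        rows.append((m, c, sex, status))
        records.append(
            DyadRecord(f"f{i}", XGenotype(FEMALE, m), XGenotype(sex, c), sex, status)
        )
    return rows, DyadDataset.from_records(records)


class TestDyadLoglik:
    def test_hand_enumerated_single_case_boy(self):
        """Case boy A2 with het mother at q=0.5, R_f=2: cell weight pq*2 = 0.5
        against normalizer 1.5 over the four boy cells."""
        d = DyadDataset.from_records(
            [DyadRecord("f1", XGenotype(FEMALE, 1), XGenotype(MALE, 1), MALE, "case")]
        )
        ll = dyad_loglik((0.5, 2.0), d, FitSpec(effect="fetal"))
        assert ll == pytest.approx(np.log(0.5 / 1.5), abs=1e-12)

    def test_null_rr_reduces_cases_to_population_law(self):
        rng = np.random.default_rng(1)
        rows, d = _random_dyads(rng, 80)
        as_controls = [(m, c, s, "control") for m, c, s, _ in rows]
        ll_cases_at_null = dyad_loglik((0.37, 1.0), d, FitSpec(effect="fetal"))
        assert ll_cases_at_null == pytest.approx(
            dyad_loglik_oracle(as_controls, 0.37, 1.0, 1.0), abs=1e-10
        )

    @pytest.mark.parametrize("effect,rrs", [
        ("fetal", (1.7,)), ("maternal", (0.6,)), ("joint", (1.4, 0.8)),
    ])
    def test_matches_bruteforce_oracle_with_missingness(self, effect, rrs):
        rng = np.random.default_rng(2)
        for rep in range(25):
            rows, d = _random_dyads(rng, 30)
            q = float(rng.uniform(0.05, 0.95))
            rr_f, rr_m = (rrs[0], 1.0) if effect == "fetal" else (
                (1.0, rrs[0]) if effect == "maternal" else rrs
            )
            got = dyad_loglik((q, *rrs), d, FitSpec(effect=effect))
            want = dyad_loglik_oracle(rows, q, rr_f, rr_m)
            assert got == pytest.approx(want, abs=1e-10)

    def test_complete_data_equals_multinomial_cell_loglik(self):
        cfg = SimulationConfig(500, 500, model=RiskModel(q=0.3, rr_fetal=1.4),
                               missing_rate=0.0, seed=5)
        d = simulate_dyads(cfg)
        q, rr = 0.31, 1.5
        ll = dyad_loglik((q, rr), d, FitSpec(effect="fetal"))
        direct = 0.0
        fam = d.families
        for sex in (MALE, FEMALE):
            cells = list(zip(*dyad_cell_table(sex)))
            f = dyad_cell_probs(sex, q)
            w = f * dyad_cell_multipliers(sex, rr, 1.0)
            case_p = w / w.sum()
            sel = (fam["child_sex"] == sex).to_numpy()
            for status, probs in (("case", case_p), ("control", f)):
                g = sel & (fam["status"] == status).to_numpy()
                for k, (mi, ci) in enumerate(cells):
                    n = int(((d.mother_gt[g, 0] == mi) & (d.child_gt[g, 0] == ci)).sum())
                    if n:
                        direct += n * np.log(probs[k])
        assert ll == pytest.approx(direct, abs=1e-9)


class TestTriadLoglik:
    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        for design in ("fetal_triad", "maternal_triad"):
            for rep in range(15):
                rows = []
                fam_rows = []
                for i in range(25):
                    sex = FEMALE if design == "maternal_triad" else (
                        MALE if rng.random() < 0.5 else FEMALE
                    )
                    fa = int(rng.binomial(1, 0.4))
                    m = int(rng.binomial(2, 0.4))
                    t = int(rng.integers(0, 2)) if m == 1 else m // 2
                    c = t if sex == MALE else t + fa
                    if rng.random() < 0.2:
                        fa = -1
                    if rng.random() < 0.2:
                        m = -1
                    if rng.random() < 0.2:
                        c = -1
                    rows.append((fa, m, c, sex))
                    fam_rows.append({"family_id": f"t{i}", "child_sex": sex,
                                     "design": design})
                import pandas as pd

                t_d = TriadDataset(
                    pd.DataFrame(fam_rows), default_snp_table(1),
                    np.array([[r[0]] for r in rows], np.int8),
                    np.array([[r[1]] for r in rows], np.int8),
                    np.array([[r[2]] for r in rows], np.int8),
                )
                q = float(rng.uniform(0.1, 0.9))
                rr = float(rng.uniform(0.5, 2.5))
                effect = "maternal" if design == "maternal_triad" else "fetal"
                got = triad_loglik((q, rr), t_d, FitSpec(effect=effect, design=design))
                rr_f, rr_m = (rr, 1.0) if effect == "fetal" else (1.0, rr)
                want = triad_loglik_oracle(rows, q, rr_f, rr_m, design=design)
                assert got == pytest.approx(want, abs=1e-10)

    def test_father_factors_out_of_boy_case_law(self):
        """For sons the father's allele is independent of case status: the
        case-conditional cell law factorizes into Bernoulli(q) x dyad law."""
        from xlinkrr.core import triad_cell_probs, triad_cell_multipliers, triad_cell_table

        q, rr = 0.3, 1.8
        fa, m, c = triad_cell_table(MALE)
        w = triad_cell_probs(MALE, q) * triad_cell_multipliers(MALE, rr, 1.0)
        law = w / w.sum()
        p_fa1 = law[fa == 1].sum()
        assert p_fa1 == pytest.approx(q, abs=1e-12)
        # conditional law given father allele does not depend on it
        for val in (0, 1):
            cond = law[fa == val] / law[fa == val].sum()
            base = law[fa == 0] / law[fa == 0].sum()
            np.testing.assert_allclose(cond, base, atol=1e-12)


class TestFit:
    def test_relabel_invariance(self):
        cfg = SimulationConfig(1500, 1500, model=RiskModel(q=0.3, rr_fetal=1.5),
                               missing_rate=0.02, seed=7)
        d = simulate_dyads(cfg)
        r = fit(d, 0, FitSpec(effect="fetal"))
        male = (d.families["child_sex"] == MALE).to_numpy()
        flip_child = np.where(
            d.child_gt >= 0,
            np.where(male[:, None], 1 - d.child_gt, 2 - d.child_gt),
            -1,
        ).astype(np.int8)
        flip_mother = np.where(d.mother_gt >= 0, 2 - d.mother_gt, -1).astype(np.int8)
        d2 = DyadDataset(d.families.copy(), d.snps.copy(), flip_mother, flip_child)
        r2 = fit(d2, 0, FitSpec(effect="fetal"))
        assert np.log(r.rr) == pytest.approx(-np.log(r2.rr), abs=1e-5)
        assert r.q_hat == pytest.approx(1 - r2.q_hat, abs=1e-6)
        assert r.ci_low == pytest.approx(1 / r2.ci_high, rel=1e-4)

    def test_monomorphic_raises(self):
        cfg = SimulationConfig(100, 100, model=RiskModel(q=0.3), missing_rate=0.0, seed=9)
        d = simulate_dyads(cfg)
        d.mother_gt[:] = 0
        d.child_gt[:] = 0
        with pytest.raises(MonomorphicSNPError, match="monomorphic"):
            fit(d, 0, FitSpec(effect="fetal"))

    def test_lrt_nonnegative_and_p_in_unit_interval(self):
        for seed in range(5):
            d = simulate_dyads(
                SimulationConfig(400, 400, model=RiskModel(q=0.2), seed=100 + seed)
            )
            r = fit(d, 0, FitSpec(effect="fetal"))
            assert 0.0 < r.p_overall <= 1.0
            assert 0.0 < r.p_wald <= 1.0
            assert r.ci_low < r.rr < r.ci_high

    def test_deterministic_given_data(self):
        d = simulate_dyads(SimulationConfig(500, 500, model=RiskModel(q=0.3), seed=11))
        a = fit(d, 0, FitSpec(effect="fetal"))
        b = fit(d, 0, FitSpec(effect="fetal"))
        assert (a.rr, a.se_log_rr, a.loglik) == (b.rr, b.se_log_rr, b.loglik)

    def test_cases_only_null_q_equals_founder_allele_frequency(self):
        """With no controls and RR fixed at 1, the ML allele frequency equals
        the founder-allele count: mothers' two alleles plus girls'
        unambiguous paternal alleles (transmitted child copies are replicas
        of observed maternal alleles and carry no extra information)."""
        cfg = SimulationConfig(800, 0, model=RiskModel(q=0.35), missing_rate=0.0, seed=13)
        d = simulate_dyads(cfg)
        spec = FitSpec(effect="fetal")

        res = optimize.minimize_scalar(
            lambda q: -dyad_loglik((q, 1.0), d, spec), bounds=(1e-4, 1 - 1e-4),
            method="bounded", options={"xatol": 1e-10},
        )
        fam = d.families
        girls = (fam["child_sex"] == FEMALE).to_numpy()
        m = d.mother_gt[:, 0].astype(int)
        c = d.child_gt[:, 0].astype(int)
        a2 = m.sum()
        total = 2 * len(m)
        unamb = girls & ~((m == 1) & (c == 1))
        # paternal allele = child dose minus the (here unambiguous) maternal
        # transmitted allele: m=0 -> c, m=2 -> c-1, m=1 with c in {0,2} -> c/2
        mu, cu = m[unamb], c[unamb]
        pat = np.where(mu == 2, cu - 1, np.where(mu == 0, cu, cu // 2))
        a2 += pat.sum()
        total += int(unamb.sum())
        assert res.x == pytest.approx(a2 / total, abs=1e-6)

    def test_joint_fit_recovers_both_effects(self):
        model = RiskModel(q=0.3, rr_fetal=1.6, rr_maternal=0.8)
        d = simulate_dyads(SimulationConfig(6000, 6000, model=model,
                                            missing_rate=0.0, seed=17))
        jr = fit(d, 0, FitSpec(effect="joint"))
        assert jr.fetal.rr == pytest.approx(1.6, abs=0.15)
        assert jr.maternal.rr == pytest.approx(0.8, abs=0.1)
        assert jr.p_overall <= 1.0

    def test_triad_fit_recovers_fetal_effect(self):
        model = RiskModel(q=0.3, rr_fetal=1.6)
        t = simulate_triads(SimulationConfig(3000, 0, model=model, seed=19),
                            design="fetal_triad")
        r = fit(t, 0, FitSpec(effect="fetal", design="fetal_triad"))
        assert r.ci_low <= 1.6 <= r.ci_high or abs(np.log(r.rr / 1.6)) < 0.1

    def test_maternal_triad_spec_is_forced_maternal(self):
        with pytest.raises(ValueError):
            FitSpec(effect="fetal", design="maternal_triad")


class TestSexStratifiedScan:
    def _sex_specific_dataset(self, seed, n=1200):
        """Boys have a fetal effect (R=1.5), girls none."""
        model_b = RiskModel(q=0.3, rr_fetal=1.5)
        model_g = RiskModel(q=0.3, rr_fetal=1.0)
        boys = simulate_dyads(SimulationConfig(
            n // 2, n // 2, model=model_b, missing_rate=0.0,
            case_male_fraction=1.0, control_male_fraction=1.0, seed=seed))
        girls = simulate_dyads(SimulationConfig(
            n // 2, n // 2, model=model_g, missing_rate=0.0,
            case_male_fraction=0.0, control_male_fraction=0.0, seed=seed + 1))
        import pandas as pd

        girls.families["family_id"] = "G" + girls.families["family_id"]
        fam = pd.concat([boys.families, girls.families], ignore_index=True)
        return DyadDataset(
            fam, boys.snps,
            np.vstack([boys.mother_gt, girls.mother_gt]),
            np.vstack([boys.child_gt, girls.child_gt]),
        )

    def test_male_stratum_detects_male_only_effect_more_often(self):
        hits = {"male_only": 0, "female_only": 0}
        for seed in range(12):
            d = self._sex_specific_dataset(1000 + 10 * seed)
            table = sex_stratified_scan(d, FitSpec(effect="fetal"))
            for _, row in table.iterrows():
                if row["p_overall"] < 0.05:
                    hits[row["stratum"]] += 1
        assert hits["male_only"] > hits["female_only"]

    def test_both_sex_estimate_lies_between_stratum_estimates(self):
        d = self._sex_specific_dataset(7000, n=4000)
        rb = fit(d, 0, FitSpec(effect="fetal", sex_stratum="both"))
        rm = fit(d, 0, FitSpec(effect="fetal", sex_stratum="male_only"))
        rf = fit(d, 0, FitSpec(effect="fetal", sex_stratum="female_only"))
        lo, hi = sorted([np.log(rm.rr), np.log(rf.rr)])
        assert lo - 1e-6 <= np.log(rb.rr) <= hi + 1e-6

    def test_stratum_counts_sum_to_total(self):
        d = simulate_dyads(SimulationConfig(300, 300, model=RiskModel(q=0.3), seed=23))
        rm = fit(d, 0, FitSpec(effect="fetal", sex_stratum="male_only"))
        rf = fit(d, 0, FitSpec(effect="fetal", sex_stratum="female_only"))
        assert rm.n_families + rf.n_families == 600

    def test_scan_survives_per_snp_failures(self):
        cfg = SimulationConfig(150, 150, model=RiskModel(q=0.3), seed=29, n_snps=4,
                               maf_bounds=(0.2, 0.4))
        from xlinkrr import simulate_null_panel

        panel, _ = simulate_null_panel(cfg)
        panel.mother_gt[:, 2] = 0
        panel.child_gt[:, 2] = 0  # monomorphic
        table = scan(panel, FitSpec(effect="fetal"))
        assert len(table) == 4
        assert "monomorphic" in table.loc[2, "error"]
        assert (table.loc[table.index != 2, "error"] == "").all()


class TestInconsistentFamilies:
    def test_impossible_dyads_are_excluded_with_warning(self):
        d = simulate_dyads(SimulationConfig(
            300, 300, model=RiskModel(q=0.3), missing_rate=0.0, seed=31))
        boys = np.flatnonzero((d.families["child_sex"] == MALE).to_numpy())[:4]
        d.mother_gt[boys, 0] = 0
        d.child_gt[boys, 0] = 1
        with pytest.warns(UserWarning, match="inconsistent"):
            r = fit(d, 0, FitSpec(effect="fetal"))
        assert r.n_excluded == 4
        assert r.n_families == 596
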