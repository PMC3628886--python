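"""Synthetic-data generator: null sampling, case-conditional law, triad
transmission, rosters, panels, determinism."""

import numpy as np
import pytest
from scipy import stats

from xlinkrr import (
    FEMALE,
    MALE,
    RiskModel,
    SimulationConfig,
    case_male_fraction,
    family_roster_summary,
    simulate_dyads,
    simulate_null_panel,
    simulate_triads,
)
from xlinkrr.core import MULTIPLICATIVE, dyad_cell_table

from oracles import dyad_case_weight, dyad_cell_space


def _cell_counts(dataset, sex):
    sel = (dataset.families["child_sex"] == sex).to_numpy()
    m = dataset.mother_gt[sel, 0]
    c = dataset.child_gt[sel, 0]
    cells = list(zip(*dyad_cell_table(sex)))
    return np.array([int(((m == mi) & (c == ci)).sum()) for mi, ci in cells])


class TestNullSampling:
    def test_control_mothers_follow_hwe(self):
        q = 0.3
        cfg = SimulationConfig(0, 4000, model=RiskModel(q=q), missing_rate=0.0, seed=7)
        d = simulate_dyads(cfg)
        doses = d.mother_gt[:, 0]
        counts = np.bincount(doses, minlength=3)
        p = 1 - q
        expected = len(doses) * np.array([p * p, 2 * p * q, q * q])
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=2) > 1e-4

    def test_null_model_case_and_control_cells_agree(self):
        cfg = SimulationConfig(3000, 3000, model=RiskModel(q=0.25), missing_rate=0.0, seed=11)
        d = simulate_dyads(cfg)
        for sex in (MALE, FEMALE):
            sel = (d.families["child_sex"] == sex).to_numpy()
            case = sel & (d.families["status"] == "case").to_numpy()
            ctrl = sel & (d.families["status"] == "control").to_numpy()
            cells = list(zip(*dyad_cell_table(sex)))
            obs = np.array(
                [
                    [
                        int(((d.mother_gt[g, 0] == mi) & (d.child_gt[g, 0] == ci)).sum())
                        for mi, ci in cells
                    ]
                    for g in (case, ctrl)
                ]
            )
            _, p, _, _ = stats.chi2_contingency(obs[:, obs.sum(axis=0) > 0])
            assert p > 1e-4


class TestCaseConditionalLaw:
    def test_risk_allele_enrichment_in_case_boys_matches_closed_form(self):
        # P(A2 boy | case) = qR / (qR + p) = 1/3 at q=0.2, R=2
        q, rr = 0.2, 2.0
        cfg = SimulationConfig(
            5000, 0, model=RiskModel(q=q, rr_fetal=rr), missing_rate=0.0,
            case_male_fraction=1.0, seed=13,
        )
        d = simulate_dyads(cfg)
        frac = (d.child_gt[:, 0] == 1).mean()
        expected = q * rr / (q * rr + (1 - q))
        assert frac == pytest.approx(expected, abs=0.02)

    @pytest.mark.parametrize("sex", [MALE, FEMALE])
    def test_exact_sampler_matches_rejection_oracle(self, sex):
        """Chi-square GOF of the sampler's case cells against rejection
        sampling (draw population dyad, accept with prob prop. to B x mult)."""
        model = RiskModel(q=0.3, rr_fetal=1.8, rr_maternal=1.3)
        cfg = SimulationConfig(
            20_000, 0, model=model, missing_rate=0.0, seed=17,
            case_male_fraction=1.0 if sex == MALE else 0.0,
        )
        d = simulate_dyads(cfg)
        counts = _cell_counts(d, sex)

        rng = np.random.default_rng(99)
        n_pop = 400_000
        mothers = rng.binomial(2, model.q, size=n_pop)
        t = np.where(mothers == 1, rng.integers(0, 2, size=n_pop), mothers // 2)
        if sex == MALE:
            children = t
        else:
            children = t + rng.binomial(1, model.q, size=n_pop)
        # acceptance probability prop. to B * multiplier (the population part
        # is already in the draw)
        from oracles import female_mult, male_mult

        base = model.baseline_male if sex == MALE else model.baseline_female
        fet = (
            np.array([male_mult(c, model.rr_fetal) for c in children])
            if sex == MALE
            else np.array([female_mult(c, model.rr_fetal) for c in children])
        )
        mat = np.array([female_mult(m, model.rr_maternal) for m in mothers])
        mult = fet * mat
        accept = rng.random(n_pop) < base * mult / (base * mult).max()
        cells = list(zip(*dyad_cell_table(sex)))
        oracle_counts = np.array(
            [
                int(((mothers[accept] == mi) & (children[accept] == ci)).sum())
                for mi, ci in cells
            ]
        )
        table = np.array([counts, oracle_counts])
        _, p, _, _ = stats.chi2_contingency(table[:, table.sum(axis=0) > 0])
        assert p > 0.001

    def test_case_sex_ratio_follows_baselines(self):
        model = RiskModel(q=0.3)  # default baselines give ~54.8% boys
        cfg = SimulationConfig(20_000, 0, model=model, missing_rate=0.0, seed=23)
        d = simulate_dyads(cfg)
        frac = (d.families["child_sex"] == MALE).mean()
        assert frac == pytest.approx(case_male_fraction(model), abs=0.01)
        assert 0.53 < case_male_fraction(model) < 0.57


class TestDeterminismAndValidity:
    def test_same_seed_same_dataset(self):
        cfg = SimulationConfig(200, 200, model=RiskModel(q=0.2), seed=31)
        a, b = simulate_dyads(cfg), simulate_dyads(cfg)
        assert a.families.equals(b.families)
        assert np.array_equal(a.mother_gt, b.mother_gt)
        assert np.array_equal(a.child_gt, b.child_gt)

    def test_simulated_genotypes_are_mendelian_before_missingness(self):
        from xlinkrr import count_mendelian_errors

        cfg = SimulationConfig(2000, 2000, model=RiskModel(q=0.3, rr_fetal=1.5),
                               missing_rate=0.0, seed=37)
        d = simulate_dyads(cfg)
        assert count_mendelian_errors(d, 0) == 0

    def test_degenerate_frequency_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            simulate_dyads(SimulationConfig(10, 10, model=RiskModel(q=1e-6)))

    def test_missingness_rate_close_to_nominal(self):
        cfg = SimulationConfig(5000, 5000, model=RiskModel(q=0.3),
                               missing_rate=0.03, seed=41)
        d = simulate_dyads(cfg)
        frac = (d.mother_gt < 0).mean()
        assert frac == pytest.approx(0.03, abs=0.006)


class TestTriads:
    def test_null_father_to_daughter_transmission_is_fair(self):
        q = 0.3
        cfg = SimulationConfig(8000, 0, model=RiskModel(q=q), missing_rate=0.0,
                               case_male_fraction=0.0, seed=43)
        t = simulate_triads(cfg, design="fetal_triad")
        # under the null the father allele matches its population frequency
        assert (t.father_gt[:, 0] == 1).mean() == pytest.approx(q, abs=0.015)

    def test_maternal_triad_overtransmission_from_het_grandmother(self):
        """Multiplicative het dose R=2 gives 2:1 transmission odds, so the
        case mother receives A2 from a heterozygous grandmother ~2/3 of the
        time (the classic TDT expectation)."""
        model = RiskModel(q=0.3, rr_maternal=2.0, female_dose_mode=MULTIPLICATIVE)
        cfg = SimulationConfig(20_000, 0, model=model, missing_rate=0.0, seed=47)
        t = simulate_triads(cfg, design="maternal_triad")
        het_gm = t.mother_gt[:, 0] == 1  # grandmother in the parent slot
        received = t.child_gt[het_gm, 0] - t.father_gt[het_gm, 0]
        assert set(np.unique(received)) <= {0, 1}
        assert received.mean() == pytest.approx(2.0 / 3.0, abs=0.015)

    def test_roster_reproduces_replication_study_composition(self):
        roster = {
            "full_triads": 182,
            "mother_child_dyads": 66,
            "father_child_dyads": 14,
            "extra_children": {2: 4, 3: 1},
        }
        cfg = SimulationConfig(0, 0, model=RiskModel(q=0.3), missing_rate=0.0, seed=53)
        t = simulate_triads(cfg, design="fetal_triad", roster=roster)
        summary = family_roster_summary(t)
        assert summary["full_triads"] == 182
        assert summary["mother_infant_dyads"] == 66
        assert summary["father_infant_dyads"] == 14
        assert summary["larger_families"] == {4: 4, 5: 1}
        assert summary["n_families"] == 267
        assert summary["n_individuals"] == 727


class TestNullPanel:
    def test_maf_within_bounds_and_null_p_uniform(self):
        cfg = SimulationConfig(400, 400, model=RiskModel(q=0.3), missing_rate=0.01,
                               seed=59, n_snps=150, maf_bounds=(0.05, 0.5))
        panel, truth = simulate_null_panel(cfg)
        assert len(truth) == 150
        assert truth["maf"].between(0.05, 0.5).all()
        assert (truth["rr_fetal"] == 1.0).all()

        from xlinkrr import FitSpec, scan

        table = scan(panel, FitSpec(effect="fetal"))
        p = table.loc[table["error"] == "", "p_overall"].to_numpy()
        assert len(p) == 150
        frac = (p < 0.05).mean()
        # binomial(150, .05) three-sigma band
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 150)

    def test_signal_snp_recovers_effect(self):
        cfg = SimulationConfig(2500, 2500, model=RiskModel(q=0.3), missing_rate=0.0,
                               seed=61, n_snps=3, maf_bounds=(0.2, 0.4))
        panel, truth = simulate_null_panel(cfg, signal_snps={1: (1.8, 1.0)})
        from xlinkrr import FitSpec, fit

        r = fit(panel, 1, FitSpec(effect="fetal"))
        assert r.ci_low <= 1.8 <= r.ci_high or abs(np.log(r.rr / 1.8)) < 0.15
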