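"""Scan a small SNP panel overall and within each child sex.

One SNP carries a fetal effect (RR 1.7); the rest are null.  Sex-stratified
fits share nothing across strata, so a male-limited biological effect would
show up only in the male column.
"""

from xlinkrr import FitSpec, RiskModel, SimulationConfig, scan, sex_stratified_scan, simulate_null_panel

config = SimulationConfig(n_case_dyads=1000, n_control_dyads=1000,
                          model=RiskModel(q=0.3), missing_rate=0.01,
                          seed=11, n_snps=6, maf_bounds=(0.15, 0.45))
panel, truth = simulate_null_panel(config, signal_snps={2: (1.7, 1.0)})

both = scan(panel, FitSpec(effect="fetal", sex_stratum="both"))
print("== both sexes ==")
print(both[["snp", "maf", "rr", "ci_low", "ci_high", "p_overall"]]
      .round(3).to_string(index=False))

strat = sex_stratified_scan(panel, FitSpec(effect="fetal"))
hit = strat[strat["snp"] == "snp3"]
print("\n== snp3 (the signal SNP) by stratum ==")
print(hit[["stratum", "rr", "ci_low", "ci_high", "p_overall", "n_families"]]
      .round(3).to_string(index=False))
# snp3 should stand out in the combined scan; with a shared (not sex-specific)
# simulated effect both strata point the same way with wider CIs.
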