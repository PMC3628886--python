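"""Run the study QC filters on a panel with injected problems.

Individuals (and their whole dyads) below a 97% call rate are dropped
first; SNPs are then filtered on call rate (<95%), Mendelian-error count
(>5) and minor allele frequency (<1%), computed on the survivors.
"""

import numpy as np

from xlinkrr import MALE, RiskModel, SimulationConfig, apply_filters, simulate_null_panel

config = SimulationConfig(n_case_dyads=500, n_control_dyads=500,
                          model=RiskModel(q=0.3), missing_rate=0.0,
                          seed=7, n_snps=20, maf_bounds=(0.05, 0.5))
panel, _truth = simulate_null_panel(config)

# a few children with terrible call rates, one SNP with 6 Mendelian errors
# (injected in dyads that survive the call-rate filter)
panel.child_gt[:8, :10] = -1
male = (panel.families["child_sex"] == MALE).to_numpy()
boys = np.flatnonzero(male & (np.arange(len(male)) >= 8))[:6]
panel.mother_gt[boys, 3] = 0
panel.child_gt[boys, 3] = 1

filtered, report = apply_filters(panel)
summary = report.summary()
print(f"dyads   : {summary['n_dyads_in']} in -> {summary['n_dyads_out']} out")
print(f"SNPs    : {summary['n_snps_in']} in -> {summary['n_snps_out']} out")
print(f"reasons : {summary['snp_drop_reasons']}")
print(report.snp_table[["snp", "call_rate", "maf", "mendel_errors", "dropped", "reason"]]
      .head(5).to_string(index=False))
# The 8 corrupted children fall below the individual call-rate threshold and
# take their dyads with them; the SNP with 6 Mendelian errors (>5) is dropped.
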