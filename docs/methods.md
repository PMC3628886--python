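# Methods

## The problem

X-linked association analysis in family designs cannot reuse autosomal
machinery unchanged. Males carry one X, so their genotype is a single
allele; females silence one X copy per cell, which argues for a dosage
model in which a heterozygote's risk lies midway between the two homozygote
risks; and for outcomes such as spontaneous preterm delivery the baseline
risk itself differs between boys and girls, so any model that shares a
single intercept across sexes confounds the allele effect with the sex
effect. `xlinkrr` estimates fetal (child-genotype) and maternal
(mother-genotype) relative risks for biallelic X SNPs from case-mother /
control-mother dyads and from case-parent triads.

## Risk model

Each SNP has alleles A1/A2 with A2 the designated risk allele at population
frequency `q`. Disease risk is multiplicative on a sex-specific baseline:

- boys: baseline `B_B`, multiplied by `R` if the boy is hemizygous A2;
- girls: baseline `B_G`, multiplied by `(1+R)/2` if heterozygous and by `R`
  if homozygous A2 (`female_dose_mode="x_inactivation_average"`, the
  default). The multiplicative alternative (het `R`, hom `R^2`) is provided
  for sensitivity analyses; we expose both for maternal effects as well
  rather than guessing which convention an external package would apply to
  the mother's genotype, and default to the inactivation average for both so
  that a SNP has one interpretable `R` per effect.
- maternal effects: the same female dose model applied to the mother's own
  genotype, with its own relative risk.

Baselines never enter the estimation: all likelihood contributions condition
on case status within a child-sex stratum, and `B_B`, `B_G` cancel. This is
precisely what buys robustness against everything else that makes boys'
and girls' risks differ. The baselines do matter for *simulation*, where
they set the case sex ratio.

## Population assumptions

Mothers are at Hardy-Weinberg equilibrium, mating is random, and the male
and female allele frequencies are equal (one generation of random mating on
the X does not equalize them exactly; we treat the population as at
equilibrium). These assumptions are not stated by most study reports but
are what the likelihood requires; they are explicit here. Girls receive one
maternal allele (fair transmission from heterozygous mothers) and one
paternal allele, Bernoulli(`q`) when the father is unobserved. Boys receive
only the maternal allele; an observed father is uninformative about his
son's genotype, and in the case-triad law the father's allele factors out
of the case-conditional distribution for sons (checked numerically in the
tests).

## Likelihoods

**Hybrid dyad design.** Within child sex `s`, the complete-data cells are
the Mendelian-consistent (mother genotype, child genotype) pairs — 4 for
boys, 7 for girls. With `f_j(q)` the population cell law and `m_j(R)` the
fetal x maternal multiplier, a case dyad in cell `j` contributes
`f_j m_j / Σ_k f_k m_k` and a control dyad `f_j`. Control dyads use the
plain population law — the rare-disease approximation, appropriate for a
~5-6% outcome whose controls are a healthy term sample; an exact mode
weighting control cells by `1 − B_s m_j` is available in the simulator for
checking the approximation's impact.

**Triads.** Cells are (father allele, mother genotype, child genotype)
under the same population law; case families are weighted by the
multiplier and renormalized within sex. The maternal-triad design places
the case mother in the child slot (all female) with her own parents in the
parent slots; only her genotype carries a multiplier.

**Missing genotypes.** Observed patterns with missing members contribute
the sum of the cell law over all Mendelian-compatible completions — exact
marginalization. At the maximum this is identical to what
expectation-maximization converges to, but it is deterministic, has no
inner loop, and its gradient is exact. Families incompatible with *every*
completion (Mendelian errors that survived QC) would contribute zero
probability; they are excluded from the fit with a warning and counted in
the result.

**Estimation.** Parameters are transformed to (logit `q`, log `R`) — or
(logit `q`, log `R_f`, log `R_m`) for a joint fit — and maximized by BFGS
from the fixed start `q` = observed allele frequency (X-copy weighted),
`R` = 1, with a Nelder-Mead polish if the gradient step stalls; estimates
are therefore deterministic given the data. Standard errors come from the
central-difference observed information (step 1e-4); `p_rr` is the
two-sided Wald p on log `R`; `p_overall` is the likelihood-ratio test
against all `R = 1`, with degrees of freedom equal to the number of free
relative risks. The two p-value columns of study reports rarely define
their construction; this Wald/LRT mapping is our declared choice. The 95%
CI uses `z = 1.959964` so that CI-derived standard errors in the
meta-analysis layer are exactly consistent. Internally each fit aggregates
the data into observed-pattern counts, so cost is independent of sample
size: a 10,000-dyad fit takes a few milliseconds.

Both-sex fits share `q` and `R` across the male and female strata, each
stratum normalized over its own cells. A stratum with no case families, or
with one allele entirely absent, raises an error (`monomorphic SNP`); the
scan records per-SNP errors and continues.

## Quality control

Filter order is fixed and matters: (1) individuals with genotype call rate
below 97% are dropped, removing their whole dyads; (2) on the survivors,
SNPs are dropped for call rate below 95%, then more than five Mendelian
inconsistencies, then minor allele frequency below 1% (first failing rule
is the recorded primary reason). All thresholds exclude on strict
inequality: a value exactly at threshold is retained. MAF counts two X
alleles per female and one per male. Female-only Hardy-Weinberg is computed
(Pearson chi-square, 1 df) and reported but never filters — observed
deviations can be real on the X and the filter would be anticonservative.
Family-level duplicate exclusion is a roster uniqueness check on family
ids, not genotype-based relatedness inference. A heterozygous male X
genotype in a PED file is impossible data: the reader decodes it to missing
and reports the count.

## Meta-analysis

Per SNP, study log-RRs are combined with inverse-variance weights, each
study's SE recovered from its 95% CI as `(ln U − ln L)/(2 × 1.959964)` —
required when only printed tables survive. Because printed RR/CI values are
2-decimal roundings, combined RRs reproduce published values to about one
unit in the second decimal, while combined p-values are *not* expected to
match published p columns. Overall p-values are combined by Fisher's
method, which is direction-agnostic and therefore complements the signed
fixed-effects estimate. Allele orientation uses the convention that the
lower-case letter in an `A/g`-style pair is the minor/risk allele; when
studies orient a SNP oppositely, the discordant study's RR is inverted
before combining and the flip is logged. Heterogeneity statistics (Q, I²)
are deliberately out of scope for the two-study setting this targets.

## Synthetic data

The generator emulates the sampling structure the estimator assumes — it is
the package's test bed, not a cohort emulator:

- **Case dyads** are drawn from the exact case-conditional cell law within
  child sex (validated against a rejection-sampling oracle); **controls**
  from the population law. Child sex among cases follows the baseline
  ratio: the defaults `B_B = 0.0636`, `B_G = 0.055` give a ~5.5-6%
  baseline risk (typical of spontaneous preterm delivery in Scandinavian
  registries) and ~54.8% boys among cases at a 51.2% live-birth male
  fraction. Default study sizes are 1,000+1,000 dyads (a large cohort) with
  500+500 for a smaller replication-style cohort.
- **Triads** sample the father allele explicitly; the maternal-triad design
  samples case mothers conditional on their own genotype's multiplier.
  A roster option fixes family composition (full triads, single-parent
  dyads, multi-sibling families) for testing roster summaries and
  marginalization over absent members.
- **Panels** draw per-SNP MAFs uniformly in configurable bounds (default
  1%-50%) with independent SNPs; per-SNP relative risks can be planted.
- **Missingness** is injected per genotype, missing completely at random,
  default 2% (study reports give only call-rate thresholds, so the rate is
  configurable, 1-3% being realistic).

What the generator does *not* emulate — linkage disequilibrium between
SNPs, population stratification, genotyping-error mechanisms beyond MCAR
missingness, and real covariate structure — bounds what passing tests show:
they validate the estimator under its own assumptions, not robustness to
their violation.

## Numerical choices and edge cases

- Optimizer: BFGS, gradient tolerance 1e-8, max 200 iterations, fixed
  starts; convergence additionally checked by the gradient norm at the
  optimum. Boundary estimates (RR outside [1e-3, 1e3]) are flagged rather
  than silently reported.
- LRT statistics are clipped at zero; monomorphic SNPs error out rather
  than returning pseudo-estimates; all-missing patterns contribute
  log 1 = 0.
- QQ tables use the `(i − 0.5)/m` expected-quantile convention.
- Pearson 2x2 chi-square is computed *without* continuity correction — the
  variant that matches published cohort sex-ratio p-values.
- Determinism: a simulation config plus seed yields a byte-identical PED
  file; a fit is a deterministic function of the data.

## Problem sizes used in validation

The automated checks run 500 null simulations of 2,000 dyads for type-I
calibration (expected Wald rejection rate 4-6% at the 5% level), 200
replicates of 10,000 dyads at fetal RR 1.5 for recovery and CI coverage,
and 100+ random small instances with 20% missingness for agreement between
the marginalized likelihood and a brute-force enumeration oracle (tolerance
1e-10). These sizes mirror the study scale the package targets while
keeping a full validation run in tens of seconds.

## Known limitations

Single-SNP analyses only (no haplotypes or LD modeling); no
parent-of-origin effects, covariate adjustment, or gene-environment
interaction; X-pseudoautosomal SNPs are rejected at parse time rather than
handled; the control model is the rare-disease approximation unless the
exact mode is requested; and CI-derived standard errors inherit the
rounding of whatever table they came from.
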