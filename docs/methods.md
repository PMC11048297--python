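# Methods

`editscape` re-creates, as a tested library, a complete analysis path from
per-site RNA-seq base counts to clinically interpretable statements about
A>I(G) RNA editing: which sites are edited, which are differentially edited
between drug-sensitivity groups, how global Alu editing behaves per sample,
and whether hyper- versus hypo-editing at a site associates with
progression-free survival. Every stage can be exercised on synthetic data
with known ground truth, which is how the test suite and the acceptance
script validate it.

## The data model

A>I editing is read out of RNA-seq as A>G mismatches on the plus strand and
T>C on the minus strand, so every site carries a strand and its alleles are
determined by it. Positions are 1-based (VCF-like) in memory; BED input is
converted at the boundary (a 1-based position `p` overlaps a half-open
interval `[start, end)` iff `start <= p-1 < end`). The central container is
the `EditingMatrix`: sites x samples of `(edited, total)` read counts, with
an explicit distinction between a covered-but-unedited cell
(`alt = 0, total > 0`) and a cell with no coverage (NaN in both layers).
Reads that are neither the reference nor the strand-rule alternative base
are ignored throughout: the working total is `ref + alt`.

## Site calling

The cascade has four stages, each audited (input − removed = output):

1. **Candidate call** — per sample, a site is called iff it has at least 5
   edited reads *and* allele frequency `alt/(alt+ref) >= 0.05`. The edited-
   read count (not total coverage) is thresholded; both cutoffs are
   configurable. The candidate list is the union of per-sample calls.
2. **Missing-value resolution** — every candidate site's cell in every
   sample is backfilled from the raw counts, so downstream statistics see
   sub-threshold and zero-edited cells as data rather than as missing.
3. **Prevalence** — keep sites present in strictly more than 50% of
   samples. "Present" defaults to *covered*; a stricter "called" mode is
   available because either reading of prevalence is defensible.
4. **DNA-variant subtraction** — a site is removed iff `(chrom, pos, ref,
   alt)` exactly matches a genomic variant, strand-aware (a minus-strand
   site matches a T>C record). One merged variant set is applied per
   cohort. A heterozygous genomic variant masquerades as a ~50%-edited site
   in RNA, which is why the synthetic generator plants its contaminants at
   allele fraction 0.5.

The cascade is idempotent and monotone in its thresholds; both properties
are tested.

## The differential test

At one site, the edited count `k` of a sample with coverage `n` is modelled
as beta-binomial: `p ~ Beta(alpha, beta)`, `k | p ~ Binomial(n, p)`, with
mean `mu = alpha/(alpha+beta)` and concentration `phi = alpha+beta`
(overdispersion `rho = 1/(1+phi)`). Coverage varies freely across samples.
The log-likelihood is computed with log-gamma functions; the MLE is found
in unconstrained `(logit mu, log phi)` coordinates with an analytic
gradient (L-BFGS-B, projected-gradient tolerance 1e-6, method-of-moments
start, jittered restarts). The parameter space is bounded at
`|logit mu| <= 15` and `phi <= 1e4`: beyond that the model is numerically
indistinguishable from a degenerate/binomial one and the MLE can diverge.
Data entirely at a boundary (all cells zero, or all fully edited) have
their likelihood supremum at the boundary with log-likelihood exactly 0 and
are returned as flagged boundary fits.

The two-group test compares a pooled null fit (2 parameters) against
independent per-group fits (4 parameters); `LLR = 2(ll_g1 + ll_g2 -
ll_null)`, clamped at zero. Cells without coverage are dropped per site per
group, never imputed.

**Small-sample calibration.** With 5–10 samples per arm the raw LLR is
stochastically larger than its chi-square(2) limit, because the per-group
concentrations are weakly identified and the alternative chases noise in
them (measured null mean LLR ~2.2 instead of 2, rejection at nominal 0.05
of ~0.07). The default p-value is therefore a smoothed parametric
bootstrap: the fitted null is simulated `n_boot = 100` times at the
observed coverages, each bootstrap dataset is refitted (all refits batched
into one vectorized damped-Newton optimization with an active-set step at
parameter bounds and a series-based trigamma), and the observed statistic
is referred to the linearly interpolated empirical survival function of the
bootstrap LLRs. Beyond the bootstrap maximum the survival is extended by a
moment-matched gamma tail, so extreme statistics map to arbitrarily small
p-values instead of saturating at `1/(n_boot+1)` — this keeps BH FDR
resolution intact for strong effects. The bootstrap seed is derived from
the data (CRC of the canonically ordered counts), making results
deterministic and invariant to sample order and group relabeling. A
`correction="bartlett"` mode (rescale by `df / E0[LLR]`, chi-square tail)
and the plain asymptotic `correction="none"` are kept for comparison; the
chi-square degrees of freedom default to 2 and are configurable.

Measured under the null conditions used in acceptance (mu = 0.2, rho =
0.05, 10 vs 8 samples, negative-binomial coverage around 50), the
bootstrap-calibrated rejection rate at p < 0.05 is ~0.05–0.06 over 2,000
replicates. The residual distance of the p-value distribution from uniform
(KS ~0.035) reflects parametric-bootstrap approximation error — the null is
simulated at estimated, not true, parameters — and sits at about the 1%
KS critical value for 2,000 draws, so a uniformity test at that size is
borderline by construction; removing it would require a far more expensive
double bootstrap.

## DES selection, fold change, delta

Per-site group means are the fitted beta means; `delta = mean_g1 - mean_g2`
signs the direction (group 1 is the low-sensitivity group by convention).
The fold change is `log2((mean_g1 + 1e-4) / (mean_g2 + 1e-4))`; the
pseudocount guards zero means, and sites with both means zero are never
selected. A site is a DES iff `p < 0.05`, BH `FDR < 0.1`, and the fold
change clears 2.5. The fold-change gate defaults to the **ratio** scale
(editing-level ratio >= 2.5); the log2 reading is selectable
(`fc_scale="log2"`). The ratio default is deliberate: a gate placed on the
same scale as a threshold-sized effect passes an unbiased estimate of that
effect only about half the time — selection should be driven by the test
and the FDR, with the gate excluding only small effects. BH is the standard
step-up procedure (statsmodels) and is verified against a brute-force
implementation of the definition.

## Alu Editing Index

Per sample, the AEI is the pooled ratio `sum(alt) / sum(alt+ref)` over that
sample's covered cells at sites overlapping ALU intervals — a ratio of
sums, not a mean of per-site ratios, so high-coverage sites weigh more.
With a single Alu cell it equals the editing level exactly. Sites in
non-Alu repeats or unique sequence are excluded; where ALU and non-Alu
intervals overlap a position, ALU takes precedence.

## Drug-sensitivity grouping and cohort statistics

Per drug, samples strictly below the first IC50 quartile are
HIGH_SENSITIVITY, strictly above the third LOW_SENSITIVITY, the rest
INTERMEDIATE (kept in the table, excluded from comparisons). Quartiles use
linear-interpolation ("type 7") quantiles by default, nearest-rank
optionally; ties at a quartile stay INTERMEDIATE (strict inequalities).
Two-group descriptive comparisons gate on Shapiro–Wilk normality at 0.05 in
both groups: normal => t-test, otherwise the Wilcoxon rank-sum test; a
constant group makes normality undefined and forces the rank test with a
warning. Batched comparisons optionally share one BH adjustment. Pearson
correlation is the standard product-moment estimate with a two-sided
t-based p-value.

## Survival validation

Patients are classified per site as HYPER-edited when their editing level
is strictly above the mean over patients with that site observed (strict
"over"; all-identical levels degenerate to all-HYPO with a warning).
Kaplan–Meier estimation and the two-sample log-rank test are delegated to
`lifelines` behind the package's own surfaces and verified in the test
suite against brute-force product-limit and O−E/V oracles plus a
permutation reference; ties between events and censoring at the same time
follow the events-first convention. The per-site scan excludes patients
missing the site, reports raw and BH-adjusted p-values, and flags
significance on the raw p at 0.05 by default (the adjusted column is there
for stricter use). An optional pre-filter keeps only patients in the first
and fourth PFS quartiles, reusing the quantile machinery.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, with
defaults chosen as the study conditions the pipeline targets:

| parameter | default | meaning |
|---|---|---|
| `n_sites` | 1000 | candidate sites |
| `frac_des` | 0.10 | fraction of sites differentially edited |
| `n_group1, n_group2` | 10, 8 | samples per sensitivity group |
| `coverage_mean, coverage_dispersion` | 50, 5 | negative-binomial read depth |
| `null_mean` | 0.10 | background editing level |
| `null_overdispersion` | 0.05 | beta-binomial rho across samples |
| `des_log2fc` | 2.5 | planted |log2 fold change| at DES sites |
| `frac_dna_variant` | 0.05 | heterozygous genomic contaminants |
| `dropout_rate` | 0.05 | per-cell missingness |

Group sizes mirror a drug-family comparison in a small cell-line panel; the
planted fold change equals the selection threshold so recovery is tested at
the decision boundary's effect size; coverage defaults are a generic
bulk-RNA-seq depth (real cell-line coverage distributions vary and the
parameter is exposed). Coverage is negative-binomial rather than fixed so
ragged totals exercise the test. DES directions split 50/50 between the two
groups. A config whose raised mean `null_mean * 2^des_log2fc` leaves (0, 1)
is rejected, never clipped, to keep the truth table honest. DNA-variant
sites express at allele fraction 0.5 in both groups (binomial, no
overdispersion — a genomic genotype has no biological editing variance) and
are never differential. Survival times are exponential with hazard
`baseline_hazard * exp(effect_beta * level)` (defaults 0.03/month — median
PFS ~23 months at level 0 — and 3 per unit level); censoring is independent
with probability `censor_rate = 0.3`, censored at a uniform fraction of the
event time. IC50 tables are standard-normal noise with a `+separation`
shift for the designated low-sensitivity samples.

What the generator does **not** emulate: read-level artifacts (mapping
error, strand bias, quality), sequence context and hyper-editing clusters,
correlated editing across neighboring sites, batch structure, and
non-exponential survival shapes. Passing tests therefore demonstrate the
statistical machinery is correct under its stated model, not that the model
captures every property of real RNA-seq.

## Numerical and design choices

- Editing level of an uncovered cell is undefined and raises; it is never
  silently 0.
- `prevalence` uses a strict `>` at the 50% boundary; a site observed in
  exactly half the samples is removed.
- A value exactly at an IC50 quartile, or an editing level exactly at the
  site mean, falls to the conservative side (INTERMEDIATE, HYPO).
- All randomness flows from single seeds; the pipeline derives per-stage
  sub-seeds from the master seed via `SeedSequence`, and two runs with the
  same config produce byte-identical tables.
- Problem sizes in the acceptance checks (2,000 null replicates, 1,000
  planted sites, 500 survival simulations, 100 scan replicates) were chosen
  to bound Monte-Carlo error on each reported rate at roughly the
  half-width of the band being checked.

## Known limitations

- The bootstrap calibration adds ~20 ms per tested site; scanning millions
  of sites would want the `correction="bartlett"` or `"none"` modes or
  coarser `n_boot`.
- The LLR's null distribution is approximated at estimated null parameters;
  exactness claims are asymptotic in `n_boot` and in the fit quality.
- Family-level drug grouping (combining per-drug quartile labels into a
  drug-family label) is left to the caller: labels are per drug.
- Coordinate liftover is consumed as a precomputed mapping table; chain
  files are out of scope.
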