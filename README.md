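# editscape

Statistical analysis of A>I(G) RNA editing and its association with drug
response and disease progression, built for cancer transcriptomics panels
(cell lines with drug IC50 profiles; patient cohorts with progression-free
survival).

Adenosine-to-inosine editing, catalyzed mainly by ADAR1/ADAR2 on
double-stranded RNA, is read by sequencers as guanosine: an edited site
appears as an A>G mismatch on the plus strand or T>C on the minus strand.
`editscape` takes per-sample, per-position base-count tables (REDItools /
bam-readcount style TSVs) and answers, with explicit statistics:

- **Which positions are edited?** A strand-aware filter cascade: per-sample
  candidate calling (≥ 5 edited reads and allele frequency ≥ 0.05),
  missing-value resolution (a covered-but-unedited cell is data, not a
  gap), a > 50% sample-prevalence filter, and subtraction of genomic DNA
  variants matched by chromosome, position and alleles — with an audited
  input/removed/output report per stage.
- **Which sites differ between drug-sensitivity groups?** Cell lines are
  grouped per drug by IC50 quartile (below Q1 = high sensitivity, above
  Q3 = low). Per site, edited counts k with coverage n are modelled as
  beta-binomial — `p ~ Beta(α, β)`, `k | p ~ Binomial(n, p)`, editing level
  `μ = α/(α+β)` — and the two groups are compared by a likelihood-ratio
  test: pooled fit (2 parameters) versus independent per-group fits (4
  parameters), `LLR = 2(ℓ₁ + ℓ₂ − ℓ₀)`. Because the small panels typical of
  this design inflate the raw statistic relative to its χ²₂ limit, the
  default p-value is calibrated by a smoothed parametric bootstrap of the
  fitted null (gamma-extended tail, data-derived seed, fully
  deterministic). Differentially edited sites (DESs) are selected at
  p < 0.05, Benjamini–Hochberg FDR < 0.1, and fold change ≥ 2.5, with the
  per-site delta `μ_low − μ_high` signing the direction.
- **How much global Alu editing does each sample show?** The Alu Editing
  Index: the pooled ratio Σ(edited reads)/Σ(total reads) over sites inside
  Alu repeat intervals — a ratio of sums, not a mean of per-site levels.
- **Does editing at a site track progression?** Patients are classified
  hyper- or hypo-edited about the per-site cohort mean and compared by
  Kaplan–Meier curves and the two-sample log-rank test, per site, with raw
  and BH-adjusted p-values.

A first-class synthetic-data module generates every input with known ground
truth — beta-binomial counts with planted differential sites, negative-
binomial coverage, heterozygous DNA-variant contaminants, dropout,
quartile-separable IC50 tables, and exponential progression times whose
hazard depends on editing level — so the whole pipeline is testable without
any external download.

## Worked example

```python
from editscape.diffedit import differential_editing, select_des
from editscape.simulate import SimConfig, gen_editing_counts

cfg = SimConfig(n_sites=150, frac_des=0.1, frac_dna_variant=0.0, seed=7)
matrix, truth = gen_editing_counts(cfg)
results, skipped = differential_editing(matrix, cfg.group1_samples, cfg.group2_samples)
des = select_des(results)
```

(`examples/02_differential_editing.py`) prints, among others:

```
              pvalue     fdr  mean_g1  mean_g2  log2fc   delta
site_id
chr1:1000:-   0.1928  0.6024   0.0637   0.1337 -1.0697 -0.0701
chr22:1000:+  0.1832  0.6016   0.0474   0.0823 -0.7931 -0.0348

sites tested: 150  skipped: 0
DESs selected: 16  (planted: 15)
true positives among selected: 15
```

`mean_g1`/`mean_g2` are the fitted beta-binomial editing levels per group,
`delta` their difference (group 1 is the low-sensitivity group), and
`log2fc` the pseudocounted log2 ratio. Of 150 sites with 15 planted
differential ones (|log2 fold change| = 2.5), selection recovers all 15
with one false positive — consistent with the FDR 0.1 target.

The survival scan (`examples/04_survival_scan.py`) on a simulated
86-patient cohort in which one site drives progression hazard prints:

```
    site_id  n_hyper  n_hypo  logrank_chi2  pvalue  pvalue_bh  significant
driver_site       42      44       49.1377  0.0000     0.0000         True
  null_site       45      41        0.1281  0.7204     0.7204        False
```

The planted driver separates hyper- from hypo-edited patients (log-rank
χ² ≈ 49); the null site does not.

The `examples/` directory has one short script per capability; the
`editscape` command exposes the same stages from a shell
(`simulate`, `call`, `groups`, `diff`, `aei`, `survive`, `run-all`), and
`editscape run-all --config cfg.yaml` executes the whole pipeline from one
YAML config with a reproducibility manifest.

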