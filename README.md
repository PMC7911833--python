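# twinstats

Classical twin-family analysis of lifetime binary phenotypes, built around
the common primary pain disorders of childhood: growing pains (`gp`),
migraine, non-migraine headache, recurrent abdominal pain (`rap`), low back
pain (`lbp`) and persistent pain not otherwise specified (`pp`).

The package is for epidemiologists and biostatisticians working with
twin-family questionnaire cohorts who want to (a) quantify how much more
similar monozygotic (MZ) twins are than dizygotic (DZ) twins for a binary
trait, (b) test that difference formally, (c) scan for familial aggregation
across co-twins, siblings and parents, and (d) validate the whole pipeline
on synthetic cohorts with known genetic architecture, since individual-level
twin registry data are rarely shareable.

## What it computes

For each condition and zygosity group, the twin pairs reduce to counts
(N_c, N_d, N_00) — both affected, exactly one affected, neither affected.
Three maximum-likelihood similarity measures are fitted on the exchangeable
pair model with marginal affection probability *q*:

* **casewise concordance** C = P(affected | co-twin affected), with MLE
  2N_c / (2N_c + N_d) and a delta-method Wald CI on the multinomial counts;
* **twin correlation** rho, parameterised via p11 = q² + rho·q(1−q) —
  algebraically the phi coefficient of the double-entered 2×2 table;
* **pair odds ratio** psi (a Plackett cross-product parameter), saturated
  MLE N_c·N_00 / (N_d/2)².

Under the equal-environments assumption of the classical twin design,
C_MZ > C_DZ (equivalently rho_MZ > rho_DZ) indicates additive genetic
influence. The MZ-vs-DZ contrast is tested by a 1-df likelihood-ratio test
that shares the association parameter across zygosities while keeping
separate marginals; covariate-adjusted variants let each twin's marginal
depend on age and sex on the log-odds scale.

Family aggregation is assessed by logistic regression of a randomly
selected index twin's status on co-twin / oldest-sibling / mother / father
statuses (univariate and multivariate, Wald tests), and the MZ-vs-DZ
prevalence contrast by a family random-intercept logistic model integrated
with adaptive Gauss–Hermite quadrature.

The `simulate` module generates cohorts under a liability-threshold ACE
model: standard-normal latent liabilities with variance fractions a², c²,
e², kinship-structured correlations (MZ co-twins share all additive genetic
variance, DZ co-twins and first-degree relatives half), and an affection
threshold set by lifetime prevalence K. Closed-form bivariate-normal
orthant oracles give the expected concordances for validation.

## Worked example

Simulate a 1000-family cohort in which growing pains has a² = 0.6,
c² = 0.1, prevalence 18%, then analyse it:

```
$ twinstats simulate --params params.yaml --seed 42 --out cohort.csv
wrote 5000 member rows (1000 families) to cohort.csv

$ twinstats similarity --method casewise --condition gp --input cohort.csv
condition,zygosity,method,estimate,se,ci_low,ci_high,n_pairs
gp,MZ,casewise,0.558659,0.0445571,0.471329,0.64599,500
gp,DZ,casewise,0.429319,0.0448863,0.341344,0.517295,500

$ twinstats lrtest --method casewise --condition gp --input cohort.csv
gp      casewise        LR=4.1172       df=1    p=0.042

$ twinstats famassoc --condition gp --mode mult --seed 7 --input cohort.csv
analysis,n,member,or,p
Mult,1000,cotwin,6.08,<0.001
Mult,1000,sibling,3.03,<0.001
Mult,1000,mother,1.74,0.007
Mult,1000,father,1.64,0.023
```

with `params.yaml`:

```yaml
conditions:
  gp: {a2: 0.6, c2: 0.1, prevalence: 0.18}
config: {n_families: 1000}
```

Reading: MZ concordance 0.56 exceeds DZ 0.43 and the likelihood-ratio test
rejects equality (p = 0.042), consistent with the simulated additive
genetic effect; the multivariate family scan shows the strongest
association with the co-twin (OR 6.08), then the sibling (who shares both
genes and the c² household component), then each parent (genes only). The
library API (`twinstats.casewise_concordance`, `lr_test_zygosity`,
`univariate_scan`, `simulate_cohort`, ...) exposes the same operations on
DataFrames, and `twinstats report --config run.yaml` runs every stage and
writes the four standard table layouts plus a manifest.

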