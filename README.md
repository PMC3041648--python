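# pepikit

A scriptable toolkit of the statistical routines epidemiologists use on
*summary* data — the numbers already counted up on a desk pad: 2x2 and
r x c tables of cases and exposures, stratified tables, discordant-pair
counts, rating matrices, stratum events over person-time, short numeric
samples, lists of P values. It is aimed at practitioners, students and
teachers who want to replicate a published Mantel-Haenszel odds ratio,
size a study while writing the grant, check a kappa from a reliability
exercise, or demonstrate how prevalence drives predictive value — without
loading individual-record data into a full statistics package.

Every routine is a plain function returning a small result object, and a
command-line "ready reckoner" (`pepikit`) wraps them for shell use. The
output policy is deliberately generous: each command reports every
quantity it can compute (alternative tests, alternative intervals,
flags for boundary handling); ignore what you don't need.

## What's inside

| Area | Routines |
| --- | --- |
| `pepikit.compare2` | OR (Woolf, exact conditional), RR (Katz), RD (Wald, Newcombe), Pearson/G²/Fisher exact (mid-P option), Mantel-Haenszel pooled OR/RR with Robins-Breslow-Greenland variance and Woolf Q heterogeneity, Cochran-Armitage trend, ridit analysis, generalized odds ratio, full r x c analysis (adjusted residuals, Cramer's V, Sakoda's C, pairwise columns), Kruskal-Wallis, one-way ANOVA with omega², adjusted eta², Cohen's f, Brown-Forsythe, linear trend |
| `pepikit.pairs` | McNemar (exact/chi-square/corrected), matched OR with exact binomial CI, Cohen's kappa (weighted, ceiling kappa, PABAK), positive/negative agreement with bootstrap CIs, ICC(1,1) and ICC(A,1), Bland-Altman limits of agreement |
| `pepikit.describe` | direct/indirect standardization (embedded world/European/African standards, interval-width weights), SMR with exact Poisson CI, Chapman capture-recapture with list exhaustiveness, diagnostic-test appraisal (sensitivity, specificity, LR+/LR−, Youden, PPV/NPV curves), stratum-specific LRs, optimal cutpoints, Rogan-Gladen misclassification correction, proportion CIs (Wald/Wilson/Clopper-Pearson/Agresti-Coull) |
| `pepikit.whatis` | P ↔ z/t/chi-square/F conversions, minimum-Bayes-factor calibration of a P value, five multiple-testing adjustments (Bonferroni, Šidák, Holm, Hochberg, Benjamini-Hochberg) |
| `pepikit.design` | sample size / power for two proportions (optional Fleiss correction), McNemar pairs, kappa (dichotomous trait), mean differences |
| `pepikit.fixtures` | seeded synthetic-data generators with truth records, including a classic confounding structure |
| `pepikit.io` | CSV/TSV readers/writers for all input kinds; append-only session results log |

The core statistical identity behind several modules, in the field's
notation: for a stratified series of 2x2 tables the pooled
Mantel-Haenszel odds ratio is

    OR_MH = Σᵢ (aᵢdᵢ/nᵢ) / Σᵢ (bᵢcᵢ/nᵢ)

with heterogeneity judged by Q = Σ wᵢ (ln ORᵢ − ln ÔR)², wᵢ the
inverse variance of ln ORᵢ, Q ~ χ²(k−1) under a common OR. And the
misclassification back-correction (Rogan-Gladen) for a measure with
sensitivity *se* and specificity *sp*:

    true prevalence = (observed − (1 − sp)) / (se + sp − 1).

## A worked example

An evaluation of a screening test counts 45 true positives, 5 false
negatives, 10 false positives and 40 true negatives:

```bash
$ pepikit describe testval --cells 45,5,10,40 --prevalence 0.1,0.5
```

prints (abridged):

```
sensitivity:
  point                    0.9
  intervals:  level 0.95  low 0.786398  high 0.956524
specificity:
  point                    0.8
  intervals:  level 0.95  low 0.669629  high 0.887562
lr_positive:
  point                    4.5
  intervals:  level 0.95  low 2.56528   high 7.89386
youden                   0.7
predictive_values:
  prevalence 0.1:   ppv 0.333333   npv 0.986301
  prevalence 0.5:   ppv 0.818182   npv 0.888889
```

Read: the test detects 90% of the diseased and clears 80% of the
healthy; a positive result multiplies the disease odds by 4.5. But the
*predictive* value of that positive result depends on who is tested — at
10% prevalence only a third of positives are truly diseased, at 50%
prevalence more than four in five are.

The same toolkit quantifies what an imperfect measure does to a
prevalence estimate. If that 90%/90% test observes a prevalence of 12%:

```bash
$ pepikit describe roggladen --observed 0.12 --sens 0.9 --spec 0.9
corrected_prevalence          0.025
corrected_prevalence_percent  2.5
```

— the true prevalence consistent with those numbers is just 2.5%: most of
the observed "cases" are false positives from the 90%-specific measure.

From the library, the equivalent calls:

```python
>>> from pepikit import describe
>>> describe.rogan_gladen_correct(0.12, 0.90, 0.90)
0.025
>>> from pepikit import design
>>> design.sample_size_two_proportions(0.5, 0.6, alpha=0.05, power=0.8).n_per_group
385
```

Every CLI invocation also appends its full results block to a session log
(`pepikit.log`, disable with `--no-log`), `--json` emits the same numbers
machine-readably, and `pepikit find <term>` indexes the procedures by
keyword.

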