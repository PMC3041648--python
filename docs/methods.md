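# Methods

`pepikit` implements the summary-data statistical routines that working
epidemiologists reach for daily: effect measures and tests for 2x2 and
r x c count tables, stratified Mantel-Haenszel analysis, matched-pair and
agreement statistics, standardization and capture-recapture, diagnostic
test appraisal and misclassification correction, P-value utilities, and
sample-size calculation. This note records the statistical conventions the
package commits to, the choices made where several defensible conventions
exist, and what the test suite does and does not demonstrate.

## Input model and validation

All analyses start from *summary* data — cell counts, rating matrices,
stratum event/denominator pairs, short numeric samples — validated once at
construction (`pepikit.tables`). Counts must be nonnegative integers;
continuity-corrected copies carry real cells and a `corrected` flag, and
exact (conditional) procedures refuse them. Orientation of a 2x2 table
(`exposure_outcome` vs `test_disease`) is explicit metadata rather than a
positional convention, so the diagnostic routines can verify they received
a test x disease table (a = TP, b = FN, c = FP, d = TN).

**Continuity correction.** The default policy is Haldane–Anscombe: add 0.5
to all four cells, *only* when some cell is zero, and *only* where a
downstream method needs logarithms (Woolf/Katz intervals, Woolf Q). Exact
tests and point estimates always use the raw cells; an infinite or zero
ratio is reported with an `upper_unbounded` / `lower_unbounded` flag and
the informative one-sided bound, never as a silent NaN. The policy is
exposed (`rule="always" | "only_if_zero_cell"`, or `correction=None`)
because practice varies across textbooks.

## Two-group comparisons (`pepikit.compare2`)

- **Odds ratio**: point ad/bc; Woolf log-normal interval
  exp(ln OR ± z·sqrt(1/a+1/b+1/c+1/d)); exact conditional-likelihood
  interval (noncentral hypergeometric) as a method option.
- **Risk ratio**: Katz interval with SE sqrt(1/a − 1/n1 + 1/c − 1/n2) on
  the log scale. **Risk difference**: Wald, and Newcombe's hybrid-score
  interval built from the two Wilson intervals (default — better behaviour
  near 0 and 1).
- **Chi-square**: Pearson (optional Yates) and likelihood-ratio G², df 1;
  a zero margin short-circuits to statistic 0, P 1, flagged.
- **Fisher's exact test**: the *probability method* — the two-sided P is
  the total conditional probability of tables no more probable than the
  observed one (with a 1e−9 relative tolerance when comparing
  probabilities, guarding float ties). One-sided is the smaller
  hypergeometric tail. Mid-P subtracts half the observed table's
  probability. Several two-sided definitions circulate; the probability
  method was chosen because it is the one most software defaults to, and
  mid-P is offered for those who find plain exact tests conservative.
- **Mantel-Haenszel**: pooled OR Σ(a_i d_i/n_i)/Σ(b_i c_i/n_i) with the
  Robins–Breslow–Greenland variance; pooled RR with the Greenland–Robins
  variance. Heterogeneity is Woolf's Q on per-stratum log estimates with
  inverse-variance weights (0.5 added to all cells of a stratum containing
  a zero, within Q only), df = informative strata − 1. Woolf Q was chosen
  over Breslow–Day for transparency: it is the weighted sum of squared
  log-scale deviations the `Heterogeneity Q` of meta-analysis users
  already know.
- **Cochran–Armitage trend**: z statistic on category scores (default
  1..k); reversing the scores negates z.
- **Ridit analysis**: reference-distribution ridits = cumulative
  proportion below + half within (Bross). The comparison group's mean
  ridit estimates P(comparison > reference) + ½P(tie). SE per Fleiss,
  1/sqrt(12·n_comparison) — this treats the reference distribution as
  fixed (a large-reference assumption), so the interval is approximate for
  small reference groups.
- **Generalized odds ratio**: P(row-1 draw > row-2 draw)/P(row-2 > row-1)
  = concordant/discordant cross-group pairs. The log-scale interval uses
  the product-multinomial delta method; in the 2-category case it
  reduces *exactly* to the Woolf interval (verified in the tests), which
  fixes the orientation convention: "row 1 greater" means row 1 in the
  higher category. With two categories the point estimate is therefore
  bc/ad for cells ((a, b), (c, d)).
- **r x c analysis**: Pearson and G² with df (r−1)(c−1) after dropping
  zero-margin rows/columns (recorded in the result); Haberman adjusted
  residuals (O−E)/sqrt(E(1−row/n)(1−col/n)); Cramer's V; Sakoda's adjusted
  contingency coefficient C/sqrt((q−1)/q); pairwise column chi-squares
  Bonferroni-multiplied by the number of pairs. Ordered columns add
  Cochran–Armitage (2 x k only) and a Kruskal–Wallis test on column
  ranks.
- **One-way ANOVA**: omega² = (SSb−(k−1)MSw)/(SSt+MSw) and the
  Wherry-type adjusted eta² = 1 − MSw/MSt may be negative in near-null
  data; they are reported as computed with a `negative_effect_size` flag
  rather than clamped, because clamping hides the null. Cohen's f uses the
  unadjusted eta². Variance homogeneity is Brown–Forsythe (median-centred
  Levene), which is robust to non-normality. The linear-trend contrast
  regresses group means on scores with group-size weights; its slope is in
  outcome units per score unit.

## Matched pairs and agreement (`pepikit.pairs`)

- **McNemar**: chi-square (f−g)²/(f+g), Edwards-corrected variant, and
  the exact two-sided binomial(f+g, ½) tail doubling capped at 1.
- **Matched OR**: conditional ML point f/g; the exact interval inverts the
  Clopper–Pearson bounds of θ = f/(f+g) through OR = θ/(1−θ), so each
  endpoint solves the binomial tail equation exactly.
- **Kappa**: observed and chance-expected (weighted) agreement from the
  square cross-classification; SE is the Fleiss–Cohen–Everitt large-sample
  SE of the estimate (not the null SE), so the interval is κ ± z·SE.
  Weight convention: agreement weights w_ij = 1 − penalty with linear
  penalty |i−j|/(q−1) or its square (quadratic); for q = 2 both coincide
  with unweighted kappa. The ceiling kappa substitutes the maximum
  attainable agreement given the observed marginals (for unweighted kappa,
  Σ min of marginals; for weighted kappa, a small linear program).
  PABAK = 2·po − 1 is reported for dichotomous tables. Multi-rater
  chance-corrected agreement is deliberately out of scope; a RatingMatrix
  with more than two raters is accepted only by the ICC.
- **Positive/negative agreement**: ppos = 2e/(2e+f+g),
  pneg = 2h/(2h+f+g), with seeded bootstrap percentile intervals
  (default B = 2000, seed 0, both reported in the result). A bootstrap was
  chosen because no closed-form interval for these indices is standard;
  the seed is a parameter so results are reproducible.
- **ICC**: one-way random ICC(1,1) and two-way absolute-agreement
  single-measure ICC(A,1) from the classical mean-square decompositions,
  with F-based (McGraw–Wong) intervals; both are verified against an
  independent implementation in the tests. Negative variance components
  are truncated to zero with a flag.
- **Limits of agreement**: mean ± z·SD of the paired differences, with
  t-based intervals for the mean and for each limit
  (SE = SD·sqrt(1/n + z²/(2(n−1)))).

## Descriptive epidemiology (`pepikit.describe`)

- **Direct standardization**: weighted mean of stratum rates. Stratum
  event counts are treated as Poisson, giving
  Var = Σw_i²e_i/d_i² / (Σw_i)²; the normal interval is truncated at 0.
  A gamma-type interval would behave better for very sparse strata and is
  noted as future work. Embedded standards (Segi world, European 1976,
  African) ship as a data file, each summing to 100,000 across eighteen
  5-year age bands; interval-width weighting parses "lo-hi"/"lo+" labels
  and uses the band width as the weight, dispensing with an external
  standard.
- **Indirect standardization / SMR**: observed over expected with the
  exact Poisson interval via the chi-square relation
  (χ²_{α/2, 2O}/2, χ²_{1−α/2, 2O+2}/2).
- **Capture-recapture**: Chapman's (n1+1)(n2+1)/(m+1) − 1 with Seber's
  variance; the interval is clamped below at the observed union; m = 0
  yields the finite Chapman value with a `sparse_overlap` flag. The
  model assumes two independent sources with homogeneous catchability —
  the usual caveat that dependent lists bias the estimate applies.
- **Diagnostic appraisal**: sensitivity/specificity with Wilson
  intervals; LR+ and LR− with log-method intervals; Youden's J; PPV/NPV
  as *functions* of prevalence via Bayes' theorem, making the
  prevalence-dependence of predictive values explicit.
- **Optimal cutpoint**: "positive if score ≥ cutpoint"; candidates are
  midpoints between adjacent distinct pooled values plus ±∞ sentinels;
  ties break toward the lowest cutpoint.
- **Rogan–Gladen correction**:
  (observed − (1 − specificity))/(sensitivity + specificity − 1), clamped
  to [0, 1] with a warning rather than an error, matching common practice;
  an unidentifiable test (sens + spec = 1) raises. The corrected risk
  ratio divides two corrected risks under a *nondifferential outcome*
  misclassification model and flags boundary clamping.
- **Proportion intervals**: Wald, Wilson, Clopper–Pearson and
  Agresti–Coull, clamped to [0, 1].

## Ready-reckoner utilities (`pepikit.whatis`)

P↔statistic conversions follow field convention: z and t are two-sided by
default, chi-square and F upper-tail only. The Bayesian calibration is the
Sellke–Bayarri–Berger minimum Bayes factor B(p) = −e·p·ln p for p < 1/e
(else 1), with minimum posterior null probability
[1 + ((1−π)/π)/B]⁻¹ at prior π (default 0.5). This −e·p·ln p bound is the
standard "minimum Bayes factor" calibration in the literature; the
alternative 1/(1 − 1/(e·p·ln p)) form is not used. The five adjustment
procedures are Bonferroni, Šidák, Holm, Hochberg and Benjamini–Hochberg —
the canonical single-step, step-down, step-up and FDR representatives.

## Design (`pepikit.design`)

Normal-approximation formulas throughout; exact-power refinements are out
of scope. Sample sizes are rounded up and then verified minimal against
the matching power function (the returned n meets the target, n − 1 does
not). Two-sided power counts both rejection tails, so power at zero effect
equals alpha exactly. Specifics:

- two proportions: (z_{α/2}+z_β)²(p1q1+p2q2)/Δ², optional Fleiss
  continuity correction (n/4)(1+sqrt(1+4/(nΔ)))²;
- McNemar: Connor's formula on the discordant probabilities;
- kappa (two raters, dichotomous trait): under the common-correlation
  model the (concordant+, discordant, concordant−) probabilities are
  determined by κ and the trait prevalence; n solves the goodness-of-fit
  noncentrality n·Σ(p₁ᵢ−p₀ᵢ)²/p₀ᵢ = (z_{α/2}+z_β)² (1 df, Donner–Eliasziw
  style). The simulation test estimates the prevalence from each
  replicate before forming expected cells, as an analyst would;
- mean difference: 2σ²(z_{α/2}+z_β)²/δ².

## Synthetic data (`pepikit.fixtures`)

Every generator is a fully specified probability model, deterministic in
its seed, returning the dataset plus a truth record. Defaults are chosen
to be representative of small observational studies: two-group binomials
at n = 100 and risk 0.3; the confounded stratified model uses two strata
with exposure prevalences (0.8, 0.2) coupled to baseline odds
(0.5, 0.05) and a common within-stratum OR of 4 — strong, classic
confounding in which the crude OR (~11) nearly triples the true effect;
agreement data follow the common-correlation model at κ = 0.6,
prevalence 0.5; paired measurements are a subject effect (SD 1) plus
method error (SD 0.2) and an optional bias; the diagnostic-marker model is
binormal with unit SDs and separation 2, whose Youden-optimal cutpoint is
the midpoint of the two means.

What the generators deliberately do *not* emulate: dependent
capture-recapture sources, differential misclassification, rater drift,
heteroscedastic method error, clustered or matched-beyond-pairs sampling,
and missing data. A passing simulation test therefore shows the estimators
recover the parameters of these idealized models, not that they are robust
to those violations.

## Numerical and testing notes

- Simulation problem sizes: the confounded-fixture check uses 100,000
  subjects per stratum (sampling error ~1.4% on the pooled OR, inside the
  3% assertion band); null-calibration checks use 2,000 replicates; the
  McNemar design check 5,000; limits-of-agreement coverage 10,000 pairs.
  These sizes keep every Monte-Carlo assertion at least ~2.5 SE wide while
  the whole suite runs in well under a minute.
- The exhaustive exact-test check enumerates all 46,375 tables with
  total ≤ 30 against a pure-combinatorial (math.comb) oracle.
- Interval invariants asserted throughout: bounds ordered, clamped to the
  parameter space, shrinking with sample size; adjusted P values dominate
  raw ones and preserve order.
- Degenerate inputs (zero margins, zero discordance, empty strata,
  all-tied samples) return flagged degenerate results where a convention
  exists and raise with a named offender where none does; no routine
  returns an unflagged NaN.

## Known limitations

- Stratified analysis offers no Breslow–Day test and no exact conditional
  MH interval; sparse-strata behaviour relies on the RBG variance.
- The ridit SE ignores reference-distribution sampling error.
- Bootstrap intervals for ppos/pneg are percentile (not BCa).
- Direct-standardization intervals are normal-approximate; very sparse
  strata would warrant a gamma interval.
- Sample-size routines are approximations; for very small n an exact
  power calculation will disagree by a few subjects.
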