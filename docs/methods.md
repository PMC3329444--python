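# Methods

This note documents the models, conventions and design choices behind
`genograde`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Frozen normalization

Classic RMA estimates its quantile target and probe effects from the batch
being normalized, so a sample's value depends on its batchmates. The
frozen variant breaks that dependence: a reference batch is normalized
once, and two sets of parameters are stored — the *quantile profile* (the
mean across reference arrays of the per-array sorted intensities) and
per-probe additive *probe effects* on the log2 scale (row effects of a
Tukey median polish within each probeset, recentred to median zero).

A new array is then processed alone: each probe intensity is replaced by
the profile value at its mid-rank (ties get average ranks, positions
between profile entries are linearly interpolated), log2-transformed,
corrected by the stored probe effect, and each probeset is summarized by
the median of its corrected probes. Consequences, both verified by tests:

* **single-sample contract** — normalizing arrays one at a time equals
  normalizing them together, bit-exactly;
* **rank invariance** — any strictly increasing distortion of an array's
  raw intensities leaves its output unchanged, since only ranks enter.

Full normal+exponential convolution background correction is omitted; the
pipeline preserves the frozen-parameter contract without it, and a
`background` callable hook on `fit_reference`/`apply_frozen` lets a caller
reinstate one. QC metrics (average noise/background, percent present,
scale factor, degradation slope, GAPDH and β-actin 3'/5' ratios) are
consumed, not computed from images. Outlier fences are Q1/Q3 ∓ 1.5 IQR
with linear-interpolation ("type 7") quartiles — quartile conventions
differ across software, so one is fixed for determinism. Exclusion is
deliberately conjunctive except for RNA degradation: noise AND background,
or scale factor AND percent present, or degradation slope alone, or GAPDH
AND actin; the first matching rule is reported as the reason.

## Scoring and the equivocal zone

The raw score is the difference of summed log2 expression over the
grade-3-up and grade-1-up probeset sets. Missing signature probesets are
an error, never dropped: a partial sum silently changes the score's scale.

Calibration is closed-form. With reference class means $m_1 < m_3$ of the
raw score, offset $=(m_1+m_3)/2$ and scale $=2/(m_3-m_1)$ put the
standardized class means exactly at −1 and +1 (exact to floating point;
the acceptance script recomputes this). Re-calibrating already
standardized scores returns scale 1, offset 0. $m_3 \le m_1$ raises a
calibration error (the signature is not oriented for the data).

The equivocal band models the standardized reference classes as Gaussians
with means *fixed* at ∓1 and class SDs estimated as the root mean square
deviation about those fixed means (n−1 denominator). With equal priors,
the upper band edge is the smallest $g \ge 0$ at which the grade-3 :
grade-1 likelihood ratio reaches the odds threshold (default 3); the
lower edge is the mirror-image condition below 0. Edges are found by a
grid scan plus Brent root bracketing (xtol 1e−12); the bracket upper
bound covers the equal-SD closed form $\sigma^2\ln(\text{odds})/2$ with
margin. Properties: equal SDs give a symmetric band; odds 1 collapses the
band to the cut-off; the band widens monotonically in the odds threshold
and in the SDs. With unequal SDs the band is asymmetric, and one side can
legitimately collapse to 0 when that class is already favoured 3:1 at the
cut-off. The equal-priors choice is the neutral reading of "3:1 odds"
absent any stated prevalence; both the priors and an explicitly supplied
band can be configured.

## Clinical categorisation conventions

* Mitotic index (per 10 HPF): MI1 < 10, MI2 10–19, MI3 ≥ 20; dichotomy
  low < 20 vs high ≥ 20. Counts must be nonnegative integers.
* Ki67 high means strictly > 20% (a tumour at exactly 20% is low); the
  cut-off is a parameter.
* Immunophenotype: HER2 positivity takes precedence, so ER+/HER2+ cases
  are HER2-positive and the ER-positive class is implicitly ER+/HER2−;
  triple negative requires ER−, PR−, HER2−.
* Tumour-cell-content filtering is strict (> threshold, default 50%);
  records with missing content fail the filter and are counted.
* Missing optional marker values exclude a record from analyses that need
  them, with a reported tally — never silent imputation.

Concordance between genomic and histological grade is reported per
histological class over non-equivocal calls only (equivocal calls are
refusals to grade, not misgrades): for HG 1 it is
$n(\mathrm{GG1},\mathrm{HG1}) / [n(\mathrm{GG1},\mathrm{HG1}) +
n(\mathrm{GG3},\mathrm{HG1})]$, symmetrically for HG 3. Chi-square tests
are Pearson without continuity correction by default (a flag enables
Yates); Fisher exact p-values are two-sided hypergeometric tail sums.
Composite summaries (e.g. low-MI/low-Ki67 by grade) are built by joining
categorical labels and reusing the generic cross-tabulation, not by
bespoke operations.

## Prognostic evaluation

The fixed-horizon binary design labels a patient positive if a distant
metastasis occurred on or before the horizon (default 120 months),
negative if followed event-free to the horizon, and excluded if censored
earlier — exclusion counts are always reported, since this is what shrinks
the evaluable n below the cohort size. AUC is the Mann–Whitney
probability with ties counted ½ (equal to the trapezoidal ROC area, and
verified against brute-force pair enumeration). Its confidence interval
uses the Hanley–McNeil variance
$SE^2 = [A(1-A) + (n_+{-}1)(Q_1-A^2) + (n_-{-}1)(Q_2-A^2)]/(n_+ n_-)$,
$Q_1 = A/(2-A)$, $Q_2 = 2A^2/(1+A)$. Two AUCs measured on the same
patients are compared with $z = (A_a - A_b)/\sqrt{SE_a^2 + SE_b^2 -
2r\,SE_a SE_b}$. The classical tabulated mapping from rating correlation
to AUC correlation is closely tracked by the mean within-class Spearman
correlation itself, which `within_class_rank_correlation` uses as a
smooth stand-in; `hanley_compare` equally accepts an externally supplied
r. With r = 0 the test reduces to the independent-AUC z-test.

Time-to-event analysis (Kaplan–Meier, log-rank, Cox) is delegated to
lifelines behind this module's interface. Cox fits use Efron tie
handling and Newton–Raphson with tightened stopping rules (undamped
steps, parameter-change tolerance 1e−11) so coefficients agree with an
independent numeric partial-likelihood maximizer to ~1e−9 on toy data;
constant covariates, too few events and complete separation raise
explicit errors. The log-rank statistic equals the squared Cox score test
on two untied groups, which the tests exploit as a cross-check. All
p-values are two-sided; the baseline hazard is never needed and not
estimated.

## Treatment-decision engine

Guidelines are ordered first-match rule lists over (ER, PR, HER2, grade,
tumour size, age, LVI, Ki67) ending in a mandatory catch-all, loadable
from YAML. Substituting the genomic for the histological grade maps GG-1
→ 1, GG-3 → 3 and equivocal → 2 (an equivocal test result changes no
decision). Impact accounting is explicit about containment:
"chemotherapy-containing" means ACT or AHT+ACT, "hormonal-containing"
means AHT or AHT+ACT, and reductions are 1 − (arm-2 count)/(arm-1 count)
with zero denominators reported as undefined rather than 0. The shipped
default ruleset is a documented reconstruction of a 2010-era
hormone-receptor-driven guideline and is marked non-authoritative; any
published-count analysis should use `impact_from_counts` directly.

## Synthetic-data generator

The generator emulates a 163-patient node-negative cohort with ~150-month
follow-up built around a latent grade variable G:

* class structure: histological grade probabilities 0.325/0.43/0.245,
  G ~ N(class mean, class SD) with means −1/0/+1 and SDs 0.7. The SD
  was chosen so that, under the 3:1 band estimated from a realistic
  reference, roughly a fifth of all tumours and a third of grade-2
  tumours fall in the equivocal zone, as observed in practice;
* Ki67 = clip(20 + 14·G + ε, 0, 100) with the noise SD derived in closed
  form from the target correlation 0.72:
  σ = slope·sd(G)·√(1/r² − 1) ≈ 13.9. Clipping at 0 depresses the
  realized correlation by ~0.01–0.02, still inside the ±0.05 acceptance
  window; intercept and slope were set against the cohort's Ki67
  marginals (median ≈ 20%, ≈ 43–48% above 20%);
* mitoses ~ negative binomial, log mean 2.0 + 1.4·G, dispersion 2.0
  (median ≈ 5 per 10 HPF, ≈ 21% at ≥ 20). No dispersion estimate exists
  for the real data, so it is a documented free parameter;
* ER/PR/LVI are Bernoulli with logit linear in G; the intercept is solved
  numerically so the *population* prevalence over the G mixture matches
  the target (ER 0.858, PR 0.687, LVI 0.20), with slopes reproducing the
  observed gradients across grade (ER −1.65, PR −0.7, LVI +0.6 per GGI
  unit). HER2 (prevalence 0.061) is independent of G, mirroring its lack
  of grade association;
* survival: exponential metastasis times with log-hazard
  log(0.0011) + 0.8·G per month, under administrative censoring uniform
  on [126, 182] months (median 154). The slope 0.8 gives a per-GGI-unit
  hazard ratio of ≈ 2.2 and, through the ≈ 2.2-unit separation of the
  called GG-3 and GG-1 groups, a categorical hazard ratio of ≈ 5; the
  baseline gives ≈ 18% observed events. A Weibull shape would be a
  one-line extension; constant hazard suffices for horizon-based and
  hazard-ratio summaries;
* expression: 32 probesets per signature direction plus 32 null
  probesets, 3 probes each, probeset loading ±0.15 log2 units per GGI
  unit, probe affinities N(0, 0.7), probe noise N(0, 0.35), baselines
  N(7, 1). Each cohort array is passed through a random strictly
  increasing distortion x → c·x^γ (γ ∈ [0.85, 1.2], log-uniform c) so
  that only rank-based normalization can recover the signal. The clean
  reference batch holds 53 grade-1-like and 59 grade-3-like arrays whose
  latent scores spread with SD 0.7 around ∓1 — the same biological spread
  as the cohort's classes, which is what gives the estimated equivocal
  band its realistic width.

All randomness flows through a single `numpy.random.default_rng(seed)`
(PCG64); the same seed reproduces every byte.

**What passing tests do and do not show.** The generator matches the
marginals and dependence structure listed above, but real microarray data
add features it omits: batch effects beyond monotone distortions,
heavy-tailed and spatially correlated probe noise, cross-hybridization,
non-exponential hazards, informative censoring and measurement error in
the clinical covariates. Recovery results (e.g. the ≥ 0.95 correlation
between recovered and latent grade at n = 200, or 90–99% CI coverage of
the generating log-hazard over 200 replicates at n = 500) therefore
validate the *implementation*, not the clinical performance of any
signature.

## Numerical choices and problem sizes

Quartiles and quantile-profile interpolation use numpy's linear (type 7)
convention throughout. Band roots are bracketed on a 4001-point grid then
polished by Brent to 1e−12. Cox convergence is parameter-change < 1e−11
with relative log-likelihood change < 1e−16 as a secondary stop. The
test suite runs the heavier simulations at deliberately modest sizes —
5 000 patients for marginal checks, 2 000 for the call-confusion oracle,
200 replicates of n = 500 for CI coverage — chosen so the full suite
completes in well under a minute of compute while keeping Monte-Carlo
error far below the asserted tolerances.

## Known limitations

* No CEL-file parsing, mismatch probes, or MAS5-style QC computation; QC
  metrics are inputs.
* The 97-gene signature itself is not shipped (it is user-supplied
  configuration); nothing here re-derives it.
* The correlated-AUC comparison relies on the within-class rank
  correlation as the correlation surrogate rather than the original
  printed lookup table.
* The default guideline ruleset is a reconstruction for demonstration,
  not a clinical reference.
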