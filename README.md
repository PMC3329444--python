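# genograde

Genomic-grade scoring and prognostic analysis for early-stage (pT1–2, pN0)
breast carcinoma expression cohorts.

Histological grade is the workhorse prognostic factor in early breast
cancer, but roughly half of node-negative tumours land in the uninformative
intermediate grade (HG 2). The *Genomic Grade Index* (GGI) is a continuous
expression-signature score of tumour proliferation designed to split those
intermediate tumours into grade-1-like and grade-3-like groups. `genograde`
implements the full analysis pipeline around such a signature for
pathologists, biostatisticians and methods developers:

* **frozen normalization** (`genograde.frozen_norm`) — chip-level QC
  flagging (1.5 × IQR fences, conjunctive exclusion rules) and RMA-style
  single-sample normalization against *stored* reference parameters (mean
  quantile profile + median-polish probe effects), applied without
  re-estimation so each array's result depends only on that array and the
  model;
* **grading** (`genograde.grading`) — signature scoring, standardization
  and equivocal-zone classification;
* **marker concordance** (`genograde.association`) — cross-tabulations of
  genomic grade against histological grade, mitotic index and Ki67, with
  chi-square / Fisher exact tests;
* **prognosis** (`genograde.survival`) — fixed-horizon (10-year) ROC/AUC
  with Hanley–McNeil confidence intervals and correlated-AUC comparison,
  Kaplan–Meier curves, log-rank tests, Cox proportional-hazards fits;
* **treatment impact** (`genograde.decision`) — a configurable
  adjuvant-therapy guideline engine and the "replace histological grade by
  genomic grade" substitution analysis;
* **synthetic data** (`genograde.synthetic`) — a generator for patient
  cohorts and probe-level expression with the statistical structure the
  analysis assumes, so every stage is testable without patient data.

## The score

For a sample with probeset-level log2 expression $x$, and a signature with
probeset sets $U_3$ (up in grade 3) and $U_1$ (up in grade 1),

$$\mathrm{GGI} = \mathrm{scale}\Big[\sum_{p \in U_3} x_p - \sum_{p \in U_1} x_p - \mathrm{offset}\Big]$$

Scale and offset are set on a reference series of histological grade 1 and
grade 3 tumours so the reference class means land exactly at −1 and +1
(closed form: offset is the midpoint of the class means, scale
$2/(m_3 - m_1)$). The genomic-grade cut-off is 0; an *equivocal zone*
around it is built from class-conditional Gaussians with means fixed at
∓1: a sample is only called GG-1 or GG-3 where the winning class is
favoured by at least 3 : 1 posterior odds (equal priors), and is reported
equivocal otherwise. With equal class SDs $\sigma$ the band edge is
$\sigma^2 \ln 3 / 2$.

## Worked example

Generate a 163-patient synthetic cohort with probe-level arrays, run the
whole pipeline (frozen normalization → scoring → calibration →
classification), and compare calls with histological grade:

```python
import numpy as np, pandas as pd
import genograde as gg

synth = gg.generate_cohort(gg.GeneratorParams(n=163, seed=17))
bundle = gg.generate_expression(synth)
res = gg.run_scoring_pipeline(bundle)

calib = res.calibration
print(f"scale={calib.scale:.4f} offset={calib.offset:.3f} "
      f"band=[{calib.band_low:.3f}, {calib.band_high:.3f}]")

df = synth.cohort.to_dataframe().set_index("patient_id")
grades = pd.Series({c.sample_id: c.grade.value for c in res.calls})
tab = gg.cross_tab(grades, df["hg"], row_order=("GG1", "EQ", "GG3"))
print(tab.to_frame())
print(gg.reclassification_summary(tab))

labels = gg.horizon_labels(df["follow_up"], df["metastasis"], horizon=120)
roc = gg.auc(res.ggi, labels)
print(f"GGI 10y AUC {roc.auc:.2f} [{roc.ci95[0]:.2f}-{roc.ci95[1]:.2f}]")
```

prints

```
scale=0.1061 offset=13.212 band=[-0.250, 0.276]
      1   2   3
GG1  45  28   0
EQ    3  31   4
GG3   0  26  26
{'GG1': 0.329..., 'EQ': 0.364..., 'GG3': 0.305...}
GGI 10y AUC 0.63 [0.49-0.77]
```

Reading the output: the calibration maps the raw signature score so the
reference grade-1/3 means sit at ∓1 and brackets the cut-off 0 with an
equivocal band of ± ≈ 0.26. Of the 85 histological grade 2 tumours, 33%
are reclassified genomic grade 1, 31% genomic grade 3, and 36% stay
equivocal; pure grade 1/3 tumours are almost perfectly concordant. The
AUC line evaluates the recovered score against the 10-year metastasis
outcome (patients censored before 120 months are excluded from the binary
design). The recovered score tracks the generating latent grade variable
at r ≈ 0.98.

A command-line interface mirrors the library
(`genograde simulate | qc | fit-reference | normalize | calibrate | score |
crosstab | prognosis | decide`); run `genograde --help`.

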