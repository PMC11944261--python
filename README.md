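# vfstack

Stacked weight-based classification of Humphrey 24-2 visual fields as
glaucomatous (GL) or not.

Standard automated perimetry measures light-sensitivity thresholds (dB) at
the 54 locations of the 24-2 pattern; glaucoma produces characteristic focal
loss (arcuate defects, nasal steps, paracentral scotomas) that clinicians
flag with published rule-based field criteria.  No single criterion is
reliable across datasets, so `vfstack` combines five of them — LoGTS, UKGTS,
Kang, HAP2 part 1 and Foster — through a stacked meta-learning pipeline:

1. **Deviation maps.** Sensitivities are converted to total deviation
   (TD = measured − age-expected normal), general height
   (GH = 7th-highest TD), pattern deviation (PD = TD − GH) and per-location
   probability maps (p<5%, 2%, 1%, 0.5%) against a normative reference.
2. **Rule-based criteria.** Each criterion is a parameterized cluster rule
   on the TD or PD probability map (≥ k contiguous flagged locations, one at
   a deeper anchor level, optionally non-edge / single-hemifield, optionally
   AND a glaucoma-hemifield-test or PSD requirement), shipped as editable
   YAML.
3. **Stacked weight extraction.** Two base MLPs (52 TD or PD values + age,
   gender, race, follow-up → the criterion verdicts of that map kind) are
   each reduced per sample to 64 values — penultimate-layer activations ⊙
   the head-averaged output-layer weights — giving, with the 4 clinical
   covariates, a 132-dimensional stacked feature vector.
4. **Meta-learners.** Logistic regression, gradient-boosted trees (XGBoost)
   and an MLP (128/64/1, batch-norm + ReLU, dropout 0.08) map the stacked
   vector to P(GL), evaluated with accuracy/precision/sensitivity/F, ROC/AUC
   and the prediction entropy H(p) = −(p ln p + (1−p) ln(1−p)).

A synthetic cohort generator (age-dependent normals, nerve-fibre-bundle
defect archetypes, severity strata, reliability indices) makes the whole
system testable without patient data.  The package is aimed at vision
scientists who want a reproducible, auditable field-classification pipeline
and a sandbox for studying criterion disagreement and ensemble behaviour.

## Worked example

```python
from vfstack import SimulationConfig, StackedVFModel, simulate_cohort

cohort, truth = simulate_cohort(SimulationConfig(n_patients=160, seed=42))
results = StackedVFModel(cohort).fit(seed=42)
print(results.summary())
```

```
Stacked visual-field classification results
=============================================================
patients: 151  (train 125 / test 26)  exams: 509
seed: 42   meta-feature variant: weighted
-------------------------------------------------------------
classifier      acc%   prec%   sens%      F%    AUC%   H mean
LR             84.62  100.00   75.00   85.71   92.50    0.539
XGB            84.62   83.33   93.75   88.24   93.12    0.159
MLP            80.77  100.00   68.75   81.48   90.00    0.164
LoGTS          92.31  100.00   87.50   93.33   93.75
UKGTS          88.46  100.00   81.25   89.66   90.62
Kang           80.77  100.00   68.75   81.48   84.38
HAP2_p1        80.77   76.19  100.00   86.49   75.00
Foster         92.31   93.75   93.75   93.75   91.88
-------------------------------------------------------------
```

160 simulated patients lose 9 to the reliability (FPR > 33%) and
longitudinal (≥ 2 dates, ≥ 6 months) filters; the rest split 125/26 at the
patient level (82.5% train).  Rows are held-out test metrics: the three
meta-learners (with mean prediction entropy — lower means more confident)
above the five stand-alone criteria.  At this small test size (26 eyes, so
~3.8% per eye) meta-learners and the best criteria overlap; aggregated over
many simulation seeds each meta-learner's AUC matches or beats the best
single criterion (see `tests/test_acceptance.py`).

Permutation importance of the TD-net inputs for the Kang head,

```python
imp = results.base_feature_importance("TD", "Kang", n_repeats=5)
print(imp.head(3).to_string(index=False))
```

```
feature  importance
   td21    0.038462
   td22    0.030769
   td23    0.030769
```

ranks the locations whose shuffling costs the surrogate most accuracy
(here a paracentral-heavy draw; features are named by 24-2 grid index,
sector aggregation via `imp.attrs["sector_scores"]`).

The same pipeline runs from the shell:

```sh
vfstack simulate --seed 1 --out run1 --n-patients 160
vfstack run-all --seed 1 --out run1
vfstack classify run1/cohort.csv --criteria Kang
```

`run-all` writes `cohort.csv`, `verdicts.csv`, `metrics.csv`, `roc.csv`,
`entropy.csv`, `criteria_correlation.csv` and `run_log.json`; two runs with
the same seed produce byte-identical files.

## Layout

- `vfstack.grid` — 24-2 geometry, adjacency, cluster search, sectors
- `vfstack.normative` — TD/PD/probability maps, MD, PSD, synthetic reference
- `vfstack.cohort` — QC filters, severity staging, splits, summaries, CSV IO
- `vfstack.criteria` — the parameterized criterion engine + packaged YAML
- `vfstack.nn` / `vfstack.stacking` — seeded MLP engine, weight extraction,
  meta-learners
- `vfstack.evaluation` — metrics, ROC/AUC, entropy, IQR fences, Wilcoxon,
  permutation importance
- `vfstack.synthdata` — the cohort generator and archetype table
- `vfstack.model` / `vfstack.pipeline` / `vfstack.cli` — Model/Results front
  end, orchestration, CLI

See `docs/methods.md` for the modelling choices and their rationale.
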