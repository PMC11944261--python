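# Methods

This note documents the models, conventions and design decisions behind
`vfstack`, in the order the pipeline uses them.  Nothing here reports an
empirical result beyond what the test suite and `scripts/acceptance.py`
compute.

## The 24-2 grid

The Humphrey 24-2 pattern is represented as 54 locations on a 6°-spaced
lattice offset 3° from both meridians, spanning the central 24° plus two
nasal locations at 27°.  Coordinates are temporal-positive in `x`,
superior-positive in `y`; a left eye is the x-mirror of a right eye.
Because rows are enumerated temporal-to-nasal, location *indices* are
laterality-invariant, so masks, sector tables and hemifield-zone tables
defined on indices apply to either eye unchanged.  The two blind-spot
locations (15°, ±3°) occupy indices 20 and 29 and are excluded from all
deviation analyses, leaving the 52 analysed locations.

**Contiguity.** "Contiguous points" in cluster criteria is read as
8-connectivity (diagonal lattice neighbours count), the common
interpretation for HFA cluster rules; 4-connectivity is available via
`build_grid(connectivity=4)`.

**Edge locations.** The default edge set is the pattern rim (any location
missing a 4-neighbour on the lattice) plus the two locations vertically
flanking the blind spot (indices 12 and 38), which "non-edge point"
conventions typically exclude; 22 of 54 locations are edge.  An explicit
index list can override this.

**Sectors.** A Garway-Heath-style structure–function grouping assigns each
location to ST/SN/IT/IN/T/N/central by field position: the |y| = 3 rows
split into central (|x| ≤ 9), temporal (x = 21), nasal (x ≤ −21) and the
arcuate bundles (x = −15), and all |y| ≥ 9 locations split by quadrant.
Superior locations never map to inferior sectors.  Deviation feature names
(`td11`, `pd34`, …) are mapped to raw 54-frame grid indices; under this
mapping `td11` is ST and `td34` is IN.  Names beyond the 54-point frame
cannot be placed and are rejected — reports that number features past 54
use a frame this package does not reconstruct.

## Normative machinery

Real HFA normative data are proprietary, so the package ships a
*synthetic* reference with the same computational structure and a loader
for user-supplied tables:

- expected sensitivity: `34 − 0.10·ecc` dB at the reference age (45 y),
  the linear hill-of-vision decay with eccentricity;
- age decay: −0.065 dB/year at every location (typical published
  estimates are −0.05 to −0.08);
- between-subject variability: `sd = 2.2 + 0.06·ecc` dB, growing with
  eccentricity, which yields 5% TD cutoffs of roughly −3.6 to −6 dB —
  the familiar range of printed deviation-plot cutoffs;
- cutoffs: Gaussian quantiles `z(α)·sd` for α ∈ {5, 2, 1, 0.5}%; PD
  cutoffs are 0.9 of the TD cutoffs because general-height subtraction
  removes the shared diffuse component;
- PSD 95th percentile: fixed-seed Monte Carlo over 4 000 normal fields.

The variability is deliberately larger than the generator's default
measurement noise (2 dB): the reference models between-subject plus
test-retest spread, so a noisy-but-normal eye should flag ~2% of
locations at p<5%, not 25%.

General height uses rank 7 of 52 (≈ 85th percentile), the standard
convention, configurable.  MD is the unweighted TD mean and PSD the
unweighted TD standard deviation; the instrument's proprietary variance
weights are not published and are not imitated.  Probability categories
are integers 0 (normal) to 4 (p<0.5%), assigned as the most extreme
cutoff strictly above the deviation.

## Cohort rules

- Reliability: exams with false-positive rate *exceeding* 0.33 are
  excluded (boundary retained, literal reading of "exceeding").
- Longitudinal inclusion: ≥ 2 exams on distinct dates and a first-to-last
  span ≥ 0.5 years, boundary inclusive; failing patients lose all exams.
- Severity: mild MD > −4.20; moderate −8.17 < MD ≤ −4.20; severe
  MD ≤ −8.17 (dB); the three bands partition the line.
- Splits are patient-level (no patient contributes to both partitions)
  with |train| = round(n·fraction), deterministic given the seed; 160
  patients at 0.825 give (132, 28).

## The criterion engine

All five criteria are instances of one engine: flag locations at or
beyond `cluster_level` on the chosen map, find maximal connected
components (optionally non-edge-only, optionally severed at the
horizontal meridian), and pass when some component has
≥ `cluster_min_size` members including one at `anchor_level`, AND-ed with
optional GHT-outside and PSD-abnormal requirements.  An eye is
glaucomatous when ≥ `confirmation_tests` exams on distinct dates qualify
(default 1, i.e. per-eye single-test criteria; the confirmation count is
the config's to change).

The packaged parameter sets are best-effort transcriptions of the
published criteria into this engine's vocabulary, shipped as editable
YAML rather than hard-coded so the transcription is auditable:

| name | map | cluster | anchor | non-edge | same hemifield | extra |
|---|---|---|---|---|---|---|
| LoGTS | TD | ≥3 @ p<5% | p<5% | no | no | — |
| UKGTS | TD | ≥3 @ p<5% | p<1% | no | yes | — |
| Kang | TD | ≥3 @ p<5% | p<1% | yes | yes | — |
| HAP2_p1 | PD | ≥3 @ p<5% | p<1% | yes | yes | — |
| Foster | PD | ≥3 @ p<5% | p<1% | no | no | GHT outside |

TD criteria therefore respond to diffuse plus focal loss, PD criteria to
focal loss only, and the non-edge rules ignore rim-only defects — the
disagreement structure the stacking stage feeds on.

**GHT.** The glaucoma hemifield test is implemented as a simplified
mirrored-zone comparison: five superior zones (nasal step, paracentral,
temporal arcuate, nasal arcuate, peripheral) and their inferior mirrors,
each scoring the sum of PD probability category codes (0–4) of its
members.  Any pair differing by ≥ 6 → outside normal limits; ≥ 4 →
borderline; else within.  This is an approximation of the proprietary
test — thresholds are package constants chosen so that a 3–4 location
defect at p<0.5% in one hemifield is "outside" while symmetric fields
are "within" — and criteria that require GHT can be reconfigured
cluster-only.

## Base networks and stacked weight extraction

The five verdict columns are learned by two multi-head surrogate
networks, one per map kind (TD net: LoGTS/UKGTS/Kang heads; PD net:
HAP2_p1/Foster), each taking the 52 deviations plus age, gender, race
and follow-up time (56 inputs, continuous columns z-scored with
train-split statistics, integer encodings persisted, missing cells
median-imputed).  Architecture 56→128→64→heads with sigmoid hidden
activation, Adam at 1e-3, ≤ 25 epochs, early stopping with patience 3 on
a 10% validation split, equal-weight binary cross-entropy per head.  The
hidden architecture mirrors the meta MLP (the only architecture printed
for this family), and the hyperparameter grid search (27 configurations:
{softmax, ReLU, sigmoid} × {1e-2, 1e-3, 1e-5} × {SGD, RMSprop, Adam},
5-fold stratified CV, 135 fits) is available as
`stacking.hyperparameter_search`, with ties broken toward
(sigmoid, 1e-3, Adam).

The networks run on a small in-repo NumPy engine (`vfstack.nn`) rather
than an external framework because the stacking construction needs the
penultimate activations and the output-layer weight matrix directly, and
the search grid needs softmax hidden units and RMSprop; the engine's
gradients are finite-difference-checked in the test suite and training
is deterministic given the seed.

**The 132-dimensional stacked vector.**  Per sample and per network, the
64 penultimate activations are multiplied elementwise by the network's
output-layer weight vector averaged across heads; TD-net 64 + PD-net 64
+ 4 raw clinical covariates = 132.  This construction was chosen because
it is per-sample, uses the output layer's weights, and lands exactly on
132 with a penultimate width of 64; it is a reconstruction, and two
variants (`activations`: raw penultimate activations; `weights`: the
weight vector alone, constant across samples) are selectable by config
flag for sensitivity analysis.

## Meta-learners

- **LR** — scikit-learn logistic regression, L2, lbfgs, C = 1.0.
- **XGB** — XGBoost `gbtree`, learning rate 0.3, max depth 6, 25 rounds,
  single-threaded so runs are bit-reproducible.
- **MLP** — 132→128→64→1 on the same NumPy engine: batch-norm + ReLU
  between hidden layers, dropout 0.08, Adam at 0.0031 with weight decay
  1e-3, batch size 32, 25 epochs.

Meta-learners are trained on the train split's clinical GL labels and
evaluated on held-out eyes at decision threshold 0.5 (configurable).

## Evaluation

Accuracy, precision, sensitivity and F are derived from the confusion
matrix with GL positive; undefined ratios (zero denominators) are
reported as undefined, never coerced to 0.  AUC uses the rank/trapezoid
construction with midrank ties (verified against the O(n²) pairwise
oracle in tests).  Prediction entropy is Eq. H(p) = −(p ln p +
(1−p) ln(1−p)) in natural log ("log" without a base is read as ln; the
10% display threshold is a plotting convention, configurable).  IQR
outlier masking uses Tukey fences with factor 1.5 (the method is named
in the source procedure, the fence is not; 1.5 is the standard choice),
and is **off** for headline metrics by default.  Wilcoxon signed-rank
comparisons drop zero differences and report the test as undefined when
all differences vanish.  Permutation importance defaults to 10 repeats
against accuracy (neither stated in the source procedure), with
sector aggregation through the grid's sector map.

## Synthetic cohorts

Each simulated patient draws age N(61.9, 17.4²) clipped to [20, 95],
gender (58% female), a five-level race mix (70.2/11.7/6.0/4.0/8.1%),
lognormal follow-up (median ≈ 2.5 y, clipped to [0.5, 25]), 2–5 visits
at random offsets within the follow-up window on distinct dates, and an
exam-level false-positive rate Beta(1.2, 8) (mean ≈ 0.13, ~7% of exams
beyond the 0.33 cutoff, so the reliability filter has work to do).
Where the emulated cohort's description disagrees with itself (two
different age SDs, follow-up medians and visit counts are printed), the
generator follows the tabulated characteristics.

A glaucomatous eye receives one defect archetype — superior-temporal
arcuate, inferior-nasal arcuate, nasal step, paracentral, or diffuse —
as an explicit index mask from an editable table (bundle-shaped masks,
not a biophysical model: sufficient to exercise cluster criteria and the
ST/IN sector emphasis at desk scale), and a severity stratum (default
50/25/25 mild/moderate/severe).  The target MD is drawn from the
stratum's band (means −1.13/−5.83/−16.34 dB) and decomposed into a focal
depth on the mask (capped at 28 dB) plus a diffuse remainder spread over
all locations; sensitivities are age-expected normal minus the defect
plus N(0, 2²) dB noise, floored at 0 dB.  The floor means deeply severe
eyes realise less loss than planned, so severe-stratum MD sits above the
−16.3 dB plan; tests assert band ordering and proximity for the
unclipped bands.  Ground-truth deviations are stored per exam, and a
fixed focal depth (`defect_depth_db`) can replace severity targeting for
controlled experiments.  Mild linear progression (dB/year on defect
locations) exists but defaults off, matching a cross-sectional framing.
All draws descend from per-patient substreams of one root seed:
cohorts are byte-reproducible and order-independent.

**What the generator does not emulate.**  Fixation losses and
false-negative rates, media opacity other than the diffuse component,
eye-level correlation between fellow eyes, learning effects across
visits, and the instrument's true (non-Gaussian, floor-inflated)
test-retest distributions.  Passing tests therefore demonstrate the
pipeline's correctness and its behaviour under the stated statistical
structure, not clinical performance on real perimetry.

## Validation conditions

Two test-suite conditions deserve explanation:

- *Criterion recovery* uses 18 dB focal defects, 0.5 dB noise and the
  focal-cluster archetype mix (ST/IN arcuate + paracentral).  The
  nasal-step mask (2 of 3 members on the pattern rim) is invisible to
  non-edge criteria and pure diffuse loss is invisible to PD criteria
  *by design*, so a mix containing them bounds those criteria's
  sensitivity away from 1 at any depth; the recovery check is about the
  engine detecting what its rules can express.
- *Stacking gain* compares each meta-learner's held-out AUC with the
  best single criterion's, averaged over 10 simulation seeds of
  400-patient mixed-archetype cohorts; per-seed AUCs on ~70-eye test
  sets have sampling noise of several points, so the property is stated
  about means.

Problem sizes throughout the suite (400–500 patients, 10 seeds) were
chosen as the smallest that make these statistical checks stable.

## Known limitations

- The normative reference, GHT zones/thresholds and criterion parameter
  transcriptions are reconstructions; absolute verdicts on real exams
  will differ from instrument printouts.
- The 132-dimensional stacking construction is one defensible reading of
  "weights extracted from the output layer"; the variants flag exists
  precisely because the construction is not uniquely determined.
- Only the 24-2 pattern is implemented; 10-2/30-2/Octopus geometries and
  OCT integration are out of scope.
- Criteria are implemented as their visual-field components only; the
  original studies' structural/IOP eligibility machinery is not modelled.
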