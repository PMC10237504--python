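# Methods

`metsrisk` implements a noninvasive metabolic-syndrome (MetS) prediction
workflow for middle-aged health-checkup populations: criterion-scaled
feature synthesis, class-imbalance-aware model selection, probability
calibration with an analytically corrected decision threshold, and the
conversion of a depth-limited decision tree into a two-dimensional risk
map. This note records the models, the parameters that matter, and the
design choices made where the design was genuinely open.

## Diagnosis model

MetS is diagnosed by the revised NCEP ATP III rule with Korean Society
for Obesity waist cutoffs: a participant with at least three of

| factor | condition |
|---|---|
| abdominal obesity | waist ≥ 90 cm (M), ≥ 85 cm (F) |
| elevated blood pressure | sbp ≥ 130 mmHg or dbp ≥ 85 mmHg |
| elevated fasting glucose | ≥ 100 mg/dl |
| elevated triglycerides | ≥ 150 mg/dl |
| reduced HDL | ≤ 40 mg/dl (M), ≤ 50 mg/dl (F) |

is labelled positive. All boundaries are inclusive exactly as written
(`≥` for four factors, `≤` for HDL). `DiagnosticCriteria` is a value
object so alternative guidelines can be substituted.

## Criterion-scaled features

A measurement `x` with diagnostic criterion `c` is mapped through the
elliot sigmoid

```
f(z) = 0.5 z / (1 + |z|) + 0.5,    z = (x − c) / denom
```

with `denom = 0.1·c` for waist and `denom = 0.1·45 = 4.5` for both
blood pressures (45 mmHg is the gap between the systolic and diastolic
criteria; using `0.1·c` for each pressure separately would give the two
pressures incompatible sensitivities). The map is strictly increasing,
has range (0, 1), equals 0.5 exactly at the criterion, and sends the
band `x ∈ [c − denom, c + denom]` — ±10% of the criterion — onto
`f ∈ [0.25, 0.75]`, so the feature is most sensitive where clinical
decisions happen. `WC` is the scaled waist (sex-specific criterion),
`BP = max(scaled sbp, scaled dbp)`, and the second-order combinations
are `BPWC_add = BP + WC`, `BPWC_mul = BP·WC`, `BPWC_dif = BP − WC`,
`BPWC_con = max(BP·WC − 0.25, 0)`. `inverse_elliot` is the exact
closed-form inverse, used to annotate risk-map axes with raw cm/mmHg
values.

The ten classical body-shape indices (BMI, BFP, WHR, WHtR, BRI, ABSI,
CUN-BAE, conicity index, AVI, BAI) follow their standard literature
definitions; heights/waists/hips are supplied in cm and converted to
metres where a definition requires it. CUN-BAE codes sex male = 0 /
female = 1 (the original index's convention). Features are carried at
full precision everywhere; two-decimal display values follow the source
convention (rounding, except the BP·WC product which is truncated
toward zero).

## Synthetic cohort generator

The generator emulates a Korean health-examination population aged
40–69 with MetS prevalence 13.6%. It is a two-component mixture: a
record is drawn from the with-MetS or without-MetS group marginals
(independent truncated normals per variable) and kept only if the
diagnosis module assigns it to the intended group (rejection sampling),
which guarantees exact label/criteria consistency without a covariance
matrix. Group means/SDs for age, blood pressure, waist, glucose, HDL
and triglycerides default to the published population summary of the
emulated cohort; sex fractions per group likewise.

Choices where no published value exists:

* **height, weight, hip** — height is drawn sex-specifically
  (M 167.1 ± 5.9 cm, F 155.7 ± 5.4 cm, typical of middle-aged Koreans);
  BMI is drawn per group (23.3 ± 2.8 without, 26.3 ± 3.0 with MetS) and
  weight derived as BMI·height²; hip = waist + offset (13 ± 4 cm
  without, 8 ± 4 cm with MetS), giving waist-hip ratios near 0.86/0.92.
* **lifestyle covariates** — pure noise by default, with plausible
  intake ranges; `signal_strength` can shift a covariate's MetS-group
  mean by (effect × SD) for selection-power experiments.
* **truncation** — each marginal is truncated to a wide physiologic
  range, and the truncated normal is moment-matched so its realised
  mean/SD equal the configured values (naive truncation would bias,
  e.g., the with-MetS age mean upward by ~0.5 y). Diastolic pressure is
  resampled until dbp < sbp.
* **correlation hook** — `latent_correlation` adds a shared latent
  metabolic factor to waist/sbp/dbp/glucose/TG (minus HDL); default 0.

What the generator does **not** emulate: the real cohort's
inter-variable covariance (marginals are independent within group
before rejection), longitudinal structure, informative missingness, or
genuine lifestyle–disease associations. Consequences worth knowing:
rejection conditions the realised cohort, so criteria-adjacent
marginals drift from the configured targets in the accepted sample
(triglycerides in positives by roughly +30 mg/dl), and classification
is *easier* than on real data — the synthetic feature/label link is
exactly the diagnosis rule, so AUCs near 0.95+ here say nothing about
real-world discrimination. Passing tests demonstrate the machinery is
correct, not that the headline performance transfers.

The eligibility filter drops ages ≥ 70, missing required fields, and
values outside configurable physiologic bounds; the emulated study does
not print its outlier thresholds, so the defaults here are declared,
not inferred.

## Split protocol and undersampling

One stratified 9:1 train/test split (stratification is our choice for
variance control; the protocol's reported test prevalence is consistent
with either), then `reps` repeated 9:1 train/validation re-splits of
the pool, unstratified, with seeds derived as master + 1 + repetition
index. The training portion of each repetition — and only it — is
undersampled to a 1:1 class ratio by subsampling negatives without
replacement, with a fresh undersample per repetition (consistent with
the small size variation the protocol reports across repetitions).
Validation and test sets keep the natural prevalence.

## Model families, selection and tuning

Four classifier families sit behind one interface: unpenalised logistic
regression (inputs standardised), CART, random forest, and
gradient-boosted trees (xgboost). CART's published leaf-size constraint
(200 records of a ~15,560-record training set) is carried as a leaf
*fraction* of 1.3% so it transfers to smaller cohorts.

Feature selection runs in three rounds — (1) anthropometric and
survey-based families separately, (2) their union, (3) round-2
survivors plus the criterion-scaled synthetics — each round being:
model-native importance (impurity for trees, exponentiated coefficient
magnitude for logistic) → top-30 filter → recursive feature
elimination retraining at every step → final scoring of the ten
ranked-prefix candidate sets {top-1}…{top-10} by mean validation AUC.
"All 10 possible feature combinations" is read as the ranked prefixes
(the only reading yielding exactly ten candidates); an exhaustive
2^k−1 mode exists for small k. Importance is always ranked on training
rows only; scoring always on held-out validation rows. Ties break
toward smaller sets (parsimony) and lexicographically within rankings.
Grid tuning is exhaustive by mean validation AUC with a first-in-grid
tie break; the full published grids are available (`FULL_GRIDS`), and
the default `DESK_GRIDS` are reduced for desk-scale runs.

## Calibration

A model trained on balanced data overestimates probabilities on a 13.6%
population. Three corrections are implemented:

* **Platt scaling** `P(y=1|f) = 1/(1+exp(Af+B))`, fitted by damped
  Newton on the exact negative log-likelihood (tolerance 1e−8); the
  fit agrees with an independent derivative-free minimiser of the same
  objective to four decimals.
* **Isotonic regression** via pool-adjacent-violators, clamped to the
  end values outside the fitted range.
* **Undersampling correction** `p′ = βp_s/(βp_s − p_s + 1)`, where β is
  the probability that a negative survived the undersample. The map is
  a monotone bijection of [0, 1]; its companion threshold equals the
  positive fraction of the full pre-undersampling training data, and
  algebraically the balanced model's 0.5 point maps exactly onto that
  threshold.

Platt and isotonic maps are fitted on the repetition's validation set
(natural prevalence) — never on undersampled training folds — because
they require an independent calibration set. Goodness is measured by
the Brier score, Spiegelhalter's z (two-sided p from the standard
normal; probabilities at exactly 0/1 are clipped to ±1e−6 to keep the
variance terms positive), and the reliability curve (equal-width bins,
empty bins omitted). The selection rule — lowest Brier among methods
with Spiegelhalter p > 0.05, ties to the larger p, fallback to lowest
Brier with a warning — is our reconstruction from the prose; the source
reports near-identical Brier scores across methods and states no
algorithm.

## Risk map

A CART over features expressible in (WC, BP) — BP+WC, BP·WC, BP−WC, or
the axes themselves — partitions the open unit square: each
root-to-leaf conjunction maps `add`/`dif` constraints to slope ∓1
lines and `mul` constraints to hyperbolas. Regions are represented
symbolically by their constraint lists (a `mul` boundary has no exact
polygon); emptiness and zone membership are checked numerically on a
200×200 grid, and rendering rasterises at configurable resolution.
Each region carries the calibrated leaf probability and
`risk = p / threshold`, interpretable as "times the population
prevalence"; `risk ≥ 1` is the MetS side. Zones: a region wholly under
`BP+WC = 0.66` is *safety*, wholly above `BP·WC = 0.31` is *risk*,
otherwise *warning*; both boundaries are configuration with those
defaults, since they derive from the specific fitted tree. The
PPV-style colouring marks green at risk ≤ 1, red at risk ≥ 4, yellow
between (the band between the reported yellow ceiling 2.5 and red
floor 4 is assigned to yellow — escalation happens at the red band).
Boundary points resolve by the tree's own `≤`-goes-left convention, so
`locate` agrees with the tree's prediction bit for bit; this oracle
equivalence is asserted on 10,000 random interior points.

## Pipeline and problem sizes

`run_pipeline` chains the stages and stamps every artifact with the
config hash, master seed and package version. The desk-scale default —
a 20,000-record synthetic cohort, logistic + CART, 8 repetitions
(3 used for the selection inner loop), reduced grids — completes in
about half a minute on one CPU and emits the labelled cohort, feature
table, split plan, selection traces, tuning tables, calibration
reports, metrics, comparison report and the risk map (JSON + SVG). The
final model of each family is trained on the first repetition's
balanced training set and calibrated on that repetition's validation
set, keeping calibration data independent of fitting data. If the
selected tree uses features outside the (WC, BP) plane, the risk map is
built from the same tuned tree retrained on the canonical
BPWC_add/mul/dif triple, mirroring the final-model structure the method
targets. Test-suite simulations use cohorts of 2,500–20,000 records
and 3–30 repetitions, chosen as the smallest sizes at which the checked
properties are stable.

## Known limitations

* Synthetic cohorts are optimistic (see above); reported AUCs are
  properties of the generator, not of any real population.
* The three-round selection is greedy per round; features informative
  only jointly across families can be lost at round 1.
* Spiegelhalter's z is asymptotic; at very small n or extreme
  probabilities the normal approximation (and hence the selection
  screen) is rough.
* The attention-based tabular network family is out of scope; the
  classifier interface is pluggable so it can be added externally.
* The yellow-zone "adjusted PPV" reported in the source tables (0.582)
  is inconsistent with its own printed counts ((387+552)/1563 = 0.601);
  the implementation uses the formula, validated against the red-zone
  row, and does not reproduce the discrepant figure.
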