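# metsrisk

Noninvasive metabolic-syndrome (MetS) risk modelling for health-checkup
populations: criterion-scaled anthropometric features, repeated-split
undersampled model selection, probability calibration with a corrected
decision threshold, and a calibrated two-dimensional **MetS risk map**
built from a depth-limited decision tree.

## The problem

MetS is diagnosed when at least three of five risk factors are present
(revised NCEP ATP III, Korean waist cutoffs): waist ≥ 90/85 cm (M/F),
sbp ≥ 130 or dbp ≥ 85 mmHg, fasting glucose ≥ 100 mg/dl, triglycerides
≥ 150 mg/dl, HDL ≤ 40/50 mg/dl (M/F). Three of these need a blood
test. A *noninvasive* predictor — using only waist circumference, blood
pressure and sex — lets people screen themselves continuously.

The core trick is to scale each noninvasive measurement by its own
diagnostic criterion through the elliot sigmoid

    f(z) = 0.5·z/(1 + |z|) + 0.5,   z = (x − c)/(0.1·c)

(for blood pressure the denominator uses the 45 mmHg gap between the
systolic and diastolic criteria, giving 0.1·45 = 4.5). The scaled
waist **WC** and blood pressure **BP = max(SBP, DBP)** live in (0, 1),
equal 0.5 exactly at the criterion, and are most sensitive within ±10%
of it. Their combinations — BP+WC, BP·WC, BP−WC — feed a CART whose
split inequalities are lines and hyperbolas in the (WC, BP) plane, so
the whole fitted model becomes a 2-D map: each region carries a
calibrated probability and a *risk* = probability / threshold, where
the threshold (the undersampling-corrected optimal cut) equals the
population prevalence. Risk 2 means "twice the average prevalence";
risk ≥ 1 is the MetS side.

Because models are trained on 1:1 undersampled data, raw probabilities
overestimate; the package implements Platt scaling, isotonic
regression, and the analytic undersampling correction
p′ = βp_s/(βp_s − p_s + 1), assessed by Brier score and Spiegelhalter's
z-test. Real cohorts of this kind are access-restricted, so a
criterion-consistent synthetic generator (truncated-normal group
mixture + diagnosis rejection) stands in for them; see
`docs/methods.md` for what it does and does not emulate.

## Worked example

```python
from metsrisk import scaled_bp, scaled_wc, bpwc_features

bp = float(scaled_bp(140, 90))   # systolic 140, diastolic 90 mmHg
wc = float(scaled_wc(89, "F"))   # female, waist 89 cm
print(f"BP = {bp:.4f}, WC = {wc:.4f}")
print({k: round(v, 4) for k, v in bpwc_features(bp, wc).items()})
```

prints

```
BP = 0.8448, WC = 0.6600
{'BPWC_add': 1.5048, 'BPWC_mul': 0.5576, 'BPWC_dif': 0.1848, 'BPWC_con': 0.3076}
```

Both measurements are above their criteria (BP and WC > 0.5): this
participant's blood pressure sits 84% of the way up the scaled risk
axis and her waist 66%. Locating her on a risk map fitted to a
synthetic cohort:

```python
from metsrisk import PipelineConfig, run_pipeline
from metsrisk.riskmap import locate

bundle = run_pipeline(PipelineConfig(n=20_000, seed=1, outdir="artifacts"))
region = locate(bundle["risk_map"], wc, bp)
print(f"calibrated p = {region.calibrated_probability:.3f}, "
      f"risk = {region.risk:.2f}x prevalence, zone = {region.zone}")
```

```
calibrated p = 0.804, risk = 5.91x prevalence, zone = risk
```

— on this synthetic cohort she falls in a region whose calibrated MetS
probability is 0.80, about six times the population prevalence, inside
the risk zone (the area above the BP·WC = 0.31 hyperbola). The same
pipeline writes the labelled cohort, split plan, selection traces,
tuning tables, calibration reports, a model-comparison table and the
risk map (`riskmap.json` + `riskmap.svg`) into `artifacts/`.

A CLI mirrors the stages:

```sh
metsrisk simulate --n 20000 --seed 1 --out cohort.csv
metsrisk diagnose --in cohort.csv --out labeled.csv
metsrisk run --n 20000 --seed 1 --out artifacts
metsrisk riskmap locate --map artifacts/riskmap.json \
    --sex F --waist 89 --sbp 140 --dbp 90
```

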