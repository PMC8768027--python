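# tofoutlier

Outlier detection for acceleromyographic train-of-four (TOF) neuromuscular
monitoring.

## The problem

Quantitative neuromuscular monitoring during anesthesia evokes four thumb
twitches (T1–T4) by ulnar-nerve stimulation and tracks the TOF ratio
TOFR = T4/T1, whose fade quantifies residual neuromuscular block.
Acceleromyographic (AMG) devices measure these twitches kinetically —
triaxial acceleration plus angular velocity — and their recordings are
notoriously prone to artifacts: rebound bursts after a single hand
movement, oscillations, missing peaks, wide gaps between twitches. Such
recordings still yield a numerically plausible TOFR, so they are easily
mistaken for valid measurements.

`tofoutlier` implements an offline outlier-detection pipeline for this
signal class, aimed at researchers in perioperative monitoring and at
developers of kinetic monitoring software:

- a **synthetic-data generator** that simulates labeled 6-channel TOF
  recordings (normal 4-twitch fade patterns and seven anomaly
  morphologies), calibrated so the extracted feature marginals match the
  descriptive statistics of a real clinical cohort (533 measurements from
  35 patients, 30 anomalies across 18 patients);
- a **feature extractor** that RMS-combines the six kinetic channels into
  one envelope, detects the four twitches, and computes 7 *basic* features
  (T1–T4, TOFR, and the envelope mean and SD — `AMG_Mean`, `AMG_StdDev`)
  plus 8 *engineered* features (inter-twitch elapsed times `deltaT2_T1`,
  `deltaT3_T2`, `deltaT4_T3`, `deltaT4_T1` and twitch-to-mean ratios
  `ratioT1..ratioT4`);
- **cost-sensitive logistic regression (CSLR)**: with ~5.6% outliers, the
  binary classifier minimizes the class-weighted penalized negative
  log-likelihood

  $$J(\beta_0,\beta) = -\sum_i w_{y_i}\left[y_i\log p_i + (1-y_i)\log(1-p_i)\right] + \lambda\lVert\beta\rVert^2,\qquad p_i = \sigma(\beta^\top x_i + \beta_0),$$

  with a larger weight $w_1$ on missed outliers;
- an **evaluation protocol** for imbalanced data: stratified 60/40
  train/test split, repeated stratified 5-fold grid search over
  $(\lambda, w_1)$, precision/recall/F1 and rank-based ROC-AUC with
  stratified bootstrap confidence intervals, learning curves, and a
  Wilcoxon signed-rank comparison of the two feature sets.

## Worked example

```python
from tofoutlier.pipeline import benchmark

report = benchmark(42, wilcoxon_repeats=5)
for tag in ("basic", "engineered"):
    t = report["models"][tag]["test"]
    lo, hi = t["ci_95"]["f1"]
    print(
        f"{tag:>10}: F1={t['f1']:.2f} (95% CI {lo:.2f}-{hi:.2f})  "
        f"AUC={t['roc_auc']:.2f}  precision={t['precision']:.2f}  "
        f"recall={t['recall']:.2f}  confusion={t['confusion']}"
    )
w = report["wilcoxon"]
print(
    f"Wilcoxon: W={w['W']:.1f} p={w['p_value']:.2e} over {w['n_pairs']} paired "
    f"folds (mean F1 {w['mean_f1_engineered']:.2f} vs {w['mean_f1_basic']:.2f})"
)
```

prints:

```
     basic: F1=0.33 (95% CI 0.21-0.45)  AUC=0.85  precision=0.22  recall=0.67  confusion={'TP': 8, 'FP': 29, 'FN': 4, 'TN': 173}
engineered: F1=0.80 (95% CI 0.50-0.96)  AUC=0.91  precision=1.00  recall=0.67  confusion={'TP': 8, 'FP': 0, 'FN': 4, 'TN': 202}
Wilcoxon: W=325.0 p=5.96e-08 over 25 paired folds (mean F1 0.74 vs 0.19)
```

Reading: the cohort of 533 simulated measurements is split into 319
training rows (18 outliers) and 214 held-out test rows (12 outliers). The
CSLR trained on the 8 engineered (timing/ratio) features flags 8 of the 12
held-out anomalies with **zero false alarms**; the CSLR trained on the 7
basic (amplitude) features floods the alarm list with 29 false positives
to reach a comparable recall, collapsing its F1 to 0.33. The Wilcoxon
signed-rank test on 25 paired cross-validation folds confirms that the
engineered features beat the basic ones at P < .001. This is the
characteristic finding the pipeline is built to reproduce: anomaly
information lives in the *timing structure* of the TOF pattern, not in the
twitch amplitudes, which the anomalies share with normal recordings.

A command-line surface wraps the same pipeline:

```bash
tofoutlier pipeline --seed 42 --out run42/       # simulate -> extract -> train -> evaluate
tofoutlier simulate --seed 7 --out recs.jsonl
tofoutlier extract --in recs.jsonl --out features.csv
tofoutlier train --features features.csv --feature-set engineered --out model.json
tofoutlier evaluate --features features.csv --out eval/
```

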