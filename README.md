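# ppgstress

Whole-recording photoplethysmogram (PPG) analysis for detecting exertional
heat stress, with a fully seeded synthetic cohort generator.

## The problem

Heat stress — elevated core temperature after hard work in protective
equipment — shows up in the cardiovascular system as a raised heart rate,
suppressed beat-to-beat variability (parasympathetic withdrawal), and a
subtly changed pulse contour. Classic PPG analysis extracts these cues
beat by beat, which requires reliable beat segmentation. This package
implements the alternative: treat the *whole 20-s recording* as the unit,
differentiate it repeatedly to emphasize contour detail, and summarize
each derivative with two scalar functionals. The question the pipeline
answers is *which derivative order is most informative* for separating
rest from heat-stressed recordings, and whether adding the traditional
HRV index RMSSD improves the detector.

## The method

For a recording $S_0$ sampled at $f_s = 367$ Hz (sampling interval
$T = 1/f_s$), the order-$i$ derivative is the recursive scaled first
difference

$$S_i[n] = \tfrac{1}{T}\,(S_{i-1}[n] - S_{i-1}[n-1]), \qquad i = 1,\dots,20,$$

applied to both the raw signal and its band-passed version (second-order
Butterworth, 0.5–7 Hz). Each derivative signal of length $N$ is reduced to

* normalized energy $E_j = \frac{1}{N}\sum_n S_j[n]^2$, and
* normalized Shannon entropy
  $P_j = -\frac{1}{N}\sum_n S_j[n]^2 \ln S_j[n]^2$ (with $0\ln 0 := 0$),

giving an 84-cell grid per recording (2 features × 2 filtering statuses ×
orders 0–20). Cells are screened across conditions with the two-sided
Wilcoxon–Mann–Whitney test (Holm–Bonferroni corrected family-wise) and
benchmarked with four classifiers — Mahalanobis distance, LDA, QDA and a
linear SVM — under leave-one-out cross-validation. Per classifier the
report gives sensitivity $SE = TP/(TP+FN)$, positive predictivity
$PP = TP/(TP+FP)$ and $F1 = 2\,SE\cdot PP/(SE+PP)$; the overall accuracy
$OA$ of a feature cell is the mean F1 across the four classifiers.
Finally a two-dimensional QDA detector combines the entropy of the
filtered seventh derivative with RMSSD (root mean square of successive
inter-beat-interval differences).

Because the original recordings are not publicly deposited, the package
ships a generator for synthetic rest/heat-stress cohorts (40 subjects by
default; rest HR median 76 bpm, post-exercise medians 132–145.5 bpm;
RMSSD 40 ms at rest vs 15 ms under stress; two-Gaussian pulse template;
baseline wander, 50 Hz powerline and white noise). All analysis code is
agnostic to whether data came from the generator or from CSV files.

## Worked example

```python
from ppgstress import SynthConfig, generate_cohort, HeatStressScan

dataset = generate_cohort(SynthConfig(n_subjects=40, seed=1))
results = HeatStressScan(dataset).fit()
print(results.summary())
```

prints (seed 1):

```
Derivative-order heat-stress scan
==================================================
Cohort: 40 subjects, conditions ['BE', 'E1', 'E2', 'E3']

Cohort-median HRV per condition:
  BE:  HR   74.1 bpm   RMSSD   43.6 ms
  E1:  HR  129.3 bpm   RMSSD   14.2 ms
  E2:  HR  141.0 bpm   RMSSD   14.3 ms
  E3:  HR  135.6 bpm   RMSSD   13.8 ms

Screening: 252 tests in the Holm family (alpha=0.05)
  tests significant after Holm correction: 19

Optimal cell per feature block (mean OA over comparisons):
  energy   filtered   order  2   OA  94.5%
  entropy  filtered   order  2   OA  94.3%
  energy   unfiltered order  0   OA  61.4%
  entropy  unfiltered order  0   OA  53.9%
Global optimum: energy/filtered order 2  (OA 94.5%)

Combined QDA detector (('entropy', 'filtered', 7) + RMSSD):
  BE vs E1:  SE  95.0%  PP  52.1%  F1  67.3%
  BE vs E2:  SE  90.0%  PP  69.2%  F1  78.3%
  BE vs E3:  SE  92.5%  PP  72.5%  F1  81.3%
  mean F1 combined: 75.6%  | entropy alone: 48.7%  | RMSSD alone: 76.3%
```

Reading: the generator hit its cohort targets (rest HR ≈ 76 bpm, stressed
HR ≈ 130–145 bpm, RMSSD suppressed ≈ 40 → 15 ms); on this synthetic
contrast the most informative cell is the filtered order-2 energy, whose
four-classifier mean F1 (OA) is 94.5 %. `results.oa_grid`,
`results.screening.table` and `results.combined` hold the full grids;
`results.save("outdir/")` writes them as CSV.

The same pipeline is scriptable from the shell:

```sh
ppgstress synth --subjects 40 --seed 1 --out cohort/
ppgstress scan --cohort cohort/ --out scanout/
```

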