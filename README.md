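# rankcbr

Rank-weighted case-based-reasoning (CBR) classification of plasma
thermograms.

## The problem

Differential scanning calorimetry of blood plasma yields a *thermogram*:
the excess heat capacity ΔC<sub>p</sub>(T) of the sample on a 45–90 °C
grid, whose one-or-two-peak shape reflects the plasma proteome and shifts
with disease state. Thermograms are a candidate diagnostic biomarker, but
they show large within-class variation and individual profiles often do
not resemble any class "average", which defeats classifiers built on
overall means of similarity. A case-based-reasoning classifier sidesteps
the problem: it stores labelled past cases and assigns a new subject the
label of the most similar stored case(s), so a single well-matched
precedent suffices.

This package is for researchers evaluating such nearest-case classifiers
on thermogram-like curve cohorts: it implements the classifier family, a
feature extractor, the weighting schemes, a seeded synthetic cohort
generator, and a cross-validated evaluation harness.

## The method

Each case is summarised by six features: the binary initial-response flag
IR, the low- and high-temperature peak locations T1 ∈ [45, 55] and
T2 ∈ (55, 90] with heights PEAK1, PEAK2 (read off a Gaussian
kernel-regression smooth of the curve), and IND, the raw ΔC<sub>p</sub>
vector itself. Per feature *f*, a local distance d<sub>f</sub> compares a
stored case with the target: squared Euclidean for the scalars and the
discrete Fréchet distance (dynamic programming over monotone point
couplings in the (T, ΔC<sub>p</sub>) plane) for IND.

Distances enter the decision only through their *dense ranks* over the
case-base, which makes the classifier robust to outlying magnitudes. The
global similarity of stored case *i* to target x₀ is

    S(x_i, x_0) = Σ_f ω_f · (N'_f − rank(d_f)) / (N'_f − 1),

where N′<sub>f</sub> is the number of distinct distance values for
feature *f* and the weights ω<sub>f</sub> ≥ 0 sum to 1. The k most
similar cases vote (classical CBR uses k = 1), and the class-conditional
probability is the vote fraction.

Four weighting schemes are provided, all estimated on training data only:

| scheme    | ω_f ∝ | idea |
|-----------|-------|------|
| `equal`   | 1     | classical CBR baseline (CLCBR) |
| `rank`    | 1 − p_f | Wilcoxon rank-sum evidence that the feature's distances separate the classes (RWCBR) |
| `entropy` | entropy_f | label-free dispersion weighting (ETCBR) |
| `wald`    | (β̂_f/se_f)² | squared Wald statistics of a logistic fit (LWCBR) |

Two baselines complete the benchmark: a k-NN vote on min–max-scaled
summed local distances, and SCUCC, which thresholds a composite
coefficient — the product of a target's mean Pearson correlation with the
control reference curves and its mean point-wise tail probability under
the reference band.

## Worked example

```python
import numpy as np
from rankcbr import CBRClassifier, CohortSpec, generate_cohort

spec = CohortSpec(n_subjects=70, seed=1)          # 35 cancer / 35 control
curves, labels = generate_cohort(spec)
X = np.vstack([c.dcp for c in curves])            # (70, 451) curve matrix
y = np.array(labels)

train = list(range(0, 28)) + list(range(35, 63))  # 28 + 28 training cases
test  = list(range(28, 35)) + list(range(63, 70)) # 7 + 7 held out

clf = CBRClassifier(weighting="rank", k=1).fit(X[train], y[train])
print({f: round(w, 4) for f, w in clf.weights_.items()})
print("accuracy:", (clf.predict(X[test]) == y[test]).mean())
```

prints

```
{'IR': 0.1309, 'T1': 0.1962, 'T2': 0.1967, 'PEAK1': 0.1165, 'PEAK2': 0.1631, 'IND': 0.1967}
accuracy: 1.0
```

The weights say the peak locations and the whole-curve shape carry the
strongest class signal on this cohort (largest ω), the first peak's
height the weakest; the held-out 14 subjects are all classified
correctly. Estimators follow the scikit-learn contract and compose with
`cross_val_score`, `StratifiedKFold`, etc.

The same pipeline is available from the shell:

```bash
rankcbr simulate --seed 1 -o cohort.csv
rankcbr features cohort.csv -o features.csv
rankcbr run --config experiment.yaml -o results/   # weights/folds/summary CSVs
rankcbr verify-tables
```

`scripts/benchmark.py` adds a library-backed RBF-kernel SVM comparator to
the same folds.

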