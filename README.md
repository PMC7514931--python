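# lucck

Instance-based classification with **concave/convex per-feature similarity
kernels**. Each feature difference is scored by a fat-tailed kernel
`(1 + λᵢ·d²)^(−θᵢ)`; a query's proximity to a class is the sum of its kernel
similarities to every training sample of that class, and the class with the
largest sum wins. The kernel widths λᵢ are tied to the feature standard
deviations, and the exponents θᵢ are learned from leave-one-out
within-class vs. overall similarity gaps, so discriminative features
automatically receive more weight. Because the kernels decay polynomially
rather than exponentially, a large error in one feature incurs only a
moderate penalty — the method is robust to heavy-tailed noise and sporadic
single-feature corruption.

The package also provides:

- **Class reweighting** (`lucck.reweighting`) — post-hoc multipliers
  ω ≥ 1 on the class probabilities, learned by linear programming from the
  training set's leave-one-out probability table.
- **Signal features** (`lucck.signal_features`) — generic statistical
  (mean/std/var/power/median), spectral (FFT peak frequency/amplitude,
  spectral power, mean/median amplitude, spectral centroid), and range
  (max/min/range) features for uniformly sampled signal windows.
- **Synthetic data** (`lucck.synthetic`) — labeled tabular generators with
  Gaussian or Student-t noise, irrelevant features, single-feature outlier
  corruption, subject grouping, and class imbalance.
- **Evaluation protocol** (`lucck.evaluation`) — group-respecting k-fold
  cross-validation (no subject straddles a fold), random undersampling of
  the majority class inside each training split to a minimum class ratio,
  accuracy and Mann–Whitney AUROC, an in-repo k-NN comparator, and a
  Λ/Θ grid-search helper.

## CLI

```bash
# generate a synthetic labeled feature table (CSV + JSON config sidecar)
lucck simulate --out data.csv --seed 1 --n-features 6 --n-informative 3 \
    --class-counts 100,100 --separation 2

# fit a model (JSON) from a feature CSV
lucck fit --data data.csv --label-column label --group-column group \
    --out model.json --capital-lambda 1 --capital-theta 1 --reweight

# predict classes + per-class probabilities
lucck predict --model model.json --data data.csv \
    --label-column label --group-column group --out preds.csv

# grouped 10-fold CV with training-split undersampling (ratio >= 0.3)
lucck evaluate --data data.csv --label-column label --group-column group \
    --k 10 --seed 0 --out report.json

# extract signal features from per-window CSVs driven by a JSON recipe
lucck extract-features --recipe recipe.json --out features.csv
```

A feature-extraction recipe names each signal's sampling rate and feature
bundles, and lists one CSV per signal per window:

```json
{
  "signals": {"bvp": {"sampling_rate": 64.0, "bundles": ["basic", "spectral"]}},
  "windows": [{"bvp": "window0.csv"}, {"bvp": "window1.csv"}]
}
```

## Library quick start

```python
import numpy as np
from lucck import fit, SimulationConfig, generate, cross_validate

X, y, groups = generate(SimulationConfig(seed=0))
model = fit(X, y, capital_lambda=1.0, capital_theta=1.0, reweight=True)
model.predict_proba(X[:5])

report = cross_validate(X, y, groups, k=5, seed=0)
print(report.mean_accuracy, report.mean_auroc)
```

Hyperparameters: `capital_lambda` scales the kernel widths
(λᵢ = Λ/sᵢ²) and `capital_theta` is the mean exponent budget
(Σθᵢ = n·Θ). Both default to 1; `lucck.evaluation.grid_search` tunes them
by cross-validation. The standard-deviation convention is population
(`std_ddof=0`) by default and switchable.

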