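# mseeg

Hybrid EEG classification pipeline for multiple-sclerosis (MS)
screening: wavelet subband decomposition and overlapping windowing of
multichannel resting EEG, linear and nonlinear descriptors, feature
selection by a modified ant colony optimization (m-ACO), and an
RBF-kernel SVM whose hyperparameters are tuned by the grasshopper
optimization algorithm (GOA), evaluated under leak-free stratified
cross-validation.

The package is aimed at biomedical-signal researchers who want a
tested, reusable implementation of this pipeline. The clinical
recordings behind the original method are private, so `mseeg` includes
a synthetic EEG generator that plants a controllable two-class
contrast in alpha/beta/gamma band power and signal complexity; every
claim the package makes is validated against analytic limits,
brute-force oracles, planted-signal recovery, and a null control on
that generator. See `docs/methods.md` for the full model description.

## The method in brief

Each channel of a recording is split into the five clinical bands
(delta, theta, alpha, beta, gamma) by a 5-level discrete wavelet
transform; overlapping frames with starts `a_n = a_1 + (n-1)d`
(400 ms, 35 % overlap by default) are cut from each band signal. Per
segment, 17 descriptors are computed: statistical time-domain features
(MAV, RMS, waveform length, zero crossings, higher moments, ...),
sample entropy `SampEn = -ln(A/B)` and spectral entropy
`H = -Σ p_i ln p_i` of the Welch spectrum, and four fractal dimensions
(Katz, Higuchi, Petrosian, Grassberger–Procaccia).

m-ACO selects a feature subset: ants draw subsets of 25–50 % of the
features with probability ∝ τ^a η^b (pheromone × information gain),
scored by the CV error of a base SVM; the best ant reinforces its
features. GOA then tunes `(log10 C, log10 γ)` of the final RBF-SVM by
minimizing

    Fitness = 1 - α·Accuracy + α·(1 - Gmean),    α = 1.25

with a swarm whose comfort coefficient decays linearly
(`c = c_max - l(c_max - c_min)/L`). Five model variants form an
ablation ladder from single-domain features + plain SVM (models 1–2)
to both domains + m-ACO + GOA (model 5).

## Worked example

```python
import numpy as np
from mseeg import (SyntheticSpec, generate_dataset, EvalConfig,
                   extract_dataset_features, run_variant)

spec = SyntheticSpec(effect_size=2.0, seed=7)   # 3 ch, 250 Hz, 15 s
recordings = generate_dataset(spec, 20)          # 40 labeled recordings
config = EvalConfig()                            # K=10, 400 ms/35 %, db8
features = extract_dataset_features(recordings, config)   # 40 x 85

rng = np.random.default_rng(1)
for vid in (1, 3, 5):
    r = run_variant(recordings, vid, config, rng, feature_matrix=features)
    print(f"model-{vid}: acc {r.accuracy:.3f} sens {r.sensitivity:.3f} "
          f"spec {r.specificity:.3f} auc {r.auc:.3f}")
```

Output:

```
model-1: acc 1.000 sens 1.000 spec 1.000 auc 1.000
model-3: acc 1.000 sens 1.000 spec 1.000 auc 1.000
model-5: acc 1.000 sens 1.000 spec 1.000 auc 1.000
```

At `effect_size=2` the planted MS contrast (oscillation amplitude ×3
in alpha/beta/gamma, hence band power ×9) is strong enough that every
rung of the ladder classifies all 40 recordings correctly under
10-fold cross-validation. With `effect_size=0` the classes are
generated identically and the same model-5 run lands at chance
(accuracy ≈ 0.55 on 40 recordings) — the null control showing the
cross-validation leaks nothing.

The same flow is available from the shell:

```bash
mseeg pipeline --seed 7 --out results/demo           # simulate + evaluate all 5 models
mseeg simulate --seed 7 --n-per-class 20 --out data/ # dataset as .txt + manifest.csv
mseeg extract  --manifest data/manifest.csv --out features.csv
mseeg write-config --out config.yaml                 # every default, editable
```

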