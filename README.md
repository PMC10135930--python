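# ecgmpa

Heartbeat classification from single-channel ECG with classical
classifiers whose hyperparameters are tuned by a from-scratch Marine
Predator Algorithm (MPA).

Automatic arrhythmia screening groups heartbeats into the four AAMI
classes — N (normal / bundle-branch), S (supraventricular ectopic),
VEB (ventricular ectopic) and F (fusion).  Classical classifiers (SVM,
gradient-boosted trees, random forest, kNN) remain attractive for this
task on wearable-scale hardware, but their accuracy hinges on
hyperparameters that interact in ways grid search handles poorly.  This
package implements the full pipeline for researchers who want to study
that tuning problem end to end without depending on clinical data
downloads:

1. **`synthetic`** — an annotated ECG generator: sum-of-Gaussians PQRST
   beats with class-specific morphology (wide QRS for VEB, absent P
   wave, premature RR timing for ectopics), baseline wander, powerline
   interference and white noise.  Every downstream stage is testable
   against known ground truth.
2. **`preprocess`** — zero-phase FIR band-pass (0.5–50 Hz, the ECG's
   diagnostic band) and beat segmentation as 75 ms before / 110 ms
   after each annotated R peak (67 samples at 360 Hz, 47 at 250/257 Hz).
3. **`features`** — six descriptor blocks per beat, concatenated into a
   131-dimensional vector at 360 Hz (125 at 250/257 Hz):
   1D local binary pattern histogram (60), subsegment skewness/kurtosis
   (12), 5th central moment (1), Hermite basis coefficients (16),
   level-3 Haar approximation (32 or 26), RR-interval context (10).
4. **`mpa`** — the Marine Predator Algorithm for bounded minimization:
   a prey population moves relative to an elite (best-so-far) solution
   through three phases — Brownian exploration, a mixed Lévy/Brownian
   transition, and Lévy exploitation damped by
   CF = (1 − t/t<sub>max</sub>)^(2t/t<sub>max</sub>) — with elitist
   memory saving and FADs (fish-aggregating-device) long jumps.
5. **`tuning`** — per-classifier search boxes (SVM C ∈ [10⁻⁴, 10³] and
   γ ∈ [10⁻⁴, 1] on log scale; tree depth ∈ [1, 13]; kNN K ∈ [1, 13];
   …), scored by 1 − accuracy on a stratified 80/20 holdout split.
6. **`evaluation`** — per-class one-vs-rest Acc/Sn/Sp/Pr/F1 with
   unweighted macro averages.
7. **`pipeline`** + `ecgmpa` CLI — orchestration with a single
   experiment seed deriving all stage seeds, plus the
   optimized-vs-default improvement table.

Records can also be read from WFDB-style files (text header + 16-bit
signal, annotations as CSV) or a plain CSV dialect, so the synthetic
path and a real-data path share one reader.

## Worked example

`examples/04_tune_classifier.py` generates a 200-beat well-separated
record, extracts the 131-feature matrix and MPA-tunes an SVM and a kNN
against the 80/20 holdout:

```python
from ecgmpa import MPAParams, extract_all, generate_record
from ecgmpa.synthetic import well_separated_config
from ecgmpa.tuning import default_holdout_accuracy, tune

record = generate_record(well_separated_config(n_beats=200, seed=5))
matrix = extract_all(record)              # 200 beats x 131 features + label
X = matrix.drop(columns="label").to_numpy()
y = matrix["label"].to_numpy()

model = tune("svm", X, y, mpa_params=MPAParams(n=8, tmax=10, seed=0), split_seed=0)
```

Running the script prints:

```
svm: tuned holdout accuracy 1.000 (default 1.000)
  best hyperparameters: {'C': 51.40139183153161, 'gamma': 0.00010255432976732008}
  160 fitness evaluations, 137 distinct configurations fitted
knn: tuned holdout accuracy 0.950 (default 0.950)
  best hyperparameters: {'n_neighbors': 1}
  160 fitness evaluations, 12 distinct configurations fitted
```

The tuned accuracy is the fraction of the 40 held-out beats classified
correctly; the optimizer spent 160 holdout evaluations, memoized down
to the distinct decoded configurations actually fitted.  See
`examples/` for one narrative script per capability (generation,
feature extraction, benchmark optimization, tuning, full experiment)
and `ecgmpa --help` for the CLI verbs (`simulate`, `extract`, `tune`,
`evaluate`, `compare`, `run-all`, `mpa-bench`).

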