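"""MPA-tune an SVM and a kNN on synthetic heartbeat features.

The optimizer searches each classifier's hyperparameter box (C and the
RBF gamma on a log10 scale for the SVM; integer K for the kNN) against
the 80/20 stratified holdout error.  The tuned accuracy is compared
with the library-default configuration on the identical split.
"""

from ecgmpa import MPAParams, extract_all, generate_record
from ecgmpa.synthetic import well_separated_config
from ecgmpa.tuning import default_holdout_accuracy, tune

record = generate_record(well_separated_config(n_beats=200, seed=5))
matrix = extract_all(record)
X = matrix.drop(columns="label").to_numpy()
y = matrix["label"].to_numpy()

for clf in ("svm", "knn"):
    model = tune(clf, X, y, mpa_params=MPAParams(n=8, tmax=10, seed=0), split_seed=0)
    default = default_holdout_accuracy(clf, X, y, split_seed=0)
    print(f"{clf}: tuned holdout accuracy {model.holdout_accuracy:.3f} "
          f"(default {default:.3f})")
    print(f"  best hyperparameters: {model.params}")
    print(f"  {model.result.evaluations} fitness evaluations, "
          f"{len(model.evaluation_log)} distinct configurations fitted")
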