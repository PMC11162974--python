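"""Classify seeds into accessions with LDA: cross-validation, holdout
metrics, predictor importance and OSP band selection.

Run:  python examples/04_classify_cohort.py
"""

import warnings

import numpy as np

from seedspectra import classify
from seedspectra.synthetic import make_cohort

warnings.simplefilter("ignore")

# 10 accessions x 20 seeds with a strong accession-specific spectral effect.
table = make_cohort(n_accessions=10, seeds_per_accession=20,
                    class_effect=1.0, seed=0)
print(f"cohort: {len(table.frame)} seeds, {table.n_predictors} predictors")

res = classify.cross_validate(table, k=5, seed=0)
acc = res["summary"]["accuracy"]
print(f"5-fold LDA accuracy: {acc['mean']:.3f} +/- {acc['sd']:.3f} "
      "(chance would be 0.10)")

train, test = classify.split_train_test(table, test_fraction=0.2, seed=0)
model = classify.train_lda(train)
pred = classify.predict_lda(model, test)
cm = classify.ConfusionMatrix.from_predictions(test.class_labels, pred)
print("holdout metrics:", {k: round(v, 3)
                           for k, v in classify.metrics(cm).items()})

top = np.argsort(model.delta_importance)[::-1][:5]
print("five most discriminative predictors:",
      [model.predictor_names[i] for i in top])

# Which reflectance bands carry the class signal?
bands = [p for p in table.predictor_names if p.startswith("refl_")]
sel = classify.select_bands_osp(table.frame[bands].to_numpy(), n_bands=5,
                                pixel_fraction=0.10, seed=0)
print("OSP-selected informative bands:",
      [bands[i] for i in sel.selected_indices])
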