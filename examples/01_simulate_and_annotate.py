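"""Annotate a synthetic single-cell dataset end to end with 5% labels.

Generates 600 cells in 4 types with skewed abundances (45/30/15/10%), 30%
dropout and lognormal noise, then runs the full pipeline: multiple-kernel
similarity -> network enhancement -> pseudo-labels -> contrastive refinement
-> two-layer GCN.  Only 5% of cells are labeled during training; the rest are
split evenly into validation and test.
"""

import numpy as np

from graphannot import RunConfig, SyntheticSpec, generate_dataset, run_pipeline

spec = SyntheticSpec(seed=0)  # m=600, c=4, dropout 0.3, 5% labels
X, truth = generate_dataset(spec)
print(f"dataset: {X.n_cells} cells x {X.n_genes} genes, "
      f"type counts {np.bincount(truth.codes).tolist()}")

cfg = RunConfig(
    simlr_max_iter=30,          # similarity optimization iterations
    ne_alphas=(0.5,),           # enhancement restart weight
    ne_neighborhood_sizes=(20,),
    classifier_epochs=100,
    seed=0,
)
result = run_pipeline(cfg, X=X, labels=truth)

print(f"pseudo-label accuracy (unlabeled cells): {result.metrics['pseudo_label_accuracy']:.3f}")
print(f"test accuracy:  {result.metrics['accuracy']:.3f}")
print(f"test macro F1:  {result.metrics['macro_f1']:.3f}")
print(f"test macro AUC: {result.metrics['macro_auc']:.3f}")
# accuracy/F1/AUC are computed on the 47.5% held-out test cells; values near 1
# mean the 30 labeled cells were enough to annotate the remaining 570.
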