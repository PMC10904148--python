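# graphannot

Semi-supervised cell-type annotation for single-cell RNA-seq when only a
handful of cells (~5%) carry labels.  Low signal-to-noise expression and
dropout make the cell–cell graph that underpins graph neural networks
unreliable; `graphannot` first *denoises* that graph and only then classifies
over it.

The pipeline:

1. **Multiple-kernel similarity.**  A bank of 55 modified Gaussian kernels
   K<sub>l</sub>(x<sub>i</sub>, x<sub>j</sub>) =
   exp(−‖x<sub>i</sub>−x<sub>j</sub>‖² / 2ε<sub>ij</sub>²) / (ε<sub>ij</sub>√2π)
   over neighbor counts k ∈ {10, 12, …, 30} and scales σ ∈ {1.0, …, 2.0} is
   combined by alternating optimization of

   min<sub>S,H,w</sub> −Σ<sub>ij</sub> (Σ<sub>l</sub> w<sub>l</sub>K<sub>l</sub>)<sub>ij</sub> S<sub>ij</sub>
   + β‖S‖²<sub>F</sub> + γ tr(Hᵀ(I−S)H) + ρ Σ<sub>l</sub> w<sub>l</sub> log w<sub>l</sub>

   over row-stochastic S, simplex kernel weights w and an orthonormal spectral
   embedding H (ρ = m²).
2. **Network enhancement.**  S is localized to K-nearest-neighborhoods,
   turned into a symmetric doubly stochastic PSD transition matrix T, and
   diffused: S<sub>t+1</sub> = αT S<sub>t</sub> T + (1−α)T.  The equilibrium
   S̃ = (1−α)T(I−αT²)⁻¹ is computed in closed form by mapping each eigenvalue
   λ of T to (1−α)λ/(1−αλ²); every eigenvalue of S̃ provably lies in [0, 1],
   so S̃ is a numerically safe propagation matrix for graph convolutions.
3. **Pseudo-labels.**  Each unlabeled cell inherits the majority label of its
   k most similar labeled cells under S̃ (default k = 1).
4. **Contrastive refinement.**  A one-layer graph convolution
   X̃ = ReLU(S̃XΦ) is trained briefly (10 epochs, SGD) with the supervised
   contrastive loss over unit-normalized rows, using true + pseudo labels, to
   pull same-type cells together without changing dimensionality.
5. **Classification.**  A two-layer GCN
   Ŷ = softmax(S̃ · ReLU(S̃X̃W₁) · W₂) is trained with cross-entropy on the
   few truly labeled cells only (Adam, validation-selected epoch), while
   propagation is transductive over all cells.

The neural components are implemented directly in numpy with analytic
gradients (finite-difference-verified in the test suite); no deep-learning
framework is required.

## Worked example

```python
from graphannot import RunConfig, SyntheticSpec, generate_dataset, run_pipeline

X, truth = generate_dataset(SyntheticSpec(seed=0))  # 600 cells, 4 types, 30% dropout
cfg = RunConfig(simlr_max_iter=30, classifier_epochs=100,
                ne_alphas=(0.5,), ne_neighborhood_sizes=(20,), seed=0)
result = run_pipeline(cfg, X=X, labels=truth)
print(result.metrics)
```

prints (see `examples/01_simulate_and_annotate.py`):

```
pseudo-label accuracy (unlabeled cells): 0.991
test accuracy:  0.993
test macro F1:  0.990
test macro AUC: 0.999
```

With only 30 labeled cells (5%), 99% of the 285 held-out test cells are typed
correctly, including the rare type that covers just 10% of cells.  The other
scripts in `examples/` walk through the similarity/enhancement stage (the
spectral eigengap at the number of types grows from 0.37 to 0.51 after
denoising), pseudo-labeling plus refinement (the within-type minus
between-type cosine margin rises from 0.28 to 0.82), and the ablation
toggles.

A thin CLI mirrors the library — `graphannot simulate | similarity | enhance |
pseudolabel | refine | classify | pipeline | evaluate`; run
`graphannot --help`.  Expression matrices are cells × genes in TSV/CSV or
Matrix Market (with `.rows`/`.cols` name sidecars); labels are
`cell_id`/`type` tables.

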