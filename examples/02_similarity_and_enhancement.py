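"""Learn a cell-cell similarity and denoise it, watching the spectrum sharpen.

Builds the 55-kernel Gaussian bank, runs the alternating multiple-kernel
optimization, localizes the similarity to 20-nearest-neighborhoods and
computes the diffusion equilibrium.  The eigengap at the number of types
grows after enhancement: cluster structure becomes more pronounced.
"""

import numpy as np

from graphannot import (
    SyntheticSpec,
    build_kernel_bank,
    build_transition_matrix,
    enhance_closed_form,
    enhance_iterative,
    generate_dataset,
    simlr_optimize,
    spectral_report,
)

X, truth = generate_dataset(SyntheticSpec(m=200, n=120, seed=1))
bank = build_kernel_bank(X)  # default grids: 11 neighbor counts x 5 scales
print(f"kernel bank: {bank.n_kernels} kernels on {bank.n_cells} cells")

simlr = simlr_optimize(bank, d=truth.n_types, max_iter=30)
S = simlr.similarity
print(f"similarity: row sums all 1 (max dev {np.abs(S.sum(1) - 1).max():.2e}), "
      f"objective decreased {simlr.objective[0]:.1f} -> {simlr.objective[-1]:.1f}")

T = build_transition_matrix(S, K=20)
denoised = enhance_closed_form(T, alpha=0.5)
report = spectral_report(T.values, denoised, d=truth.n_types)
print(f"eigengap at rank {truth.n_types}: "
      f"{report['eigengap_before']:.4f} -> {report['eigengap_after']:.4f}")
print(f"equilibrium spectrum within [0, 1]: {report['range_ok_after']}")

# the closed form equals the fixed point of the diffusion iteration
iterated = enhance_iterative(T, alpha=0.5)
print(f"closed form vs iteration: max |diff| = "
      f"{np.abs(denoised.values - iterated.values).max():.2e}")
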