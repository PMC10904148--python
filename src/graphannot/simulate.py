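"""Seeded synthetic single-cell expression data with known cell types.

The generator emulates the data regime the annotation pipeline targets:
clustered expression with per-type mean profiles, overdispersed (lognormal
multiplicative) noise, dropout zero-inflation, a skewed type-abundance
distribution and only a small fraction (~5%) of labeled cells.  It does not
attempt platform-faithful simulation (no batch effects, no library-size
variation); it provides tunable separability so every stage of the pipeline is
testable without external downloads.

Model per cell i of type t and gene g:

    x[i, g] = base[g] * exp(separation * delta[t, g])     (type centroid)
              * exp(dispersion * eta[i, g])               (cell-level noise)
    x[i, g] -> 0 with probability dropout_rate            (zero-inflation)

with base[g] lognormal, delta and eta standard normal.  ``separation`` scales
the per-gene log-fold-changes between types; 0 removes all signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ValidationError
from .io import ExpressionMatrix, LabelTable

__all__ = ["SyntheticSpec", "Split", "generate_dataset", "split_dataset"]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    m: int = 600
    n: int = 150
    c: int = 4
    proportions: tuple[float, ...] = (0.45, 0.30, 0.15, 0.10)
    separation: float = 1.0
    dispersion: float = 0.3
    dropout_rate: float = 0.3
    label_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2 or self.n < 1 or self.c < 2:
            raise ParameterError("need m >= 2, n >= 1, c >= 2")
        if len(self.proportions) != self.c:
            raise ParameterError("proportions must have one entry per type")
        if abs(sum(self.proportions) - 1.0) > 1e-8 or min(self.proportions) <= 0:
            raise ParameterError("proportions must be positive and sum to 1")
        if min(self.proportions) * self.m < 2:
            raise ParameterError(
                "every type needs an expected count of at least 2 cells"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ParameterError("dropout_rate must be in [0, 1)")
        if not 0.0 < self.label_fraction < 1.0:
            raise ParameterError("label_fraction must be in (0, 1)")
        if self.separation < 0 or self.dispersion < 0:
            raise ParameterError("separation and dispersion must be non-negative")


@dataclass
class Split:
    """Disjoint, exhaustive train / validation / test cell index sets."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray


def _largest_remainder(quotas: np.ndarray, total: int, minimum: int) -> np.ndarray:
    """Integer allocation summing to ``total``, close to ``quotas``, each >= minimum."""
    counts = np.maximum(np.floor(quotas).astype(int), minimum)
    remainder = total - counts.sum()
    if remainder > 0:
        frac = quotas - np.floor(quotas)
        for idx in np.argsort(-frac, kind="stable"):
            if remainder == 0:
                break
            counts[idx] += 1
            remainder -= 1
        counts[np.argmax(quotas)] += remainder  # any residue to the largest quota
    elif remainder < 0:
        for idx in np.argsort(quotas - counts, kind="stable"):
            while counts[idx] > minimum and remainder < 0:
                counts[idx] -= 1
                remainder += 1
        if remainder < 0:
            raise ParameterError("allocation infeasible under the per-type minimum")
    return counts


def generate_dataset(spec: SyntheticSpec) -> tuple[ExpressionMatrix, LabelTable]:
    """Generate one clustered dataset; the label table carries the FULL truth."""
    rng = np.random.default_rng(spec.seed)
    quotas = np.asarray(spec.proportions) * spec.m
    counts = _largest_remainder(quotas, spec.m, minimum=2)

    base = rng.lognormal(mean=1.0, sigma=0.5, size=spec.n)
    delta = rng.normal(size=(spec.c, spec.n))
    centroids = base[None, :] * np.exp(spec.separation * delta)

    types = np.repeat(np.arange(spec.c), counts)
    noise = np.exp(spec.dispersion * rng.normal(size=(spec.m, spec.n)))
    values = centroids[types] * noise
    if spec.dropout_rate > 0:
        values = np.where(rng.random((spec.m, spec.n)) < spec.dropout_rate, 0.0, values)
    values = np.maximum(values, 0.0)

    width = len(str(spec.m))
    cell_ids = np.asarray([f"cell_{i + 1:0{width}d}" for i in range(spec.m)], dtype=object)
    gene_ids = np.asarray([f"gene_{g + 1:04d}" for g in range(spec.n)], dtype=object)
    type_names = [f"type_{chr(ord('A') + t)}" for t in range(spec.c)]
    return (
        ExpressionMatrix(values, cell_ids, gene_ids),
        LabelTable(cell_ids, type_names, types.copy()),
    )


def split_dataset(truth: LabelTable, label_fraction: float = 0.05, seed: int = 0) -> Split:
    """Stratified train draw of ``label_fraction`` cells; rest split evenly val/test.

    The train set targets round(label_fraction * m) cells overall, allocated
    across types by largest remainder with at least one cell per type, so rare
    types are always represented.  Remaining cells are shuffled and divided
    into validation and test halves (sizes within 1 of each other).
    """
    if not 0.0 < label_fraction < 1.0:
        raise ParameterError("label_fraction must be in (0, 1)")
    codes = truth.codes
    if np.any(codes < 0):
        raise ValidationError("split_dataset requires fully annotated truth")
    m = truth.n_cells
    type_counts = np.bincount(codes, minlength=truth.n_types)
    if type_counts.min() < 2:
        tiny = truth.type_names[int(np.argmin(type_counts))]
        raise ValidationError(
            f"type {tiny!r} has fewer than 2 cells; regenerate with more cells"
        )
    total_train = max(truth.n_types, int(np.floor(label_fraction * m + 0.5)))
    quotas = label_fraction * type_counts.astype(float)
    per_type = _largest_remainder(quotas, total_train, minimum=1)
    if np.any(per_type >= type_counts):
        raise ValidationError("a type would have every cell in train; lower the fraction")

    rng = np.random.default_rng(seed)
    train_parts = [
        rng.choice(np.flatnonzero(codes == t), size=per_type[t], replace=False)
        for t in range(truth.n_types)
    ]
    train = np.sort(np.concatenate(train_parts))
    rest = np.setdiff1d(np.arange(m), train)
    rest = rng.permutation(rest)
    n_val = len(rest) // 2
    return Split(
        train=train,
        validation=np.sort(rest[:n_val]),
        test=np.sort(rest[n_val:]),
    )
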