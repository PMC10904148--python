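"""Preliminary annotation of unlabeled cells by nearest labeled neighbors.

Under the denoised similarity, each unlabeled cell inherits the majority label
of its ``k`` most similar labeled cells (default k = 1: the single nearest
labeled cell).  Labeled cells always keep their true annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enhance import DenoisedSimilarity
from .errors import ParameterError, ValidationError
from .io import LabelTable

__all__ = ["PseudoLabelSet", "knn_pseudo_labels"]


@dataclass
class PseudoLabelSet:
    """Combined true + pseudo annotation covering every cell."""

    codes: np.ndarray  # (m,) type index for every cell
    is_true: np.ndarray  # (m,) True where the label is ground truth
    type_names: list[str]
    k: int

    @property
    def n_cells(self) -> int:
        return len(self.codes)

    def onehot(self) -> np.ndarray:
        out = np.zeros((self.n_cells, len(self.type_names)))
        out[np.arange(self.n_cells), self.codes] = 1.0
        return out

    def provenance(self) -> np.ndarray:
        return np.where(self.is_true, "true", "pseudo").astype(object)


def knn_pseudo_labels(
    S_denoised: DenoisedSimilarity | np.ndarray,
    labels: LabelTable,
    k: int = 1,
) -> PseudoLabelSet:
    """Majority vote over the ``k`` labeled cells most similar to each unlabeled cell.

    Vote ties break toward the class of the single most similar neighbor among
    the tied classes; similarity ties at the k-th rank break by ascending cell
    index.
    """
    S = S_denoised.values if isinstance(S_denoised, DenoisedSimilarity) else S_denoised
    S = np.asarray(S, dtype=float)
    labeled = labels.labeled_indices
    if len(labeled) == 0:
        raise ValidationError("pseudo-labeling requires at least one labeled cell")
    if not 1 <= k <= len(labeled):
        raise ParameterError(
            f"neighbor count k={k} needs 1 <= k <= {len(labeled)} labeled cells"
        )
    if S.shape[0] != labels.n_cells:
        raise ValidationError("similarity matrix and label table sizes differ")

    codes = labels.codes.copy()
    for i in labels.unlabeled_indices:
        sims = S[i, labeled]
        if np.all(sims <= 0):
            raise ValidationError(
                f"cell {labels.cell_ids[i]!r} has zero similarity to every labeled cell"
            )
        order = np.argsort(-sims, kind="stable")[:k]
        votes = labels.codes[labeled[order]]
        counts = np.bincount(votes, minlength=labels.n_types)
        winners = np.flatnonzero(counts == counts.max())
        if len(winners) == 1:
            codes[i] = winners[0]
        else:
            # tie: fall back to the most similar neighbor among tied classes
            codes[i] = next(v for v in votes if v in winners)

    return PseudoLabelSet(
        codes=codes,
        is_true=labels.labeled_mask.copy(),
        type_names=list(labels.type_names),
        k=k,
    )
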