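"""Feature refinement by supervised contrastive learning over a denoised graph.

Raw expression ``X`` is projected through a one-layer graph convolution
``X~ = ReLU(S~ X Phi)`` with a square weight matrix ``Phi`` (dimensionality
unchanged).  ``Phi`` is trained for a few epochs of plain SGD on the
supervised contrastive loss over unit-normalized rows ``z_i = x~_i / ||x~_i||``:

    L = sum_{i in B} -(1/|P_i|) sum_{j in P_i}
            log[ exp(z_i.z_j / tau) / (exp(z_i.z_j / tau)
                 + sum_{k in M_i} exp(z_i.z_k / tau)) ]

where ``P_i`` / ``M_i`` are the same-label / different-label cells of the
mini-batch (true + pseudo labels).  Training is kept short deliberately:
pseudo labels are noisy, and a handful of epochs already pulls same-type
cells together without overfitting label noise.

Gradients are computed analytically in numpy (the model is a single linear
map); they are validated against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enhance import DenoisedSimilarity
from .errors import NumericError, ParameterError, ValidationError
from .io import ExpressionMatrix
from .pseudolabel import PseudoLabelSet

__all__ = [
    "RefinementConfig",
    "RefinedFeatures",
    "denoised_gcn_layer",
    "supcon_loss",
    "refine_features",
]


@dataclass
class RefinementConfig:
    temperature: float = 0.5
    epochs: int = 10
    learning_rate: float = 0.05
    batch_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ParameterError("temperature must be positive")
        if self.epochs < 0:
            raise ParameterError("epochs must be non-negative")
        if self.learning_rate <= 0:
            raise ParameterError("learning rate must be positive")
        if self.batch_size < 2:
            raise ParameterError("batch size must be at least 2")


@dataclass
class RefinedFeatures:
    values: np.ndarray  # (m, n) = ReLU(S~ X Phi), non-negative
    projection: np.ndarray  # (n, n) learned Phi
    normalized: np.ndarray  # (m, n) unit rows (zero rows stay zero)
    loss_history: list[float] = field(default_factory=list)


def _matrix(x) -> np.ndarray:
    if isinstance(x, DenoisedSimilarity):
        return x.values
    if isinstance(x, ExpressionMatrix):
        return x.values
    return np.asarray(x, dtype=float)


def denoised_gcn_layer(S_denoised, X, Phi: np.ndarray) -> np.ndarray:
    """One graph-convolution layer: elementwise max(0, S~ X Phi)."""
    S = _matrix(S_denoised)
    Xv = _matrix(X)
    Phi = np.asarray(Phi, dtype=float)
    if S.shape[1] != Xv.shape[0] or Xv.shape[1] != Phi.shape[0]:
        raise ValidationError(
            f"shape mismatch: S {S.shape}, X {Xv.shape}, Phi {Phi.shape}"
        )
    return np.maximum(S @ Xv @ Phi, 0.0)


def _normalize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    return X / safe[:, None], norms


def _contrastive_terms(
    Z: np.ndarray,
    codes: np.ndarray,
    valid: np.ndarray,
    tau: float,
) -> tuple[float, np.ndarray]:
    """Loss and gradient d(loss)/dZ for one batch of unit-row embeddings.

    Zero rows (``valid`` False) take no role as anchor, positive or negative.
    Anchors with no positive in the batch are skipped.
    """
    b = Z.shape[0]
    A = (Z @ Z.T) / tau
    E = np.exp(A - A.max())  # common shift cancels in every ratio
    same = codes[:, None] == codes[None, :]
    both = valid[:, None] & valid[None, :]
    pos = same & both & ~np.eye(b, dtype=bool)
    neg = ~same & both

    D = (E * neg).sum(axis=1)  # sum over negatives, per anchor
    n_pos = pos.sum(axis=1)
    anchors = valid & (n_pos > 0)

    loss = 0.0
    G = np.zeros((b, b))
    for i in np.flatnonzero(anchors):
        j = np.flatnonzero(pos[i])
        denom = E[i, j] + D[i]
        loss += float(np.sum(np.log(denom) - np.log(E[i, j]))) / n_pos[i]
        G[i, j] += (E[i, j] / denom - 1.0) / n_pos[i]
        kk = np.flatnonzero(neg[i])
        if len(kk):
            G[i, kk] += E[i, kk] * (np.sum(1.0 / denom) / n_pos[i])
    dZ = ((G + G.T) @ Z) / tau
    return loss, dZ


def supcon_loss(
    Z: np.ndarray,
    labels: PseudoLabelSet | np.ndarray,
    batch: np.ndarray | None = None,
    tau: float = 0.5,
) -> float:
    """Supervised contrastive loss of unit-row embeddings ``Z`` on ``batch``.

    ``labels`` may be a :class:`PseudoLabelSet` or a plain integer code array.
    """
    codes = labels.codes if isinstance(labels, PseudoLabelSet) else np.asarray(labels)
    Z = np.asarray(Z, dtype=float)
    if batch is None:
        batch = np.arange(Z.shape[0])
    batch = np.asarray(batch)
    if len(batch) < 2:
        raise ParameterError("contrastive batch needs at least 2 cells")
    if tau <= 0:
        raise ParameterError("temperature must be positive")
    Zb = Z[batch]
    norms = np.linalg.norm(Zb, axis=1)
    valid = norms > 0
    if np.any(np.abs(norms[valid] - 1.0) > 1e-6):
        raise ValidationError("non-zero rows of Z must be unit-normalized")
    loss, _ = _contrastive_terms(Zb, codes[batch], valid, tau)
    return loss


def _batch_loss_and_phi_grad(
    Mb: np.ndarray,
    Phi: np.ndarray,
    codes_b: np.ndarray,
    tau: float,
) -> tuple[float, np.ndarray]:
    """Contrastive loss of one batch and its gradient w.r.t. ``Phi``.

    Forward: A = Mb Phi, X~ = ReLU(A), z = row-normalize(X~); backward chains
    through the normalization ((dZ - z (z.dZ)) / ||x~||) and the ReLU mask.
    """
    Ab = Mb @ Phi
    Xb = np.maximum(Ab, 0.0)
    Zb, norms = _normalize_rows(Xb)
    valid = norms > 0
    loss, dZ = _contrastive_terms(Zb, codes_b, valid, tau)
    inner = np.sum(Zb * dZ, axis=1, keepdims=True)
    dXb = np.where(
        valid[:, None],
        (dZ - Zb * inner) / np.where(valid, norms, 1.0)[:, None],
        0.0,
    )
    dAb = dXb * (Ab > 0)
    return loss, Mb.T @ dAb


def refine_features(
    S_denoised,
    X,
    pseudo: PseudoLabelSet,
    cfg: RefinementConfig | None = None,
) -> RefinedFeatures:
    """Train ``Phi`` by mini-batch SGD on the contrastive loss; return ReLU(S~ X Phi).

    Batches are contiguous chunks of a fresh random permutation of all cells
    each epoch; leftover chunks of size < 2 are skipped.  With ``epochs=0``
    the initial random projection is returned unchanged.
    """
    cfg = cfg or RefinementConfig()
    S = _matrix(S_denoised)
    Xv = _matrix(X)
    m, n = Xv.shape
    if pseudo.n_cells != m:
        raise ValidationError("pseudo-label set must cover every cell")

    rng = np.random.default_rng(cfg.seed)
    bound = 1.0 / np.sqrt(n)
    Phi = rng.uniform(-bound, bound, size=(n, n))
    M = S @ Xv  # fixed propagation term
    codes = pseudo.codes

    loss_history: list[float] = []
    for epoch in range(cfg.epochs):
        perm = rng.permutation(m)
        epoch_loss = 0.0
        for start in range(0, m, cfg.batch_size):
            batch = perm[start : start + cfg.batch_size]
            if len(batch) < 2:
                continue
            loss, grad = _batch_loss_and_phi_grad(
                M[batch], Phi, codes[batch], cfg.temperature
            )
            epoch_loss += loss
            Phi -= cfg.learning_rate * grad
        if not np.isfinite(epoch_loss) or not np.all(np.isfinite(Phi)):
            raise NumericError(f"contrastive training diverged at epoch {epoch}")
        loss_history.append(epoch_loss)

    values = np.maximum(M @ Phi, 0.0)
    normalized, _ = _normalize_rows(values)
    return RefinedFeatures(
        values=values,
        projection=Phi,
        normalized=normalized,
        loss_history=loss_history,
    )
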