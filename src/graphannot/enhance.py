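"""Network Enhancement: random-walk denoising of a cell-cell similarity graph.

From a non-negative similarity matrix ``S`` a doubly stochastic transition
matrix ``T`` is built on K-nearest-neighborhoods,

    P[i, j] = S[i, j] 1{j in N_i} / sum_{o in N_i} S[i, o]
    T[i, j] = sum_o P[i, o] P[j, o] / sum_v P[v, o],

and the similarity is diffused by S_{t+1} = alpha T S_t T + (1 - alpha) T.
The iteration has the closed-form equilibrium S~ = (1-alpha) T (I - alpha T^2)^{-1},
computed here through the eigendecomposition of ``T`` by mapping each
eigenvalue lambda to (1-alpha) lambda / (1 - alpha lambda^2).  Because ``T``
is symmetric, positive semi-definite and doubly stochastic, every eigenvalue
of the equilibrium lies in [0, 1], which makes it a safe propagation matrix
for graph convolutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError, NumericError, ParameterError, ValidationError

__all__ = [
    "TransitionMatrix",
    "DenoisedSimilarity",
    "build_transition_matrix",
    "enhance_closed_form",
    "enhance_iterative",
    "spectral_report",
]


@dataclass
class TransitionMatrix:
    """Symmetric doubly stochastic PSD transition matrix with its local walk."""

    values: np.ndarray  # (m, m) symmetric, rows sum to 1
    neighborhood_size: int
    localized: np.ndarray  # (m, m) row-stochastic P supported on K-neighborhoods


@dataclass
class DenoisedSimilarity:
    """Equilibrium of the enhancement diffusion; doubly stochastic, spectrum in [0, 1]."""

    values: np.ndarray
    alpha: float
    eigvals: np.ndarray | None = None


def build_transition_matrix(S: np.ndarray, K: int) -> TransitionMatrix:
    """Localize ``S`` to K-nearest-neighborhoods and form the NE transition matrix.

    The neighborhood of cell ``i`` is the ``K`` largest entries of row ``i``
    (the cell itself competes like any neighbor; ties break by index).
    """
    S = np.asarray(S, dtype=float)
    m = S.shape[0]
    if S.ndim != 2 or S.shape[1] != m:
        raise ValidationError("similarity matrix must be square")
    if np.any(S < 0):
        raise ValidationError("similarity matrix must be non-negative")
    if not 1 <= K <= m:
        raise ParameterError(f"neighborhood size K={K} needs 1 <= K <= m = {m}")

    order = np.argsort(-S, axis=1, kind="stable")[:, :K]
    P = np.zeros_like(S)
    rows = np.repeat(np.arange(m), K)
    P[rows, order.ravel()] = S[rows, order.ravel()]
    mass = P.sum(axis=1)
    if np.any(mass <= 0):
        cell = int(np.flatnonzero(mass <= 0)[0])
        raise NumericError(
            f"cell {cell} has zero similarity mass on its {K}-neighborhood"
        )
    P /= mass[:, None]

    col = P.sum(axis=0)
    inv_col = np.divide(1.0, col, out=np.zeros_like(col), where=col > 0)
    T = (P * inv_col[None, :]) @ P.T
    T = (T + T.T) / 2.0  # absorb rounding-level asymmetry
    return TransitionMatrix(values=T, neighborhood_size=K, localized=P)


def _eigh(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    try:
        return np.linalg.eigh((matrix + matrix.T) / 2.0)
    except np.linalg.LinAlgError as exc:
        raise NumericError(f"symmetric eigendecomposition failed: {exc}") from exc


def enhance_closed_form(T: TransitionMatrix | np.ndarray, alpha: float) -> DenoisedSimilarity:
    """Equilibrium of the diffusion via the eigenvalue map lambda -> (1-a)l/(1-a l^2).

    Mapped eigenvalues are clipped to [0, 1] so rounding noise cannot push the
    spectrum outside its provable range.  Cost is one symmetric
    eigendecomposition, cubic in the number of cells.
    """
    if not 0.0 <= alpha < 1.0:
        raise ParameterError(f"restart weight alpha must be in [0, 1), got {alpha}")
    values = T.values if isinstance(T, TransitionMatrix) else np.asarray(T, dtype=float)
    lam, U = _eigh(values)
    mapped = np.clip((1.0 - alpha) * lam / (1.0 - alpha * lam**2), 0.0, 1.0)
    denoised = (U * mapped[None, :]) @ U.T
    denoised = (denoised + denoised.T) / 2.0
    return DenoisedSimilarity(values=denoised, alpha=alpha, eigvals=np.sort(mapped)[::-1])


def enhance_iterative(
    T: TransitionMatrix | np.ndarray,
    alpha: float,
    S0: np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> DenoisedSimilarity:
    """Fixed point of S_{t+1} = alpha T S_t T + (1 - alpha) T by direct iteration.

    The limit is independent of ``S0`` (default: ``T``); a learned similarity
    matrix may be supplied to reproduce the diffusion as originally stated.
    Mainly a cross-check oracle for :func:`enhance_closed_form`.
    """
    if not 0.0 <= alpha < 1.0:
        raise ParameterError(f"restart weight alpha must be in [0, 1), got {alpha}")
    Tv = T.values if isinstance(T, TransitionMatrix) else np.asarray(T, dtype=float)
    S = Tv.copy() if S0 is None else np.asarray(S0, dtype=float).copy()
    base = (1.0 - alpha) * Tv
    residual = np.inf
    for _ in range(max_iter):
        nxt = alpha * (Tv @ S @ Tv) + base
        residual = float(np.abs(nxt - S).max())
        S = nxt
        if residual < tol:
            return DenoisedSimilarity(values=(S + S.T) / 2.0, alpha=alpha)
    raise ConvergenceError(
        f"diffusion did not converge in {max_iter} iterations (last residual {residual:.3e})"
    )


def spectral_report(
    S_before: np.ndarray,
    S_after: np.ndarray | DenoisedSimilarity,
    d: int = 2,
) -> dict:
    """Sorted spectra, eigengaps at rank ``d`` and the [0, 1] range check.

    The eigengap is the difference between the d-th and (d+1)-th largest
    eigenvalues; a larger gap after enhancement indicates sharpened cluster
    structure.
    """
    after = S_after.values if isinstance(S_after, DenoisedSimilarity) else S_after
    before = np.asarray(S_before, dtype=float)
    if before.shape != np.asarray(after).shape:
        raise ValidationError("matrices must have identical shape")
    if not 1 <= d < before.shape[0]:
        raise ParameterError(f"eigengap rank d={d} needs 1 <= d < m")
    ev_before = np.sort(_eigh(before)[0])[::-1]
    ev_after = np.sort(_eigh(np.asarray(after, dtype=float))[0])[::-1]
    return {
        "eigenvalues_before": ev_before,
        "eigenvalues_after": ev_after,
        "eigengap_before": float(ev_before[d - 1] - ev_before[d]),
        "eigengap_after": float(ev_after[d - 1] - ev_after[d]),
        "range_ok_after": bool(
            ev_after.min() >= -1e-8 and ev_after.max() <= 1.0 + 1e-8
        ),
    }
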