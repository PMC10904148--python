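"""Multi-scale Gaussian kernel bank and multiple-kernel similarity learning.

Cell-cell similarity is learned in the style of SIMLR: a bank of modified
Gaussian kernels at several neighborhood sizes ``k`` and scale multipliers
``sigma`` is combined with learned weights ``w`` while a row-stochastic
similarity matrix ``S`` and a spectral embedding ``H`` are alternately
optimized.  The objective is

    min_{S,H,w}  - sum_ij (sum_l w_l K_l[i,j]) S[i,j] + beta ||S||_F^2
                 + gamma tr(H^T (I - S) H) + rho sum_l w_l log w_l

subject to S row-stochastic and non-negative, w on the simplex and H with
orthonormal columns, with rho = m^2.  Each block subproblem has a closed-form
or projected solution, so the objective is non-increasing across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist
from scipy.special import xlogy

from .errors import NumericError, ParameterError, ValidationError
from .io import ExpressionMatrix

__all__ = [
    "KernelBank",
    "SimlrResult",
    "DEFAULT_K_VALUES",
    "DEFAULT_SIGMA_VALUES",
    "compute_scale_parameters",
    "compute_kernel",
    "build_kernel_bank",
    "simlr_optimize",
    "project_rows_to_simplex",
]

# default grids: 11 neighbor counts x 5 scale multipliers = 55 kernels
DEFAULT_K_VALUES: tuple[int, ...] = tuple(range(10, 31, 2))
DEFAULT_SIGMA_VALUES: tuple[float, ...] = (1.0, 1.25, 1.5, 1.75, 2.0)

EPSILON_FLOOR = 1e-12


def _as_values(X) -> np.ndarray:
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError("expression matrix contains non-finite entries")
    return values


def _pairwise_distances(values: np.ndarray) -> np.ndarray:
    dist = squareform(pdist(values, metric="euclidean"))
    if not np.all(np.isfinite(dist)):
        raise ValidationError("non-finite pairwise distances")
    return dist


def compute_scale_parameters(
    X, k: int, sigma: float, distances: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Local scales ``mu`` and pairwise bandwidths ``eps`` for one kernel.

    ``mu[i]`` is the mean Euclidean distance from cell ``i`` to its ``k``
    nearest neighbors (self excluded, ties broken by cell index) and
    ``eps[i, j] = sigma * (mu[i] + mu[j]) / 2``, floored at a tiny positive
    value so duplicate cells do not produce a zero bandwidth.
    """
    values = _as_values(X)
    m = values.shape[0]
    if not 1 <= k <= m - 1:
        raise ParameterError(f"neighbor count k={k} needs 1 <= k <= m-1 = {m - 1}")
    if sigma <= 0:
        raise ParameterError(f"scale multiplier sigma must be positive, got {sigma}")
    dist = _pairwise_distances(values) if distances is None else distances
    masked = dist.copy()
    np.fill_diagonal(masked, np.inf)
    # stable argsort => ties at the k-th rank resolved by ascending cell index
    order = np.argsort(masked, axis=1, kind="stable")[:, :k]
    mu = np.take_along_axis(dist, order, axis=1).mean(axis=1)
    eps = sigma * (mu[:, None] + mu[None, :]) / 2.0
    return mu, np.maximum(eps, EPSILON_FLOOR)


def compute_kernel(
    X, k: int, sigma: float, distances: np.ndarray | None = None
) -> np.ndarray:
    """One modified Gaussian kernel: ``exp(-d_ij^2 / (2 eps_ij^2)) / (eps_ij sqrt(2 pi))``."""
    values = _as_values(X)
    dist = _pairwise_distances(values) if distances is None else distances
    _, eps = compute_scale_parameters(values, k, sigma, distances=dist)
    kernel = np.exp(-(dist**2) / (2.0 * eps**2)) / (eps * np.sqrt(2.0 * np.pi))
    if not np.all(np.isfinite(kernel)):
        raise NumericError("kernel evaluation produced non-finite entries")
    return kernel


@dataclass
class KernelBank:
    """A stack of Gaussian kernels with their (k, sigma) grid and local scales."""

    kernels: np.ndarray  # (L, m, m)
    grid: list[tuple[int, float]]
    local_scales: np.ndarray  # (L, m)

    def __post_init__(self) -> None:
        if self.kernels.ndim != 3 or self.kernels.shape[1] != self.kernels.shape[2]:
            raise ValidationError("kernel stack must be (L, m, m)")
        if len(self.grid) != self.kernels.shape[0]:
            raise ValidationError("grid length does not match number of kernels")

    @property
    def n_kernels(self) -> int:
        return self.kernels.shape[0]

    @property
    def n_cells(self) -> int:
        return self.kernels.shape[1]

    def scales(self, l: int) -> np.ndarray:
        """Pairwise bandwidth matrix eps_ij for kernel ``l`` (recomputed from mu)."""
        k, sigma = self.grid[l]
        mu = self.local_scales[l]
        return np.maximum(sigma * (mu[:, None] + mu[None, :]) / 2.0, EPSILON_FLOOR)


def build_kernel_bank(
    X,
    k_values: tuple[int, ...] = DEFAULT_K_VALUES,
    sigma_values: tuple[float, ...] = DEFAULT_SIGMA_VALUES,
) -> KernelBank:
    """Build one kernel per (k, sigma) pair, grid-major (k outer, sigma inner)."""
    values = _as_values(X)
    m = values.shape[0]
    if len(k_values) == 0 or len(sigma_values) == 0:
        raise ParameterError("k_values and sigma_values must be non-empty")
    if max(k_values) > m - 1:
        raise ParameterError(
            f"max neighbor count {max(k_values)} exceeds m-1 = {m - 1}; "
            "shrink k_values for this dataset"
        )
    dist = _pairwise_distances(values)
    L = len(k_values) * len(sigma_values)
    kernels = np.empty((L, m, m))
    local_scales = np.empty((L, m))
    grid: list[tuple[int, float]] = []
    for a, k in enumerate(k_values):
        mu, _ = compute_scale_parameters(values, k, 1.0, distances=dist)
        for b, sigma in enumerate(sigma_values):
            l = a * len(sigma_values) + b
            eps = np.maximum(sigma * (mu[:, None] + mu[None, :]) / 2.0, EPSILON_FLOOR)
            kernels[l] = np.exp(-(dist**2) / (2.0 * eps**2)) / (eps * np.sqrt(2.0 * np.pi))
            local_scales[l] = mu
            grid.append((int(k), float(sigma)))
    if not np.all(np.isfinite(kernels)):
        raise NumericError("kernel bank contains non-finite entries")
    return KernelBank(kernels, grid, local_scales)


@dataclass
class SimlrResult:
    """Output of the alternating similarity optimization."""

    similarity: np.ndarray  # (m, m), row-stochastic
    kernel_weights: np.ndarray  # (L,), simplex
    embedding: np.ndarray  # (m, d), orthonormal columns
    objective: list[float] = field(default_factory=list)
    converged: bool = True
    hyperparams: dict = field(default_factory=dict)


def project_rows_to_simplex(V: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row of ``V`` onto the probability simplex."""
    m, n = V.shape
    U = np.sort(V, axis=1)[:, ::-1]
    css = np.cumsum(U, axis=1) - 1.0
    ind = np.arange(1, n + 1)
    cond = U - css / ind > 0
    rho = cond.sum(axis=1)  # >= 1 always
    theta = css[np.arange(m), rho - 1] / rho
    return np.maximum(V - theta[:, None], 0.0)


def _objective(
    kernels: np.ndarray,
    S: np.ndarray,
    H: np.ndarray,
    w: np.ndarray,
    beta: float,
    gamma: float,
    rho: float,
) -> float:
    Kw = np.tensordot(w, kernels, axes=1)
    G = H @ H.T
    fit = -float((Kw * S).sum())
    frob = beta * float((S**2).sum())
    spectral = gamma * (H.shape[1] - float((S * G).sum()))
    entropy = rho * float(xlogy(w, w).sum())
    return fit + frob + spectral + entropy


def _top_eigenvectors(S: np.ndarray, d: int) -> np.ndarray:
    sym = (S + S.T) / 2.0
    try:
        _, vecs = np.linalg.eigh(sym)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise NumericError(f"eigendecomposition failed: {exc}") from exc
    return vecs[:, ::-1][:, :d]


def simlr_optimize(
    bank: KernelBank,
    d: int,
    beta: float = 0.8,
    gamma: float = 0.8,
    max_iter: int = 50,
    tol: float = 1e-6,
    seed: int | None = None,
) -> SimlrResult:
    """Alternating optimization for the multiple-kernel similarity objective.

    The S-block is a per-row simplex-projected quadratic, the H-block keeps the
    top-``d`` eigenvectors of the symmetrized similarity, and the w-block has
    the entropy-regularized softmax closed form with rho = m^2.  ``beta`` and
    ``gamma`` default to 0.8 (the conventional data-driven estimates are not
    part of this implementation; override them explicitly if needed).  The
    procedure is deterministic: ``seed`` is accepted for interface uniformity.
    """
    del seed  # deterministic initialization; kept for a uniform stage signature
    m = bank.n_cells
    L = bank.n_kernels
    if d < 1:
        raise ParameterError(f"cluster count d must be >= 1, got {d}")
    if d >= m:
        raise ParameterError(f"cluster count d={d} must be smaller than m={m}")
    if beta < 0 or gamma < 0:
        raise ParameterError("beta and gamma must be non-negative")
    rho = float(m) ** 2

    w = np.full(L, 1.0 / L)
    Kw = np.tensordot(w, bank.kernels, axes=1)
    row_sums = Kw.sum(axis=1, keepdims=True)
    S = Kw / np.where(row_sums > 0, row_sums, 1.0)
    H = _top_eigenvectors(S, d)

    objective = [_objective(bank.kernels, S, H, w, beta, gamma, rho)]
    converged = False
    for _ in range(max_iter):
        S_prev = S
        # S-block: min beta ||s||^2 - <Kw_row + gamma G_row, s> over the simplex
        G = H @ H.T
        S = project_rows_to_simplex((Kw + gamma * G) / (2.0 * beta))
        # H-block: top-d eigenvectors of the symmetrized similarity
        H = _top_eigenvectors(S, d)
        # w-block: entropy-regularized closed form (softmax of kernel alignments)
        align = np.tensordot(bank.kernels, S, axes=([1, 2], [0, 1]))
        shifted = align / rho
        shifted -= shifted.max()
        w = np.exp(shifted)
        w /= w.sum()
        Kw = np.tensordot(w, bank.kernels, axes=1)

        objective.append(_objective(bank.kernels, S, H, w, beta, gamma, rho))
        if float(np.abs(S - S_prev).max()) <= tol:
            converged = True
            break

    return SimlrResult(
        similarity=S,
        kernel_weights=w,
        embedding=H,
        objective=objective,
        converged=converged,
        hyperparams={"d": d, "beta": beta, "gamma": gamma, "rho": rho},
    )
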