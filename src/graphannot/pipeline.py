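"""End-to-end annotation pipeline and its configuration.

Stages: variable-gene selection -> kernel bank -> multiple-kernel similarity
-> network enhancement (or a vanilla normalized KNN adjacency when disabled)
-> KNN pseudo-labels -> contrastive feature refinement (optional) -> two-layer
GCN classification.  The (alpha, K) enhancement grid is searched by validation
accuracy; test metrics are reported for the winning combination only.

``run_pipeline`` works either from files (paths in the config) or from
in-memory objects.  When the label table carries the full truth, the
5% / 47.5% / 47.5% stratified split is drawn internally and metrics are
computed; when labels are partial, the labeled cells train the model and
predictions are produced without test metrics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as gio
from .classify import ClassifierConfig, evaluate, train_classifier
from .enhance import DenoisedSimilarity, build_transition_matrix, enhance_closed_form
from .errors import ParameterError, ValidationError
from .io import ExpressionMatrix, LabelTable, select_variable_genes
from .kernels import DEFAULT_K_VALUES, DEFAULT_SIGMA_VALUES, build_kernel_bank, simlr_optimize
from .pseudolabel import knn_pseudo_labels
from .refine import RefinementConfig, refine_features
from .simulate import Split, split_dataset

logger = logging.getLogger("graphannot")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "vanilla_adjacency"]


@dataclass
class RunConfig:
    # paths (optional; in-memory objects may be passed to run_pipeline instead)
    expression_path: str | None = None
    labels_path: str | None = None
    output_dir: str | None = None
    transpose: bool = False
    # preprocessing: number of most-variable genes to keep, or None for all
    top_genes: int | None = None
    # kernel bank / similarity learning
    kernel_k_values: tuple[int, ...] = DEFAULT_K_VALUES
    kernel_sigma_values: tuple[float, ...] = DEFAULT_SIGMA_VALUES
    n_clusters: int | None = None  # d in the similarity objective; default = #types
    simlr_beta: float = 0.8
    simlr_gamma: float = 0.8
    simlr_max_iter: int = 50
    simlr_tol: float = 1e-6
    # network enhancement grid (searched by validation accuracy)
    ne_alphas: tuple[float, ...] = (0.4, 0.5, 0.6)
    ne_neighborhood_sizes: tuple[int, ...] | None = None  # default from cells/type
    # pseudo-labeling
    pseudo_k: int = 1
    # refinement
    refine_temperature: float = 0.5
    refine_epochs: int = 10
    refine_lr: float = 0.05
    refine_batch_size: int = 100
    # classifier
    hidden_dim: int = 100
    classifier_epochs: int = 400
    classifier_lr: float = 0.001
    classifier_batch_size: int = 100
    # split
    label_fraction: float = 0.05
    seed: int = 0
    # ablation toggles
    use_ne: bool = True
    use_scl: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("kernel_k_values", "kernel_sigma_values", "ne_alphas", "ne_neighborhood_sizes"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    probabilities: np.ndarray
    hard_labels: np.ndarray
    metrics: dict
    alpha: float | None
    neighborhood_size: int | None
    pseudo_accuracy: float | None
    similarity: np.ndarray
    denoised: np.ndarray
    split: Split | None
    type_names: list[str] = field(default_factory=list)


def vanilla_adjacency(S: np.ndarray, K: int) -> np.ndarray:
    """Two-sided normalized KNN adjacency D^{-1/2} (A + I) D^{-1/2}.

    The unweighted KNN graph is built from the similarity matrix (an edge when
    either endpoint ranks the other in its top ``K``), self-loops added, then
    symmetrically normalized.  This is the propagation matrix used when
    enhancement is disabled.
    """
    m = S.shape[0]
    if not 1 <= K <= m:
        raise ParameterError(f"K={K} needs 1 <= K <= m = {m}")
    masked = np.asarray(S, dtype=float).copy()
    np.fill_diagonal(masked, -np.inf)
    order = np.argsort(-masked, axis=1, kind="stable")[:, :K]
    A = np.zeros((m, m))
    rows = np.repeat(np.arange(m), K)
    A[rows, order.ravel()] = 1.0
    A = np.maximum(A, A.T)
    np.fill_diagonal(A, 1.0)
    deg = A.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(deg)
    return A * inv_sqrt[:, None] * inv_sqrt[None, :]


def _default_neighborhood_grid(m: int, n_types: int) -> tuple[int, ...]:
    """Neighborhood sizes tied to the mean number of cells per type."""
    per_type = m / max(n_types, 1)
    grid = (18, 20) if per_type <= 120 else (20, 22)
    return tuple(k for k in grid if k <= m) or (min(m, 10),)


def run_pipeline(
    cfg: RunConfig,
    X: ExpressionMatrix | None = None,
    labels: LabelTable | None = None,
    split: Split | None = None,
) -> PipelineResult:
    t0 = time.time()
    if X is None:
        if cfg.expression_path is None:
            raise ValidationError("no expression matrix: pass X or set expression_path")
        X = gio.read_expression(cfg.expression_path, transpose=cfg.transpose)
    if labels is None:
        if cfg.labels_path is None:
            raise ValidationError("no labels: pass labels or set labels_path")
        labels = gio.read_labels(cfg.labels_path, X.cell_ids)
    if labels.n_cells != X.n_cells:
        raise ValidationError("label table and expression matrix disagree on cells")

    outdir = Path(cfg.output_dir) if cfg.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.json").write_text(json.dumps(cfg.to_dict(), indent=2))

    if cfg.top_genes is not None:
        X = select_variable_genes(X, cfg.top_genes)
        logger.info("kept %d most variable genes", cfg.top_genes)

    full_truth = bool(np.all(labels.codes >= 0))
    if split is None and full_truth:
        split = split_dataset(labels, cfg.label_fraction, seed=cfg.seed)
    if split is not None:
        working_labels = labels.subset_labels(split.train)
    else:
        working_labels = labels

    d = cfg.n_clusters or labels.n_types
    logger.info("building kernel bank (%d x %d grid) on %d cells",
                len(cfg.kernel_k_values), len(cfg.kernel_sigma_values), X.n_cells)
    bank = build_kernel_bank(X, cfg.kernel_k_values, cfg.kernel_sigma_values)
    simlr = simlr_optimize(
        bank, d=d, beta=cfg.simlr_beta, gamma=cfg.simlr_gamma,
        max_iter=cfg.simlr_max_iter, tol=cfg.simlr_tol, seed=cfg.seed,
    )
    S = simlr.similarity
    logger.info("similarity learned in %d iterations (converged=%s)",
                len(simlr.objective) - 1, simlr.converged)
    if outdir:
        np.savez_compressed(outdir / "similarity.npz", S=S, w=simlr.kernel_weights)

    K_grid = cfg.ne_neighborhood_sizes or _default_neighborhood_grid(X.n_cells, labels.n_types)
    K_grid = tuple(min(k, X.n_cells) for k in K_grid)
    alpha_grid = cfg.ne_alphas if cfg.use_ne else (None,)

    refinement_cfg = RefinementConfig(
        temperature=cfg.refine_temperature, epochs=cfg.refine_epochs,
        learning_rate=cfg.refine_lr, batch_size=cfg.refine_batch_size, seed=cfg.seed,
    )
    classifier_cfg = ClassifierConfig(
        hidden_dim=cfg.hidden_dim, epochs=cfg.classifier_epochs,
        learning_rate=cfg.classifier_lr, batch_size=cfg.classifier_batch_size,
        seed=cfg.seed,
    )

    best = None
    for K in K_grid:
        for alpha in alpha_grid:
            if cfg.use_ne:
                T = build_transition_matrix(S, K)
                denoised = enhance_closed_form(T, alpha)
                propagation = denoised.values
                pseudo_similarity = denoised
            else:
                propagation = vanilla_adjacency(S, K)
                pseudo_similarity = S  # pseudo-labels fall back to the raw similarity
            pseudo = knn_pseudo_labels(pseudo_similarity, working_labels, k=cfg.pseudo_k)
            if cfg.use_scl:
                refined = refine_features(propagation, X, pseudo, refinement_cfg).values
            else:
                refined = X.values
            if split is not None:
                # full truth available: validation selection and test metrics
                # use the held-out labels; training still sees only split.train
                params, result = train_classifier(
                    propagation, refined, labels, split, classifier_cfg
                )
                score = result.metrics.get("validation_accuracy", 0.0)
            else:
                pseudo_table = LabelTable(
                    labels.cell_ids, list(labels.type_names), pseudo.codes.copy()
                )
                train_idx = working_labels.labeled_indices
                inference_split = Split(
                    train=train_idx,
                    validation=np.array([], dtype=int),
                    test=np.array([], dtype=int),
                )
                params, result = train_classifier(
                    propagation, refined, pseudo_table, inference_split, classifier_cfg
                )
                score = result.metrics.get("validation_accuracy", 0.0)
            logger.info("combo K=%s alpha=%s -> validation accuracy %.4f", K, alpha, score)
            if best is None or score > best[0]:
                best = (score, K, alpha, propagation, pseudo, result)

    assert best is not None
    _, K, alpha, propagation, pseudo, result = best

    pseudo_accuracy = None
    if full_truth:
        unlabeled = np.flatnonzero(~pseudo.is_true)
        if len(unlabeled):
            pseudo_accuracy = float(
                np.mean(pseudo.codes[unlabeled] == labels.codes[unlabeled])
            )

    metrics = dict(result.metrics)
    metrics["elapsed_seconds"] = round(time.time() - t0, 2)
    if pseudo_accuracy is not None:
        metrics["pseudo_label_accuracy"] = pseudo_accuracy

    if outdir:
        np.savez_compressed(outdir / "denoised_similarity.npz", S=propagation,
                            alpha=np.nan if alpha is None else alpha, K=K)
        table = LabelTable(labels.cell_ids, list(labels.type_names), pseudo.codes.copy())
        gio.write_labels(table, outdir / "pseudo_labels.tsv", provenance=pseudo.provenance())
        _write_predictions(outdir / "predictions.tsv", labels, result)
        (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2))

    return PipelineResult(
        probabilities=result.probabilities,
        hard_labels=result.hard_labels,
        metrics=metrics,
        alpha=alpha,
        neighborhood_size=K,
        pseudo_accuracy=pseudo_accuracy,
        similarity=S,
        denoised=propagation,
        split=split,
        type_names=list(labels.type_names),
    )


def _write_predictions(path: Path, labels: LabelTable, result) -> None:
    import pandas as pd

    frame = pd.DataFrame(
        result.probabilities,
        columns=[f"p_{t}" for t in labels.type_names],
    )
    frame.insert(0, "predicted_type", result.hard_labels)
    frame.insert(0, "cell_id", labels.cell_ids)
    frame.to_csv(path, sep="\t", index=False)
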