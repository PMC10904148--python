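"""Two-layer graph-convolutional classifier trained on the few labeled cells.

Prediction is Y^ = softmax(S~ . ReLU(S~ X~ W1) . W2): two propagation hops
over the denoised (doubly stochastic) similarity, a hidden layer of width
``h`` and a row-wise softmax, i.e. the standard two-layer GCN head.  The
logits feed the softmax unrectified: clamping them at zero creates a flat
loss region in which a class whose logit column has gone negative for every
cell can never recover, which silences rare cell types permanently under
class-imbalanced cross-entropy (see the methods note).  Only labeled cells
contribute to the cross-entropy loss, but propagation always runs over the
whole graph (transductive: unlabeled cells shape the messages).  Optimization
is Adam on mini-batches of labeled cells; the parameters of the epoch with
the highest validation accuracy are returned.

The forward/backward pass is written directly in numpy; gradients are checked
against finite differences in the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score, roc_auc_score

from .errors import NumericError, ParameterError, ValidationError
from .io import LabelTable
from .refine import _matrix

__all__ = [
    "ClassifierConfig",
    "ClassifierParams",
    "AnnotationResult",
    "forward",
    "cross_entropy",
    "train_classifier",
    "evaluate",
]

PROB_FLOOR = 1e-12


@dataclass
class ClassifierConfig:
    hidden_dim: int = 100
    epochs: int = 400
    learning_rate: float = 0.001
    batch_size: int = 100
    seed: int = 0
    strict_classes: bool = False

    def __post_init__(self) -> None:
        if self.hidden_dim < 1:
            raise ParameterError("hidden_dim must be >= 1")
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ParameterError("learning rate must be positive")
        if self.batch_size < 1:
            raise ParameterError("batch size must be >= 1")


@dataclass
class ClassifierParams:
    W1: np.ndarray  # (n, h)
    W2: np.ndarray  # (h, c)


@dataclass
class AnnotationResult:
    probabilities: np.ndarray  # (m, c), rows on the simplex
    hard_labels: np.ndarray  # (m,) type names
    metrics: dict = field(default_factory=dict)


def _softmax_rows(R: np.ndarray) -> np.ndarray:
    shifted = R - R.max(axis=1, keepdims=True)
    E = np.exp(shifted)
    return E / E.sum(axis=1, keepdims=True)


def forward(S_denoised, X_refined, params: ClassifierParams) -> np.ndarray:
    """Per-cell class probabilities from the two-hop denoised propagation."""
    probs, _ = _forward_cached(_matrix(S_denoised), _matrix(X_refined), params)
    return probs


def _forward_cached(S: np.ndarray, X: np.ndarray, params: ClassifierParams):
    if S.shape[1] != X.shape[0] or X.shape[1] != params.W1.shape[0] \
            or params.W1.shape[1] != params.W2.shape[0]:
        raise ValidationError(
            f"shape mismatch: S {S.shape}, X {X.shape}, "
            f"W1 {params.W1.shape}, W2 {params.W2.shape}"
        )
    A1 = (S @ X) @ params.W1
    H1 = np.maximum(A1, 0.0)
    SH1 = S @ H1
    U = SH1 @ params.W2
    if not np.all(np.isfinite(U)):
        raise NumericError("non-finite activations in classifier forward pass")
    return _softmax_rows(U), (A1, H1, SH1, U)


def cross_entropy(
    probabilities: np.ndarray,
    labels: LabelTable | np.ndarray,
    batch: np.ndarray,
) -> float:
    """Summed negative log-probability of the true class over ``batch`` cells."""
    codes = labels.codes if isinstance(labels, LabelTable) else np.asarray(labels)
    batch = np.asarray(batch)
    if np.any(codes[batch] < 0):
        raise ValidationError("cross-entropy batch contains unlabeled cells")
    p_true = probabilities[batch, codes[batch]]
    return float(-np.log(np.maximum(p_true, PROB_FLOOR)).sum())


def _backward(S, X, params, cache, probs, codes, batch):
    """Gradients of the summed cross-entropy over ``batch`` w.r.t. W1, W2."""
    A1, H1, SH1, U = cache
    m, c = probs.shape
    dU = np.zeros((m, c))
    dU[batch] = probs[batch]
    dU[batch, codes[batch]] -= 1.0
    dW2 = SH1.T @ dU
    dH1 = (S.T @ dU) @ params.W2.T
    dA1 = dH1 * (A1 > 0)
    dW1 = (S @ X).T @ dA1
    return dW1, dW2


def init_params(n: int, h: int, c: int, seed: int = 0) -> ClassifierParams:
    """Seeded scaled-uniform initialization (bound 1/sqrt(fan-in))."""
    rng = np.random.default_rng(seed)
    W1 = rng.uniform(-1.0 / np.sqrt(n), 1.0 / np.sqrt(n), size=(n, h))
    W2 = rng.uniform(-1.0 / np.sqrt(h), 1.0 / np.sqrt(h), size=(h, c))
    return ClassifierParams(W1=W1, W2=W2)


class _Adam:
    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_classifier(
    S_denoised,
    X_refined,
    labels: LabelTable,
    split,
    cfg: ClassifierConfig | None = None,
) -> tuple[ClassifierParams, AnnotationResult]:
    """Adam training on labeled train cells with per-epoch validation selection.

    ``split`` must expose disjoint ``train``, ``validation`` and ``test`` index
    arrays; every train cell must be labeled.  Returns the parameters of the
    best validation epoch and the annotation computed with them, with metrics
    on the test subset.
    """
    cfg = cfg or ClassifierConfig()
    S = _matrix(S_denoised)
    X = _matrix(X_refined)
    train = np.asarray(split.train)
    val = np.asarray(split.validation)
    test = np.asarray(split.test)
    if len(train) == 0:
        raise ValidationError("empty train split")
    if np.any(labels.codes[train] < 0):
        raise ValidationError("all train cells must be labeled")
    present = np.unique(labels.codes[train])
    if len(present) < labels.n_types:
        msg = "some cell types have no labeled train cell"
        if cfg.strict_classes:
            raise ValidationError(msg)
        warnings.warn(msg, stacklevel=2)

    n, c = X.shape[1], labels.n_types
    params = init_params(n, cfg.hidden_dim, c, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    adam = _Adam([params.W1.shape, params.W2.shape], cfg.learning_rate)
    codes = labels.codes

    best_val, best = -1.0, ClassifierParams(params.W1.copy(), params.W2.copy())
    for _ in range(cfg.epochs):
        perm = rng.permutation(train)
        for start in range(0, len(perm), cfg.batch_size):
            batch = perm[start : start + cfg.batch_size]
            probs, cache = _forward_cached(S, X, params)
            dW1, dW2 = _backward(S, X, params, cache, probs, codes, batch)
            adam.step([params.W1, params.W2], [dW1, dW2])
        probs, _ = _forward_cached(S, X, params)
        if len(val):
            val_acc = float(np.mean(probs[val].argmax(axis=1) == codes[val]))
        else:
            val_acc = float(np.mean(probs[train].argmax(axis=1) == codes[train]))
        if val_acc > best_val:
            best_val = val_acc
            best = ClassifierParams(params.W1.copy(), params.W2.copy())

    probs, _ = _forward_cached(S, X, best)
    hard = np.asarray([labels.type_names[i] for i in probs.argmax(axis=1)], dtype=object)
    metrics = evaluate(probs, labels, test) if len(test) else {}
    metrics["validation_accuracy"] = best_val
    return best, AnnotationResult(probabilities=probs, hard_labels=hard, metrics=metrics)


def evaluate(
    probabilities: np.ndarray,
    truth: LabelTable | np.ndarray,
    subset: np.ndarray,
) -> dict:
    """Accuracy, macro F1 and macro one-vs-rest AUC over ``subset`` cells.

    Classes absent from the truth subset are excluded from the macro averages
    (with a warning); AUC for a class degenerates to NaN when the subset has a
    single class.
    """
    codes = truth.codes if isinstance(truth, LabelTable) else np.asarray(truth)
    subset = np.asarray(subset)
    y = codes[subset]
    if np.any(y < 0):
        raise ValidationError("evaluation subset contains cells without ground truth")
    P = probabilities[subset]
    pred = P.argmax(axis=1)
    present = np.unique(y)
    if len(present) < probabilities.shape[1]:
        warnings.warn(
            "classes absent from the evaluation subset are excluded from macro averages",
            stacklevel=2,
        )
    accuracy = float(np.mean(pred == y))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        macro_f1 = float(f1_score(y, pred, labels=present, average="macro", zero_division=0))
    aucs = []
    for cls in present:
        binary = (y == cls).astype(int)
        if binary.min() == binary.max():
            continue
        aucs.append(roc_auc_score(binary, P[:, cls]))
    macro_auc = float(np.mean(aucs)) if aucs else float("nan")
    return {"accuracy": accuracy, "macro_f1": macro_f1, "macro_auc": macro_auc}
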