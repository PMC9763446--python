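"""Probabilistic endpoint classifiers: P(endpoint | x) for every instance.

The causal engine downstream only needs a conditional-probability table
``p(x_i)`` from *some* probabilistic classifier, so the classifier is a
contract (:class:`ProbabilisticTextClassifier`) with a desk-scale default:
a bag-of-words linear model with logistic output trained by mini-batch
gradient descent on the summed cross-entropy loss

    LOSS(D) = - sum_i [ y_i log p(x_i) + (1 - y_i) log(1 - p(x_i)) ].

The training schedule mirrors the transformer fine-tuning recipe the
framework was designed around (2,500 steps, 500-step linear warmup,
mini-batch 128, checkpoint every 200 steps with minimum held-out loss
selecting the final weights); a transformer adapter satisfying the same
contract can be dropped in without touching the causal engine.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Protocol, Sequence, runtime_checkable

import numpy as np
import scipy.sparse as sp

from .corpus import Corpus

__all__ = [
    "CLIP_EPSILON",
    "TrainingConfig",
    "LM_ADAPTER_CONFIG",
    "PredictionTable",
    "EvalMetrics",
    "ProbabilisticTextClassifier",
    "BagOfWordsLogisticClassifier",
    "NotFittedError",
    "cross_entropy_loss",
    "fit_default_classifier",
    "predict_corpus",
    "evaluate",
]

#: Probabilities are clipped to [eps, 1-eps] inside the loss so a confident
#: mistake cannot produce an infinite value.
CLIP_EPSILON = 1e-12


class NotFittedError(RuntimeError):
    """Prediction was requested from a classifier that has not been fitted."""


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization schedule for the default classifier (and any adapter).

    ``training_steps`` counts gradient steps; ``warmup_steps`` scales the
    learning rate linearly from 0; every ``checkpoint_interval`` steps the
    held-out loss is recorded and the checkpoint with minimum held-out loss
    is kept (early stopping).  ``batch_size <= 0`` (or >= corpus size)
    means full-batch proximal gradient descent — the default model's mode,
    since stochastic mini-batch noise keeps pure-noise feature weights away
    from the exact zeros that the downstream causal null calibration relies
    on.  The transformer-recipe values (mini-batch 128, 2,500 steps,
    500-step warmup, checkpoints every 200) remain the documented settings
    for an LM adapter.
    """

    max_sequence_length: int = 128
    batch_size: int = 0
    training_steps: int = 2500
    warmup_steps: int = 500
    checkpoint_interval: int = 200
    seed: int = 0
    learning_rate: float = 2.0
    l2: float = 1e-4
    l1: float = 7.5e-3

    def __post_init__(self) -> None:
        if self.warmup_steps > self.training_steps:
            raise ValueError("warmup_steps must not exceed training_steps")


#: Transformer fine-tuning recipe recorded for the optional LM adapter.
LM_ADAPTER_CONFIG = TrainingConfig(batch_size=128, learning_rate=0.5)


@dataclass(frozen=True)
class PredictionTable:
    """Mapping instance id -> p(x_i), covering a scored corpus exactly once."""

    probabilities: Mapping[str, float]

    def __post_init__(self) -> None:
        for pid, p in self.probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {pid!r} outside [0, 1]: {p}")

    def __len__(self) -> int:
        return len(self.probabilities)

    def __getitem__(self, instance_id: str) -> float:
        return self.probabilities[instance_id]

    def ids(self) -> set[str]:
        return set(self.probabilities)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tprobability\n")
            for pid, p in self.probabilities.items():
                fh.write(f"{pid}\t{p:.17g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PredictionTable":
        probs: dict[str, float] = {}
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                pid, value = line.rstrip("\n").split("\t")
                probs[pid] = float(value)
        return cls(probs)


@dataclass(frozen=True)
class EvalMetrics:
    """Confusion-matrix metrics at a decision threshold.

    ``recall`` (and ``f1``) are NaN-flagged when no positive labels exist;
    ``precision`` likewise when nothing is predicted positive.
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    loss: float


@runtime_checkable
class ProbabilisticTextClassifier(Protocol):
    """Contract every classifier (default or transformer adapter) satisfies."""

    def fit(self, train: Corpus, eval_corpus: Corpus | None = None) -> "ProbabilisticTextClassifier":
        ...

    def predict_probability(self, tokens: Sequence[str]) -> float:
        ...


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class BagOfWordsLogisticClassifier:
    """Logistic-output linear model over token counts.

    The vocabulary is fixed from the training corpus; unseen tokens are
    ignored at prediction time.  Sequences are truncated to
    ``max_sequence_length`` tokens before counting.
    """

    def __init__(self, config: TrainingConfig | None = None) -> None:
        self.config = config or TrainingConfig()
        self.vocabulary_: dict[str, int] | None = None
        self.weights_: np.ndarray | None = None
        self.bias_: float = 0.0
        self.loss_history_: list[float] = []
        self.eval_loss_history_: list[tuple[int, float]] = []
        self.selected_step_: int | None = None

    # -- featurization -------------------------------------------------

    def _count_matrix(self, corpus: Corpus, vocab: dict[str, int]) -> sp.csr_matrix:
        data, indices, indptr = [], [], [0]
        limit = self.config.max_sequence_length
        for inst in corpus:
            counts: dict[int, int] = {}
            for token in inst.tokens[:limit]:
                j = vocab.get(token)
                if j is not None:
                    counts[j] = counts.get(j, 0) + 1
            indices.extend(counts.keys())
            data.extend(counts.values())
            indptr.append(len(indices))
        return sp.csr_matrix(
            (np.array(data, dtype=float), np.array(indices, dtype=np.int32), np.array(indptr, dtype=np.int32)),
            shape=(corpus.n, len(vocab)),
        )

    # -- training ------------------------------------------------------

    def fit(self, train: Corpus, eval_corpus: Corpus | None = None) -> "BagOfWordsLogisticClassifier":
        cfg = self.config
        labels = np.array([inst.y for inst in train], dtype=float)
        if labels.min() == labels.max():
            raise ValueError("training corpus must contain both endpoint classes")
        vocab: dict[str, int] = {}
        for inst in train:
            for token in inst.tokens[: cfg.max_sequence_length]:
                if token not in vocab:
                    vocab[token] = len(vocab)
        x = self._count_matrix(train, vocab)
        x_eval = y_eval = None
        if eval_corpus is not None:
            x_eval = self._count_matrix(eval_corpus, vocab)
            y_eval = np.array([inst.y for inst in eval_corpus], dtype=float)

        rng = np.random.default_rng(cfg.seed)
        w = rng.normal(0.0, 0.01, size=x.shape[1])
        b = float(np.log(labels.mean() / (1.0 - labels.mean())))
        n = x.shape[0]
        batch = n if cfg.batch_size <= 0 else min(cfg.batch_size, n)
        full_batch = batch >= n
        order = np.arange(n)
        cursor = n  # force shuffle on first step

        best = (math.inf, w.copy(), b)
        self.loss_history_ = []
        self.eval_loss_history_ = []
        for step in range(1, cfg.training_steps + 1):
            lr = cfg.learning_rate * min(1.0, step / max(cfg.warmup_steps, 1))
            if full_batch:
                xb, yb = x, labels
            else:
                if cursor + batch > n:
                    rng.shuffle(order)
                    cursor = 0
                rows = order[cursor : cursor + batch]
                cursor += batch
                xb, yb = x[rows], labels[rows]
            p = _sigmoid(xb @ w + b)
            grad_z = (p - yb) / xb.shape[0]
            w -= lr * (xb.T @ grad_z + cfg.l2 * w)
            b -= lr * float(grad_z.sum())
            if cfg.l1 > 0.0:
                # proximal step: soft-threshold so pure-noise weights stay
                # at exactly zero (keeps the do-calculus null calibrated)
                w = np.sign(w) * np.maximum(np.abs(w) - lr * cfg.l1, 0.0)
            if step % cfg.checkpoint_interval == 0 or step == cfg.training_steps:
                self.loss_history_.append(self._loss(x, labels, w, b))
                if x_eval is not None:
                    eval_loss = self._loss(x_eval, y_eval, w, b)
                    self.eval_loss_history_.append((step, eval_loss))
                    if eval_loss < best[0]:
                        best = (eval_loss, w.copy(), b)
                        self.selected_step_ = step
        if x_eval is not None and best[0] < math.inf:
            w, b = best[1], best[2]
        self.vocabulary_ = vocab
        self.weights_ = w
        self.bias_ = b
        return self

    @staticmethod
    def _loss(x: sp.csr_matrix, y: np.ndarray, w: np.ndarray, b: float) -> float:
        p = np.clip(_sigmoid(x @ w + b), CLIP_EPSILON, 1.0 - CLIP_EPSILON)
        return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))

    # -- prediction ----------------------------------------------------

    def _check_fitted(self) -> None:
        if self.vocabulary_ is None or self.weights_ is None:
            raise NotFittedError("classifier has not been fitted")

    def predict_probability(self, tokens: Sequence[str]) -> float:
        self._check_fitted()
        z = self.bias_
        for token in tokens[: self.config.max_sequence_length]:
            j = self.vocabulary_.get(token)
            if j is not None:
                z += self.weights_[j]
        return float(_sigmoid(np.array([z]))[0])

    def predict_matrix(self, corpus: Corpus) -> np.ndarray:
        self._check_fitted()
        x = self._count_matrix(corpus, self.vocabulary_)
        return _sigmoid(x @ self.weights_ + self.bias_)

    # -- persistence ---------------------------------------------------

    def save(self, path: str | Path) -> None:
        self._check_fitted()
        payload = {
            "config": asdict(self.config),
            "vocabulary": list(self.vocabulary_),
            "weights": self.weights_.tolist(),
            "bias": self.bias_,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "BagOfWordsLogisticClassifier":
        payload = json.loads(Path(path).read_text())
        model = cls(TrainingConfig(**payload["config"]))
        model.vocabulary_ = {t: i for i, t in enumerate(payload["vocabulary"])}
        model.weights_ = np.array(payload["weights"], dtype=float)
        model.bias_ = float(payload["bias"])
        return model


def cross_entropy_loss(
    predictions: PredictionTable,
    labels: Mapping[str, int],
    epsilon: float = CLIP_EPSILON,
) -> float:
    """Summed binary cross entropy between a prediction table and labels.

    Probabilities are clipped to ``[epsilon, 1 - epsilon]``.  The id sets of
    the two mappings must coincide.
    """
    if predictions.ids() != set(labels):
        raise ValueError("prediction and label id sets differ")
    total = 0.0
    for pid, p in predictions.probabilities.items():
        p = min(max(p, epsilon), 1.0 - epsilon)
        y = labels[pid]
        total -= y * math.log(p) + (1 - y) * math.log(1.0 - p)
    return total


def fit_default_classifier(
    train: Corpus,
    config: TrainingConfig | None = None,
    eval_corpus: Corpus | None = None,
) -> BagOfWordsLogisticClassifier:
    """Fit the default bag-of-words logistic classifier.

    Raises ``ValueError`` on a single-class corpus.  With an ``eval_corpus``
    the returned weights are the checkpoint with minimum held-out loss.
    """
    return BagOfWordsLogisticClassifier(config).fit(train, eval_corpus=eval_corpus)


def predict_corpus(model: ProbabilisticTextClassifier, corpus: Corpus) -> PredictionTable:
    """Score every instance of a corpus, one probability per id."""
    if isinstance(model, BagOfWordsLogisticClassifier):
        if corpus.n == 0:
            return PredictionTable({})
        probs = model.predict_matrix(corpus)
        return PredictionTable({inst.id: float(p) for inst, p in zip(corpus, probs)})
    return PredictionTable({inst.id: float(model.predict_probability(inst.tokens)) for inst in corpus})


def evaluate(
    predictions: PredictionTable,
    labels: Mapping[str, int],
    threshold: float = 0.5,
) -> EvalMetrics:
    """Confusion-matrix metrics of thresholded predictions against labels."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if predictions.ids() != set(labels):
        raise ValueError("prediction and label id sets differ")
    tp = fp = fn = tn = 0
    for pid, p in predictions.probabilities.items():
        predicted = p >= threshold
        actual = labels[pid] == 1
        if predicted and actual:
            tp += 1
        elif predicted:
            fp += 1
        elif actual:
            fn += 1
        else:
            tn += 1
    n = tp + fp + fn + tn
    accuracy = (tp + tn) / n if n else math.nan
    precision = tp / (tp + fp) if (tp + fp) else math.nan
    recall = tp / (tp + fn) if (tp + fn) else math.nan
    if not math.isnan(precision) and not math.isnan(recall) and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = math.nan
    loss = cross_entropy_loss(predictions, labels)
    return EvalMetrics(accuracy=accuracy, precision=precision, recall=recall, f1=f1, loss=loss)
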