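"""Six-way clause classification into quality dimensions.

A shallow bag-of-n-grams linear classifier in the fastText style: each
feature (word, optionally word bigram) owns a d-dimensional embedding;
a clause is represented by the mean of its feature embeddings; a 6-way
softmax over a linear layer produces class probabilities. Training is
plain SGD on the negative log-likelihood with a learning rate that
decays linearly to zero. Six classes need no hierarchical softmax.

Also provides stratified train/test splitting, evaluation reports, and
Cohen's kappa for inter-annotator agreement.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from hsq5d.constants import LABELS
from hsq5d.corpus import Clause

logger = logging.getLogger(__name__)

LABEL_INDEX = {lab: i for i, lab in enumerate(LABELS)}


@dataclass(frozen=True)
class LabeledClause:
    clause: Clause
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABEL_INDEX:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the shallow classifier.

    Defaults are the grid-search optimum used throughout: learning rate
    0.8, 25 epochs, 20 embedding dimensions, unigram features only.
    """

    learning_rate: float = 0.8
    epochs: int = 25
    dim: int = 20
    use_bigrams: bool = False


@dataclass
class AspectModel:
    """Feature vocabulary, embedding table, and softmax output weights."""

    vocab: dict[str, int]
    embeddings: np.ndarray      # (n_features, dim)
    output: np.ndarray          # (6, dim)
    config: TrainConfig
    seed: int


@dataclass(frozen=True)
class EvalReport:
    """Accuracy, per-class precision/recall/F1, and a 6x6 confusion table
    (rows = true label, columns = predicted)."""

    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    confusion: np.ndarray
    n: int


def _features(tokens: Sequence[str], use_bigrams: bool) -> list[str]:
    feats = list(tokens)
    if use_bigrams:
        feats += [f"{a}__{b}" for a, b in zip(tokens, tokens[1:])]
    return feats


def split_labeled(
    labeled: Sequence[LabeledClause],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[list[LabeledClause], list[LabeledClause]]:
    """Stratified disjoint train/test split; per-class train counts are
    within one item of ``train_fraction``. Requires ≥ 2 items per class."""
    if len(labeled) < 5:
        raise ValueError("need at least 5 labeled clauses to split")
    by_label: dict[str, list[int]] = {}
    for i, lc in enumerate(labeled):
        by_label.setdefault(lc.label, []).append(i)
    for lab, idx in by_label.items():
        if len(idx) < 2:
            raise ValueError(f"class {lab!r} has {len(idx)} example(s); need >= 2")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for lab in sorted(by_label):
        idx = np.array(by_label[lab])
        rng.shuffle(idx)
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)  # both sides non-empty
        train_idx.extend(idx[:n_train].tolist())
        test_idx.extend(idx[n_train:].tolist())
    return [labeled[i] for i in sorted(train_idx)], [labeled[i] for i in sorted(test_idx)]


def train_aspect(
    train: Sequence[LabeledClause],
    config: TrainConfig | None = None,
    seed: int = 0,
) -> AspectModel:
    """Train the averaged-embedding softmax classifier by SGD.

    Embeddings start uniform(−1/d, 1/d), output weights at zero; the
    learning rate decays linearly from ``config.learning_rate`` to 0
    over epochs × examples updates. Deterministic given seed.
    """
    if not train:
        raise ValueError("empty training set")
    config = config or TrainConfig()
    for lc in train:
        if not lc.clause.tokens:
            raise ValueError(f"clause {lc.clause.review_id!r} has no tokens")

    vocab: dict[str, int] = {}
    for lc in train:
        for f in _features(lc.clause.tokens, config.use_bigrams):
            vocab.setdefault(f, len(vocab))

    rng = np.random.default_rng(seed)
    d = config.dim
    emb = rng.uniform(-1.0 / d, 1.0 / d, size=(len(vocab), d))
    out = np.zeros((len(LABELS), d))

    feats = [
        np.array([vocab[f] for f in _features(lc.clause.tokens, config.use_bigrams)])
        for lc in train
    ]
    labels = np.array([LABEL_INDEX[lc.label] for lc in train])

    n = len(train)
    total_updates = config.epochs * n
    step = 0
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for i in order:
            lr = config.learning_rate * (1.0 - step / total_updates)
            step += 1
            ids = feats[i]
            h = emb[ids].mean(axis=0)
            logits = out @ h
            logits -= logits.max()
            p = np.exp(logits)
            p /= p.sum()
            grad = p.copy()
            grad[labels[i]] -= 1.0
            # gradients: d/d out = grad ⊗ h ; d/d h = outᵀ grad, shared over features
            g_h = out.T @ grad
            out -= lr * np.outer(grad, h)
            emb[ids] -= lr * g_h / len(ids)
    return AspectModel(vocab=vocab, embeddings=emb, output=out, config=config, seed=seed)


def predict_aspect(model: AspectModel, clause: Clause) -> tuple[str, np.ndarray]:
    """Predict a clause's label and 6-class probability vector.

    Ties break by the fixed class order (expertise, process, attitude,
    empathy, outcome, other). A clause whose every feature is out of
    vocabulary falls back to "other" with uniform probabilities, so that
    downstream sentiment never scores unclassifiable text into a
    dimension.
    """
    ids = [
        model.vocab[f]
        for f in _features(clause.tokens, model.config.use_bigrams)
        if f in model.vocab
    ]
    if not ids:
        logger.debug("clause %r: all features out of vocabulary", clause.review_id)
        return "other", np.full(len(LABELS), 1.0 / len(LABELS))
    h = model.embeddings[np.array(ids)].mean(axis=0)
    logits = model.output @ h
    logits -= logits.max()
    p = np.exp(logits)
    p /= p.sum()
    return LABELS[int(np.argmax(p))], p


def evaluate(model: AspectModel, test: Sequence[LabeledClause]) -> EvalReport:
    """Accuracy, per-class precision/recall/F1 and confusion table on a
    held-out labeled set."""
    if not test:
        raise ValueError("empty test set")
    C = np.zeros((len(LABELS), len(LABELS)), dtype=np.int64)
    for lc in test:
        pred, _ = predict_aspect(model, lc.clause)
        C[LABEL_INDEX[lc.label], LABEL_INDEX[pred]] += 1
    precision, recall, f1 = {}, {}, {}
    for lab, i in LABEL_INDEX.items():
        tp = C[i, i]
        p = tp / C[:, i].sum() if C[:, i].sum() else 0.0
        r = tp / C[i, :].sum() if C[i, :].sum() else 0.0
        precision[lab] = float(p)
        recall[lab] = float(r)
        f1[lab] = float(2 * p * r / (p + r)) if (p + r) else 0.0
    return EvalReport(
        accuracy=float(np.trace(C) / C.sum()),
        precision=precision,
        recall=recall,
        f1=f1,
        confusion=C,
        n=int(C.sum()),
    )


def cohen_kappa(ann_a: Sequence[str], ann_b: Sequence[str]) -> float:
    """Cohen's kappa between two parallel label sequences.

    κ = (p_o − p_e) / (1 − p_e) with chance agreement p_e from the two
    annotators' marginal label frequencies. If both annotators are
    constant and identical (p_e = 1), returns 1 by convention.
    """
    if len(ann_a) != len(ann_b):
        raise ValueError(f"length mismatch: {len(ann_a)} vs {len(ann_b)}")
    if not ann_a:
        raise ValueError("empty annotation sequences")
    n = len(ann_a)
    cats = sorted(set(ann_a) | set(ann_b))
    p_o = sum(a == b for a, b in zip(ann_a, ann_b)) / n
    p_e = sum(
        (sum(a == c for a in ann_a) / n) * (sum(b == c for b in ann_b) / n) for c in cats
    )
    if p_e >= 1.0:
        logger.info("degenerate kappa: both annotators constant and equal")
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def drop_disagreements(
    ann_a: Sequence[LabeledClause], ann_b: Sequence[LabeledClause]
) -> list[LabeledClause]:
    """Gold-standard construction: keep only clauses where the two
    annotators agree; the dropped count is logged."""
    if len(ann_a) != len(ann_b):
        raise ValueError("annotation sets differ in length")
    kept = [a for a, b in zip(ann_a, ann_b) if a.label == b.label]
    logger.info("dropped %d disagreeing clause pairs", len(ann_a) - len(kept))
    return kept


# ---------------------------------------------------------------------------
# Model persistence: vocabulary TSV + weight arrays + config JSON


def save_model(model: AspectModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with (directory / "vocab.tsv").open("w", encoding="utf-8") as fh:
        for w, i in sorted(model.vocab.items(), key=lambda kv: kv[1]):
            fh.write(f"{w}\t{i}\n")
    np.savetxt(directory / "embeddings.txt", model.embeddings)
    np.savetxt(directory / "output.txt", model.output)
    (directory / "config.json").write_text(
        json.dumps(
            {
                "learning_rate": model.config.learning_rate,
                "epochs": model.config.epochs,
                "dim": model.config.dim,
                "use_bigrams": model.config.use_bigrams,
                "seed": model.seed,
            }
        )
    )


def load_model(directory: str | Path) -> AspectModel:
    directory = Path(directory)
    vocab: dict[str, int] = {}
    with (directory / "vocab.tsv").open(encoding="utf-8") as fh:
        for line in fh:
            w, i = line.rstrip("\n").split("\t")
            vocab[w] = int(i)
    emb = np.loadtxt(directory / "embeddings.txt", ndmin=2)
    out = np.loadtxt(directory / "output.txt", ndmin=2)
    cfg = json.loads((directory / "config.json").read_text())
    return AspectModel(
        vocab=vocab,
        embeddings=emb,
        output=out,
        config=TrainConfig(
            learning_rate=cfg["learning_rate"],
            epochs=cfg["epochs"],
            dim=cfg["dim"],
            use_bigrams=cfg["use_bigrams"],
        ),
        seed=cfg["seed"],
    )
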