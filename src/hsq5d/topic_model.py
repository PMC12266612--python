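"""Collapsed-Gibbs LDA with held-out perplexity and topic refinement.

Topics are discovered from tokenized reviews by latent Dirichlet
allocation with symmetric priors, inferred by collapsed Gibbs sampling:
each token's topic is resampled from

    p(z = k) ∝ (n_dk + α) · (n_kw + β) / (n_k + V·β)

with the token's own count removed. Model selection runs k-fold
cross-validation over a grid of topic counts, scoring held-out folds by
perplexity (exponentiated negative mean per-token log-likelihood under
the trained topic-word distributions with document mixtures estimated
by fold-in Gibbs). Near-duplicate topics — cosine similarity of their
smoothed word distributions above a threshold — are merged greedily.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


@dataclass
class TopicModelState:
    """Count tables and assignments of a collapsed-Gibbs LDA fit.

    Invariants: ``n_kw.sum(axis=1) == n_k`` and ``n_dk[d].sum()`` equals
    the length of document ``d``.
    """

    K: int
    vocabulary: tuple[str, ...]
    alpha: float
    beta: float
    z: list[np.ndarray]            # per-document topic assignments
    docs: list[np.ndarray]         # per-document word ids
    n_dk: np.ndarray               # (D, K)
    n_kw: np.ndarray               # (K, V)
    n_k: np.ndarray                # (K,)
    rng_seed: int

    @property
    def V(self) -> int:
        return len(self.vocabulary)

    def phi(self) -> np.ndarray:
        """Smoothed topic-word distributions, rows summing to 1."""
        return (self.n_kw + self.beta) / (self.n_k[:, None] + self.V * self.beta)

    def theta(self) -> np.ndarray:
        """Smoothed document-topic mixtures, rows summing to 1."""
        lengths = self.n_dk.sum(axis=1, keepdims=True)
        return (self.n_dk + self.alpha) / (lengths + self.K * self.alpha)

    def check_counts(self) -> None:
        assert (self.n_kw.sum(axis=1) == self.n_k).all()
        for d, doc in enumerate(self.docs):
            assert self.n_dk[d].sum() == len(doc)
        assert (self.n_dk >= 0).all() and (self.n_kw >= 0).all()


def _build_vocab(documents: Sequence[Sequence[str]]) -> tuple[tuple[str, ...], dict[str, int]]:
    vocab = sorted({w for doc in documents for w in doc})
    return tuple(vocab), {w: i for i, w in enumerate(vocab)}


def fit_lda(
    documents: Sequence[Sequence[str]],
    K: int,
    *,
    alpha: float | None = None,
    beta: float = 0.01,
    n_iter: int = 200,
    seed: int = 0,
) -> TopicModelState:
    """Fit LDA by collapsed Gibbs sampling.

    ``documents`` are token sequences (every document non-empty). ``alpha``
    defaults to ``50 / K``. Identical seed and input reproduce identical
    assignments.
    """
    if not documents:
        raise ValueError("empty corpus")
    if any(len(d) == 0 for d in documents):
        raise ValueError("every document must be non-empty")
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    total_tokens = sum(len(d) for d in documents)
    if K > total_tokens:
        raise ValueError(f"K={K} exceeds total token count {total_tokens}")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    alpha = 50.0 / K if alpha is None else alpha

    vocabulary, index = _build_vocab(documents)
    V = len(vocabulary)
    docs = [np.array([index[w] for w in doc], dtype=np.int64) for doc in documents]
    D = len(docs)

    rng = np.random.default_rng(seed)
    n_dk = np.zeros((D, K), dtype=np.int64)
    n_kw = np.zeros((K, V), dtype=np.int64)
    n_k = np.zeros(K, dtype=np.int64)
    z = []
    for d, doc in enumerate(docs):
        zd = rng.integers(0, K, size=len(doc))
        z.append(zd)
        for w, k in zip(doc, zd):
            n_dk[d, k] += 1
            n_kw[k, w] += 1
            n_k[k] += 1

    vbeta = V * beta
    for _ in range(n_iter):
        for d, doc in enumerate(docs):
            zd = z[d]
            row = n_dk[d]
            for i, w in enumerate(doc):
                k_old = zd[i]
                row[k_old] -= 1
                n_kw[k_old, w] -= 1
                n_k[k_old] -= 1
                p = (row + alpha) * (n_kw[:, w] + beta) / (n_k + vbeta)
                cum = np.cumsum(p)
                k_new = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
                zd[i] = k_new
                row[k_new] += 1
                n_kw[k_new, w] += 1
                n_k[k_new] += 1

    return TopicModelState(
        K=K, vocabulary=vocabulary, alpha=alpha, beta=beta,
        z=z, docs=docs, n_dk=n_dk, n_kw=n_kw, n_k=n_k, rng_seed=seed,
    )


def _fold_in_theta(
    state: TopicModelState,
    doc_ids: np.ndarray,
    n_sweeps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Estimate a held-out document's topic mixture by Gibbs sampling with
    the trained topic-word counts held fixed."""
    K, alpha = state.K, state.alpha
    phi_w = state.phi()[:, doc_ids]  # (K, n) column per token
    zd = rng.integers(0, K, size=len(doc_ids))
    m_k = np.bincount(zd, minlength=K)
    for _ in range(n_sweeps):
        for i in range(len(doc_ids)):
            m_k[zd[i]] -= 1
            p = (m_k + alpha) * phi_w[:, i]
            cum = np.cumsum(p)
            zd[i] = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
            m_k[zd[i]] += 1
    return (m_k + alpha) / (len(doc_ids) + K * alpha)


def heldout_loglik(
    state: TopicModelState,
    documents: Sequence[Sequence[str]],
    *,
    foldin_iters: int = 20,
    seed: int = 0,
) -> tuple[float, int]:
    """Total held-out log-likelihood and the token count it covers.

    Out-of-vocabulary tokens are dropped. Each document's mixture θ̂ is a
    fold-in Gibbs point estimate; p(w|d) = Σ_k θ̂_dk φ̂_kw.
    """
    if not documents:
        raise ValueError("empty held-out set")
    index = {w: i for i, w in enumerate(state.vocabulary)}
    rng = np.random.default_rng(seed)
    phi = state.phi()
    total = 0.0
    n_tokens = 0
    for doc in documents:
        ids = np.array([index[w] for w in doc if w in index], dtype=np.int64)
        if len(ids) == 0:
            continue
        theta = _fold_in_theta(state, ids, foldin_iters, rng)
        p_w = theta @ phi[:, ids]
        total += float(np.log(p_w).sum())
        n_tokens += len(ids)
    if n_tokens == 0:
        raise ValueError("no in-vocabulary tokens in the held-out set")
    return total, n_tokens


def heldout_perplexity(
    state: TopicModelState,
    documents: Sequence[Sequence[str]],
    *,
    foldin_iters: int = 20,
    seed: int = 0,
) -> float:
    """exp(−mean per-token held-out log-likelihood); always ≥ 1."""
    loglik, n = heldout_loglik(state, documents, foldin_iters=foldin_iters, seed=seed)
    return float(np.exp(-loglik / n))


def select_topic_count(
    documents: Sequence[Sequence[str]],
    K_grid: Sequence[int],
    *,
    folds: int = 3,
    n_iter: int = 100,
    foldin_iters: int = 20,
    alpha: float | None = None,
    beta: float = 0.01,
    seed: int = 0,
) -> tuple[int, dict[int, dict[str, float]]]:
    """Choose the topic count by k-fold cross-validated perplexity.

    Documents are partitioned into ``folds`` folds; for each candidate K
    a model is trained on the other folds and scored on the held-out
    fold. The selected K minimizes mean perplexity; ties (to within 1e-9,
    so float noise cannot break an exact tie) prefer larger mean
    log-likelihood, then smaller K. Returns (K, per-K metrics with keys
    "perplexity" and "loglik").

    ``alpha``/``beta`` forward to :func:`fit_lda`. For model selection a
    weak K-independent document-topic prior (e.g. ``alpha=0.5``) is
    usually preferable to the 50/K fitting default, whose heavy
    smoothing rewards ever-larger K on short documents.
    """
    if not K_grid:
        raise ValueError("K_grid must be non-empty")
    if len(documents) < folds:
        raise ValueError(f"need at least {folds} documents for {folds}-fold CV")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(documents))
    fold_of = np.arange(len(documents)) % folds
    assignment = np.empty(len(documents), dtype=np.int64)
    assignment[order] = fold_of

    metrics: dict[int, dict[str, float]] = {}
    for K in K_grid:
        perps, logliks = [], []
        for f in range(folds):
            train = [documents[i] for i in range(len(documents)) if assignment[i] != f]
            test = [documents[i] for i in range(len(documents)) if assignment[i] == f]
            state = fit_lda(
                train, K, n_iter=n_iter, seed=seed + 1000 * f, alpha=alpha, beta=beta
            )
            ll, n = heldout_loglik(state, test, foldin_iters=foldin_iters, seed=seed + f)
            perps.append(np.exp(-ll / n))
            logliks.append(ll)
        metrics[K] = {
            "perplexity": float(np.mean(perps)),
            "loglik": float(np.mean(logliks)),
        }
    # minimize perplexity; ties -> larger loglik, then smaller K
    best = min(
        metrics,
        key=lambda K: (round(metrics[K]["perplexity"], 9), -round(metrics[K]["loglik"], 9), K),
    )
    return best, metrics


# ---------------------------------------------------------------------------
# Topic comparison, merging, labeling


def topic_cosine(state: TopicModelState, i: int, j: int) -> float:
    """Cosine similarity of two topics' smoothed word distributions."""
    if i == j:
        raise ValueError("topic indices must differ")
    phi = state.phi()
    a, b = phi[i], phi[j]
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def merge_similar_topics(
    state: TopicModelState, threshold: float = 0.75
) -> tuple[TopicModelState, list[tuple[int, int]]]:
    """Greedily merge the most-similar topic pair while any pair's cosine
    exceeds ``threshold``; merging sums count rows and renumbers topics.

    Returns the new state and a log of merged index pairs (indices refer
    to the state at the time of each merge). The merge threshold of 0.75
    is the conventional near-duplicate cutoff for word distributions.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    n_kw = state.n_kw.copy()
    n_dk = state.n_dk.copy()
    log: list[tuple[int, int]] = []

    def best_pair(nkw: np.ndarray, beta: float) -> tuple[float, int, int]:
        nk = nkw.sum(axis=1)
        phi = (nkw + beta) / (nk[:, None] + nkw.shape[1] * beta)
        norms = np.linalg.norm(phi, axis=1)
        sim = (phi @ phi.T) / np.outer(norms, norms)
        np.fill_diagonal(sim, -np.inf)
        idx = int(np.argmax(sim))
        i, j = divmod(idx, sim.shape[1])
        return float(sim[i, j]), min(i, j), max(i, j)

    while n_kw.shape[0] > 1:
        s, i, j = best_pair(n_kw, state.beta)
        if s <= threshold:
            break
        n_kw[i] += n_kw[j]
        n_kw = np.delete(n_kw, j, axis=0)
        n_dk[:, i] += n_dk[:, j]
        n_dk = np.delete(n_dk, j, axis=1)
        log.append((i, j))

    K_new = n_kw.shape[0]
    # remap assignments through the accumulated merges
    mapping = np.arange(state.K)
    for i, j in log:
        # at merge time indices were in the then-current numbering
        mapping = _apply_merge(mapping, i, j)
    z_new = [mapping[zd] for zd in state.z]
    merged = TopicModelState(
        K=K_new, vocabulary=state.vocabulary, alpha=state.alpha, beta=state.beta,
        z=z_new, docs=state.docs, n_dk=n_dk, n_kw=n_kw, n_k=n_kw.sum(axis=1),
        rng_seed=state.rng_seed,
    )
    merged.check_counts()
    return merged, log


def _apply_merge(mapping: np.ndarray, i: int, j: int) -> np.ndarray:
    """Update an original-index -> current-index map after merging current
    topic j into i (then deleting j)."""
    out = mapping.copy()
    out[mapping == j] = i
    out[mapping > j] -= 1
    return out


def top_words(state: TopicModelState, n: int = 20) -> list[list[tuple[str, float]]]:
    """Per topic, the ``n`` highest-probability words with probabilities,
    sorted descending."""
    phi = state.phi()
    out = []
    for k in range(state.K):
        idx = np.argsort(phi[k])[::-1][:n]
        out.append([(state.vocabulary[i], float(phi[k, i])) for i in idx])
    return out


def _bow_cosine(a: str, b: str) -> float:
    """Cosine similarity of two strings as bags of whitespace tokens."""
    from collections import Counter

    ca, cb = Counter(a.split()), Counter(b.split())
    if not ca or not cb:
        return 1.0 if ca == cb else 0.0
    dot = sum(ca[w] * cb[w] for w in ca)
    na = np.sqrt(sum(v * v for v in ca.values()))
    nb = np.sqrt(sum(v * v for v in cb.values()))
    return float(dot / (na * nb))


def label_agreement(labels_a: Sequence[str], labels_b: Sequence[str]) -> float:
    """Mean per-topic bag-of-words cosine between two annotators' topic
    labels; 1 iff each topic's two labels use identical word bags."""
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"label sets differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    if not labels_a:
        raise ValueError("empty label sets")
    return float(np.mean([_bow_cosine(a, b) for a, b in zip(labels_a, labels_b)]))
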