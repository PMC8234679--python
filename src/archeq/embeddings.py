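"""Word embeddings: skip-gram training, word2vec text I/O, similarity queries.

The synonym miner at the core of query expansion needs only three things
from an embedding model: a vocabulary, one fixed-dimension vector per
token, and cosine similarity.  Training is skip-gram with negative
sampling (SGNS), the standard choice for synonym mining on modest corpora:
words that occur in interchangeable contexts receive nearby vectors, so a
lay term and the professional term it stands in for become each other's
nearest neighbours.

The trainer is a compact numpy implementation of SGNS with a linearly
decaying learning rate and a dynamically shrunk context window, seeded and
single-threaded, so identical inputs yield identical vectors.  Models are
exchanged in the word2vec text format (header line ``<vocab> <dim>``, then
one ``token v1 ... vd`` row per word).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Corpus",
    "EmbeddingModel",
    "Neighbor",
    "train_embeddings",
    "load_word2vec_text",
    "save_word2vec_text",
    "cosine_similarity",
    "nearest_neighbors",
    "phrase_vector",
    "phrase_similarity",
    "load_corpus",
    "save_corpus",
]


@dataclass
class Corpus:
    """An ordered sequence of tokenized sentences."""

    sentences: list[list[str]]

    def __post_init__(self) -> None:
        for sent in self.sentences:
            if any(not tok for tok in sent):
                raise ValueError("corpus contains an empty token")

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self):
        return iter(self.sentences)


def load_corpus(path: str | Path) -> Corpus:
    """Read a corpus file: UTF-8 text, one sentence per line, tokens
    space-delimited."""
    sentences = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            toks = line.split()
            if toks:
                sentences.append(toks)
    return Corpus(sentences)


def save_corpus(corpus: Corpus, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for sent in corpus:
            fh.write(" ".join(sent) + "\n")


@dataclass(frozen=True)
class Neighbor:
    """A vocabulary word and its cosine similarity to the query token."""

    token: str
    similarity: float


@dataclass
class EmbeddingModel:
    """Vocabulary plus a |V| x d real vector matrix.

    ``vocabulary`` maps each token to its row in ``vectors``.  All vectors
    are finite and share the same dimension.
    """

    vocabulary: dict[str, int]
    vectors: np.ndarray
    train_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D matrix")
        if len(self.vocabulary) != self.vectors.shape[0]:
            raise ValueError(
                f"vocabulary size {len(self.vocabulary)} does not match "
                f"vector rows {self.vectors.shape[0]}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("vectors contain non-finite values")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, token: str) -> bool:
        return token in self.vocabulary

    def __len__(self) -> int:
        return len(self.vocabulary)

    def vector(self, token: str) -> np.ndarray:
        try:
            return self.vectors[self.vocabulary[token]]
        except KeyError:
            raise KeyError(f"token {token!r} not in vocabulary") from None


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def train_embeddings(
    corpus: Corpus,
    dim: int = 100,
    window: int = 5,
    epochs: int = 5,
    min_count: int = 1,
    negative: int = 5,
    seed: int = 0,
    alpha: float = 0.025,
    min_alpha: float = 1e-4,
) -> EmbeddingModel:
    """Train skip-gram-with-negative-sampling embeddings.

    Vocabulary keeps tokens with corpus frequency >= ``min_count``,
    ordered by descending frequency (ties by token) for reproducibility.
    Negative samples are drawn from the unigram distribution raised to the
    3/4 power.  Deterministic for fixed inputs and seed.
    """
    if dim < 2:
        raise ValueError("embedding dimension must be >= 2")
    if len(corpus) == 0:
        raise ValueError("corpus is empty")

    counts: dict[str, int] = {}
    for sent in corpus:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    kept = sorted(
        (tok for tok, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )
    if not kept:
        raise ValueError(
            f"vocabulary is empty after min_count={min_count} filtering"
        )
    vocab = {tok: i for i, tok in enumerate(kept)}
    n_vocab = len(vocab)

    # noise distribution for negative sampling: unigram^0.75
    noise = np.array([counts[tok] for tok in kept], dtype=np.float64) ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    rng = np.random.default_rng(seed)
    w_in = (rng.random((n_vocab, dim)) - 0.5) / dim
    w_out = np.zeros((n_vocab, dim))

    encoded = [
        np.array([vocab[t] for t in sent if t in vocab], dtype=np.intp)
        for sent in corpus
    ]
    encoded = [s for s in encoded if len(s) >= 2]
    total_centers = max(1, epochs * sum(len(s) for s in encoded))
    processed = 0

    for _epoch in range(epochs):
        for sent in encoded:
            n = len(sent)
            for i in range(n):
                lr = alpha - (alpha - min_alpha) * (processed / total_centers)
                processed += 1
                b = int(rng.integers(1, window + 1))
                lo, hi = max(0, i - b), min(n, i + b + 1)
                ctx = np.concatenate([sent[lo:i], sent[i + 1 : hi]])
                if len(ctx) == 0:
                    continue
                m = len(ctx)
                if negative > 0:
                    draws = rng.random(m * negative)
                    negs = np.searchsorted(noise_cdf, draws)
                    targets = np.concatenate([ctx, negs])
                else:
                    targets = ctx
                labels = np.zeros(len(targets))
                labels[:m] = 1.0
                center = sent[i]
                w = w_in[center]
                out = w_out[targets]
                g = (labels - _sigmoid(out @ w)) * lr
                grad_w = g @ out
                np.add.at(w_out, targets, g[:, None] * w)
                w_in[center] = w + grad_w

    return EmbeddingModel(
        vocabulary=vocab,
        vectors=w_in,
        train_params={
            "dim": dim,
            "window": window,
            "epochs": epochs,
            "min_count": min_count,
            "negative": negative,
            "seed": seed,
        },
    )


def save_word2vec_text(model: EmbeddingModel, path: str | Path) -> None:
    """Write the model in word2vec text format at 6 significant digits."""
    order = sorted(model.vocabulary, key=model.vocabulary.__getitem__)
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"{len(model)} {model.dim}\n")
        for tok in order:
            vec = model.vectors[model.vocabulary[tok]]
            fh.write(tok + " " + " ".join(f"{x:.6g}" for x in vec) + "\n")


def load_word2vec_text(path: str | Path) -> EmbeddingModel:
    """Read a word2vec text-format embedding file.

    Raises ``ValueError`` if the header disagrees with the body or any row
    has a ragged vector length.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header {header!r}")
        n_vocab, dim = int(header[0]), int(header[1])
        vocab: dict[str, int] = {}
        vectors = np.empty((n_vocab, dim))
        row = 0
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2:
                continue
            if row >= n_vocab:
                raise ValueError(
                    f"{path}: more rows than the header's {n_vocab} tokens"
                )
            tok, values = parts[0], parts[1:]
            if len(values) != dim:
                raise ValueError(
                    f"{path}:{lineno}: expected {dim} components, got {len(values)}"
                )
            if tok in vocab:
                raise ValueError(f"{path}:{lineno}: duplicate token {tok!r}")
            vocab[tok] = row
            vectors[row] = [float(v) for v in values]
            row += 1
    if row != n_vocab:
        raise ValueError(
            f"{path}: header claims {n_vocab} tokens but file has {row}"
        )
    return EmbeddingModel(vocabulary=vocab, vectors=vectors)


def cosine_similarity(model: EmbeddingModel, a: str, b: str) -> float:
    """Cosine of the angle between two vocabulary tokens' vectors."""
    va, vb = model.vector(a), model.vector(b)
    return _cosine(va, vb)


def _cosine(va: np.ndarray, vb: np.ndarray) -> float:
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0))


def nearest_neighbors(model: EmbeddingModel, token: str, n: int) -> list[Neighbor]:
    """Top-``n`` vocabulary neighbours of ``token`` by cosine similarity.

    The query token itself is excluded; ties in similarity break by
    ascending token text.  Returns min(n, |V|-1) neighbours.
    """
    if n < 1:
        raise ValueError("n must be positive")
    query = model.vector(token)
    qnorm = np.linalg.norm(query)
    norms = np.linalg.norm(model.vectors, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = model.vectors @ query / np.where(norms * qnorm == 0, 1.0, norms * qnorm)
    sims = np.clip(np.nan_to_num(sims), -1.0, 1.0)
    order = sorted(
        (tok for tok in model.vocabulary if tok != token),
        key=lambda t: (-sims[model.vocabulary[t]], t),
    )
    return [Neighbor(t, float(sims[model.vocabulary[t]])) for t in order[:n]]


def phrase_vector(model: EmbeddingModel, tokens: Sequence[str]) -> np.ndarray | None:
    """Mean of the vectors of in-vocabulary tokens.

    Returns ``None`` (the "undefined" marker) when every token is out of
    vocabulary; raises on an empty token list.  At the ranking layer an
    undefined phrase scores similarity 0 with anything.
    """
    if len(tokens) == 0:
        raise ValueError("token list is empty")
    rows = [model.vocabulary[t] for t in tokens if t in model.vocabulary]
    if not rows:
        return None
    return model.vectors[rows].mean(axis=0)


def phrase_similarity(
    model: EmbeddingModel, tokens_a: Sequence[str], tokens_b: Sequence[str]
) -> float:
    """Cosine between two phrase vectors; 0 if either is undefined."""
    va = phrase_vector(model, tokens_a)
    vb = phrase_vector(model, tokens_b)
    if va is None or vb is None:
        return 0.0
    return _cosine(va, vb)
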