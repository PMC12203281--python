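"""Semantic representation: word vectors, sentence vectors, text matching.

Word vectors are trained by skip-gram with negative sampling (plain numpy,
fully seeded).  A sentence vector is the weighted mean of its in-vocabulary
token vectors,

    V_s = (sum_i V_i * e_w(i)) / m,

where m counts only in-vocabulary tokens.  The default weight is the
smoothed inverse corpus frequency a / (a + p(token)) with a = 1e-3 (the
smooth-inverse-frequency convention); a uniform-weight option is exposed.
Text matching ranks candidates by the cosine of their sentence vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "WordVectors",
    "SentenceVector",
    "train_word_vectors",
    "sentence_vector",
    "cosine_similarity",
    "match_text",
    "save_word_vectors",
    "load_word_vectors",
]

SIF_A = 1e-3


@dataclass
class WordVectors:
    """A vocabulary with one d-dimensional vector and a corpus frequency
    per token."""

    vocabulary: list
    vectors: np.ndarray  # (|vocab|, d)
    frequencies: np.ndarray  # raw corpus counts, parallel to vocabulary
    seed: int = 0

    def __post_init__(self):
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.vocabulary):
            raise ValueError("one vector per vocabulary token required")
        if self.dim < 1:
            raise ValueError("vector dimension must be >= 1")
        self.index = {t: i for i, t in enumerate(self.vocabulary)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[self.index[token]]

    def relative_frequency(self, token: str) -> float:
        return float(self.frequencies[self.index[token]] / self.frequencies.sum())


@dataclass
class SentenceVector:
    """A pooled sentence representation with its provenance."""

    vector: np.ndarray
    token_count: int          # m: in-vocabulary tokens pooled
    weight_fn: str = "sif"


def train_word_vectors(corpus: Sequence[Sequence[str]], d: int = 64,
                       window: int = 2, negatives: int = 5, epochs: int = 5,
                       seed: int = 0, learning_rate: float = 0.05,
                       min_count: int = 1) -> WordVectors:
    """Skip-gram with negative sampling; deterministic given the seed.

    Every token at or above ``min_count`` receives a vector.  The unigram
    distribution raised to 3/4 drives negative sampling, as is conventional.
    """
    sents = [list(s) for s in corpus if len(s)]
    if not sents:
        raise ValueError("cannot train word vectors on an empty corpus")
    counts: dict[str, int] = {}
    for s in sents:
        for t in s:
            counts[t] = counts.get(t, 0) + 1
    vocab = sorted(t for t, c in counts.items() if c >= min_count)
    if not vocab:
        raise ValueError("no token reaches the frequency floor")
    index = {t: i for i, t in enumerate(vocab)}
    freq = np.array([counts[t] for t in vocab], dtype=float)
    rng = np.random.default_rng(seed)
    w_in = (rng.random((len(vocab), d)) - 0.5) / d
    w_out = np.zeros((len(vocab), d))
    noise = freq ** 0.75
    noise /= noise.sum()
    encoded = [[index[t] for t in s if t in index] for s in sents]
    for _ in range(epochs):
        for sent in encoded:
            for pos, center in enumerate(sent):
                lo = max(0, pos - window)
                for ctx_pos in range(lo, min(len(sent), pos + window + 1)):
                    if ctx_pos == pos:
                        continue
                    ctx = sent[ctx_pos]
                    targets = [(ctx, 1.0)]
                    for neg in rng.choice(len(vocab), size=negatives, p=noise):
                        if neg != ctx:
                            targets.append((int(neg), 0.0))
                    v = w_in[center]
                    grad_v = np.zeros(d)
                    for tgt, label in targets:
                        u = w_out[tgt]
                        score = 1.0 / (1.0 + np.exp(-np.dot(v, u)))
                        g = learning_rate * (label - score)
                        grad_v += g * u
                        w_out[tgt] = u + g * v
                    w_in[center] = v + grad_v
    return WordVectors(vocab, w_in, freq, seed=seed)


def _resolve_weight_fn(weight_fn, wv: WordVectors) -> tuple[Callable[[str], float], str]:
    if weight_fn is None or weight_fn == "sif":
        return (lambda t: SIF_A / (SIF_A + wv.relative_frequency(t)), "sif")
    if weight_fn == "uniform":
        return (lambda t: 1.0, "uniform")
    if callable(weight_fn):
        return weight_fn, getattr(weight_fn, "__name__", "custom")
    raise ValueError(f"unknown weight function {weight_fn!r}")


def sentence_vector(tokens: Sequence[str], word_vectors: WordVectors,
                    weight_fn=None) -> SentenceVector:
    """Weighted mean of in-vocabulary token vectors.

    Out-of-vocabulary tokens are skipped (not zero-imputed) and do not count
    toward m; a sentence with no known token is a coverage error.
    """
    fn, name = _resolve_weight_fn(weight_fn, word_vectors)
    known = [t for t in tokens if t in word_vectors]
    if not known:
        raise ValueError("no token of the sentence is in the vocabulary")
    acc = np.zeros(word_vectors.dim)
    for t in known:
        acc += word_vectors[t] * fn(t)
    return SentenceVector(acc / len(known), len(known), name)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """dot(a, b) / (|a| |b|); symmetric, in [-1, 1]; zero vectors rejected."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have equal dimension")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity of a zero vector is undefined")
    return float(np.dot(a, b) / (na * nb))


def match_text(query_tokens: Sequence[str], candidates: Sequence[Sequence[str]],
               word_vectors: WordVectors, threshold: float = 0.0,
               weight_fn=None) -> list[tuple[int, float]]:
    """Rank candidates by sentence-vector cosine against the query.

    Returns ``(candidate index, score)`` sorted by descending score (stable
    for ties); candidates scoring below the threshold, or with no vocabulary
    coverage, are excluded.
    """
    if not candidates:
        raise ValueError("at least one candidate is required")
    q = sentence_vector(query_tokens, word_vectors, weight_fn)
    scored: list[tuple[int, float]] = []
    for i, cand in enumerate(candidates):
        try:
            c = sentence_vector(cand, word_vectors, weight_fn)
        except ValueError:
            continue
        s = cosine_similarity(q.vector, c.vector)
        if s >= threshold:
            scored.append((i, s))
    scored.sort(key=lambda x: -x[1])
    return scored


# ---------------------------------------------------------------------------
# Persistence (standard text format: header line, then token + floats)
# ---------------------------------------------------------------------------


def save_word_vectors(wv: WordVectors, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(wv.vocabulary)} {wv.dim}\n")
        for t, vec, c in zip(wv.vocabulary, wv.vectors, wv.frequencies):
            floats = " ".join(repr(float(x)) for x in vec)
            fh.write(f"{t} {int(c)} {floats}\n")


def load_word_vectors(path) -> WordVectors:
    with open(path, encoding="utf-8") as fh:
        n, d = map(int, fh.readline().split())
        vocab, freqs, rows = [], [], []
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            vocab.append(parts[0])
            freqs.append(float(parts[1]))
            rows.append([float(x) for x in parts[2:]])
    vectors = np.array(rows)
    if vectors.shape != (n, d):
        raise ValueError("word-vector file header disagrees with its body")
    return WordVectors(vocab, vectors, np.array(freqs))
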