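"""Key named-entity recognition for HICH electronic medical records.

The module has two layers:

* **Functional core** — pure-numpy reference implementations of the building
  blocks: scaled dot-product attention, dilated-convolution receptive fields,
  a single LSTM cell step, and a linear-chain CRF (partition function,
  log-likelihood, Viterbi decoding).  These are the forms the trainable stack
  realizes, exposed so they can be verified directly against brute-force
  oracles.

* **Trainable stack** — a composable sequence labeler covering seven
  variants: IDCNN-CRF, BiLSTM-CRF, BiLSTM-IDCNN-CRF and the same three plus a
  small masked-LM-pretrained transformer encoder in front, ending with
  the transformer-only variant ("bert-crf").  All variants are terminated by
  a CRF layer.  Training runs on the in-repo autodiff engine
  (:mod:`hichkit.autodiff`), float64, CPU, fully seeded.

Entity-level precision/recall/F1 use exact (span, type) matching on the
0-100 scale, with zero denominators defined as 0 (CoNLL convention).
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autodiff import Adam, Tensor, concat, embedding, logsumexp

PAD, UNK, MASK = "<pad>", "<unk>", "<mask>"

# ---------------------------------------------------------------------------
# BIO tags and spans
# ---------------------------------------------------------------------------


def make_tag_alphabet(entity_types: Sequence[str]) -> list[str]:
    """BIO tag list: ``O`` first, then B-/I- per type in the given order."""
    tags = ["O"]
    for t in entity_types:
        tags += [f"B-{t}", f"I-{t}"]
    return tags


def spans_from_bio(tags: Sequence[str]) -> list[tuple[tuple[int, int], str]]:
    """Decode BIO tags into half-open ``((start, end), type)`` spans.

    Lenient on model output: an I- tag that does not continue a span of the
    same type opens a new span (conlleval convention).  Adjacent B- tags of
    the same type yield separate spans.
    """
    spans: list[tuple[tuple[int, int], str]] = []
    start, etype = None, None
    for i, tag in enumerate(tags):
        if tag.startswith("B-") or (tag.startswith("I-") and etype != tag[2:]):
            if start is not None:
                spans.append(((start, i), etype))
            start, etype = i, tag[2:]
        elif tag == "O":
            if start is not None:
                spans.append(((start, i), etype))
            start, etype = None, None
        # I- continuing the open span: nothing to do
    if start is not None:
        spans.append(((start, len(tags)), etype))
    return spans


def ner_metrics(gold: Sequence[set], predicted: Sequence[set]) -> tuple[float, float, float]:
    """Entity-level (P, R, F1) on the 0-100 scale by exact (span, type) match.

    ``gold`` and ``predicted`` are parallel per-document sets of
    ``((start, end), type)`` items.  P = TP/(TP+FP)*100, R = TP/(TP+FN)*100,
    F1 = 2PR/(P+R); any zero denominator yields 0 with a warning.
    """
    if len(gold) != len(predicted):
        raise ValueError("gold and predicted must cover the same documents")
    tp = fp = fn = 0
    for g, p in zip(gold, predicted):
        g, p = set(g), set(p)
        tp += len(g & p)
        fp += len(p - g)
        fn += len(g - p)
    if tp + fp == 0:
        warnings.warn("no predicted entities: precision defined as 0")
        prec = 0.0
    else:
        prec = 100.0 * tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no gold entities: recall defined as 0")
        rec = 0.0
    else:
        rec = 100.0 * tp / (tp + fn)
    f1 = f1_score(prec, rec)
    return prec, rec, f1


def f1_score(p: float, r: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    return 0.0 if p + r == 0 else 2.0 * p * r / (p + r)


# ---------------------------------------------------------------------------
# Functional core: attention
# ---------------------------------------------------------------------------


def attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray, d_k: int) -> np.ndarray:
    """Scaled dot-product attention ``softmax(Q K^T / sqrt(d_k)) V``.

    Each output row is a convex combination of the rows of ``V``; the
    attention weight rows sum to one.
    """
    Q, K, V = (np.asarray(x, dtype=float) for x in (Q, K, V))
    if K.shape[0] != V.shape[0]:
        raise ValueError("K and V must have the same number of rows")
    if Q.shape[1] != K.shape[1]:
        raise ValueError("Q and K must share the key dimension")
    scores = Q @ K.T / np.sqrt(float(d_k))
    scores -= scores.max(axis=1, keepdims=True)
    w = np.exp(scores)
    w /= w.sum(axis=1, keepdims=True)
    return w @ V


@dataclass
class AttentionBlock:
    """Projection weights for one multi-head self-attention block."""

    w_query: np.ndarray
    w_key: np.ndarray
    w_value: np.ndarray
    d_k: int
    n_heads: int = 1

    def __post_init__(self):
        if self.d_k <= 0 or self.n_heads <= 0:
            raise ValueError("d_k and n_heads must be positive")
        if self.w_query.shape != self.w_key.shape:
            raise ValueError("query/key projections must agree in shape")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return attention(x @ self.w_query, x @ self.w_key, x @ self.w_value, self.d_k)


# ---------------------------------------------------------------------------
# Functional core: dilated receptive field
# ---------------------------------------------------------------------------


@dataclass
class DilationSchedule:
    """Kernel width and per-layer dilation widths of a dilated conv stack."""

    kernel_width: int = 3
    dilations: tuple[int, ...] = (1, 2, 4)

    def __post_init__(self):
        if self.kernel_width < 1 or self.kernel_width % 2 == 0:
            raise ValueError("kernel width must be odd and positive")
        if any(d < 1 for d in self.dilations):
            raise ValueError("dilation widths must be positive")


def receptive_field(schedule: DilationSchedule, layer: int) -> int:
    """Input positions influencing one output after ``layer`` stacked convs.

    Counted exactly as the size of the input support: each layer convolves
    the current support with its k tap offsets (multiples of the dilation).
    For kernel 3 with dilations doubling 1, 2, 4, ... the support is dense
    and the count is 2^(i+1+1) - 1; for gappy schedules the support count
    can be smaller than its span.
    """
    if layer < 1:
        raise ValueError("layer must be >= 1")
    if layer > len(schedule.dilations):
        raise IndexError("layer exceeds the dilation schedule length")
    half = schedule.kernel_width // 2
    support = {0}
    for d in schedule.dilations[:layer]:
        support = {s + off * d for s in support for off in range(-half, half + 1)}
    return len(support)


# ---------------------------------------------------------------------------
# Functional core: LSTM cell
# ---------------------------------------------------------------------------


@dataclass
class RecurrentCell:
    """One LSTM cell: gate weights act on the concatenation [h_prev, u_t].

    The forget, input and output gates pass through the logistic function
    and so lie strictly in (0, 1); the candidate state and the output pass
    through tanh.
    """

    w_f: np.ndarray
    w_i: np.ndarray
    w_o: np.ndarray
    w_c: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.w_f.shape[0]


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def lstm_step(cell: RecurrentCell, u_t: np.ndarray, h_prev: np.ndarray,
              c_prev: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM update.

    f_t = sigma_g(W_f [h_{t-1}, u_t] + b_f), likewise i_t and O_t;
    C~_t = tanh(W_c [h_{t-1}, u_t] + b_c);
    C_t = f_t * C_{t-1} + i_t * C~_t;  h_t = O_t * tanh(C_t).
    """
    u_t, h_prev, c_prev = (np.asarray(x, dtype=float) for x in (u_t, h_prev, c_prev))
    hu = np.concatenate([h_prev, u_t])
    if cell.w_f.shape[1] != hu.shape[0]:
        raise ValueError("cell weight width does not match [h_prev, u_t]")
    f = _logistic(cell.w_f @ hu + cell.b_f)
    i = _logistic(cell.w_i @ hu + cell.b_i)
    o = _logistic(cell.w_o @ hu + cell.b_o)
    c_tilde = np.tanh(cell.w_c @ hu + cell.b_c)
    c_t = f * c_prev + i * c_tilde
    h_t = o * np.tanh(c_t)
    return h_t, c_t


# ---------------------------------------------------------------------------
# Functional core: linear-chain CRF
# ---------------------------------------------------------------------------


@dataclass
class CrfParams:
    """Linear-chain CRF parameters over a tag alphabet of size L.

    The per-position score W_t(y_{t-1}, y_t | X) decomposes into the
    emission score of y_t plus the transition score y_{t-1} -> y_t, i.e. a
    weighted sum of indicator features; learned start and stop vectors
    supply the boundary terms at t = 1 and t = n + 1.
    """

    transitions: np.ndarray  # (L, L), [from, to]
    start: np.ndarray        # (L,)
    stop: np.ndarray         # (L,)

    @property
    def num_tags(self) -> int:
        return self.transitions.shape[0]

    @classmethod
    def zeros(cls, num_tags: int) -> "CrfParams":
        return cls(np.zeros((num_tags, num_tags)), np.zeros(num_tags), np.zeros(num_tags))


def _check_emissions(emissions: np.ndarray, params: CrfParams) -> np.ndarray:
    emissions = np.asarray(emissions, dtype=float)
    if emissions.ndim != 2 or emissions.shape[0] == 0:
        raise ValueError("emissions must be a non-empty (length, tags) matrix")
    if emissions.shape[1] != params.num_tags:
        raise ValueError("emissions width must equal the tag alphabet size")
    return emissions


def crf_path_score(emissions: np.ndarray, params: CrfParams,
                   tags: Sequence[int]) -> float:
    """Unnormalized log score of one tag path, boundary terms included."""
    emissions = _check_emissions(emissions, params)
    tags = list(tags)
    if len(tags) != emissions.shape[0]:
        raise ValueError("tags length must equal emissions length")
    if any(t < 0 or t >= params.num_tags for t in tags):
        raise ValueError("tag outside the alphabet")
    s = params.start[tags[0]] + emissions[0, tags[0]]
    for t in range(1, len(tags)):
        s += params.transitions[tags[t - 1], tags[t]] + emissions[t, tags[t]]
    return float(s + params.stop[tags[-1]])


def crf_partition(emissions: np.ndarray, params: CrfParams) -> float:
    """log R(X): log-sum over all tag sequences of exponentiated path scores.

    Computed by the forward recursion in log space; for all-zero scores over
    L tags and length n this is n * log L.
    """
    emissions = _check_emissions(emissions, params)
    from scipy.special import logsumexp as lse
    alpha = params.start + emissions[0]
    for t in range(1, emissions.shape[0]):
        alpha = lse(alpha[:, None] + params.transitions, axis=0) + emissions[t]
    return float(lse(alpha + params.stop))


def crf_log_likelihood(emissions: np.ndarray, params: CrfParams,
                       tags: Sequence[int]) -> float:
    """log P(Y|X) = path score - log R(X); always <= 0."""
    return crf_path_score(emissions, params, tags) - crf_partition(emissions, params)


def viterbi_decode(emissions: np.ndarray, params: CrfParams) -> list[int]:
    """Maximum-score tag path.

    Ties are broken toward the lowest tag index at the latest differing
    position, which is what first-argmax backpointers combined with a
    first-argmax final state produce.
    """
    emissions = _check_emissions(emissions, params)
    n, L = emissions.shape
    score = params.start + emissions[0]
    back = np.zeros((n, L), dtype=int)
    for t in range(1, n):
        cand = score[:, None] + params.transitions  # (from, to)
        back[t] = np.argmax(cand, axis=0)
        score = cand[back[t], np.arange(L)] + emissions[t]
    score = score + params.stop
    best = int(np.argmax(score))
    path = [best]
    for t in range(n - 1, 0, -1):
        best = int(back[t, best])
        path.append(best)
    return path[::-1]


# ---------------------------------------------------------------------------
# Trainable stack: vocabulary and featurization
# ---------------------------------------------------------------------------


class Vocab:
    """Token-to-id mapping with pad/unk/mask specials, frozen at build time."""

    def __init__(self, tokens: Sequence[str]):
        self.itos = [PAD, UNK, MASK] + sorted(set(tokens))
        self.stoi = {t: i for i, t in enumerate(self.itos)}

    def __len__(self) -> int:
        return len(self.itos)

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        unk = self.stoi[UNK]
        return np.array([self.stoi.get(t, unk) for t in tokens], dtype=int)


def _pad_batch(seqs: list[np.ndarray], pad_value: int = 0) -> tuple[np.ndarray, np.ndarray]:
    T = max(len(s) for s in seqs)
    ids = np.full((len(seqs), T), pad_value, dtype=int)
    mask = np.zeros((len(seqs), T))
    for i, s in enumerate(seqs):
        ids[i, :len(s)] = s
        mask[i, :len(s)] = 1.0
    return ids, mask


# ---------------------------------------------------------------------------
# Trainable stack: layers
# ---------------------------------------------------------------------------


def _init(rng: np.random.Generator, *shape: int, scale: float = 0.1) -> Tensor:
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class _Layer:
    def params(self) -> list[Tensor]:
        raise NotImplementedError


class TransformerEncoder(_Layer):
    """Small pre-norm-free transformer encoder (the masked-LM-pretrainable
    contextual encoder in front of the task stacks)."""

    def __init__(self, vocab_size: int, dim: int, n_layers: int, n_heads: int,
                 max_len: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.dim, self.n_heads, self.n_layers = dim, n_heads, n_layers
        self.tok = _init(rng, vocab_size, dim)
        self.pos = _init(rng, max_len, dim)
        self.layers = []
        for _ in range(n_layers):
            lay = {
                "wq": _init(rng, dim, dim), "wk": _init(rng, dim, dim),
                "wv": _init(rng, dim, dim), "wo": _init(rng, dim, dim),
                "w1": _init(rng, dim, 2 * dim), "b1": Tensor(np.zeros(2 * dim), requires_grad=True),
                "w2": _init(rng, 2 * dim, dim), "b2": Tensor(np.zeros(dim), requires_grad=True),
                "g1": Tensor(np.ones(dim), requires_grad=True), "c1": Tensor(np.zeros(dim), requires_grad=True),
                "g2": Tensor(np.ones(dim), requires_grad=True), "c2": Tensor(np.zeros(dim), requires_grad=True),
            }
            self.layers.append(lay)

    def params(self) -> list[Tensor]:
        out = [self.tok, self.pos]
        for lay in self.layers:
            out.extend(lay.values())
        return out

    @staticmethod
    def _layernorm(x: Tensor, g: Tensor, c: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + 1e-6) ** -0.5 * g + c

    def __call__(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        B, T = ids.shape
        h = embedding(self.tok, ids) + self.pos[:T]
        dh = self.dim // self.n_heads
        neg = (1.0 - mask)[:, None, None, :] * -1e9  # bias out padded keys
        for lay in self.layers:
            def split(t: Tensor) -> Tensor:
                return t.reshape(B, T, self.n_heads, dh).swapaxes(1, 2)
            q, k, v = split(h @ lay["wq"]), split(h @ lay["wk"]), split(h @ lay["wv"])
            scores = q @ k.swapaxes(2, 3) * (dh ** -0.5) + neg
            w = (scores - logsumexp(scores, axis=3, keepdims=True)).exp()
            att = (w @ v).swapaxes(1, 2).reshape(B, T, self.dim) @ lay["wo"]
            h = self._layernorm(h + att, lay["g1"], lay["c1"])
            ff = (h @ lay["w1"] + lay["b1"]).relu() @ lay["w2"] + lay["b2"]
            h = self._layernorm(h + ff, lay["g2"], lay["c2"])
        return h


class IDCNNEncoder(_Layer):
    """Stack of dilated width-3 convolutions with ReLU and residual input."""

    def __init__(self, in_dim: int, dim: int, dilations: Sequence[int],
                 rng: np.random.Generator):
        self.dim = dim
        self.dilations = tuple(dilations)
        self.w_in = _init(rng, in_dim, dim)
        self.kernels = []
        for _ in self.dilations:
            self.kernels.append({
                "w": [_init(rng, dim, dim) for _ in range(3)],
                "b": Tensor(np.zeros(dim), requires_grad=True),
            })

    def params(self) -> list[Tensor]:
        out = [self.w_in]
        for k in self.kernels:
            out.extend(k["w"])
            out.append(k["b"])
        return out

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        B, T, _ = x.shape
        h = x @ self.w_in
        m = mask[:, :, None]
        for d, ker in zip(self.dilations, self.kernels):
            h = h * m  # zero out pads so dilated taps see no pad content
            zpad = Tensor(np.zeros((B, d, self.dim)))
            hp = concat([zpad, h, zpad], axis=1)
            y = hp[:, 0:T] @ ker["w"][0] + hp[:, d:T + d] @ ker["w"][1] \
                + hp[:, 2 * d:T + 2 * d] @ ker["w"][2] + ker["b"]
            h = (y + h).relu()
        return h


class BiLSTMEncoder(_Layer):
    """Bidirectional LSTM; outputs the concatenated direction states."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.cells = {}
        for d in ("fwd", "bwd"):
            self.cells[d] = {
                g: _init(rng, in_dim + hidden, hidden) for g in ("wf", "wi", "wo", "wc")
            }
            self.cells[d].update({
                g: Tensor(np.zeros(hidden), requires_grad=True) for g in ("bf", "bi", "bo", "bc")
            })

    def params(self) -> list[Tensor]:
        return [t for c in self.cells.values() for t in c.values()]

    def _run(self, x: Tensor, mask: np.ndarray, reverse: bool) -> Tensor:
        B, T, _ = x.shape
        c = self.cells["bwd" if reverse else "fwd"]
        h = Tensor(np.zeros((B, self.hidden)))
        cs = Tensor(np.zeros((B, self.hidden)))
        outs: list[Tensor] = [None] * T
        order = range(T - 1, -1, -1) if reverse else range(T)
        for t in order:
            hu = concat([h, x[:, t]], axis=1)
            f = (hu @ c["wf"] + c["bf"]).sigmoid()
            i = (hu @ c["wi"] + c["bi"]).sigmoid()
            o = (hu @ c["wo"] + c["bo"]).sigmoid()
            ct = (hu @ c["wc"] + c["bc"]).tanh()
            c_new = f * cs + i * ct
            h_new = o * c_new.tanh()
            m = mask[:, t][:, None]
            h = h_new * m + h * (1.0 - m)
            cs = c_new * m + cs * (1.0 - m)
            outs[t] = h.reshape(B, 1, self.hidden)
        return concat(outs, axis=1)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        return concat([self._run(x, mask, False), self._run(x, mask, True)], axis=2)


class CRFLayer(_Layer):
    """Terminal CRF: batched NLL for training, per-sequence Viterbi decode."""

    def __init__(self, num_tags: int, rng: np.random.Generator):
        self.num_tags = num_tags
        self.transitions = _init(rng, num_tags, num_tags, scale=0.01)
        self.start = Tensor(np.zeros(num_tags), requires_grad=True)
        self.stop = Tensor(np.zeros(num_tags), requires_grad=True)

    def params(self) -> list[Tensor]:
        return [self.transitions, self.start, self.stop]

    def as_numpy(self) -> CrfParams:
        return CrfParams(self.transitions.data.copy(), self.start.data.copy(),
                         self.stop.data.copy())

    def nll(self, emissions: Tensor, tags: np.ndarray, mask: np.ndarray) -> Tensor:
        B, T, L = emissions.shape
        lengths = mask.sum(axis=1).astype(int)
        bidx = np.arange(B)
        # log partition by masked forward recursion
        alpha = self.start.reshape(1, L) + emissions[:, 0]
        for t in range(1, T):
            new = logsumexp(alpha.reshape(B, L, 1) + self.transitions.reshape(1, L, L),
                            axis=1) + emissions[:, t]
            m = mask[:, t][:, None]
            alpha = new * m + alpha * (1.0 - m)
        log_z = logsumexp(alpha + self.stop.reshape(1, L), axis=1)
        # gold path score
        score = self.start[tags[:, 0]] + emissions[bidx, 0, tags[:, 0]]
        for t in range(1, T):
            m = mask[:, t]
            step = self.transitions[tags[:, t - 1], tags[:, t]] \
                + emissions[bidx, t, tags[:, t]]
            score = score + step * m
        score = score + self.stop[tags[bidx, lengths - 1]]
        return ((log_z - score).sum()) * (1.0 / B)


# ---------------------------------------------------------------------------
# Variant configuration
# ---------------------------------------------------------------------------

VARIANT_NAMES = (
    "idcnn-crf",
    "bilstm-crf",
    "bilstm-idcnn-crf",
    "bert-crf",
    "bert-idcnn-crf",
    "bert-bilstm-crf",
    "bert-idcnn-bilstm-crf",
)


@dataclass
class VariantConfig:
    """Which stacks a labeler variant composes, plus training knobs.

    All seven variants terminate in a CRF; at least one encoder must be on.
    ``order`` controls whether the dilated or the recurrent stack runs first
    when both are enabled.
    """

    use_pretrained_encoder: bool = False
    use_dilated_stack: bool = False
    use_recurrent_stack: bool = True
    order: str = "idcnn-first"  # or "bilstm-first"
    emb_dim: int = 48
    hidden: int = 48
    dilations: tuple[int, ...] = (1, 2)
    encoder_layers: int = 2
    encoder_heads: int = 2
    max_len: int = 160
    learning_rate: float = 0.01
    epochs: int = 10
    batch_size: int = 32
    seed: int = 0
    pretrain_epochs: int = 3
    pretrain_mask_rate: float = 0.15

    def __post_init__(self):
        if not (self.use_pretrained_encoder or self.use_dilated_stack
                or self.use_recurrent_stack):
            raise ValueError("at least one encoder stack must be enabled")
        if self.order not in ("idcnn-first", "bilstm-first"):
            raise ValueError("order must be 'idcnn-first' or 'bilstm-first'")

    @classmethod
    def from_name(cls, name: str, **overrides) -> "VariantConfig":
        name = name.lower()
        if name not in VARIANT_NAMES:
            raise ValueError(f"unknown variant {name!r}; expected one of {VARIANT_NAMES}")
        parts = name.split("-")[:-1]  # strip terminal 'crf'
        kw = dict(
            use_pretrained_encoder="bert" in parts,
            use_dilated_stack="idcnn" in parts,
            use_recurrent_stack="bilstm" in parts,
            order="bilstm-first" if parts and "bilstm" in parts and "idcnn" in parts
                  and parts.index("bilstm") < parts.index("idcnn") else "idcnn-first",
        )
        kw.update(overrides)
        return cls(**kw)

    @property
    def name(self) -> str:
        parts = []
        if self.use_pretrained_encoder:
            parts.append("bert")
        a, b = ("bilstm", "idcnn") if self.order == "bilstm-first" else ("idcnn", "bilstm")
        for p in (a, b):
            if (p == "idcnn" and self.use_dilated_stack) or \
               (p == "bilstm" and self.use_recurrent_stack):
                parts.append(p)
        parts.append("crf")
        return "-".join(parts)


# ---------------------------------------------------------------------------
# Masked-LM pretraining
# ---------------------------------------------------------------------------


class MaskedLMEncoder:
    """A transformer encoder plus vocabulary, pretrained by masked-token
    prediction on a raw token corpus.  ``head`` is the LM output projection
    (kept so masked-token predictions remain probeable)."""

    def __init__(self, vocab: Vocab, encoder: TransformerEncoder,
                 head: Tensor | None = None):
        self.vocab = vocab
        self.encoder = encoder
        self.head = head

    def predict_masked(self, tokens: Sequence[str], position: int) -> str:
        """Most likely vocabulary token for ``position`` when masked."""
        ids = self.vocab.encode(tokens).copy()
        ids[position] = self.vocab.stoi[MASK]
        h = self.encoder(ids[None, :], np.ones((1, len(ids))))
        logits = h.data[0, position] @ self.head.data
        return self.vocab.itos[int(np.argmax(logits))]


def pretrain_masked_lm(corpus: list[list[str]], config: VariantConfig,
                       vocab: Vocab | None = None) -> tuple[MaskedLMEncoder, list[float]]:
    """Pretrain the small transformer encoder by masked-token cross-entropy.

    Deterministic given ``config.seed``.  Returns the encoder with its
    vocabulary and the per-epoch mean training loss trajectory.
    """
    if not corpus or all(len(s) == 0 for s in corpus):
        raise ValueError("masked-LM pretraining needs a non-empty corpus")
    rng = np.random.default_rng(config.seed)
    if vocab is None:
        vocab = Vocab([t for sent in corpus for t in sent])
    enc = TransformerEncoder(len(vocab), config.emb_dim, config.encoder_layers,
                             config.encoder_heads, config.max_len, rng)
    head = _init(rng, config.emb_dim, len(vocab))
    opt = Adam(enc.params() + [head], lr=config.learning_rate)
    seqs = [vocab.encode(s)[:config.max_len] for s in corpus if len(s)]
    mask_id = vocab.stoi[MASK]
    losses: list[float] = []
    order = np.arange(len(seqs))
    for _ in range(config.pretrain_epochs):
        rng.shuffle(order)
        total, count = 0.0, 0
        for lo in range(0, len(seqs), config.batch_size):
            batch = [seqs[i] for i in order[lo:lo + config.batch_size]]
            ids, mask = _pad_batch(batch)
            corrupt = ids.copy()
            sel = (rng.random(ids.shape) < config.pretrain_mask_rate) & (mask > 0)
            if not sel.any():  # guarantee at least one target
                i = int(rng.integers(len(batch)))
                sel[i, int(rng.integers(len(batch[i])))] = True
            corrupt[sel] = mask_id
            h = enc(corrupt, mask)
            logits = h @ head
            logp = logits - logsumexp(logits, axis=2, keepdims=True)
            bi, ti = np.nonzero(sel)
            nll = -(logp[bi, ti, ids[sel]].sum()) * (1.0 / sel.sum())
            opt.zero_grad()
            nll.backward()
            opt.step()
            total += float(nll.data) * sel.sum()
            count += sel.sum()
        losses.append(total / count)
    return MaskedLMEncoder(vocab, enc, head), losses


# ---------------------------------------------------------------------------
# The sequence labeler
# ---------------------------------------------------------------------------


class SequenceLabeler:
    """A composed variant: [transformer] -> [IDCNN] -> [BiLSTM] -> linear -> CRF."""

    def __init__(self, config: VariantConfig, vocab: Vocab, tag_alphabet: list[str],
                 pretrained: MaskedLMEncoder | None = None):
        self.config = config
        self.vocab = vocab
        self.tags = list(tag_alphabet)
        rng = np.random.default_rng(config.seed + 1)
        d = config.emb_dim
        self.encoder: TransformerEncoder | None = None
        self.emb: Tensor | None = None
        if config.use_pretrained_encoder:
            if pretrained is not None:
                self.encoder = pretrained.encoder
                self.vocab = pretrained.vocab
            else:
                self.encoder = TransformerEncoder(len(vocab), d, config.encoder_layers,
                                                  config.encoder_heads, config.max_len, rng)
        else:
            self.emb = _init(rng, len(vocab), d)
        width = d
        self.stacks: list[tuple[str, _Layer]] = []
        names = ("bilstm", "idcnn") if config.order == "bilstm-first" else ("idcnn", "bilstm")
        for name in names:
            if name == "idcnn" and config.use_dilated_stack:
                lay = IDCNNEncoder(width, d, config.dilations, rng)
                width = d
                self.stacks.append((name, lay))
            elif name == "bilstm" and config.use_recurrent_stack:
                lay = BiLSTMEncoder(width, config.hidden, rng)
                width = 2 * config.hidden
                self.stacks.append((name, lay))
        self.proj = _init(rng, width, len(self.tags))
        self.proj_b = Tensor(np.zeros(len(self.tags)), requires_grad=True)
        self.crf = CRFLayer(len(self.tags), rng)

    def params(self) -> list[Tensor]:
        out: list[Tensor] = []
        if self.encoder is not None:
            out.extend(self.encoder.params())
        if self.emb is not None:
            out.append(self.emb)
        for _, lay in self.stacks:
            out.extend(lay.params())
        out.extend([self.proj, self.proj_b])
        out.extend(self.crf.params())
        return out

    def emissions(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        if self.encoder is not None:
            h = self.encoder(ids, mask)
        else:
            h = embedding(self.emb, ids)
        for _, lay in self.stacks:
            h = lay(h, mask)
        return h @ self.proj + self.proj_b

    def loss(self, ids: np.ndarray, tags: np.ndarray, mask: np.ndarray) -> Tensor:
        return self.crf.nll(self.emissions(ids, mask), tags, mask)

    def predict(self, tokens: Sequence[str]) -> list[str]:
        """Viterbi-decoded BIO tags for one token sequence."""
        n = len(tokens)
        ids = self.vocab.encode(tokens[:self.config.max_len])[None, :]
        mask = np.ones_like(ids, dtype=float)
        emis = self.emissions(ids, mask).data[0]
        path = viterbi_decode(emis, self.crf.as_numpy())
        out = [self.tags[i] for i in path]
        return out + ["O"] * (n - len(out))

    # -- persistence --------------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        for p, a in zip(self.params(), arrays):
            p.data = a.copy()

    def save(self, path) -> None:
        manifest = {
            "format_version": 1,
            "variant": self.config.name,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.config.__dict__.items()},
            "tags": self.tags,
            "vocab": self.vocab.itos,
        }
        arrays = {f"p{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(path, manifest=json.dumps(manifest), **arrays)

    @classmethod
    def load(cls, path) -> "SequenceLabeler":
        with np.load(path if str(path).endswith(".npz") else str(path) + ".npz",
                     allow_pickle=False) as z:
            manifest = json.loads(str(z["manifest"]))
            arrays = [z[f"p{i}"] for i in range(len(z.files) - 1)]
        cfg_d = manifest["config"]
        cfg_d["dilations"] = tuple(cfg_d["dilations"])
        config = VariantConfig(**cfg_d)
        vocab = Vocab([])
        vocab.itos = manifest["vocab"]
        vocab.stoi = {t: i for i, t in enumerate(vocab.itos)}
        model = cls(config, vocab, manifest["tags"])
        model.load_state_arrays(arrays)
        return model


def train_ner(train_docs, dev_docs, variant: VariantConfig,
              pretrained: MaskedLMEncoder | None = None):
    """Train a labeler variant; return (model, per-epoch dev metric trace).

    Documents are :class:`hichkit.emr_synth.AnnotatedDocument`-like objects
    with ``tokens`` and ``tags``.  The trace records dev precision and recall
    per epoch; the checkpoint with the best dev F1 is retained.  With zero
    epochs the initialized model is returned unchanged.
    """
    alphabet = sorted({t for d in train_docs for t in d.tags},
                      key=lambda t: ("" if t == "O" else t[2:], t[:1]))
    for d in dev_docs:
        bad = set(d.tags) - set(alphabet)
        if bad:
            raise ValueError(
                f"document {d.doc_id} uses tags outside the training alphabet: {bad}")
    if "O" in alphabet:
        alphabet = ["O"] + [t for t in alphabet if t != "O"]
    vocab = Vocab([t for d in train_docs for t in d.tokens])
    if variant.use_pretrained_encoder and pretrained is None:
        pretrained, _ = pretrain_masked_lm([list(d.tokens) for d in train_docs],
                                           variant, vocab=vocab)
    model = SequenceLabeler(variant, vocab, alphabet, pretrained)
    tag_id = {t: i for i, t in enumerate(model.tags)}
    enc_tok = [model.vocab.encode(d.tokens)[:variant.max_len] for d in train_docs]
    enc_tag = [np.array([tag_id[t] for t in d.tags[:variant.max_len]]) for d in train_docs]
    opt = Adam(model.params(), lr=variant.learning_rate)
    rng = np.random.default_rng(variant.seed + 2)
    trace: list[dict] = []
    best = (model.state_arrays(), -1.0)
    order = np.arange(len(enc_tok))
    for epoch in range(variant.epochs):
        rng.shuffle(order)
        ep_loss = 0.0
        for lo in range(0, len(order), variant.batch_size):
            sel = order[lo:lo + variant.batch_size]
            ids, mask = _pad_batch([enc_tok[i] for i in sel])
            tags, _ = _pad_batch([enc_tag[i] for i in sel])
            loss = model.loss(ids, tags, mask)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data) * len(sel)
        p, r, f1 = evaluate_ner(model, dev_docs)
        trace.append({"epoch": epoch, "loss": ep_loss / len(order),
                      "precision": p, "recall": r, "f1": f1})
        if f1 > best[1]:
            best = (model.state_arrays(), f1)
    model.load_state_arrays(best[0])
    return model, trace


def extract_entities(model: SequenceLabeler, document) -> list[tuple[tuple[int, int], str]]:
    """Decode a document into non-overlapping ``((start, end), type)`` spans."""
    tokens = list(document.tokens) if hasattr(document, "tokens") else list(document)
    if not tokens:
        return []
    return spans_from_bio(model.predict(tokens))


def evaluate_ner(model: SequenceLabeler, docs) -> tuple[float, float, float]:
    """Entity-level (P, R, F1) of a model over annotated documents."""
    gold = [set(spans_from_bio(d.tags)) for d in docs]
    pred = [set(extract_entities(model, d)) for d in docs]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ner_metrics(gold, pred)
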