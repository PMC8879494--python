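"""Residue-level word embeddings.

Protein sequences are treated as sentences whose words are single amino
acids.  A shallow word2vec model (CBOW or skip-gram, trained by stochastic
gradient descent on the negative-sampling objective with a linearly decaying
learning rate) maps each residue type to a dense vector; the trained table
acts as a semantic dictionary for featurizing sequence windows.

The SGD loop is compiled with numba; the same per-example loss/gradient
math is exposed as plain NumPy functions (``cbow_loss``/``cbow_gradients``,
``skipgram_loss``/``skipgram_gradients``) so it can be checked against
finite differences.

Determinism: training is sequential (single worker) and every random draw
comes from an explicitly seeded generator, so a fixed seed reproduces the
dictionary bit for bit.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .seqio import ProteinChain

CBOW = "cbow"
SKIPGRAM = "skipgram"


@dataclass(frozen=True)
class EmbeddingParams:
    """Word2vec training parameters.

    Defaults follow the predictor's final configuration: CBOW structure,
    25-dimensional vectors, context window 5, 5 negative samples, 200
    epochs, one worker.
    """

    structure: str = CBOW
    dim: int = 25
    window: int = 5
    negative: int = 5
    epochs: int = 200
    seed: int = 1
    initial_lr: float = 0.025
    min_lr: float = 1e-4
    noise_exponent: float = 0.75

    def __post_init__(self) -> None:
        if self.structure not in (CBOW, SKIPGRAM):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.dim < 1 or self.window < 1 or self.epochs < 1 or self.negative < 0:
            raise ValueError("invalid embedding parameters")


@dataclass
class SemanticDictionary:
    """Trained token -> vector table.

    Out-of-vocabulary tokens (notably the padding token 'X', which never
    occurs in a raw corpus) map to the all-zero vector: padding is
    semantically neutral.
    """

    vocab: list[str]
    vectors: np.ndarray
    params: EmbeddingParams
    loss_history: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.shape[0] != len(self.vocab):
            raise ValueError("vector rows must align with vocab")
        if not np.isfinite(self.vectors).all():
            raise ValueError("non-finite embedding vectors")
        self._index = {t: i for i, t in enumerate(self.vocab)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, token: str) -> np.ndarray:
        """Embedding of ``token``; zero vector for out-of-vocabulary tokens."""
        i = self._index.get(token)
        if i is None:
            return np.zeros(self.dim)
        return self.vectors[i]

    def lookup_table(self, alphabet: str) -> np.ndarray:
        """(len(alphabet), dim) matrix of embeddings in alphabet order, with
        zero rows for out-of-vocabulary letters."""
        return np.stack([self.vector(c) for c in alphabet])

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "vocab": list(self.vocab),
            "vectors": self.vectors.tolist(),
            "params": asdict(self.params),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SemanticDictionary":
        return cls(list(doc["vocab"]), np.array(doc["vectors"]), EmbeddingParams(**doc["params"]))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for tok, vec in zip(self.vocab, self.vectors):
                fh.write(tok + "\t" + "\t".join(repr(float(v)) for v in vec) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, params: EmbeddingParams | None = None) -> "SemanticDictionary":
        vocab, rows = [], []
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                vocab.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(vocab, np.array(rows), params or EmbeddingParams(dim=len(rows[0])))


def tokenize_corpus(chains: Iterable[ProteinChain]) -> list[list[str]]:
    """One sentence per chain; each residue is a word."""
    return [list(ch.sequence) for ch in chains]


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity sum(a_i b_i) / (||a|| ||b||); errors on zero vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine undefined for zero vector")
    return float(a @ b / (na * nb))


# ---------------------------------------------------------------------------
# Per-example negative-sampling loss and analytic gradients (NumPy reference)

def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def cbow_loss(W: np.ndarray, C: np.ndarray, context: Sequence[int], center: int,
              negatives: Sequence[int]) -> float:
    """Negative-sampling loss of one CBOW example.

    ``h`` is the mean of the context rows of ``W``; the center token is the
    positive target and each id in ``negatives`` a noise target.
    """
    h = W[list(context)].mean(axis=0)
    loss = -np.log(_sigmoid(C[center] @ h))
    for o in negatives:
        loss -= np.log(_sigmoid(-(C[o] @ h)))
    return float(loss)


def cbow_gradients(W: np.ndarray, C: np.ndarray, context: Sequence[int], center: int,
                   negatives: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of :func:`cbow_loss`.

    Returns ``(gW, gC)`` of the same shapes as ``W`` and ``C`` (dense, zero
    outside the touched rows).
    """
    context = list(context)
    h = W[context].mean(axis=0)
    gW = np.zeros_like(W)
    gC = np.zeros_like(C)
    gh = np.zeros_like(h)
    for o, label in [(center, 1.0)] + [(o, 0.0) for o in negatives]:
        f = _sigmoid(C[o] @ h)
        gC[o] += (f - label) * h
        gh += (f - label) * C[o]
    for c in context:
        gW[c] += gh / len(context)
    return gW, gC


def skipgram_loss(W: np.ndarray, C: np.ndarray, center: int, context_word: int,
                  negatives: Sequence[int]) -> float:
    """Negative-sampling loss of one skip-gram (center, context word) pair."""
    h = W[center]
    loss = -np.log(_sigmoid(C[context_word] @ h))
    for o in negatives:
        loss -= np.log(_sigmoid(-(C[o] @ h)))
    return float(loss)


def skipgram_gradients(W: np.ndarray, C: np.ndarray, center: int, context_word: int,
                       negatives: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    h = W[center]
    gW = np.zeros_like(W)
    gC = np.zeros_like(C)
    for o, label in [(context_word, 1.0)] + [(o, 0.0) for o in negatives]:
        f = _sigmoid(C[o] @ h)
        gC[o] += (f - label) * h
        gW[center] += (f - label) * C[o]
    return gW, gC


# ---------------------------------------------------------------------------
# Compiled SGD loop

@njit(cache=True, inline="always")
def _rand_u64(state: np.uint64) -> tuple[np.uint64, np.float64]:
    # xorshift64* : deterministic, seedable, good enough for noise sampling
    s = state
    s ^= s >> np.uint64(12)
    s ^= s << np.uint64(25)
    s ^= s >> np.uint64(27)
    x = s * np.uint64(0x2545F4914F6CDD1D)
    return s, np.float64(x >> np.uint64(11)) / np.float64(9007199254740992.0)


@njit(cache=True)
def _train_sgd(tokens, offsets, W, C, noise_cdf, window, negative, epochs,
               initial_lr, min_lr, is_cbow, seed):
    """Sequential negative-sampling SGD over the corpus.

    Returns per-epoch mean loss.  ``noise_cdf`` is the cumulative noise
    distribution over vocabulary ids.
    """
    dim = W.shape[1]
    n_sent = offsets.shape[0] - 1
    n_tokens = tokens.shape[0]
    total = np.float64(epochs) * np.float64(n_tokens)
    processed = 0
    state = np.uint64(seed * np.uint64(2862933555777941757) + np.uint64(3037000493))
    if state == np.uint64(0):
        state = np.uint64(88172645463325252)
    losses = np.zeros(epochs)
    h = np.zeros(dim)
    gh = np.zeros(dim)
    for ep in range(epochs):
        ep_loss = 0.0
        for s in range(n_sent):
            lo, hi = offsets[s], offsets[s + 1]
            for t in range(lo, hi):
                lr = initial_lr * (1.0 - np.float64(processed) / total)
                if lr < min_lr:
                    lr = min_lr
                processed += 1
                center = tokens[t]
                c0 = t - window
                if c0 < lo:
                    c0 = lo
                c1 = t + window + 1
                if c1 > hi:
                    c1 = hi
                m = (c1 - c0) - 1  # context size excluding the center
                if m <= 0:
                    continue
                if is_cbow:
                    for d in range(dim):
                        h[d] = 0.0
                        gh[d] = 0.0
                    for j in range(c0, c1):
                        if j == t:
                            continue
                        for d in range(dim):
                            h[d] += W[tokens[j], d]
                    for d in range(dim):
                        h[d] /= m
                    for k in range(negative + 1):
                        if k == 0:
                            target = center
                            label = 1.0
                        else:
                            state, u = _rand_u64(state)
                            target = np.searchsorted(noise_cdf, u)
                            if target == center:
                                continue
                            label = 0.0
                        dot = 0.0
                        for d in range(dim):
                            dot += C[target, d] * h[d]
                        if dot > 30.0:
                            f = 1.0
                        elif dot < -30.0:
                            f = 0.0
                        else:
                            f = 1.0 / (1.0 + np.exp(-dot))
                        if label == 1.0:
                            ep_loss += -np.log(max(f, 1e-12))
                        else:
                            ep_loss += -np.log(max(1.0 - f, 1e-12))
                        g = (label - f) * lr
                        for d in range(dim):
                            gh[d] += g * C[target, d]
                            C[target, d] += g * h[d]
                    for j in range(c0, c1):
                        if j == t:
                            continue
                        for d in range(dim):
                            W[tokens[j], d] += gh[d] / m
                else:  # skip-gram: one update per (center, context word) pair
                    for j in range(c0, c1):
                        if j == t:
                            continue
                        ctx = tokens[j]
                        for d in range(dim):
                            gh[d] = 0.0
                        for k in range(negative + 1):
                            if k == 0:
                                target = ctx
                                label = 1.0
                            else:
                                state, u = _rand_u64(state)
                                target = np.searchsorted(noise_cdf, u)
                                if target == ctx:
                                    continue
                                label = 0.0
                            dot = 0.0
                            for d in range(dim):
                                dot += C[target, d] * W[center, d]
                            if dot > 30.0:
                                f = 1.0
                            elif dot < -30.0:
                                f = 0.0
                            else:
                                f = 1.0 / (1.0 + np.exp(-dot))
                            if label == 1.0:
                                ep_loss += -np.log(max(f, 1e-12))
                            else:
                                ep_loss += -np.log(max(1.0 - f, 1e-12))
                            g = (label - f) * lr
                            for d in range(dim):
                                gh[d] += g * C[target, d]
                                C[target, d] += g * W[center, d]
                        for d in range(dim):
                            W[center, d] += gh[d]
        losses[ep] = ep_loss / n_tokens
    return losses


def train(corpus_sentences: Sequence[Sequence[str]], params: EmbeddingParams) -> SemanticDictionary:
    """Train a semantic dictionary on tokenized sentences.

    Vocabulary is every token seen, ordered by descending frequency (ties by
    token); the noise distribution is the unigram distribution raised to
    ``noise_exponent``.  Input vectors are initialized uniformly in
    ``[-0.5/dim, 0.5/dim)``, output vectors at zero.
    """
    sentences = [list(s) for s in corpus_sentences if len(s) > 0]
    if not sentences:
        raise ValueError("empty corpus")
    counts = Counter(tok for s in sentences for tok in s)
    if len(counts) < 2:
        raise ValueError("vocabulary must contain at least 2 tokens")
    vocab = sorted(counts, key=lambda t: (-counts[t], t))
    index = {t: i for i, t in enumerate(vocab)}

    tokens = np.fromiter(
        (index[t] for s in sentences for t in s), dtype=np.int64,
        count=sum(len(s) for s in sentences),
    )
    offsets = np.zeros(len(sentences) + 1, dtype=np.int64)
    np.cumsum([len(s) for s in sentences], out=offsets[1:])

    freq = np.array([counts[t] for t in vocab], dtype=float)
    noise = freq ** params.noise_exponent
    noise_cdf = np.cumsum(noise / noise.sum())
    noise_cdf[-1] = 1.0 + 1e-12  # guard searchsorted at u ~ 1

    rng = np.random.default_rng(params.seed)
    W = (rng.random((len(vocab), params.dim)) - 0.5) / params.dim
    C = np.zeros((len(vocab), params.dim))

    losses = _train_sgd(
        tokens, offsets, W, C, noise_cdf,
        params.window, params.negative, params.epochs,
        params.initial_lr, params.min_lr,
        params.structure == CBOW, np.uint64(params.seed % (2 ** 63 - 1) + 1),
    )
    return SemanticDictionary(vocab, W, params, loss_history=losses)
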