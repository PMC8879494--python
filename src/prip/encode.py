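"""Segment featurization.

The primary encoder concatenates the semantic-dictionary vectors of the
``2n+1`` tokens of a window, giving a ``(2n+1) * dim`` feature vector per
residue ('X' and other out-of-vocabulary tokens contribute a zero block).
Three classical composition encoders are provided as baselines:

* AAC  - amino-acid composition (20 frequencies),
* DPC  - dipeptide composition (400 ordered-pair frequencies),
* CKSAAPGP - composition of k-spaced amino-acid group pairs over five
  physicochemical groups, k = 0..3 (4 blocks of 25 frequencies = 100).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .embed import SemanticDictionary
from .seqio import ALPHABET, STANDARD_AA
from .windows import Segment, segment_token_ids

#: five physicochemical groups used by CKSAAPGP
GROUPS = {
    "aliphatic": "GAVLMI",
    "aromatic": "FYW",
    "positive": "KRH",
    "negative": "DE",
    "uncharged": "STCPNQ",
}
GROUP_NAMES = list(GROUPS)
_GROUP_OF = {aa: gi for gi, g in enumerate(GROUPS.values()) for aa in g}
_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}


@dataclass
class EncodedDataset:
    """Feature matrix + labels for a set of segments."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    encoder_tag: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int8)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X rows must match y length")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match X columns")
        if not np.isfinite(self.X).all():
            raise ValueError("features contain NaN/Inf")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("label\t" + "\t".join(self.feature_names) + "\n")
            for yi, row in zip(self.y, self.X):
                fh.write(str(int(yi)) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def embed_segment(segment: Segment, dictionary: SemanticDictionary) -> np.ndarray:
    """Concatenate the dictionary vectors of the segment's tokens in order."""
    return np.concatenate([dictionary.vector(t) for t in segment.tokens])


def encode_segments(
    segments: Sequence[Segment], dictionary: SemanticDictionary
) -> EncodedDataset:
    """Embed many segments at once (vectorized lookup by token id)."""
    table = dictionary.lookup_table(ALPHABET)
    token_ids = np.array(
        [[ALPHABET.index(t) for t in s.tokens] for s in segments], dtype=np.int64
    )
    n_seg, L = token_ids.shape
    X = table[token_ids].reshape(n_seg, L * dictionary.dim)
    y = np.array([0 if s.label is None else s.label for s in segments], dtype=np.int8)
    names = [f"p{p}_d{d}" for p in range(L) for d in range(dictionary.dim)]
    return EncodedDataset(X, y, names, "embedding")


def encode_chains(chains, n: int, dictionary: SemanticDictionary) -> tuple[np.ndarray, np.ndarray]:
    """Embedding features and labels for every residue of every chain.

    Fast path used by the training/prediction pipeline; rows are in chain
    order then position order.  Labels are -1 where a chain is unlabeled.
    """
    table = dictionary.lookup_table(ALPHABET)
    ids = segment_token_ids(chains, n)
    X = table[ids].reshape(ids.shape[0], (2 * n + 1) * dictionary.dim)
    y = np.concatenate([
        np.full(len(c), -1, dtype=np.int8) if c.labels is None else c.labels
        for c in chains
    ])
    return X, y


# ---------------------------------------------------------------------------
# Composition encoders.  Pairs or positions containing 'X' are skipped and
# excluded from the normalization denominators.

def aac(sequence: str) -> np.ndarray:
    """Amino-acid composition over standard positions; sums to 1."""
    if not sequence:
        raise ValueError("empty sequence")
    v = np.zeros(20)
    for c in sequence:
        i = _AA_INDEX.get(c)
        if i is not None:
            v[i] += 1
    total = v.sum()
    return v / total if total > 0 else v


def dpc(sequence: str) -> np.ndarray:
    """Dipeptide composition: ordered adjacent-pair frequencies; sums to 1."""
    if len(sequence) < 2:
        raise ValueError("sequence shorter than 2")
    v = np.zeros((20, 20))
    for a, b in zip(sequence, sequence[1:]):
        ia, ib = _AA_INDEX.get(a), _AA_INDEX.get(b)
        if ia is not None and ib is not None:
            v[ia, ib] += 1
    total = v.sum()
    v = v / total if total > 0 else v
    return v.ravel()


def cksaapgp(sequence: str, kmax: int = 3) -> np.ndarray:
    """k-spaced group-pair composition for k = 0..kmax.

    For each spacing k the 25 ordered group-pair frequencies over pairs
    ``(i, i+k+1)`` are computed and normalized to sum 1 within the block;
    the ``kmax+1`` blocks are concatenated (default 4 x 25 = 100 features).
    """
    if len(sequence) < kmax + 2:
        raise ValueError(f"sequence shorter than kmax + 2 = {kmax + 2}")
    blocks = []
    for k in range(kmax + 1):
        block = np.zeros((5, 5))
        for i in range(len(sequence) - k - 1):
            ga = _GROUP_OF.get(sequence[i])
            gb = _GROUP_OF.get(sequence[i + k + 1])
            if ga is not None and gb is not None:
                block[ga, gb] += 1
        total = block.sum()
        if total > 0:
            block /= total
        blocks.append(block.ravel())
    return np.concatenate(blocks)


_COMPOSITION = {"aac": (aac, 20), "dpc": (dpc, 400), "cksaapgp": (cksaapgp, 100)}


def encode_segments_composition(segments: Sequence[Segment], encoder: str) -> EncodedDataset:
    """Apply a composition encoder to each segment's token string."""
    fn, dim = _COMPOSITION[encoder]
    X = np.stack([fn(s.tokens) for s in segments])
    y = np.array([0 if s.label is None else s.label for s in segments], dtype=np.int8)
    if encoder == "aac":
        names = list(STANDARD_AA)
    elif encoder == "dpc":
        names = [a + b for a in STANDARD_AA for b in STANDARD_AA]
    else:
        names = [f"k{k}_{a}_{b}" for k in range(4) for a in GROUP_NAMES for b in GROUP_NAMES]
    return EncodedDataset(X, y, names, encoder)
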