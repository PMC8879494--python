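"""Fixed-length, X-padded sequence windows.

Every residue of a chain yields one segment of length ``2n + 1`` centered on
it; positions past either terminus are filled with the padding token 'X'.
Segments whose center residue is an interface residue are positive examples,
all others negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seqio import ALPHABET, PAD, ProteinChain

#: token -> integer id over the 21-letter alphabet; PAD ('X') is id 20
TOKEN_IDS = {c: i for i, c in enumerate(ALPHABET)}
PAD_ID = TOKEN_IDS[PAD]


@dataclass
class Segment:
    """One classification window: ``tokens[n]`` is the residue being judged."""

    chain_id: str
    center_pos: int  # 1-based position of the center residue in its chain
    tokens: str
    label: int | None
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("half-window n must be >= 1")
        if len(self.tokens) != 2 * self.n + 1:
            raise ValueError(
                f"segment length {len(self.tokens)} != 2n+1 = {2 * self.n + 1}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError("label must be 0, 1 or None")


def divide(chain: ProteinChain | str, n: int) -> list[Segment]:
    """Split a chain into one length-``2n+1`` segment per residue.

    The first and last ``n`` segments carry 'X' padding where the window
    extends past the chain termini.  Labels are copied from the chain when
    present, omitted otherwise.  A plain string may be passed instead of a
    chain; its letters are then windowed verbatim (no alphabet mapping).
    """
    if n < 1:
        raise ValueError("half-window n must be >= 1")
    if isinstance(chain, str):
        raw = chain
        chain = ProteinChain.__new__(ProteinChain)
        chain.chain_id, chain.sequence, chain.labels = "", raw, None
    padded = PAD * n + chain.sequence + PAD * n
    out = []
    for i in range(len(chain.sequence)):
        label = None if chain.labels is None else int(chain.labels[i])
        out.append(Segment(chain.chain_id, i + 1, padded[i : i + 2 * n + 1], label, n))
    return out


def segment_token_ids(chains: Sequence[ProteinChain], n: int) -> np.ndarray:
    """All segments of all chains as an (N, 2n+1) int array of token ids.

    Row order matches ``[seg for chain in chains for seg in divide(chain, n)]``.
    """
    rows = []
    for ch in chains:
        ids = np.fromiter((TOKEN_IDS[c] for c in ch.sequence), dtype=np.int64, count=len(ch))
        padded = np.full(len(ch) + 2 * n, PAD_ID, dtype=np.int64)
        padded[n : n + len(ch)] = ids
        idx = np.arange(len(ch))[:, None] + np.arange(2 * n + 1)[None, :]
        rows.append(padded[idx])
    return np.concatenate(rows, axis=0)


def build_dataset(
    chains: Iterable[ProteinChain], n: int
) -> tuple[list[Segment], list[Segment]]:
    """Partition all segments of labeled chains by center label.

    Returns ``(positives, negatives)``; counts are conserved, i.e.
    ``len(pos) + len(neg)`` equals the total residue count.
    """
    pos, neg = [], []
    for ch in chains:
        if ch.labels is None:
            raise ValueError(f"chain {ch.chain_id!r} has no labels")
        for seg in divide(ch, n):
            (pos if seg.label == 1 else neg).append(seg)
    return pos, neg


def disrupt_negatives(
    segments_neg: Sequence[Segment], seed: int, mode: str = "shuffle"
) -> list[Segment]:
    """Disrupt negative segments while keeping labels (and, in the default
    mode, residue composition).

    ``mode="shuffle"`` permutes each segment's own tokens uniformly at
    random; ``mode="replace"`` substitutes each token by a uniform draw from
    the 21-letter alphabet.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    out = []
    for seg in segments_neg:
        if seg.label not in (0, None):
            raise ValueError("disrupt_negatives expects negative segments")
        if mode == "shuffle":
            toks = "".join(rng.permutation(list(seg.tokens)))
        elif mode == "replace":
            toks = "".join(ALPHABET[i] for i in rng.integers(0, len(ALPHABET), len(seg.tokens)))
        else:
            raise ValueError(f"unknown mode {mode!r}")
        out.append(Segment(seg.chain_id, seg.center_pos, toks, seg.label, seg.n))
    return out


def write_segments_tsv(segments: Iterable[Segment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chain_id\tcenter_pos\ttokens\tlabel\n")
        for s in segments:
            lab = "" if s.label is None else str(s.label)
            fh.write(f"{s.chain_id}\t{s.center_pos}\t{s.tokens}\t{lab}\n")
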