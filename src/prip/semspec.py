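"""Semantic-specificity and enrichment analyses.

Two questions are addressed.  First, are the learned residue-residue
semantic relations specific to the corpus of RNA-binding sequences, or
would random sequences produce the same relations?  An ensemble of
embeddings trained on the real corpus (varying epochs) is compared, pair by
pair, against an ensemble trained on corpora with 40-55% of residues
randomly altered, using a two-sided equal-variance two-sample t-test on the
cosine similarities.  Second, which residues are enriched or depleted at
each window position of interface-centered segments relative to
non-interface segments?  A two-proportion z-test per (position, residue)
provides the calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from . import embed
from .embed import EmbeddingParams, SemanticDictionary, cosine
from .seqio import STANDARD_AA, PAD, ProteinChain
from .windows import Segment

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}


@dataclass
class RelationMatrix:
    """20 x 20 symmetric matrix of pairwise cosine similarities."""

    values: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (20, 20):
            raise ValueError("relation matrix must be 20 x 20")

    def to_tsv(self, path: str | Path) -> None:
        _write_matrix_tsv(self.values, path)


@dataclass
class PValueMatrix:
    """20 x 20 matrix of two-sided p-values; the diagonal is NaN."""

    values: np.ndarray
    alpha: float = 0.05

    def significant_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(20):
            for j in range(i + 1, 20):
                if self.values[i, j] < self.alpha:
                    out.append((STANDARD_AA[i], STANDARD_AA[j]))
        return out

    def to_tsv(self, path: str | Path) -> None:
        _write_matrix_tsv(self.values, path)


def _write_matrix_tsv(values: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(STANDARD_AA) + "\n")
        for aa, row in zip(STANDARD_AA, values):
            fh.write(aa + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def shuffle_corpus(chains: Sequence[ProteinChain], fraction: float, seed: int) -> list[ProteinChain]:
    """Randomly alter a fraction of residues of each chain.

    ``round(fraction * L)`` positions per chain are chosen uniformly without
    replacement; each chosen residue is replaced by a uniform draw from the
    19 other standard residues, so ``fraction=1`` changes every position.
    Labels are dropped (the shuffled corpus is used only for embedding).
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for ch in chains:
        seq = list(ch.sequence)
        n_alter = int(round(fraction * len(seq)))
        for pos in rng.choice(len(seq), size=n_alter, replace=False):
            current = seq[pos]
            choices = [a for a in STANDARD_AA if a != current]
            seq[pos] = choices[rng.integers(0, len(choices))]
        out.append(ProteinChain(ch.chain_id, "".join(seq)))
    return out


def relation_matrix(dictionary: SemanticDictionary, source: str = "") -> RelationMatrix:
    """Pairwise cosines between the embeddings of the 20 standard residues."""
    missing = [aa for aa in STANDARD_AA if aa not in dictionary.vocab]
    if missing:
        raise ValueError(f"residues missing from vocabulary: {missing}")
    V = np.stack([dictionary.vector(aa) for aa in STANDARD_AA])
    norms = np.linalg.norm(V, axis=1)
    M = (V @ V.T) / np.outer(norms, norms)
    np.fill_diagonal(M, 1.0)
    return RelationMatrix(M, source)


def true_ensemble(
    corpus: Sequence[Sequence[str]],
    base_params: EmbeddingParams,
    epochs_list: Sequence[int] = (100, 200, 300, 400),
) -> list[RelationMatrix]:
    """Relation matrices from the real corpus at several epoch settings
    (same seed policy for every member)."""
    from dataclasses import replace

    out = []
    for ep in epochs_list:
        d = embed.train(corpus, replace(base_params, epochs=ep))
        out.append(relation_matrix(d, source=f"true_epochs{ep}"))
    return out


def null_ensemble(
    chains: Sequence[ProteinChain],
    params: EmbeddingParams,
    fractions: Sequence[float] = (0.40, 0.45, 0.50, 0.55),
    seed: int = 0,
) -> list[RelationMatrix]:
    """Relation matrices from corpora with a fraction of residues altered;
    one shuffled corpus per fraction, each trained once."""
    out = []
    for i, frac in enumerate(fractions):
        shuffled = shuffle_corpus(chains, frac, seed + i)
        d = embed.train(embed.tokenize_corpus(shuffled), params)
        out.append(relation_matrix(d, source=f"null_frac{frac}"))
    return out


def seed_ensemble(
    corpus: Sequence[Sequence[str]],
    params: EmbeddingParams,
    seeds: Sequence[int],
) -> list[RelationMatrix]:
    """Relation matrices from the same corpus, varying only the training
    seed (used for null calibration of the t-test)."""
    from dataclasses import replace

    return [
        relation_matrix(embed.train(corpus, replace(params, seed=s)), source=f"seed{s}")
        for s in seeds
    ]


def pvalue_matrix(
    true_ms: Sequence[RelationMatrix],
    null_ms: Sequence[RelationMatrix],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> PValueMatrix:
    """Two-sided two-sample t-test per residue pair.

    For each off-diagonal pair the cosines across the true ensemble are
    tested against those across the null ensemble (pooled-variance Student
    t by default; Welch behind ``equal_var=False``).  Degenerate cases:
    zero variance in both groups gives p = 1 for equal means and p = 0
    otherwise.
    """
    if len(true_ms) < 2 or len(null_ms) < 2:
        raise ValueError("both ensembles must have size >= 2")
    P = np.full((20, 20), np.nan)
    A = np.stack([m.values for m in true_ms])
    B = np.stack([m.values for m in null_ms])
    for i in range(20):
        for j in range(i + 1, 20):
            a, b = A[:, i, j], B[:, i, j]
            if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
                p = 1.0 if a.mean() == b.mean() else 0.0
            else:
                p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
            P[i, j] = P[j, i] = p
    return PValueMatrix(P, alpha)


# ---------------------------------------------------------------------------
# Positional enrichment

@dataclass
class EnrichmentRow:
    position: int  # offset from the window center, -n .. +n
    residue: str
    pos_fraction: float
    neg_fraction: float
    difference: float
    p_value: float
    call: str  # "enriched" | "depleted" | ""


@dataclass
class EnrichmentTable:
    rows: list[EnrichmentRow]
    alpha: float

    def calls(self, position: int | None = None) -> dict[str, str]:
        """residue -> call at a window offset (default: the center)."""
        position = 0 if position is None else position
        return {
            r.residue: r.call for r in self.rows if r.position == position and r.call
        }

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tresidue\tpos_fraction\tneg_fraction\tdifference\tp_value\tcall\n")
            for r in self.rows:
                fh.write(
                    f"{r.position}\t{r.residue}\t{float(r.pos_fraction)!r}"
                    f"\t{float(r.neg_fraction)!r}\t{float(r.difference)!r}"
                    f"\t{float(r.p_value)!r}\t{r.call}\n"
                )


def _occurrence_counts(segments: Sequence[Segment]) -> tuple[np.ndarray, np.ndarray]:
    """(2n+1, 20) residue counts per position, and per-position totals of
    standard (non-X) tokens."""
    L = 2 * segments[0].n + 1
    counts = np.zeros((L, 20))
    totals = np.zeros(L)
    for s in segments:
        for p, tok in enumerate(s.tokens):
            i = _AA_INDEX.get(tok)
            if i is not None:
                counts[p, i] += 1
                totals[p] += 1
    return counts, totals


def positional_enrichment(
    pos_segments: Sequence[Segment],
    neg_segments: Sequence[Segment],
    alpha: float = 0.05,
) -> EnrichmentTable:
    """Per (position, residue) two-proportion z-test between positive and
    negative segments; calls 'enriched'/'depleted' where p < alpha."""
    if not pos_segments or not neg_segments:
        raise ValueError("both segment sets must be non-empty")
    n = pos_segments[0].n
    if any(s.n != n for s in list(pos_segments) + list(neg_segments)):
        raise ValueError("segments must share one window length")
    cp, tp = _occurrence_counts(pos_segments)
    cn, tn = _occurrence_counts(neg_segments)
    rows = []
    for p in range(2 * n + 1):
        for i, aa in enumerate(STANDARD_AA):
            f1 = cp[p, i] / tp[p] if tp[p] else 0.0
            f2 = cn[p, i] / tn[p] if tn[p] else 0.0
            pv = _two_proportion_p(cp[p, i], tp[p], cn[p, i], tn[p])
            call = ""
            if pv < alpha:
                call = "enriched" if f1 > f2 else "depleted"
            rows.append(EnrichmentRow(p - n, aa, f1, f2, f1 - f2, pv, call))
    return EnrichmentTable(rows, alpha)


def _two_proportion_p(x1: float, n1: float, x2: float, n2: float) -> float:
    """Two-sided pooled two-proportion z-test."""
    if n1 == 0 or n2 == 0:
        return 1.0
    p1, p2 = x1 / n1, x2 / n2
    pool = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    if se == 0.0:
        return 1.0 if p1 == p2 else 0.0
    z = (p1 - p2) / se
    return float(2 * stats.norm.sf(abs(z)))


def residue_frequencies(segments: Sequence[Segment]) -> np.ndarray:
    """Counts of the 20 standard residues over all segment tokens
    ('X' excluded); basis of the positive-sample word-frequency table."""
    counts = np.zeros(20)
    for s in segments:
        for tok in s.tokens:
            i = _AA_INDEX.get(tok)
            if i is not None:
                counts[i] += 1
    return counts
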