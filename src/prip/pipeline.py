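"""End-to-end workflows: train, predict, evaluate, cross-validate, scan.

The predictor is assembled from the library modules in the canonical order:
tokenize the training chains into a corpus, train the semantic dictionary,
divide chains into windows, featurize by concatenated embeddings, and fit
the boosted-tree classifier.  One user-facing seed fans out
deterministically to the embedding, fold-assignment and classifier seeds
via ``sub_seed(seed, i) = (seed * 1_000_003 + i) mod 2**31``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import embed, encode, gbt, metrics, windows
from .embed import EmbeddingParams, SemanticDictionary
from .gbt import BoostedModel, GBTParams
from .seqio import ModelBundle, ProteinChain

log = logging.getLogger("prip")


def sub_seed(seed: int, i: int) -> int:
    """Deterministic fan-out of one user seed into component seeds."""
    return (seed * 1_000_003 + i) % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """Workflow configuration; defaults are the final predictor settings
    (window length 39, CBOW size-25 window-5 negative-5 epoch-200
    embeddings, probability call threshold 0.5, five folds)."""

    window_length: int = 39
    embedding: EmbeddingParams = field(default_factory=EmbeddingParams)
    classifier: GBTParams = field(default_factory=GBTParams)
    threshold: float = 0.5
    k: int = 5
    seed: int = 1

    def __post_init__(self) -> None:
        if self.window_length < 3 or self.window_length % 2 == 0:
            raise ValueError("window_length must be odd and >= 3")

    @property
    def n(self) -> int:
        return (self.window_length - 1) // 2

    def seeded(self) -> "RunConfig":
        """Resolve component seeds from the single workflow seed."""
        return replace(
            self,
            embedding=replace(self.embedding, seed=sub_seed(self.seed, 1)),
            classifier=replace(self.classifier, seed=sub_seed(self.seed, 2)),
        )


def train_dictionary(chains: Sequence[ProteinChain], config: RunConfig) -> SemanticDictionary:
    corpus = embed.tokenize_corpus(chains)
    log.info("training embeddings: %d sentences, params=%s", len(corpus), config.embedding)
    return embed.train(corpus, config.seeded().embedding)


def train_model(chains: Sequence[ProteinChain], config: RunConfig = RunConfig()) -> ModelBundle:
    """Full training workflow on labeled chains; returns a model bundle."""
    cfg = config.seeded()
    dictionary = embed.train(embed.tokenize_corpus(chains), cfg.embedding)
    X, y = encode.encode_chains(chains, cfg.n, dictionary)
    if (y < 0).any():
        raise ValueError("training requires labels on every chain")
    n_pos = int((y == 1).sum())
    log.info("training classifier: %d segments (%d positive, %d negative)",
             len(y), n_pos, len(y) - n_pos)
    model = gbt.fit(X, y, cfg.classifier)
    return ModelBundle(dictionary=dictionary, classifier=model, window_n=cfg.n)


def predict_bundle(bundle: ModelBundle, chains: Sequence[ProteinChain]) -> np.ndarray:
    """Per-residue interface probabilities, concatenated over chains."""
    X, _ = encode.encode_chains(chains, bundle.window_n, bundle.dictionary)
    return bundle.classifier.predict_proba(X)


def evaluate_bundle(
    bundle: ModelBundle, chains: Sequence[ProteinChain], threshold: float = 0.5
) -> dict[str, float]:
    """Independent-test metrics of a trained bundle on labeled chains."""
    X, y = encode.encode_chains(chains, bundle.window_n, bundle.dictionary)
    if (y < 0).any():
        raise ValueError("evaluation requires labels on every chain")
    scores = bundle.classifier.predict_proba(X)
    return metrics.evaluate_scores(y, scores, threshold)


def _trainer(params: GBTParams):
    return lambda X, y: gbt.fit(X, y, params)


def cross_validate(
    chains: Sequence[ProteinChain],
    config: RunConfig = RunConfig(),
    disrupt_negatives: bool = False,
    group_by_chain: bool = False,
) -> metrics.CVReport:
    """k-fold cross-validation of the full predictor.

    The semantic dictionary is trained once on the whole corpus (the corpus
    is the training set itself), then the encoded segments are partitioned
    into stratified folds.  ``disrupt_negatives`` retrains on negatives
    whose tokens were shuffled within each segment (the composition-
    preserving variant); ``group_by_chain`` keeps whole chains in one fold.
    """
    cfg = config.seeded()
    dictionary = embed.train(embed.tokenize_corpus(chains), cfg.embedding)
    if disrupt_negatives:
        pos, neg = windows.build_dataset(chains, cfg.n)
        neg = windows.disrupt_negatives(neg, seed=sub_seed(cfg.seed, 4))
        segs = pos + neg
        ds = encode.encode_segments(segs, dictionary)
        X, y = ds.X, ds.y
        groups = np.array([s.chain_id for s in segs]) if group_by_chain else None
    else:
        X, y = encode.encode_chains(chains, cfg.n, dictionary)
        groups = (
            np.concatenate([[c.chain_id] * len(c) for c in chains])
            if group_by_chain
            else None
        )
    return metrics.kfold_cv(
        X, y, _trainer(cfg.classifier), k=cfg.k, seed=sub_seed(cfg.seed, 3),
        threshold=cfg.threshold, groups=groups,
    )


def cv_auroc_for_length(
    chains: Sequence[ProteinChain],
    n: int,
    config: RunConfig = RunConfig(),
    dictionary: SemanticDictionary | None = None,
) -> float:
    """Mean CV AUROC at half-window ``n`` (dictionary reusable across
    lengths of a scan, since embeddings do not depend on the window)."""
    cfg = config.seeded()
    if dictionary is None:
        dictionary = embed.train(embed.tokenize_corpus(chains), cfg.embedding)
    X, y = encode.encode_chains(chains, n, dictionary)
    report = metrics.kfold_cv(
        X, y, _trainer(cfg.classifier), k=cfg.k, seed=sub_seed(cfg.seed, 3),
        threshold=cfg.threshold,
    )
    return report.means["AUROC"]


def window_scan(
    chains: Sequence[ProteinChain],
    config: RunConfig = RunConfig(),
    lengths: Sequence[int] = tuple(range(21, 40, 2)),
) -> dict[int, float]:
    """Mean CV AUROC per window length over the scan grid (default
    21, 23, ..., 39)."""
    cfg = config.seeded()
    dictionary = embed.train(embed.tokenize_corpus(chains), cfg.embedding)
    return metrics.window_scan(
        chains,
        lambda ch, n: cv_auroc_for_length(ch, n, cfg, dictionary),
        lengths,
    )
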