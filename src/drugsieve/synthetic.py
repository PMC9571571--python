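"""Synthetic fixtures with the statistical structure the pipeline assumes.

The extraction stage presumes that compound-name embeddings occupy a
compact region of the embedding space ("a generic compound" region) while
ordinary words lie far from it. The generator makes that geometry explicit
and returns its ground truth, so training, sensitivity evaluation and
clustering are testable end-to-end without downloads:

* a hidden unit-norm centroid ``c``;
* ``drug_lexicon_size`` drug tokens ("drug000"...) whose vectors lie within
  ``centroid_spread`` (epsilon) of ``c``;
* a distractor vocabulary ("word000"...) of unit vectors kept at least
  ``distractor_margin * epsilon`` away from ``c``;
* sentences of ``tokens_per_sentence`` tokens containing exactly one drug
  token, labeled with it.

QA pairs for the relevance stage follow a hidden affine map
``answer = A q + b + noise`` whose parameters are returned for recovery
tests.

Split sizes default to 500/250/250 (train/test/validation), the scale of a
manually curated thousand-entry sentence-drug dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embedding import EMBED_DIM, fixture_embedder
from .errors import InputError
from .extraction import ExtractionExample, SplitDataset
from .relevance import QAPair


@dataclass
class SyntheticConfig:
    dim: int = EMBED_DIM
    n_train: int = 500
    n_test: int = 250
    n_val: int = 250
    tokens_per_sentence: int = 14
    drug_lexicon_size: int = 50
    distractor_vocab_size: int = 500
    centroid_spread: float = 0.05  # epsilon
    distractor_margin: float = 10.0  # in units of epsilon
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.dim != EMBED_DIM:
            raise InputError(f"embedding dimension is fixed at {EMBED_DIM}")
        if self.drug_lexicon_size < 1:
            raise InputError("drug_lexicon_size must be >= 1")
        if self.distractor_margin <= 1:
            raise InputError("distractor_margin must exceed 1")
        if min(self.n_train, self.n_test, self.n_val, self.tokens_per_sentence) < 1:
            raise InputError("split sizes and tokens_per_sentence must be >= 1")


@dataclass
class SyntheticCorpus:
    config: SyntheticConfig
    splits: SplitDataset
    vocabulary: dict  # token -> embedding vector (the fixture-embedder table)
    hidden_centroid: np.ndarray
    drug_tokens: list = field(default_factory=list)

    @property
    def examples(self):
        return self.splits.train + self.splits.test + self.splits.validation

    def embedder(self):
        """Fixture embedder whose token table is this corpus's vocabulary."""
        return fixture_embedder(self.config.seed, vocabulary=self.vocabulary)


@dataclass
class SyntheticQA:
    pairs: list
    matrix: np.ndarray  # the hidden A
    offset: np.ndarray  # the hidden b


def _unit(rng, dim):
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


def generate_extraction_corpus(cfg: SyntheticConfig) -> SyntheticCorpus:
    """Deterministic (per seed) labeled corpus satisfying the separability
    invariants exactly; the ground-truth centroid is returned for
    recovery tests."""
    rng = np.random.default_rng(cfg.seed)
    dim, eps = cfg.dim, cfg.centroid_spread
    centroid = _unit(rng, dim)

    drug_tokens = [f"drug{i:03d}" for i in range(cfg.drug_lexicon_size)]
    vocabulary = {}
    for tok in drug_tokens:
        v = centroid + 0.9 * eps * _unit(rng, dim)
        v = v / np.linalg.norm(v)
        assert np.linalg.norm(v - centroid) <= eps
        vocabulary[tok] = v

    min_dist = cfg.distractor_margin * eps
    distractors = []
    while len(distractors) < cfg.distractor_vocab_size:
        v = _unit(rng, dim)
        if np.linalg.norm(v - centroid) >= min_dist:
            tok = f"word{len(distractors):03d}"
            vocabulary[tok] = v
            distractors.append(tok)

    def make_examples(n):
        out = []
        for _ in range(n):
            drug = drug_tokens[rng.integers(len(drug_tokens))]
            others = [
                distractors[i]
                for i in rng.choice(
                    len(distractors), size=cfg.tokens_per_sentence - 1, replace=False
                )
            ]
            pos = rng.integers(cfg.tokens_per_sentence)
            tokens = others[:pos] + [drug] + others[pos:]
            out.append(
                ExtractionExample(sentence_text=" ".join(tokens), drug_label=drug)
            )
        return out

    splits = SplitDataset(
        train=make_examples(cfg.n_train),
        test=make_examples(cfg.n_test),
        validation=make_examples(cfg.n_val),
    )
    return SyntheticCorpus(
        config=cfg,
        splits=splits,
        vocabulary=vocabulary,
        hidden_centroid=centroid,
        drug_tokens=drug_tokens,
    )


def generate_qa_pairs(cfg: SyntheticConfig, n: int | None = None) -> SyntheticQA:
    """QA pairs with ``answer = A q + b + N(0, noise_sigma)`` for a hidden
    seeded orthogonal ``A`` and small offset ``b``."""
    if n is None:
        n = cfg.n_train + cfg.n_test + cfg.n_val
    rng = np.random.default_rng(cfg.seed + 1)
    a = rng.standard_normal((cfg.dim, cfg.dim))
    q_mat, r_mat = np.linalg.qr(a)
    matrix = q_mat * np.sign(np.diag(r_mat))
    offset = 0.1 * _unit(rng, cfg.dim)
    pairs = []
    for i in range(n):
        q = _unit(rng, cfg.dim)
        ans = matrix @ q + offset + cfg.noise_sigma * rng.standard_normal(cfg.dim)
        pairs.append(
            QAPair(
                question_text=f"question {i}",
                answer_text=f"answer {i}",
                question_vec=q,
                answer_vec=ans,
            )
        )
    return SyntheticQA(pairs=pairs, matrix=matrix, offset=offset)


def write_extraction_csv(corpus: SyntheticCorpus, path, split: str = "train") -> None:
    """Write one split in the two-column CSV layout the extraction reader
    consumes (dogfooding the real I/O path)."""
    import csv

    examples = getattr(corpus.splits, split)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sentence", "drug"])
        for ex in examples:
            writer.writerow([ex.sentence_text, ex.drug_label])
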