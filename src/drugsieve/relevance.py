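"""Relevance stage: regress question embeddings onto answer embeddings and
rank corpus sentences by Euclidean distance to the predicted answer.

The regressor is trained with an MSE loss and the Adam optimizer on
question/answer pairs (SciQ-style). At query time the model maps the
embedded question to a predicted answer embedding; every sentence in the
corpus is then sorted by the Euclidean (L2) distance between its embedding
and that prediction — the closest sentence is the most relevant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .embedding import EMBED_DIM, EmbeddedSentence, as_embedding
from .errors import InputError, ParseError
from .net import Conv1D, Dense, Flatten, Reshape, Sequential, TrainConfig

DEFAULT_EPOCHS = 100


@dataclass
class QAPair:
    question_text: str
    answer_text: str | None = None
    question_vec: np.ndarray | None = None
    answer_vec: np.ndarray | None = None


@dataclass
class RankedSentence:
    sentence: EmbeddedSentence
    distance: float
    rank: int


def build_relevance_network(
    seed: int, architecture: str = "conv", conv_filters: int = 8, kernel_size: int = 9
) -> Sequential:
    """Default relevance regressor: a 1-D convolution over the 512-vector
    (treated as a length-512, single-channel signal) followed by a fully
    connected 512-unit output layer. A plain dense stack is offered as an
    alternative. Linear activations keep the noiseless affine QA structure
    exactly representable.
    """
    if architecture == "conv":
        layers = [
            Reshape((EMBED_DIM, 1)),
            Conv1D(conv_filters, kernel_size),
            Flatten(),
            Dense(EMBED_DIM),
        ]
    elif architecture == "dense":
        layers = [Dense(EMBED_DIM, "selu"), Dense(EMBED_DIM)]
    else:
        raise InputError(f"unknown relevance architecture {architecture!r}")
    return Sequential(layers, seed=seed)


def train_relevance(pairs, config: TrainConfig, architecture: str = "conv"):
    """Train the question->answer embedding regressor.

    Returns ``(model, history)``; requires at least two embedded pairs.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise InputError("need at least 2 QA pairs to train")
    X = np.stack([as_embedding(p.question_vec, "question_vec") for p in pairs])
    Y = np.stack([as_embedding(p.answer_vec, "answer_vec") for p in pairs])
    model = build_relevance_network(seed=config.seed, architecture=architecture)
    history = model.fit(X, Y, config)
    return model, history


def predict_answer_embedding(model: Sequential, question_vec) -> np.ndarray:
    q = as_embedding(question_vec, "question_vec")
    return as_embedding(model.predict(q[None, :])[0], "predicted answer")


def rank_sentences(pred, sentences, top_k: int):
    """Sort sentences by ascending Euclidean distance to the prediction.

    Ties are broken by ``(doc_id, sentence_index)``; returns the closest
    ``min(top_k, n)`` sentences with 1-based ranks.
    """
    sentences = list(sentences)
    if not sentences:
        raise InputError("no sentences to rank")
    if top_k < 1:
        raise InputError("top_k must be >= 1")
    pred = as_embedding(pred, "predicted answer")
    mat = np.stack([s.sentence_vec for s in sentences])
    dists = np.linalg.norm(mat - pred, axis=1)
    order = sorted(
        range(len(sentences)),
        key=lambda i: (
            dists[i],
            sentences[i].sentence.doc_id,
            sentences[i].sentence.sentence_index,
        ),
    )
    return [
        RankedSentence(sentence=sentences[i], distance=float(dists[i]), rank=r + 1)
        for r, i in enumerate(order[:top_k])
    ]


def read_sciq(path):
    """Read a SciQ-layout JSON file (list of objects with ``question``,
    ``correct_answer`` and ``support`` fields) into QAPair scaffolds.

    The support sentence containing the correct answer serves as the answer
    text; entries with empty support are skipped. Returns
    ``(pairs, n_skipped)``; vectors are left to the caller's embedder.
    """
    with open(path, encoding="utf-8") as fh:
        try:
            entries = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(entries, list):
        raise ParseError(f"{path}: expected a JSON list of entries")
    pairs, skipped = [], 0
    for entry in entries:
        if not isinstance(entry, dict) or "question" not in entry:
            raise ParseError(f"{path}: entry without 'question' field")
        support = (entry.get("support") or "").strip()
        if not support:
            skipped += 1
            continue
        pairs.append(QAPair(question_text=entry["question"], answer_text=support))
    return pairs, skipped


def embed_qa_pairs(embedder, pairs):
    """Fill in question/answer vectors of QAPair scaffolds in place."""
    for p in pairs:
        p.question_vec = embedder.embed(p.question_text)
        p.answer_vec = embedder.embed(p.answer_text)
    return pairs


def write_ranked_tsv(ranked, path):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tdoc_id\tsentence_index\tdistance\ttext\n")
        for r in ranked:
            s = r.sentence.sentence
            fh.write(f"{r.rank}\t{s.doc_id}\t{s.sentence_index}\t{r.distance:.6g}\t{s.text}\n")
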