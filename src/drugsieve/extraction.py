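"""Compound-name extraction: regress sentence embeddings onto a "generic
compound" embedding and return the sentence token nearest the prediction.

Eight alternative network designs (ids ``A``..``H``) are compared for this
regression; the recurrent designs reshape the 512-vector into a
``(timesteps, features)`` sequence before the recurrent layer (default
32 x 16). Extraction quality is measured as sensitivity —
``true / (true + false)`` predictions — optionally against a uniform
random-token baseline, and model sensitivity profiles across question
categories are compared by K-means clustering.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .embedding import EMBED_DIM, EmbeddedSentence, as_embedding, embed_text
from .errors import ContractError, InputError, ParseError
from .net import (
    Activation,
    Dense,
    LeakyReLU,
    LSTM,
    PReLU,
    Reshape,
    Sequential,
    SimpleRNN,
    TrainConfig,
)

# ---------------------------------------------------------------------------
# architecture registry

#: Layer vocabulary: ("dense", units, activation) | ("simple_rnn", units) |
#: ("lstm", units) | ("activation", name) | ("leaky_relu",) | ("prelu",)
ARCHITECTURES: dict[str, tuple] = {
    "A": (
        ("dense", 512, "selu"),
        ("dense", 512, "sigmoid"),
        ("dense", 512, "relu"),
        ("dense", 512, "relu"),
        ("dense", 512, "selu"),
        ("leaky_relu",),
        ("activation", "selu"),
        ("simple_rnn", 512),
        ("dense", 512, "selu"),
        ("dense", 512, "relu"),
        ("dense", 512, "selu"),
        ("dense", 512, "relu"),
        ("dense", 512, "selu"),
    ),
    "B": (
        ("dense", 512, "selu"),
        ("dense", 512, "sigmoid"),
    ),
    "C": (
        ("dense", 512, "relu"),
        ("dense", 512, "selu"),
        ("dense", 512, "sigmoid"),
    ),
    "D": (
        # softmax across the 512 output units, as designed; its probability-
        # simplex output is a poor fit for embedding regression, which is
        # exactly what the architecture comparison exposes
        ("dense", 512, "selu"),
        ("dense", 512, "softmax"),
        ("prelu",),
    ),
    "E": (
        ("dense", 512, "selu"),
        ("simple_rnn", 512),
    ),
    "F": (
        ("activation", "selu"),
        ("lstm", 512),
        ("leaky_relu",),
        ("leaky_relu",),
    ),
    "G": (
        ("dense", 512, "selu"),
        ("prelu",),
        ("dense", 512, "selu"),
        ("simple_rnn", 512),
        ("activation", "selu"),
        ("leaky_relu",),
    ),
    "H": (
        ("activation", "selu"),
        ("lstm", 512),
        ("prelu",),
        ("leaky_relu",),
        ("leaky_relu",),
    ),
}

RECURRENT_KINDS = {"simple_rnn", "lstm"}
DEFAULT_RESHAPE = (32, 16)


@dataclass(frozen=True)
class ArchitectureSpec:
    id: str
    layers: tuple
    input_reshape: tuple = DEFAULT_RESHAPE

    @property
    def has_recurrent(self) -> bool:
        return any(kind in RECURRENT_KINDS for kind, *_ in self.layers)


def get_architecture(arch_id: str, input_reshape=DEFAULT_RESHAPE) -> ArchitectureSpec:
    if arch_id not in ARCHITECTURES:
        raise InputError(f"unknown architecture id {arch_id!r}; expected one of A..H")
    t, f = input_reshape
    if t * f != EMBED_DIM:
        raise ContractError(
            f"input reshape {input_reshape} does not factor {EMBED_DIM}"
        )
    return ArchitectureSpec(
        id=arch_id, layers=ARCHITECTURES[arch_id], input_reshape=(int(t), int(f))
    )


def _make_layer(descriptor):
    kind = descriptor[0]
    if kind == "dense":
        return Dense(descriptor[1], descriptor[2])
    if kind == "simple_rnn":
        return SimpleRNN(descriptor[1])
    if kind == "lstm":
        return LSTM(descriptor[1])
    if kind == "activation":
        return Activation(descriptor[1])
    if kind == "leaky_relu":
        return LeakyReLU()
    if kind == "prelu":
        return PReLU()
    raise InputError(f"unknown layer descriptor {descriptor!r}")


def build_architecture(arch_id: str, input_reshape=DEFAULT_RESHAPE, seed: int = 0) -> Sequential:
    """Instantiate one of the eight registered extraction-network designs.

    Recurrent designs consume the 512-vector reshaped to
    ``input_reshape = (timesteps, features)``; dense layers placed before a
    recurrent layer act on the feature axis of the reshaped tensor (the
    layer order requires it to type-check). Purely dense designs consume
    the flat 512-vector. The final output width is always 512.
    """
    spec = get_architecture(arch_id, input_reshape)
    layers = []
    if spec.has_recurrent:
        layers.append(Reshape(spec.input_reshape))
    layers.extend(_make_layer(d) for d in spec.layers)
    return Sequential(layers, seed=seed)


# ---------------------------------------------------------------------------
# data containers

@dataclass
class ExtractionExample:
    """One labeled sentence: the text and the manually identified compound."""

    sentence_text: str
    drug_label: str


@dataclass
class SplitDataset:
    train: list = field(default_factory=list)
    test: list = field(default_factory=list)
    validation: list = field(default_factory=list)


@dataclass
class SensitivityReport:
    n_true: int
    n_false: int

    @property
    def sensitivity(self) -> float:
        total = self.n_true + self.n_false
        if total == 0:
            raise InputError("sensitivity undefined on zero predictions")
        return self.n_true / total


@dataclass
class ModelComparison:
    model_ids: list
    sensitivity_matrix: np.ndarray  # models x question categories
    labels: np.ndarray  # cluster index per model
    k: int

    def clusters(self):
        """Model ids grouped per cluster label."""
        return {
            int(c): [m for m, l in zip(self.model_ids, self.labels) if l == c]
            for c in sorted(set(int(x) for x in self.labels))
        }


# ---------------------------------------------------------------------------
# training and inference

def train_extraction(arch_id: str, data: SplitDataset, embedder, config: TrainConfig,
                     input_reshape=DEFAULT_RESHAPE):
    """Train one extraction design: sentence embedding -> drug-label embedding.

    Returns ``(model, history)``. The per-epoch history covers the training
    fraction and the internal validation fraction of the train split
    (0.61:0.39 by default, see :class:`~drugsieve.net.TrainConfig`).
    """
    if not data.train:
        raise InputError("training split is empty")
    X = np.stack([embed_text(embedder, ex.sentence_text) for ex in data.train])
    Y = np.stack([embed_text(embedder, ex.drug_label) for ex in data.train])
    model = build_architecture(arch_id, input_reshape=input_reshape, seed=config.seed)
    history = model.fit(X, Y, config)
    return model, history


def extract_compound(model: Sequential, s: EmbeddedSentence):
    """Return ``(token, distance)`` of the sentence token whose embedding is
    nearest (Euclidean) to the model's predicted compound embedding.

    Ties are broken by earliest sentence position.
    """
    if not s.token_vecs:
        raise InputError("sentence has no tokens")
    pred = model.predict(np.asarray(s.sentence_vec)[None, :])[0]
    mat = np.stack(s.token_vecs)
    dists = np.linalg.norm(mat - pred, axis=1)
    i = int(np.argmin(dists))  # argmin returns the first minimum: earliest position
    return s.sentence.tokens[i], float(dists[i])


_PUNCT_RE = re.compile(r"^\W+|\W+$")


def normalize_token(token: str) -> str:
    return _PUNCT_RE.sub("", token).casefold()


def _label_tokens(label: str):
    toks = [normalize_token(t) for t in re.findall(r"\S+", label)]
    toks = [t for t in toks if t]
    long_toks = [t for t in toks if len(t) >= 3]
    # multi-word labels count a match on any informative (>= 3 char) token
    return long_toks or toks


def _matches(token: str, label: str) -> bool:
    return normalize_token(token) in _label_tokens(label)


def _embed_examples(examples, embedder):
    from .corpus import SentenceRecord, tokenize

    for i, ex in enumerate(examples):
        rec = SentenceRecord(
            doc_id="eval", sentence_index=i, text=ex.sentence_text,
            tokens=tokenize(ex.sentence_text),
        )
        yield ex, EmbeddedSentence(
            sentence=rec,
            sentence_vec=embed_text(embedder, ex.sentence_text),
            token_vecs=[embed_text(embedder, t) for t in rec.tokens],
        )


def evaluate_sensitivity(model: Sequential, examples, embedder) -> SensitivityReport:
    """Sensitivity = true / (true + false) extractions over labeled examples.

    A prediction is true iff the extracted token equals any token of the
    drug label after normalization (case-folding and punctuation stripping).
    The extractor never abstains, so every example is either true or false.
    """
    examples = list(examples)
    if not examples:
        raise InputError("no examples to evaluate")
    n_true = 0
    for ex, emb in _embed_examples(examples, embedder):
        token, _ = extract_compound(model, emb)
        n_true += _matches(token, ex.drug_label)
    return SensitivityReport(n_true=n_true, n_false=len(examples) - n_true)


def random_baseline(examples, seed: int) -> SensitivityReport:
    """Sensitivity of drawing the extracted token uniformly from each sentence."""
    from .corpus import tokenize

    examples = list(examples)
    if not examples:
        raise InputError("no examples to evaluate")
    rng = np.random.default_rng(seed)
    n_true = 0
    for ex in examples:
        tokens = tokenize(ex.sentence_text)
        if not tokens:
            raise InputError(f"sentence without tokens: {ex.sentence_text!r}")
        token = tokens[rng.integers(len(tokens))]
        n_true += _matches(token, ex.drug_label)
    return SensitivityReport(n_true=n_true, n_false=len(examples) - n_true)


def compare_models(sensitivity_matrix, k: int, seed: int, model_ids=None) -> ModelComparison:
    """K-means (Euclidean, multiple restarts) over per-model sensitivity
    profiles; each model receives exactly one cluster label.
    """
    mat = np.atleast_2d(np.asarray(sensitivity_matrix, dtype=float))
    n_models = mat.shape[0]
    if not 1 <= k <= n_models:
        raise InputError(f"k={k} out of range for {n_models} models")
    if model_ids is None:
        model_ids = list(ARCHITECTURES)[:n_models]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(mat)
    return ModelComparison(
        model_ids=list(model_ids), sensitivity_matrix=mat, labels=labels, k=k
    )


# ---------------------------------------------------------------------------
# I/O

def read_extraction_csv(path):
    """Read the two-column (sentence, drug) CSV of labeled examples.

    A first row whose cells look like column titles ("sentence", "drug"...)
    is treated as a header. Rows whose label shares no token with the
    sentence are excluded; returns ``(examples, n_excluded)``.
    """
    with open(path, encoding="utf-8", newline="") as fh:
        rows = [row for row in csv.reader(fh) if row]
    if not rows:
        return [], 0
    header_words = {"sentence", "sentences", "drug", "drugs", "compound", "label"}
    if {c.strip().casefold() for c in rows[0]} & header_words:
        rows = rows[1:]
    examples, excluded = [], 0
    for j, row in enumerate(rows):
        if len(row) != 2:
            raise ParseError(f"{path}: row {j + 1} has {len(row)} columns, expected 2")
        sentence, label = row[0].strip(), row[1].strip()
        sentence_tokens = {normalize_token(t) for t in sentence.split()}
        if not set(_label_tokens(label)) & sentence_tokens:
            excluded += 1
            continue
        examples.append(ExtractionExample(sentence_text=sentence, drug_label=label))
    return examples, excluded


def write_sensitivity_tsv(reports, path):
    """``reports``: iterable of (model_id, category, SensitivityReport)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("model\tcategory\tn_true\tn_false\tsensitivity\n")
        for model_id, category, rep in reports:
            fh.write(
                f"{model_id}\t{category}\t{rep.n_true}\t{rep.n_false}\t{rep.sensitivity:.4f}\n"
            )


def write_cluster_tsv(comparison: ModelComparison, path):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("model\tcluster\n")
        for m, l in zip(comparison.model_ids, comparison.labels):
            fh.write(f"{m}\t{int(l)}\n")
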