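"""The 512-dimensional text-embedding contract.

Every downstream stage (relevance ranking, compound extraction) consumes
fixed-width 512-d real vectors. Two embedders satisfy the contract:

* :func:`pretrained_adapter` wraps a caller-supplied pretrained sentence
  encoder (e.g. a deep-averaging-network universal encoder loaded by the
  caller); it is never loaded implicitly.
* :func:`fixture_embedder` is a deterministic offline stand-in: each token
  maps to a fixed pseudo-random unit-norm vector keyed by ``(seed, token)``
  and a sentence embeds as the arithmetic mean of its token vectors —
  mirroring the deep-averaging design of the encoder it stands in for.
  Sentence means are deliberately NOT re-normalized so that the
  mean-of-token-vectors identity is exact.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .corpus import SentenceRecord, tokenize
from .errors import ContractError, InputError

EMBED_DIM = 512


def as_embedding(values, context="embedding") -> np.ndarray:
    """Validate and return a finite float64 vector of width 512."""
    vec = np.asarray(values, dtype=np.float64)
    if vec.shape != (EMBED_DIM,):
        raise ContractError(f"{context}: expected shape ({EMBED_DIM},), got {vec.shape}")
    if not np.all(np.isfinite(vec)):
        raise ContractError(f"{context}: non-finite entries")
    return vec


@dataclass
class Embedder:
    name: str
    embed_fn: object  # callable: str -> 512-vector
    deterministic: bool = True

    def embed(self, text: str) -> np.ndarray:
        return embed_text(self, text)


@dataclass
class EmbeddedSentence:
    """A sentence with its sentence-level and per-token embeddings."""

    sentence: SentenceRecord
    sentence_vec: np.ndarray
    token_vecs: list = field(default_factory=list)


def embed_text(embedder: Embedder, text: str) -> np.ndarray:
    if not isinstance(text, str) or not text.strip():
        raise InputError("cannot embed empty text")
    return as_embedding(embedder.embed_fn(text), context=f"embedder {embedder.name!r}")


def embed_sentence_record(embedder: Embedder, s: SentenceRecord) -> EmbeddedSentence:
    if not s.tokens:
        raise InputError(
            f"sentence {s.doc_id}[{s.sentence_index}] has no tokens to embed"
        )
    return EmbeddedSentence(
        sentence=s,
        sentence_vec=embed_text(embedder, s.text),
        token_vecs=[embed_text(embedder, tok) for tok in s.tokens],
    )


def _hashed_unit_vector(seed: int, token: str) -> np.ndarray:
    digest = hashlib.blake2b(
        f"{seed}:{token}".encode("utf-8"), digest_size=8
    ).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "big"))
    v = rng.standard_normal(EMBED_DIM)
    return v / np.linalg.norm(v)


def fixture_embedder(seed: int, vocabulary: dict | None = None) -> Embedder:
    """Deterministic mean-of-token-vectors embedder for offline pipelines.

    ``vocabulary`` optionally pins specific tokens to given vectors (used by
    the synthetic corpus generator, whose ground-truth geometry lives in its
    vocabulary table); any other token receives a fixed unit-norm
    pseudo-random vector keyed by ``(seed, token)``.
    """
    vocab = dict(vocabulary) if vocabulary else {}
    cache: dict[str, np.ndarray] = {}

    def token_vector(token: str) -> np.ndarray:
        if token in vocab:
            return np.asarray(vocab[token], dtype=np.float64)
        if token not in cache:
            cache[token] = _hashed_unit_vector(seed, token)
        return cache[token]

    def embed(text: str) -> np.ndarray:
        tokens = tokenize(text)
        if not tokens:
            raise InputError(f"text {text!r} contains no tokens")
        return np.mean([token_vector(t) for t in tokens], axis=0)

    return Embedder(name=f"fixture(seed={seed})", embed_fn=embed, deterministic=True)


class EmbeddingCache:
    """Compressed-array sidecar of computed embeddings.

    Entries are keyed by ``(embedder name, blake2 hash of the text)`` so a
    cache populated by one embedder is never served to another. Useful when
    a slow pretrained encoder re-reads the same corpus; the fixture embedder
    rarely needs it.
    """

    def __init__(self):
        self._store: dict[str, np.ndarray] = {}

    @staticmethod
    def _key(embedder_name: str, text: str) -> str:
        digest = hashlib.blake2b(text.encode("utf-8"), digest_size=16).hexdigest()
        return f"{embedder_name}|{digest}"

    def get_or_compute(self, embedder: Embedder, text: str) -> np.ndarray:
        key = self._key(embedder.name, text)
        if key not in self._store:
            self._store[key] = embed_text(embedder, text)
        return self._store[key]

    def __len__(self) -> int:
        return len(self._store)

    def save(self, path) -> None:
        np.savez_compressed(path, **self._store)

    @classmethod
    def load(cls, path) -> "EmbeddingCache":
        cache = cls()
        with np.load(path) as data:
            for key in data.files:
                cache._store[key] = as_embedding(data[key], context=f"cache[{key}]")
        return cache


def pretrained_adapter(model_handle, name: str = "pretrained") -> Embedder:
    """Wrap a loaded third-party sentence encoder into the Embedder contract.

    ``model_handle`` must be callable on a single string (or expose an
    ``embed`` method) and return a length-512 vector; wrong dimensionality
    raises :class:`~drugsieve.errors.ContractError` rather than being
    silently truncated.
    """
    fn = model_handle if callable(model_handle) else model_handle.embed

    def embed(text: str) -> np.ndarray:
        return as_embedding(np.squeeze(np.asarray(fn(text))), context=name)

    return Embedder(name=name, embed_fn=embed, deterministic=False)
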