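"""Sentence-level corpus database: documents -> sentences -> tokens -> JSON.

The first stage of the pipeline turns locally supplied text (or text
extracted from PDFs by an external parser) into an ordered collection of
sentences with their tokens, persisted as a single UTF-8 JSON file that the
embedding and ranking stages consume.

Sentence segmentation uses a rule-based splitter: a sentence ends at
``.``/``!``/``?`` followed by whitespace and an uppercase letter, digit or
opening quote, except inside decimal numbers and after a stop-list of
common scientific abbreviations ("e.g.", "i.e.", "Fig.", "et al.", ...).
Tokens are maximal runs of word characters, keeping internal hyphens
("IL-17A", "anti-oxidant") because compound names are frequently
hyphenated or alphanumeric.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass, field

from .errors import InputError, SchemaError, ServiceError

SCHEMA_VERSION = "1"

#: Abbreviations after which a period never ends a sentence.
ABBREVIATIONS = frozenset(
    {
        "e.g",
        "i.e",
        "etc",
        "cf",
        "fig",
        "figs",
        "eq",
        "ref",
        "refs",
        "al",  # "et al."
        "vs",
        "ca",
        "approx",
        "no",
        "vol",
        "dr",
        "prof",
        "st",
    }
)

_TOKEN_RE = re.compile(r"\w+(?:-\w+)*")
_BOUNDARY_RE = re.compile(r"([.!?])(\s+)(?=[\"'(“‘]?[A-Z0-9])")


@dataclass
class SentenceRecord:
    """One sentence of one document; the unit of ranking and extraction."""

    doc_id: str
    sentence_index: int
    text: str
    tokens: list[str] = field(default_factory=list)


@dataclass
class DocumentRecord:
    doc_id: str
    source: str
    raw_text: str
    sentences: list[SentenceRecord] = field(default_factory=list)


@dataclass
class CorpusDatabase:
    records: list[DocumentRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def all_sentences(self):
        for doc in self.records:
            yield from doc.sentences


def tokenize(sentence: str) -> list[str]:
    """Maximal runs of word characters with internal hyphens, case preserved."""
    return _TOKEN_RE.findall(sentence)


def _is_abbreviation(prefix: str) -> bool:
    m = re.search(r"([A-Za-z][\w.]*)$", prefix)
    if not m:
        return False
    word = m.group(1).rstrip(".").rsplit(".", 1)[-1]
    return word.lower() in ABBREVIATIONS


def segment_sentences(text: str) -> list[str]:
    """Split text into sentences, preserving every non-whitespace character.

    The concatenation of the returned strings equals the input up to
    whitespace; no returned string is empty.
    """
    sentences = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        end = m.end(1)
        prefix = text[start : m.start(1)]
        if _is_abbreviation(prefix):
            continue
        piece = text[start:end].strip()
        if piece:
            sentences.append(piece)
            start = m.end(2)
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def ingest_text(doc_id: str, source: str, raw_text) -> DocumentRecord:
    """Segment and tokenize one document's text into a :class:`DocumentRecord`.

    Empty text yields a document with zero sentences. Bytes are accepted only
    if they decode as UTF-8.
    """
    if isinstance(raw_text, bytes):
        try:
            raw_text = raw_text.decode("utf-8")
        except UnicodeDecodeError as exc:
            raise InputError(f"document {doc_id!r}: undecodable bytes: {exc}") from exc
    if not isinstance(raw_text, str):
        raise InputError(f"document {doc_id!r}: raw_text must be str or UTF-8 bytes")
    sentences = [
        SentenceRecord(doc_id=doc_id, sentence_index=i, text=s, tokens=tokenize(s))
        for i, s in enumerate(segment_sentences(raw_text))
    ]
    return DocumentRecord(doc_id=doc_id, source=source, raw_text=raw_text, sentences=sentences)


def build_database(documents, query: str | None = None, timestamp: str | None = None) -> CorpusDatabase:
    """Assemble documents into a database with creation metadata.

    ``timestamp`` defaults to the current UTC time; callers needing
    bit-reproducible output may pass a deterministic value (e.g. derived
    from the input files).
    """
    docs = list(documents)
    ids = [d.doc_id for d in docs]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate doc_id in database")
    if timestamp is None:
        timestamp = _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
    meta = {"created": timestamp, "query": query}
    return CorpusDatabase(records=docs, metadata=meta)


def save_db(db: CorpusDatabase, path) -> None:
    payload = {
        "version": SCHEMA_VERSION,
        "metadata": db.metadata,
        "documents": [
            {
                "doc_id": d.doc_id,
                "source": d.source,
                "raw_text": d.raw_text,
                "sentences": [
                    {"i": s.sentence_index, "text": s.text, "tokens": s.tokens}
                    for s in d.sentences
                ],
            }
            for d in db.records
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, ensure_ascii=False, indent=1)


def _require(mapping, key, context):
    if key not in mapping:
        raise SchemaError(f"{context}: missing required field {key!r}")
    return mapping[key]


def load_db(path) -> CorpusDatabase:
    with open(path, encoding="utf-8") as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(payload, dict):
        raise SchemaError(f"{path}: top level must be an object")
    _require(payload, "version", str(path))
    docs = []
    for j, dd in enumerate(_require(payload, "documents", str(path))):
        ctx = f"{path}: documents[{j}]"
        doc = DocumentRecord(
            doc_id=_require(dd, "doc_id", ctx),
            source=_require(dd, "source", ctx),
            raw_text=dd.get("raw_text", ""),
            sentences=[],
        )
        for sd in _require(dd, "sentences", ctx):
            doc.sentences.append(
                SentenceRecord(
                    doc_id=doc.doc_id,
                    sentence_index=_require(sd, "i", ctx),
                    text=_require(sd, "text", ctx),
                    tokens=list(_require(sd, "tokens", ctx)),
                )
            )
        docs.append(doc)
    return CorpusDatabase(records=docs, metadata=payload.get("metadata", {}))


def fetch_pubmed(query: str, max_docs: int, fetcher) -> list[DocumentRecord]:
    """Fetch up to ``max_docs`` abstracts through a caller-supplied client.

    ``fetcher(query, max_docs)`` must return an iterable of
    ``(pubmed_id, abstract_text)`` pairs; a real network client and a test
    mock are interchangeable. Network use is always explicit, never implied.
    """
    if fetcher is None:
        raise InputError("fetch_pubmed requires an explicit fetcher")
    try:
        hits = list(fetcher(query, max_docs))
    except Exception as exc:
        raise ServiceError(f"PubMed fetch failed (retriable): {exc}") from exc
    return [
        ingest_text(doc_id=str(pmid), source=f"pubmed:{pmid}", raw_text=text)
        for pmid, text in hits[:max_docs]
    ]
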