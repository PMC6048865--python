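"""Document collections, tokenization, vocabularies and tf-idf matrices.

Documents are read from JSON-lines or TSV, tokenized into unigrams,
adjacent-unigram bigrams and optional controlled-vocabulary terms (a
MeSH-like indexing vocabulary), and stacked into a sparse tf-idf matrix.
The three term sources live in disjoint namespaces: bigrams contain a
space, controlled terms carry the ``cv:`` prefix, unigrams contain
neither.
"""

from __future__ import annotations

import json
import logging
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: joins the two members of a bigram; never produced by the unigram tokenizer
BIGRAM_SEP = " "
#: prefix marking controlled-vocabulary terms
CV_PREFIX = "cv:"

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


class CorpusError(ValueError):
    """Malformed input collection (bad record, duplicate id, ...)."""


@dataclass
class RawDocument:
    """One record of a collection: stable id plus free text.

    ``vocab_terms`` holds optional controlled-vocabulary index terms and
    ``ref_label`` an optional reference cluster label for evaluation.
    """

    doc_id: str
    text: str
    vocab_terms: list[str] | None = None
    ref_label: str | None = None


@dataclass(frozen=True)
class TokenConfig:
    """Which term sources feed the vocabulary and how tokens are filtered."""

    use_unigrams: bool = True
    use_bigrams: bool = False
    use_vocab_terms: bool = False
    stopwords: frozenset[str] = frozenset()
    lowercase: bool = True
    min_token_length: int = 1
    min_df: int = 2

    def __post_init__(self) -> None:
        if not (self.use_unigrams or self.use_bigrams or self.use_vocab_terms):
            raise ValueError("at least one term source must be enabled")
        if self.min_df < 1:
            raise ValueError("min_df must be >= 1")
        if self.min_token_length < 1:
            raise ValueError("min_token_length must be >= 1")


@dataclass
class Vocabulary:
    """Term index with per-term document frequencies.

    ``df[i]`` counts the documents containing term ``i`` at least once
    (document frequency, not token frequency); ``n_docs`` is the total
    number of admitted documents, including any that retained no terms.
    """

    terms: list[str]
    df: np.ndarray
    n_docs: int
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {t: i for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.index


@dataclass
class CorpusMatrix:
    """Sparse tf-idf document-term matrix with row lookup by document id.

    ``X`` holds the raw tf-idf weights; ``unit()`` returns the
    row-normalized view used by the projection and theme algorithms,
    while raw rows serve dot-product similarity analyses.
    """

    doc_ids: list[str]
    vocab: Vocabulary
    X: sp.csr_matrix
    _unit: sp.csr_matrix | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self._index = {d: i for i, d in enumerate(self.doc_ids)}
        if len(self._index) != len(self.doc_ids):
            raise CorpusError("duplicate doc_id in matrix")
        if self.X.shape != (len(self.doc_ids), len(self.vocab)):
            raise CorpusError("matrix shape does not match ids/vocabulary")

    @property
    def n_docs(self) -> int:
        return len(self.doc_ids)

    @property
    def n_terms(self) -> int:
        return len(self.vocab)

    def index(self, doc_id: str) -> int:
        try:
            return self._index[doc_id]
        except KeyError:
            raise KeyError(f"unknown doc_id: {doc_id!r}") from None

    def row(self, doc_id: str) -> sp.csr_matrix:
        return self.X.getrow(self.index(doc_id))

    @property
    def norms(self) -> np.ndarray:
        if not hasattr(self, "_norms"):
            self._norms = np.sqrt(np.asarray(self.X.multiply(self.X).sum(axis=1)).ravel())
        return self._norms

    def unit(self) -> sp.csr_matrix:
        """Row-normalized view; all-zero rows stay zero."""
        if self._unit is None:
            inv = np.divide(1.0, self.norms, out=np.zeros_like(self.norms), where=self.norms > 0)
            self._unit = sp.diags(inv).dot(self.X).tocsr()
        return self._unit


# ---------------------------------------------------------------------------
# I/O


def read_corpus(path: str | Path, format: str = "jsonl") -> list[RawDocument]:
    """Read a collection from JSONL or TSV; drops empty-text records.

    JSONL records carry ``doc_id``, ``text`` and optional ``vocab_terms``
    / ``ref_label``; TSV rows are ``doc_id<TAB>label<TAB>text``.
    """
    path = Path(path)
    docs: list[RawDocument] = []
    seen: set[str] = set()
    dropped = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if format == "jsonl":
                try:
                    rec = json.loads(line)
                    doc = RawDocument(
                        doc_id=str(rec["doc_id"]),
                        text=str(rec["text"]),
                        vocab_terms=list(rec["vocab_terms"]) if rec.get("vocab_terms") else None,
                        ref_label=rec.get("ref_label"),
                    )
                except (json.JSONDecodeError, KeyError, TypeError) as exc:
                    raise CorpusError(f"{path}:{lineno}: malformed record ({exc})") from exc
            elif format == "tsv":
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 3:
                    raise CorpusError(f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}")
                doc = RawDocument(doc_id=parts[0], text=parts[2], ref_label=parts[1] or None)
            else:
                raise ValueError(f"unknown format: {format!r}")
            if doc.doc_id in seen:
                raise CorpusError(f"{path}:{lineno}: duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)
            if not doc.text.strip():
                dropped += 1
                continue
            docs.append(doc)
    if dropped:
        logger.info("read_corpus: dropped %d empty-text record(s) from %s", dropped, path)
    return docs


def write_corpus(docs: Iterable[RawDocument], path: str | Path, format: str = "jsonl") -> None:
    """Inverse of :func:`read_corpus` on admitted records."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in docs:
            if format == "jsonl":
                rec: dict = {"doc_id": doc.doc_id, "text": doc.text}
                if doc.vocab_terms is not None:
                    rec["vocab_terms"] = doc.vocab_terms
                if doc.ref_label is not None:
                    rec["ref_label"] = doc.ref_label
                fh.write(json.dumps(rec, sort_keys=True) + "\n")
            elif format == "tsv":
                if "\t" in doc.text or "\n" in doc.text:
                    raise CorpusError(f"doc {doc.doc_id!r}: text contains tab/newline, not TSV-safe")
                fh.write(f"{doc.doc_id}\t{doc.ref_label or ''}\t{doc.text}\n")
            else:
                raise ValueError(f"unknown format: {format!r}")


# ---------------------------------------------------------------------------
# Tokenization and weighting


def tokenize(doc: RawDocument, cfg: TokenConfig) -> Counter:
    """Bag-of-terms for one document.

    Unigrams are lowercased (if configured), stripped of stopwords and
    short tokens; bigrams join adjacent *surviving* unigrams; controlled
    terms are appended verbatim under the ``cv:`` prefix.
    """
    words = _TOKEN_RE.findall(doc.text)
    if cfg.lowercase:
        words = [w.lower() for w in words]
    words = [w for w in words if len(w) >= cfg.min_token_length and w not in cfg.stopwords]
    bag: Counter = Counter()
    if cfg.use_unigrams:
        bag.update(words)
    if cfg.use_bigrams:
        bag.update(a + BIGRAM_SEP + b for a, b in zip(words, words[1:]))
    if cfg.use_vocab_terms and doc.vocab_terms:
        bag.update(CV_PREFIX + t for t in doc.vocab_terms)
    return bag


def build_vocabulary(token_docs: Sequence[Mapping[str, int]], cfg: TokenConfig) -> Vocabulary:
    """Collect document frequencies and drop terms below ``min_df``.

    Terms are indexed in sorted order so the vocabulary — and everything
    downstream — is invariant to document order.
    """
    if len(token_docs) == 0:
        raise CorpusError("cannot build a vocabulary from zero documents")
    df_counter: Counter = Counter()
    for bag in token_docs:
        df_counter.update(bag.keys())
    terms = sorted(t for t, c in df_counter.items() if c >= cfg.min_df)
    df = np.array([df_counter[t] for t in terms], dtype=np.int64)
    return Vocabulary(terms=terms, df=df, n_docs=len(token_docs))


def tfidf_weight(count: int, df: int, n_docs: int, scheme: str = "log") -> float:
    """Single-cell weight: tf-component × idf-component.

    ``log`` uses tf = 1+ln(count); ``raw`` uses tf = count. The idf
    component is ln(N/df) in both, so a ubiquitous term weighs zero.
    """
    if count <= 0:
        return 0.0
    if scheme == "log":
        tf = 1.0 + math.log(count)
    elif scheme == "raw":
        tf = float(count)
    else:
        raise ValueError(f"unknown tf-idf scheme: {scheme!r}")
    return tf * math.log(n_docs / df)


def compute_tfidf(
    doc_ids: Sequence[str],
    token_docs: Sequence[Mapping[str, int]],
    vocab: Vocabulary,
    scheme: str = "log",
) -> CorpusMatrix:
    """Stack per-document tf-idf rows into a :class:`CorpusMatrix`.

    Terms outside the vocabulary are silently skipped; explicit zeros
    (ubiquitous terms) are eliminated from the sparse structure.
    """
    if len(doc_ids) != len(token_docs):
        raise CorpusError("doc_ids and token_docs length mismatch")
    indptr = [0]
    indices: list[int] = []
    data: list[float] = []
    for bag in token_docs:
        for term, count in bag.items():
            j = vocab.index.get(term)
            if j is None:
                continue
            w = tfidf_weight(count, int(vocab.df[j]), vocab.n_docs, scheme)
            if w != 0.0:
                indices.append(j)
                data.append(w)
        indptr.append(len(indices))
    X = sp.csr_matrix(
        (np.array(data), np.array(indices, dtype=np.int32), np.array(indptr, dtype=np.int32)),
        shape=(len(doc_ids), len(vocab)),
    )
    X.sort_indices()
    return CorpusMatrix(doc_ids=list(doc_ids), vocab=vocab, X=X)


def build_matrix(
    docs: Sequence[RawDocument], cfg: TokenConfig | None = None, scheme: str = "log"
) -> CorpusMatrix:
    """Tokenize, build the vocabulary and weight in one step."""
    cfg = cfg or TokenConfig()
    bags = [tokenize(d, cfg) for d in docs]
    vocab = build_vocabulary(bags, cfg)
    return compute_tfidf([d.doc_id for d in docs], bags, vocab, scheme)
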