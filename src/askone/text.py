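"""Bag-of-terms representation of parental concern narratives.

Narratives are short free texts (a few to a few hundred words). They are
represented by word n-grams (unigrams, bigrams, trigrams) built over the
stopword-filtered token stream, optionally augmented with "lexical affinity"
terms: unordered word pairs that co-occur within a +/-5-token window more
often than chance predicts (ranked by document-level pointwise mutual
information). Terms below a minimum document frequency (default 10) are
dropped.

The central class is :class:`TextFeaturizer`, a sklearn-style transformer.
Documents may be raw strings (tokenized internally) or pre-tokenized lists
of tokens, which lets callers amortize tokenization across repeated fits
(e.g. leave-one-out loops).
"""

from __future__ import annotations

import importlib.resources
import math
import re
import warnings
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "tokenize",
    "load_stopwords",
    "VocabTerm",
    "Vocabulary",
    "TextFeaturizer",
]

_APOSTROPHES = re.compile(r"[’']")
_NON_ALPHA = re.compile(r"[^a-z\s]+")

TERM_KINDS = ("unigram", "bigram", "trigram", "affinity")

#: separator inside n-gram terms / affinity terms
_NGRAM_SEP = " "
_AFFINITY_SEP = "~"


def tokenize(text: str) -> list[str]:
    """Lowercased alphabetic tokens; apostrophes removed, other punctuation
    and digits treated as separators.

    ``"He doesn't point!"`` -> ``["he", "doesnt", "point"]``. Empty or
    whitespace-only input yields an empty list with a warning.
    """
    if not text or not text.strip():
        warnings.warn("tokenize: empty or whitespace-only text", stacklevel=2)
        return []
    t = _APOSTROPHES.sub("", text.lower())
    t = _NON_ALPHA.sub(" ", t)
    return t.split()


def load_stopwords() -> frozenset[str]:
    """The bundled English stopword list."""
    path = importlib.resources.files("askone.data").joinpath("stopwords.txt")
    words = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.append(line)
    return frozenset(words)


def _as_tokens(doc) -> list[str]:
    if isinstance(doc, str):
        return tokenize(doc)
    return list(doc)


@dataclass(frozen=True)
class VocabTerm:
    term: str
    kind: str  # unigram / bigram / trigram / affinity
    document_frequency: int


@dataclass
class Vocabulary:
    """Ordered term list with deterministic ordering.

    Terms are grouped by kind in the order unigram, bigram, trigram,
    affinity, and sorted lexicographically within each kind, so the index
    assignment is invariant to corpus order.
    """

    terms: list[VocabTerm]

    def __post_init__(self) -> None:
        self.index = {t.term: i for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.terms:
                fh.write(f"{t.term}\t{t.kind}\t{t.document_frequency}\n")

    @classmethod
    def from_tsv(cls, path) -> "Vocabulary":
        terms = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                term, kind, df = line.split("\t")
                terms.append(VocabTerm(term, kind, int(df)))
        return cls(terms)


def _ngrams(tokens: Sequence[str], n: int) -> Iterable[str]:
    for i in range(len(tokens) - n + 1):
        yield _NGRAM_SEP.join(tokens[i : i + n])


def _affinity_pairs(tokens: Sequence[str], window: int) -> set[str]:
    """Unordered within-window co-occurring pairs of distinct words."""
    pairs: set[str] = set()
    for i, w in enumerate(tokens):
        for k in range(i + 1, min(i + 1 + window, len(tokens))):
            v = tokens[k]
            if v == w:
                continue
            a, b = sorted((w, v))
            pairs.add(f"{a}{_AFFINITY_SEP}{b}")
    return pairs


class TextFeaturizer(TransformerMixin, BaseEstimator):
    """Vectorize narratives as n-grams (1-3) plus optional lexical affinities.

    Parameters
    ----------
    min_df : int, default 10
        Minimum number of documents a term must appear in.
    ngram_max : int, default 3
        Largest n-gram order (1..3).
    use_affinities : bool, default False
        Add windowed co-occurrence pair terms ranked by PMI.
    affinity_window : int, default 5
        Co-occurrence window (tokens, after stopword removal).
    affinity_top_k : int, default 200
        Keep at most this many affinity terms (highest PMI first).
    binary : bool, default True
        Presence/absence features; if False, counts.
    stop_words : iterable of str or None
        Stopword list; None uses the bundled English list.

    Attributes
    ----------
    vocabulary_ : Vocabulary
        Ordered terms with kinds and document frequencies.
    """

    def __init__(
        self,
        min_df: int = 10,
        ngram_max: int = 3,
        use_affinities: bool = False,
        affinity_window: int = 5,
        affinity_top_k: int = 200,
        binary: bool = True,
        stop_words=None,
    ):
        self.min_df = min_df
        self.ngram_max = ngram_max
        self.use_affinities = use_affinities
        self.affinity_window = affinity_window
        self.affinity_top_k = affinity_top_k
        self.binary = binary
        self.stop_words = stop_words

    # -- internals ---------------------------------------------------------

    def _stopset(self) -> frozenset[str]:
        if self.stop_words is None:
            return load_stopwords()
        return frozenset(self.stop_words)

    def _filtered(self, doc) -> list[str]:
        stop = self._stopset_
        return [t for t in _as_tokens(doc) if t not in stop]

    def _doc_terms(self, tokens: list[str]) -> Counter:
        """All candidate n-gram terms of one document, with counts."""
        c: Counter = Counter()
        for n in range(1, self.ngram_max + 1):
            c.update(_ngrams(tokens, n))
        return c

    # -- sklearn API -------------------------------------------------------

    def fit(self, raw_documents, y=None) -> "TextFeaturizer":
        if len(raw_documents) == 0:
            raise ValueError("corpus must be non-empty")
        if self.min_df < 1:
            raise ValueError("min_df must be >= 1")
        if not 1 <= self.ngram_max <= 3:
            raise ValueError("ngram_max must be in 1..3")
        self._stopset_ = self._stopset()
        n_docs = len(raw_documents)
        streams = [self._filtered(d) for d in raw_documents]

        if self.min_df > n_docs:
            warnings.warn(
                f"min_df={self.min_df} exceeds corpus size {n_docs}; "
                "vocabulary is empty",
                stacklevel=2,
            )

        df: Counter = Counter()
        for toks in streams:
            df.update(self._doc_terms(toks).keys())

        terms: list[VocabTerm] = []
        kind_of = {1: "unigram", 2: "bigram", 3: "trigram"}
        for n in range(1, self.ngram_max + 1):
            kept = sorted(
                t
                for t, c in df.items()
                if c >= self.min_df and t.count(_NGRAM_SEP) == n - 1
            )
            terms.extend(VocabTerm(t, kind_of[n], df[t]) for t in kept)

        if self.use_affinities:
            pair_df: Counter = Counter()
            word_df: Counter = Counter()
            for toks in streams:
                pair_df.update(_affinity_pairs(toks, self.affinity_window))
                word_df.update(set(toks))
            candidates = []
            for pair, c in pair_df.items():
                if c < self.min_df:
                    continue
                a, b = pair.split(_AFFINITY_SEP)
                pmi = math.log(c * n_docs / (word_df[a] * word_df[b]))
                candidates.append((-pmi, pair, c))
            candidates.sort()
            for _, pair, c in sorted(
                candidates[: self.affinity_top_k], key=lambda x: x[1]
            ):
                terms.append(VocabTerm(pair, "affinity", c))

        self.vocabulary_ = Vocabulary(terms)
        self.n_features_in_ = None  # transformer over raw text
        return self

    def transform(self, raw_documents) -> sp.csr_matrix:
        if not hasattr(self, "vocabulary_"):
            raise ValueError("TextFeaturizer is not fitted")
        index = self.vocabulary_.index
        has_affinities = any(t.kind == "affinity" for t in self.vocabulary_.terms)
        rows, cols, vals = [], [], []
        for r, doc in enumerate(raw_documents):
            toks = self._filtered(doc)
            counts = self._doc_terms(toks)
            if has_affinities:
                for pair in _affinity_pairs(toks, self.affinity_window):
                    counts[pair] += 1
            for term, c in counts.items():
                j = index.get(term)
                if j is not None:
                    rows.append(r)
                    cols.append(j)
                    vals.append(1 if self.binary else c)
        X = sp.csr_matrix(
            (vals, (rows, cols)),
            shape=(len(raw_documents), len(self.vocabulary_)),
            dtype=np.float64,
        )
        return X

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array([t.term for t in self.vocabulary_.terms], dtype=object)
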