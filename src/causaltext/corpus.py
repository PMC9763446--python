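"""Corpus construction, endpoint labeling, tf-idf statistics and stratified splitting.

A corpus is an ordered collection of labeled sentence instances
``d_i = (x_i, y_i)``: ``x_i`` a tokenized sentence, ``y_i`` a binary
endpoint flag (here: idiosyncratic-DILI positive vs negative).  Sentences
inherit their label from the expert likelihood category of the source drug
record: categories A ("well known") and B ("known or highly likely") define
the positive endpoint; C/D/E/X are negative.

Term weighting follows the classic scheme

    tf-idf(t, d) = tf(t, d) * idf(t),
    tf(t, d)     = count of t in d / number of tokens in d,
    idf(t)       = log(N / (df(t) + 1)),

with natural log by default (switchable to base 10).  Note the ``df+1``
smoothing makes idf negative for a term present in every document; scores
are reported as-is.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "LIKELIHOOD_CATEGORIES",
    "POSITIVE_CATEGORIES",
    "UnknownLikelihoodCategoryError",
    "Instance",
    "Corpus",
    "TfidfReport",
    "SplitResult",
    "tokenize",
    "split_sentences",
    "label_instances",
    "tfidf_score",
    "corpus_stats",
    "stratified_split",
]

POSITIVE = "positive"
NEGATIVE = "negative"

#: Expert likelihood categories for a drug record's hepatotoxic potential:
#: A well known, B known or highly likely, C probable, D possible,
#: E not believed / unlikely, X unknown.
LIKELIHOOD_CATEGORIES = frozenset("ABCDEX")
POSITIVE_CATEGORIES = frozenset("AB")

_TOKEN_RE = re.compile(r"[a-z0-9]+")


class UnknownLikelihoodCategoryError(ValueError):
    """Raised for a likelihood category outside {A, B, C, D, E, X}."""


def tokenize(text: str) -> tuple[str, ...]:
    """Normalize text to a token sequence: lowercase, alphanumeric runs.

    Deterministic and lexicon-matchable; numerals are kept as tokens.
    """
    return tuple(_TOKEN_RE.findall(text.lower()))


# Sentence segmentation: split on {. ! ?} followed by whitespace and an
# upper-case letter or digit.  The whitespace requirement already guards
# decimal numbers ("2.5 mg/dL"); a short abbreviation list guards the rest.
_BOUNDARY_RE = re.compile(r"[.!?]+\s+(?=[A-Z0-9])")
_ABBREVIATIONS = frozenset(
    {"e.g", "i.e", "etc", "vs", "cf", "dr", "mr", "mrs", "ms", "st",
     "fig", "figs", "al", "approx", "ca", "resp"}
)


def split_sentences(document_text: str) -> list[str]:
    """Split a document into sentences with a deterministic rule-based segmenter.

    Returns an empty list for empty/whitespace input.  The concatenation of
    the returned sentences covers the input up to surrounding whitespace.
    """
    text = document_text.strip()
    if not text:
        return []
    sentences: list[str] = []
    start = 0
    for match in _BOUNDARY_RE.finditer(text):
        candidate = text[start : match.end()].rstrip()
        # word immediately before the terminator, with internal periods
        # (handles "e.g." and "et al.")
        head = re.search(r"([A-Za-z][A-Za-z.]*)[.!?]+$", candidate)
        if head is not None and head.group(1).rstrip(".").lower() in _ABBREVIATIONS:
            continue
        sentences.append(candidate)
        start = match.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


@dataclass(frozen=True)
class Instance:
    """One labeled sentence ``d_i = (x_i, y_i)``."""

    id: str
    raw_text: str
    tokens: tuple[str, ...]
    label: str
    source_record: str | None = None
    source_section: str | None = None

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be {POSITIVE!r} or {NEGATIVE!r}, got {self.label!r}")

    @property
    def y(self) -> int:
        """Endpoint as 0/1."""
        return 1 if self.label == POSITIVE else 0

    @classmethod
    def from_text(
        cls,
        id: str,
        raw_text: str,
        label: str,
        source_record: str | None = None,
        source_section: str | None = None,
    ) -> "Instance":
        return cls(id, raw_text, tokenize(raw_text), label, source_record, source_section)


@dataclass(frozen=True)
class Corpus:
    """An ordered collection of instances with unique ids."""

    instances: tuple[Instance, ...]

    def __post_init__(self) -> None:
        ids = [inst.id for inst in self.instances]
        if len(set(ids)) != len(ids):
            raise ValueError("instance ids must be unique")

    @property
    def n(self) -> int:
        return len(self.instances)

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.instances)

    def ids(self) -> list[str]:
        return [inst.id for inst in self.instances]

    def labels(self) -> dict[str, int]:
        """Mapping instance id -> endpoint (0/1)."""
        return {inst.id: inst.y for inst in self.instances}

    def positive_ratio(self) -> float:
        if self.n == 0:
            raise ValueError("empty corpus has no positive ratio")
        return sum(inst.y for inst in self.instances) / self.n

    def subset(self, keep_ids: Iterable[str]) -> "Corpus":
        keep = set(keep_ids)
        return Corpus(tuple(inst for inst in self.instances if inst.id in keep))

    # -- line-delimited record I/O ------------------------------------

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for inst in self.instances:
                record = {"id": inst.id, "text": inst.raw_text, "label": inst.label}
                if inst.source_record is not None:
                    record["source_record"] = inst.source_record
                if inst.source_section is not None:
                    record["source_section"] = inst.source_section
                fh.write(json.dumps(record) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "Corpus":
        instances = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                record = json.loads(line)
                instances.append(
                    Instance.from_text(
                        id=str(record["id"]),
                        raw_text=record["text"],
                        label=record["label"],
                        source_record=record.get("source_record"),
                        source_section=record.get("source_section"),
                    )
                )
        return cls(tuple(instances))


def label_instances(
    sentences: Sequence[tuple[str, str]],
    id_prefix: str = "s",
    source_records: Sequence[str | None] | None = None,
) -> Corpus:
    """Build a labeled corpus from (sentence, likelihood_category) pairs.

    A sentence is endpoint-positive iff its source record's likelihood
    category is A or B; otherwise negative.  Sentences that state the
    likelihood score itself must be excluded by the caller beforehand.

    Raises
    ------
    UnknownLikelihoodCategoryError
        For a category outside {A, B, C, D, E, X}.
    """
    width = max(1, len(str(max(len(sentences) - 1, 0))))
    instances = []
    for i, (text, category) in enumerate(sentences):
        category = category.strip().upper()
        if category not in LIKELIHOOD_CATEGORIES:
            raise UnknownLikelihoodCategoryError(
                f"unknown likelihood category {category!r} (expected one of A,B,C,D,E,X)"
            )
        label = POSITIVE if category in POSITIVE_CATEGORIES else NEGATIVE
        source = source_records[i] if source_records is not None else None
        instances.append(
            Instance.from_text(f"{id_prefix}{i:0{width}d}", text, label, source_record=source)
        )
    return Corpus(tuple(instances))


def _document_frequencies(corpus: Corpus) -> dict[str, int]:
    df: dict[str, int] = {}
    for inst in corpus:
        for token in set(inst.tokens):
            df[token] = df.get(token, 0) + 1
    return df


def tfidf_score(
    t: str,
    d: Sequence[str],
    corpus: Corpus,
    log_base: float = math.e,
) -> float:
    """tf-idf of term ``t`` in document ``d`` against ``corpus``.

    ``tf = count(t in d)/len(d)``; ``idf = log(N/(df+1))``.  A term absent
    from ``d`` scores 0; ``df+1 == N`` forces idf (hence the score) to 0;
    ``df+1 > N`` yields a negative score.
    """
    if corpus.n == 0:
        raise ValueError("corpus must be non-empty")
    if len(d) == 0:
        raise ValueError("document must be non-empty")
    tf = sum(1 for token in d if token == t) / len(d)
    if tf == 0.0:
        return 0.0
    df = sum(1 for inst in corpus if t in inst.tokens)
    idf = math.log(corpus.n / (df + 1)) / math.log(log_base)
    return tf * idf


@dataclass(frozen=True)
class TfidfReport:
    """Corpus-level token statistics and top terms by maximal tf-idf."""

    vocabulary_size: int
    length_mean: float
    length_sd: float
    top_terms: tuple[tuple[str, float], ...]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("term\tmax_tfidf\n")
            for term, score in self.top_terms:
                fh.write(f"{term}\t{score:.6g}\n")


def corpus_stats(corpus: Corpus, top_k: int = 10, log_base: float = math.e) -> TfidfReport:
    """Vocabulary size, token-length mean/sd and top-k terms by max tf-idf.

    Length sd is the population standard deviation.  Each term is ranked by
    its maximum tf-idf over documents; ties break lexicographically.
    """
    if corpus.n == 0:
        raise ValueError("corpus must be non-empty")
    lengths = np.array([len(inst.tokens) for inst in corpus], dtype=float)
    df = _document_frequencies(corpus)
    n = corpus.n
    log_scale = math.log(log_base)
    idf = {t: math.log(n / (c + 1)) / log_scale for t, c in df.items()}
    best: dict[str, float] = {}
    for inst in corpus:
        if not inst.tokens:
            continue
        inv_len = 1.0 / len(inst.tokens)
        counts: dict[str, int] = {}
        for token in inst.tokens:
            counts[token] = counts.get(token, 0) + 1
        for token, c in counts.items():
            score = c * inv_len * idf[token]
            if token not in best or score > best[token]:
                best[token] = score
    ranked = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    return TfidfReport(
        vocabulary_size=len(df),
        length_mean=float(lengths.mean()),
        length_sd=float(lengths.std(ddof=0)),
        top_terms=tuple(ranked),
    )


@dataclass(frozen=True)
class SplitResult:
    """A stratified train/test partition of a corpus."""

    train: Corpus
    test: Corpus
    train_fraction: float
    per_class_counts: dict[str, tuple[int, int]] = field(compare=False)


def stratified_split(corpus: Corpus, train_fraction: float, seed: int) -> SplitResult:
    """Class-stratified split preserving per-class proportions within 1 instance.

    Per class the train count is ``floor(class_n * train_fraction)`` and the
    remainder goes to the test set; membership within a class is a seeded
    permutation, so the split is deterministic for a fixed seed.  For the
    14,361-sentence corpus with 3,578 positives at fraction 0.9 this yields
    a 12,924 / 1,437 train/test partition.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    by_label: dict[str, list[int]] = {}
    for idx, inst in enumerate(corpus):
        by_label.setdefault(inst.label, []).append(idx)
    if len(by_label) < 2:
        raise ValueError("both endpoint classes must be present")
    for label, members in by_label.items():
        if len(members) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 members")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    per_class: dict[str, tuple[int, int]] = {}
    for label in sorted(by_label):
        members = np.array(by_label[label])
        perm = rng.permutation(len(members))
        n_train = int(math.floor(len(members) * train_fraction))
        chosen = members[perm[:n_train]]
        rest = members[perm[n_train:]]
        train_idx.extend(chosen.tolist())
        test_idx.extend(rest.tolist())
        per_class[label] = (len(chosen), len(rest))
    train_idx.sort()
    test_idx.sort()
    train = Corpus(tuple(corpus.instances[i] for i in train_idx))
    test = Corpus(tuple(corpus.instances[i] for i in test_idx))
    return SplitResult(train=train, test=test, train_fraction=train_fraction, per_class_counts=per_class)
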