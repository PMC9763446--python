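"""Gazetteer named-entity recognition over tokenized instances.

A lexicon maps normalized surface forms (token sequences) to entity ids in
three categories (drug, gene, disease); synonyms are allowed.  Matching is
case-insensitive (tokens are lowercased by the corpus tokenizer), scans for
contiguous token subsequences, and resolves overlaps longest-match-first,
so "acute liver failure" suppresses a nested "liver failure".

The corpus-wide occurrence map records, per entity, the *set of instances*
containing at least one mention — presence, not mention counts, is what the
do-calculus partition needs — and a frequency filter keeps entities seen in
strictly more than ``min_exclusive`` instances (default 50).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .corpus import Corpus, Instance, tokenize

__all__ = [
    "CATEGORIES",
    "EntityLexicon",
    "EntityOccurrence",
    "extract_entities",
    "build_occurrence",
    "frequency_filter",
    "vocabulary_compression",
]

CATEGORIES = ("drug", "gene", "disease")


@dataclass
class EntityLexicon:
    """Surface form (token tuple) -> (entity id, category); many forms per id."""

    entries: dict[tuple[str, ...], tuple[str, str]] = field(default_factory=dict)

    def add(self, surface_form: str, entity_id: str, category: str) -> None:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}")
        form = tokenize(surface_form)
        if not form:
            raise ValueError(f"surface form {surface_form!r} normalizes to nothing")
        self.entries[form] = (entity_id, category)

    def __len__(self) -> int:
        return len(self.entries)

    def entity_ids(self) -> set[str]:
        return {eid for eid, _ in self.entries.values()}

    def categories(self) -> dict[str, str]:
        """Mapping entity id -> category."""
        return {eid: cat for eid, cat in self.entries.values()}

    # grouped by first token, longest form first, for the matcher
    def _index(self) -> dict[str, list[tuple[str, ...]]]:
        by_first: dict[str, list[tuple[str, ...]]] = {}
        for form in self.entries:
            by_first.setdefault(form[0], []).append(form)
        for forms in by_first.values():
            forms.sort(key=len, reverse=True)
        return by_first

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("surface_form\tentity_id\tcategory\n")
            for form, (eid, cat) in self.entries.items():
                fh.write(f"{' '.join(form)}\t{eid}\t{cat}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EntityLexicon":
        lexicon = cls()
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                surface, eid, cat = line.split("\t")
                lexicon.add(surface, eid, cat)
        return lexicon


@dataclass(frozen=True)
class EntityOccurrence:
    """Per-entity instance-id support sets over a corpus."""

    instance_sets: Mapping[str, frozenset[str]]
    categories: Mapping[str, str]

    def frequency(self, entity_id: str) -> int:
        return len(self.instance_sets[entity_id])

    def entity_ids(self) -> set[str]:
        return set(self.instance_sets)

    def __len__(self) -> int:
        return len(self.instance_sets)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("entity_id\tcategory\tfrequency\n")
            for eid in sorted(self.instance_sets):
                fh.write(f"{eid}\t{self.categories.get(eid, '?')}\t{self.frequency(eid)}\n")


def extract_entities(instance: Instance, lexicon: EntityLexicon) -> set[str]:
    """Entity ids mentioned in one instance (longest match wins, set semantics)."""
    return _extract_from_tokens(instance.tokens, lexicon._index(), lexicon.entries)


def _extract_from_tokens(
    tokens: tuple[str, ...],
    index: dict[str, list[tuple[str, ...]]],
    entries: Mapping[tuple[str, ...], tuple[str, str]],
) -> set[str]:
    found: set[str] = set()
    i = 0
    n = len(tokens)
    while i < n:
        candidates = index.get(tokens[i])
        matched = False
        if candidates:
            for form in candidates:  # longest first
                if tokens[i : i + len(form)] == form:
                    found.add(entries[form][0])
                    i += len(form)
                    matched = True
                    break
        if not matched:
            i += 1
    return found


def build_occurrence(corpus: Corpus, lexicon: EntityLexicon) -> EntityOccurrence:
    """Union of per-instance extractions; frequency counts supporting instances."""
    index = lexicon._index()
    sets: dict[str, set[str]] = {}
    for inst in corpus:
        for eid in _extract_from_tokens(inst.tokens, index, lexicon.entries):
            sets.setdefault(eid, set()).add(inst.id)
    return EntityOccurrence(
        instance_sets={eid: frozenset(ids) for eid, ids in sets.items()},
        categories=lexicon.categories(),
    )


def frequency_filter(occ: EntityOccurrence, min_exclusive: int = 50) -> EntityOccurrence:
    """Keep entities whose instance frequency is strictly greater than the bound."""
    if min_exclusive < 0:
        raise ValueError("min_exclusive must be >= 0")
    kept = {eid: ids for eid, ids in occ.instance_sets.items() if len(ids) > min_exclusive}
    return EntityOccurrence(
        instance_sets=kept,
        categories={eid: occ.categories[eid] for eid in kept if eid in occ.categories},
    )


def vocabulary_compression(full_vocabulary_size: int, entity_count: int) -> float:
    """Fraction of the corpus vocabulary discarded by restricting to entities.

    Narrowing 15,804 unique words to 87 entities compresses by ~0.994.
    """
    if full_vocabulary_size <= 0:
        raise ValueError("full vocabulary size must be positive")
    return 1.0 - entity_count / full_vocabulary_size
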