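"""Dictionary-based clinical concept extraction with negation.

This is a deliberately simple stand-in for a full clinical NLP concept
extractor: surface phrases from a concept dictionary are matched greedily
left-to-right (longest match wins, matched spans are consumed), and each
mention is checked for negation with a NegEx-style rule — a negation trigger
within a fixed window before the mention, with no scope-terminating token in
between. Negated and affirmed mentions become *separate* count features,
because a note that says "denies alcohol abuse" is evidence against the
phenotype, not for it.

TF-IDF weighting uses the unsmoothed form ``tf · ln(N / df)`` so a feature
present in every document receives weight exactly zero.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

Phrase = tuple[str, ...]

#: NegEx-lite pre-triggers; multi-token triggers are supported.
DEFAULT_TRIGGERS: frozenset[Phrase] = frozenset({
    ("no",), ("denies",), ("without",), ("not",), ("negative", "for"),
})
#: Tokens that terminate a negation scope.
DEFAULT_TERMINATORS: frozenset[str] = frozenset({"but", "however"})
DEFAULT_SCOPE_WINDOW = 5


@dataclass
class ConceptDictionary:
    """concept_id → surface phrases, phenotype tags, and a display name."""

    surfaces: dict[str, tuple[Phrase, ...]]
    tags: dict[str, frozenset[str]] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, phrases in self.surfaces.items():
            if not phrases or any(len(p) == 0 for p in phrases):
                raise ValueError(f"concept {cid} has an empty surface form")
            if len(set(phrases)) != len(phrases):
                raise ValueError(f"concept {cid} has duplicate surface forms")

    @property
    def concept_ids(self) -> list[str]:
        return sorted(self.surfaces)

    def all_phenotypes(self) -> set[str]:
        return set().union(*self.tags.values()) if self.tags else set()

    def to_tsv(self, path: str | Path) -> None:
        """One line per (concept, surface): id, phrase, comma-joined tags."""
        with open(path, "w") as fh:
            for cid in self.concept_ids:
                tag_str = ",".join(sorted(self.tags.get(cid, ())))
                for phrase in self.surfaces[cid]:
                    fh.write(f"{cid}\t{' '.join(phrase)}\t{tag_str}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConceptDictionary":
        surfaces: dict[str, list[Phrase]] = {}
        tags: dict[str, frozenset[str]] = {}
        names: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
                cid, phrase_str, tag_str = parts
                phrase = tuple(phrase_str.split())
                surfaces.setdefault(cid, []).append(phrase)
                tags[cid] = frozenset(t for t in tag_str.split(",") if t)
                names.setdefault(cid, phrase_str)
        return cls(surfaces={c: tuple(p) for c, p in surfaces.items()},
                   tags=tags, names=names)


@dataclass(frozen=True)
class ConceptMention:
    concept_id: str
    start: int
    end: int  # half-open token span
    negated: bool = False


def tag_concepts(tokens: Sequence[str], dictionary: ConceptDictionary
                 ) -> list[ConceptMention]:
    """Greedy left-to-right longest-match tagging; matched spans are consumed
    so mentions never overlap. Negation flags are not set here — see
    :func:`detect_negation` / :func:`tag_and_flag`."""
    # index surfaces by first token, longest first for the greedy scan
    by_first: dict[str, list[tuple[Phrase, str]]] = {}
    for cid, phrases in dictionary.surfaces.items():
        for phrase in phrases:
            by_first.setdefault(phrase[0], []).append((phrase, cid))
    for entries in by_first.values():
        entries.sort(key=lambda e: (-len(e[0]), e[1]))

    mentions: list[ConceptMention] = []
    i, n = 0, len(tokens)
    while i < n:
        matched = False
        for phrase, cid in by_first.get(tokens[i], ()):
            end = i + len(phrase)
            if end <= n and tuple(tokens[i:end]) == phrase:
                mentions.append(ConceptMention(concept_id=cid, start=i, end=end))
                i = end
                matched = True
                break
        if not matched:
            i += 1
    return mentions


def detect_negation(tokens: Sequence[str], mention: ConceptMention,
                    trigger_set: Iterable[Phrase] = DEFAULT_TRIGGERS,
                    scope_window: int = DEFAULT_SCOPE_WINDOW,
                    terminators: Iterable[str] = DEFAULT_TERMINATORS) -> bool:
    """True iff a pre-trigger occurs within ``scope_window`` tokens before the
    mention with no scope terminator between trigger end and mention start."""
    triggers = [t if isinstance(t, tuple) else tuple(t) for t in trigger_set]
    stop = set(terminators)
    lo = max(0, mention.start - scope_window)
    for p in range(lo, mention.start):
        for trig in triggers:
            t_end = p + len(trig)
            if t_end <= mention.start and tuple(tokens[p:t_end]) == trig:
                if not any(tok in stop for tok in tokens[t_end:mention.start]):
                    return True
    return False


def tag_and_flag(tokens: Sequence[str], dictionary: ConceptDictionary,
                 scope_window: int = DEFAULT_SCOPE_WINDOW) -> list[ConceptMention]:
    """Tag concepts and set each mention's negation flag."""
    return [
        ConceptMention(m.concept_id, m.start, m.end,
                       negated=detect_negation(tokens, m, scope_window=scope_window))
        for m in tag_concepts(tokens, dictionary)
    ]


@dataclass
class ConceptBag:
    """Per-note mention counts keyed by ``(concept_id, negated)``."""

    note_id: str
    counts: Counter = field(default_factory=Counter)

    @classmethod
    def from_mentions(cls, note_id: str, mentions: Iterable[ConceptMention]
                      ) -> "ConceptBag":
        bag = cls(note_id=note_id)
        for m in mentions:
            bag.counts[(m.concept_id, m.negated)] += 1
        return bag

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def build_bags(mentions_per_note: Mapping[str, Sequence[ConceptMention]]
               ) -> list[ConceptBag]:
    return [ConceptBag.from_mentions(nid, ms)
            for nid, ms in mentions_per_note.items()]


def filter_bag(bag: ConceptBag, phenotype: str,
               dictionary: ConceptDictionary) -> ConceptBag:
    """Keep only features whose concept carries the given phenotype tag
    (the clinician-filtered dictionary arm). Counts are unchanged."""
    if phenotype not in dictionary.all_phenotypes():
        raise KeyError(f"unknown phenotype {phenotype!r}")
    kept = Counter({
        (cid, neg): c for (cid, neg), c in bag.counts.items()
        if phenotype in dictionary.tags.get(cid, ())
    })
    return ConceptBag(note_id=bag.note_id, counts=kept)


# ---------------------------------------------------------------------------
# Vectorization and TF-IDF

FeatureKey = tuple[str, bool]


@dataclass
class BagVectorizer:
    """Maps (concept_id, negated) feature keys to fixed columns.

    With ``merge_negation=True`` the negation flag is dropped from the key,
    collapsing affirmed and negated counts into one column (the ablation that
    shows why the counts must be kept separate).
    """

    feature_index: dict[FeatureKey | str, int]
    merge_negation: bool = False

    @classmethod
    def fit(cls, bags: Sequence[ConceptBag], merge_negation: bool = False
            ) -> "BagVectorizer":
        keys: set = set()
        for bag in bags:
            for (cid, neg) in bag.counts:
                keys.add(cid if merge_negation else (cid, neg))
        index = {k: i for i, k in enumerate(sorted(keys, key=repr))}
        return cls(feature_index=index, merge_negation=merge_negation)

    @property
    def n_features(self) -> int:
        return len(self.feature_index)

    def feature_names(self) -> list[str]:
        out = []
        for key, _ in sorted(self.feature_index.items(), key=lambda kv: kv[1]):
            if self.merge_negation:
                out.append(str(key))
            else:
                cid, neg = key
                out.append(f"{cid}:{'negated' if neg else 'affirmed'}")
        return out

    def transform(self, bags: Sequence[ConceptBag]) -> sp.csr_matrix:
        rows, cols, vals = [], [], []
        for r, bag in enumerate(bags):
            acc: Counter = Counter()
            for (cid, neg), c in bag.counts.items():
                key = cid if self.merge_negation else (cid, neg)
                if key in self.feature_index:
                    acc[self.feature_index[key]] += c
            for col, c in acc.items():
                rows.append(r)
                cols.append(col)
                vals.append(c)
        return sp.csr_matrix(
            (np.asarray(vals, dtype=float), (rows, cols)),
            shape=(len(bags), max(self.n_features, 1)))


@dataclass
class TfidfWeighter:
    """Unsmoothed TF-IDF: weight(d, t) = count(d, t) · ln(N / df(t)).

    ``df`` and ``N`` come from the fit corpus (the training split); features
    unseen at fit time get idf 0. A feature present in all N fit documents
    has idf ln(1) = 0, i.e. carries no weight anywhere.
    """

    idf: np.ndarray
    n_documents: int

    @classmethod
    def fit(cls, counts: sp.spmatrix) -> "TfidfWeighter":
        n_docs = counts.shape[0]
        if n_docs == 0:
            raise ValueError("TF-IDF requires at least one document")
        df = np.asarray((counts > 0).sum(axis=0)).ravel()
        idf = np.zeros(counts.shape[1])
        seen = df > 0
        idf[seen] = np.log(n_docs / df[seen])
        return cls(idf=idf, n_documents=n_docs)

    def transform(self, counts: sp.spmatrix) -> sp.csr_matrix:
        return sp.csr_matrix(counts.multiply(self.idf))


def tfidf(counts: sp.spmatrix) -> sp.csr_matrix:
    """Fit-and-transform convenience for a single document collection."""
    return TfidfWeighter.fit(counts).transform(counts)


def export_triplets(matrix: sp.spmatrix, note_ids: Sequence[str],
                    feature_names: Sequence[str], path: str | Path) -> None:
    """Sparse triplet text export: note_id <tab> feature <tab> value."""
    coo = sp.coo_matrix(matrix)
    order = np.lexsort((coo.col, coo.row))
    with open(path, "w") as fh:
        for k in order:
            fh.write(f"{note_ids[coo.row[k]]}\t{feature_names[coo.col[k]]}\t"
                     f"{coo.data[k]:g}\n")
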