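"""Dictionary tagging of protein names, interaction words, context terms.

Protein tagging is a "soft" maximum-length dictionary match: the sentence
is matched on a working copy where every non-word character becomes a
space (so ``CD2+`` matches dictionary entry ``CD2``), single-token
entries match case-sensitively while multi-token entries match
case-insensitively, and a matched name may be extended rightward through
general modifier tokens (``beta``, ``alpha``...) and domain head nouns
(``receptor``...).  Interaction words and context terms are tagged by
case-insensitive whole-token matching.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

from pinminer.corpus import AbstractRecord, Sentence

_NON_WORD = re.compile(r"[^A-Za-z0-9_]")
_TOKEN = re.compile(r"\S+")

#: at most this many modifier/head tokens are appended to a match
MAX_EXTENSIONS = 2


def softened(text: str) -> str:
    """Replace every non-word character with a space (length-preserving)."""
    return _NON_WORD.sub(" ", text)


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """(token, start, end) triples over whitespace-separated tokens."""
    return [(m.group(), m.start(), m.end()) for m in _TOKEN.finditer(text)]


def _default_stopwords() -> set[str]:
    data = resources.files("pinminer.data").joinpath("english_stopwords.txt")
    return {
        line.strip().casefold()
        for line in data.read_text(encoding="utf-8").splitlines()
        if line.strip()
    }


@dataclass(frozen=True)
class Mention:
    """An offset-anchored tagged span in a preprocessed sentence.

    ``start``/``end`` are 0-based half-open offsets into the sentence's
    preprocessed text; ``surface`` always equals the slice.
    """

    kind: str  # protein | interaction | context
    surface: str
    start: int
    end: int
    matched_entry: str
    sentence_ref: tuple[str, int | None]  # (pmid, sentence index; None = abstract scope)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("mention offsets must satisfy 0 <= start < end")


@dataclass
class ProteinDictionary:
    """Protein-name dictionary with soft-match support sets.

    ``general_terms`` are modifier tokens a match may absorb rightward
    (e.g. ``beta``); ``head_extensions`` are domain head nouns (e.g.
    ``receptor``); ``stopwords`` are removed from the entry set at load.
    """

    entries: set[str] = field(default_factory=set)
    general_terms: set[str] = field(default_factory=set)
    head_extensions: set[str] = field(default_factory=set)
    stopwords: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.general_terms = {t.casefold() for t in self.general_terms}
        self.head_extensions = {t.casefold() for t in self.head_extensions}
        self.stopwords = {t.casefold() for t in self.stopwords}
        self._index()

    def _index(self) -> None:
        # single-token entries: exact-case token -> entry
        # multi-token entries: casefolded token tuple -> entry
        self._single: dict[str, str] = {}
        self._multi: dict[tuple[str, ...], str] = {}
        self._max_tokens = 1
        # sorted so collisions resolve deterministically (last wins)
        for entry in sorted(self.entries):
            tokens = softened(entry).split()
            if not tokens:
                continue
            if len(tokens) == 1:
                self._single[tokens[0]] = entry
            else:
                self._multi[tuple(t.casefold() for t in tokens)] = entry
                self._max_tokens = max(self._max_tokens, len(tokens))

    @classmethod
    def load(cls, path, general_terms=(), head_extensions=(), stopwords=None
             ) -> "ProteinDictionary":
        """Read a one-name-per-line UTF-8 dictionary, cleaning as it goes.

        Cleaning drops stopwords (common English words) and one-character
        acronyms/short-forms.
        """

        stop = set(stopwords) if stopwords is not None else _default_stopwords()
        stop = {s.casefold() for s in stop}
        entries = set()
        with open(path, encoding="utf-8") as handle:
            for line in handle:
                name = line.strip()
                if len(name) <= 1 or name.casefold() in stop:
                    continue
                entries.add(name)
        return cls(entries=entries, general_terms=set(general_terms),
                   head_extensions=set(head_extensions), stopwords=stop)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as out:
            for entry in sorted(self.entries):
                out.write(entry + "\n")


@dataclass
class InteractionLexicon:
    """Interaction-word lexicon with per-word direction semantics.

    ``words`` maps each canonical interaction word to ``with_direction``
    or ``without_direction``; ``variants`` maps inflected/hyphenated/
    spelling variants to their canonical word.  Lookup is
    case-insensitive.
    """

    words: dict[str, str] = field(default_factory=dict)
    variants: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.words = {w.casefold(): f for w, f in self.words.items()}
        self.variants = {v.casefold(): w.casefold() for v, w in self.variants.items()}
        for flag in self.words.values():
            if flag not in ("with_direction", "without_direction"):
                raise ValueError(f"bad direction flag: {flag!r}")

    def canonical(self, surface: str) -> str | None:
        key = surface.casefold()
        if key in self.words:
            return key
        return self.variants.get(key)

    def direction_flag(self, word: str) -> str | None:
        canon = self.canonical(word)
        return self.words.get(canon) if canon else None

    def all_forms(self) -> dict[str, str]:
        """Every matchable surface form -> canonical word."""
        forms = {w: w for w in self.words}
        forms.update(self.variants)
        return forms

    @classmethod
    def load(cls, path) -> "InteractionLexicon":
        """Read TSV: ``word<TAB>with_direction|without_direction[<TAB>canonical]``."""
        words, variants = {}, {}
        with open(path, encoding="utf-8") as handle:
            for line in handle:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                cols = line.split("\t")
                if len(cols) == 2:
                    words[cols[0]] = cols[1]
                elif len(cols) == 3:
                    variants[cols[0]] = cols[2]
                else:
                    raise ValueError(f"bad lexicon line: {line!r}")
        return cls(words=words, variants=variants)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as out:
            for word in sorted(self.words):
                out.write(f"{word}\t{self.words[word]}\n")
            for variant in sorted(self.variants):
                canon = self.variants[variant]
                out.write(f"{variant}\t{self.words[canon]}\t{canon}\n")


# ---------------------------------------------------------------------------
# protein tagging


def tag_proteins(sentence: Sentence, dictionary: ProteinDictionary) -> list[Mention]:
    """Leftmost-longest soft dictionary match over a preprocessed sentence.

    At each token position the longest dictionary-matchable token span
    wins; the winning span may then absorb up to two right-adjacent
    general/head-extension tokens.  Mentions never overlap.
    """

    work = softened(sentence.preprocessed)
    tokens = tokenize(work)
    mentions: list[Mention] = []
    i = 0
    while i < len(tokens):
        match = _match_at(tokens, i, dictionary)
        if match is None:
            i += 1
            continue
        entry, n_tokens = match
        last = i + n_tokens - 1
        # rightward extension through modifier / head-noun tokens
        ext = 0
        while ext < MAX_EXTENSIONS and last + 1 < len(tokens):
            nxt = tokens[last + 1][0].casefold()
            if nxt in dictionary.general_terms or nxt in dictionary.head_extensions:
                last += 1
                ext += 1
            else:
                break
        start, end = tokens[i][1], tokens[last][2]
        mentions.append(Mention(
            kind="protein",
            surface=sentence.preprocessed[start:end],
            start=start, end=end,
            matched_entry=entry,
            sentence_ref=(sentence.pmid, sentence.index),
        ))
        i = last + 1
    return mentions


def _match_at(tokens, i, dictionary) -> tuple[str, int] | None:
    """Longest dictionary entry starting at token i, honoring case rules."""
    upper = min(dictionary._max_tokens, len(tokens) - i)
    for length in range(upper, 1, -1):
        key = tuple(tokens[i + k][0].casefold() for k in range(length))
        entry = dictionary._multi.get(key)
        if entry is not None:
            return entry, length
    entry = dictionary._single.get(tokens[i][0])
    if entry is not None:
        return entry, 1
    return None


# ---------------------------------------------------------------------------
# interaction-word tagging


def tag_interaction_words(sentence: Sentence, lexicon: InteractionLexicon
                          ) -> list[Mention]:
    """Tag every lexicon word (and variant) by case-insensitive token match."""

    text = sentence.preprocessed
    candidates: list[tuple[int, int, str]] = []
    for form, canon in lexicon.all_forms().items():
        pattern = re.compile(
            r"(?<![A-Za-z0-9])" + re.escape(form) + r"(?![A-Za-z0-9])", re.IGNORECASE
        )
        for m in pattern.finditer(text):
            candidates.append((m.start(), m.end(), canon))

    # leftmost-longest, non-overlapping
    candidates.sort(key=lambda c: (c[0], -(c[1] - c[0])))
    mentions: list[Mention] = []
    cursor = -1
    for start, end, canon in candidates:
        if start <= cursor:
            continue
        mentions.append(Mention(
            kind="interaction",
            surface=text[start:end],
            start=start, end=end,
            matched_entry=canon,
            sentence_ref=(sentence.pmid, sentence.index),
        ))
        cursor = end - 1
    return mentions


# ---------------------------------------------------------------------------
# context-term tagging


def _find_term(text: str, term: str) -> list[tuple[int, int]]:
    pattern = re.compile(
        r"(?<![A-Za-z0-9])" + re.escape(term) + r"(?![A-Za-z0-9])", re.IGNORECASE
    )
    return [(m.start(), m.end()) for m in pattern.finditer(text)]


def tag_context_terms(record: AbstractRecord, sentences: list[Sentence],
                      expanded_sets) -> list[Mention]:
    """Tag expanded query context terms at sentence and abstract scope.

    Sentence-scope mentions (sentence index set) let the reporting layer
    test sentence-level co-occurrence; abstract-scope mentions (sentence
    index None, offsets into ``record.document_text``) cover title, body
    and MeSH for document-level co-occurrence.
    """

    mentions: list[Mention] = []
    terms = []
    for exp in expanded_sets:
        seed = exp.seed_term
        for term in exp.expansions:
            terms.append((term, seed))

    for sentence in sentences:
        for term, seed in terms:
            for start, end in _find_term(sentence.preprocessed, term):
                mentions.append(Mention(
                    kind="context",
                    surface=sentence.preprocessed[start:end],
                    start=start, end=end,
                    matched_entry=seed,
                    sentence_ref=(sentence.pmid, sentence.index),
                ))

    doc = record.document_text
    for term, seed in terms:
        for start, end in _find_term(doc, term):
            mentions.append(Mention(
                kind="context",
                surface=doc[start:end],
                start=start, end=end,
                matched_entry=seed,
                sentence_ref=(record.pmid, None),
            ))
    return mentions
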