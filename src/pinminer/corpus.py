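"""Abstract retrieval, MEDLINE reading, sentence splitting, preprocessing.

Abstracts come either from an E-utilities-compatible client (live
``Bio.Entrez`` or an offline replay client exposing the same
``search``/``fetch`` contract) or from local MEDLINE-format files.  Each
record is split into sentences (title = sentence 0) and delimiters are
space-normalized while a character map keeps every preprocessed offset
traceable to the raw text.
"""

from __future__ import annotations

import logging
import re
import time
from dataclasses import dataclass, field, replace
from typing import Protocol

from Bio import Medline

logger = logging.getLogger(__name__)


@dataclass
class AbstractRecord:
    pmid: str
    title: str = ""
    body: str = ""
    mesh_terms: list[str] = field(default_factory=list)
    pub_date: str | None = None
    processable: bool = True

    @property
    def document_text(self) -> str:
        """Title, body, and MeSH headings as one searchable string."""
        parts = [self.title, self.body]
        if self.mesh_terms:
            parts.append("; ".join(self.mesh_terms))
        return " ".join(p for p in parts if p)


@dataclass
class Sentence:
    """A sentence with raw text, preprocessed text, and an offset map.

    ``char_map[i]`` is the raw-text offset of preprocessed character
    ``i``, or None when the character was inserted by preprocessing.
    Dropping the inserted characters from ``preprocessed`` reproduces
    ``raw``.
    """

    pmid: str
    index: int
    raw: str
    preprocessed: str
    char_map: list[int | None]

    def raw_span(self, start: int, end: int) -> tuple[int, int] | None:
        """Map a preprocessed [start, end) span back to raw offsets."""
        real = [self.char_map[i] for i in range(start, end) if self.char_map[i] is not None]
        if not real:
            return None
        return real[0], real[-1] + 1

    @classmethod
    def from_raw(cls, pmid: str, index: int, raw: str) -> "Sentence":
        return cls(pmid=pmid, index=index, raw=raw,
                   preprocessed=raw, char_map=list(range(len(raw))))


# ---------------------------------------------------------------------------
# retrieval


class RetrievalClient(Protocol):
    """E-utilities-style contract: esearch then efetch."""

    def search(self, query: str, max_n: int,
               date_range: tuple[str, str] | None = None) -> list[str]: ...

    def fetch(self, pmids: list[str]) -> list[AbstractRecord]: ...


class RetrievalError(RuntimeError):
    def __init__(self, message: str, attempts: int):
        super().__init__(f"{message} (after {attempts} attempts)")
        self.attempts = attempts


class ReplayClient:
    """Offline client replaying canned records; satisfies RetrievalClient."""

    def __init__(self, records: list[AbstractRecord]):
        self._records = {r.pmid: r for r in records}
        self._order = [r.pmid for r in records]

    def search(self, query, max_n, date_range=None):
        hits = []
        for pmid in self._order:
            rec = self._records[pmid]
            if date_range is not None and not _date_in_range(rec.pub_date, date_range):
                continue
            hits.append(pmid)
            if len(hits) >= max_n:
                break
        return hits

    def fetch(self, pmids):
        return [self._records[p] for p in pmids if p in self._records]


class EntrezClient:
    """Live NCBI E-utilities client (opt-in; never used by the tests)."""

    def __init__(self, email: str, api_key: str | None = None, delay: float = 0.34):
        from Bio import Entrez

        Entrez.email = email
        if api_key:
            Entrez.api_key = api_key
        self._entrez = Entrez
        self._delay = delay

    def search(self, query, max_n, date_range=None):
        kwargs = {"db": "pubmed", "term": query, "retmax": max_n}
        if date_range is not None:
            kwargs.update(datetype="pdat", mindate=date_range[0], maxdate=date_range[1])
        with self._entrez.esearch(**kwargs) as handle:
            result = self._entrez.read(handle)
        time.sleep(self._delay)
        return list(result["IdList"])

    def fetch(self, pmids):
        if not pmids:
            return []
        with self._entrez.efetch(db="pubmed", id=",".join(pmids),
                                 rettype="medline", retmode="text") as handle:
            records = list(Medline.parse(handle))
        time.sleep(self._delay)
        return [_medline_to_record(r, i) for i, r in enumerate(records)]


def _date_in_range(pub_date: str | None, date_range: tuple[str, str]) -> bool:
    if pub_date is None:
        return False
    start, end = date_range
    return start <= pub_date <= end


def fetch_abstracts(query, max_n: int, date_range=None,
                    client: RetrievalClient | None = None,
                    retries: int = 3) -> list[AbstractRecord]:
    """Search + fetch at most ``max_n`` abstracts via the client contract.

    Transport failures are retried; a persistent failure raises
    :class:`RetrievalError` carrying the attempt count.  Zero hits return
    an empty list.
    """

    if client is None:
        raise ValueError("a retrieval client is required")
    emitted = getattr(query, "emitted", query)
    last_exc = None
    for attempt in range(1, retries + 1):
        try:
            pmids = client.search(emitted, max_n, date_range)
            records = client.fetch(pmids[:max_n]) if pmids else []
            return records[:max_n]
        except (ConnectionError, TimeoutError, OSError) as exc:
            last_exc = exc
            logger.warning("retrieval attempt %d/%d failed: %s", attempt, retries, exc)
    raise RetrievalError(str(last_exc), attempts=retries)


# ---------------------------------------------------------------------------
# MEDLINE reading


def _medline_to_record(rec: dict, block_index: int) -> AbstractRecord:
    pmid = rec.get("PMID")
    if not pmid:
        raise ValueError(f"MEDLINE block {block_index} has no PMID field")
    body = rec.get("AB", "") or ""
    record = AbstractRecord(
        pmid=pmid,
        title=rec.get("TI", "") or "",
        body=body,
        mesh_terms=list(rec.get("MH", [])),
        pub_date=rec.get("DP"),
        processable=bool(body),
    )
    return record


def read_medline(path) -> list[AbstractRecord]:
    """Read a MEDLINE tagged-format file into AbstractRecords.

    One record per PMID block; continuation-indented field lines are
    unfolded with single spaces (Bio.Medline semantics).  A record with
    no AB field gets an empty body and is flagged unprocessable.
    """

    with open(path, encoding="utf-8") as handle:
        raw_records = list(Medline.parse(handle))
    return [_medline_to_record(r, i) for i, r in enumerate(raw_records)]


def write_medline(records: list[AbstractRecord], path) -> None:
    """Write records back out in MEDLINE tagged format (single-line fields)."""

    with open(path, "w", encoding="utf-8") as out:
        for rec in records:
            out.write(f"PMID- {rec.pmid}\n")
            if rec.pub_date:
                out.write(f"DP  - {rec.pub_date}\n")
            if rec.title:
                out.write(f"TI  - {rec.title}\n")
            if rec.body:
                out.write(f"AB  - {rec.body}\n")
            for mh in rec.mesh_terms:
                out.write(f"MH  - {mh}\n")
            out.write("\n")


# ---------------------------------------------------------------------------
# sentence splitting

#: tokens after which a period never ends a sentence
ABBREVIATIONS = frozenset({
    "i.e", "e.g", "al", "fig", "figs", "vs", "dr", "mr", "mrs", "prof",
    "etc", "ca", "cf", "approx", "no", "nos", "sp", "spp", "st", "resp",
})

_BOUNDARY = re.compile(r"([.!?])(\s+)(?=[A-Z0-9\"'(\[])")


def _is_abbreviation(text_before: str) -> bool:
    m = re.search(r"(\S+)$", text_before)
    if not m:
        return False
    token = m.group(1).rstrip(".").casefold()
    # single capital letter = initial, never a boundary
    if len(token) == 1 and token.isalpha():
        return True
    return token in ABBREVIATIONS


def _split_text(text: str) -> list[str]:
    sentences = []
    start = 0
    for m in _BOUNDARY.finditer(text):
        if _is_abbreviation(text[start:m.end(1)]):
            continue
        sentences.append(text[start:m.end(1)])
        start = m.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(text[start:].strip())
    return [s.strip() for s in sentences if s.strip()]


def split_sentences(record: AbstractRecord) -> list[Sentence]:
    """Split an abstract into sentences; the title is sentence index 0."""

    raws: list[str] = []
    if record.title:
        raws.append(record.title.strip())
    raws.extend(_split_text(record.body))
    return [Sentence.from_raw(record.pmid, i, raw) for i, raw in enumerate(raws)]


# ---------------------------------------------------------------------------
# delimiter normalization

_DELIMITERS = {",", ";", ":"}


def normalize_delimiters(sentence: Sentence) -> Sentence:
    """Flank every comma/colon/semicolon with single spaces.

    Works on the current ``preprocessed`` text, updating ``char_map`` so
    inserted spaces carry a None raw offset.  Idempotent.
    """

    src = sentence.preprocessed
    src_map = sentence.char_map
    out_chars: list[str] = []
    out_map: list[int | None] = []

    for i, ch in enumerate(src):
        if ch in _DELIMITERS:
            if out_chars and out_chars[-1] != " ":
                out_chars.append(" ")
                out_map.append(None)
            out_chars.append(ch)
            out_map.append(src_map[i])
            nxt = src[i + 1] if i + 1 < len(src) else None
            if nxt is not None and nxt != " ":
                out_chars.append(" ")
                out_map.append(None)
        else:
            out_chars.append(ch)
            out_map.append(src_map[i])

    return replace(sentence, preprocessed="".join(out_chars), char_map=out_map)


def preprocess(record: AbstractRecord) -> list[Sentence]:
    """Split into sentences and normalize delimiters in one step."""

    return [normalize_delimiters(s) for s in split_sentences(record)]
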