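"""Build, ontology-expand, and serialize boolean context queries.

A context query is an ordered list of category-tagged keyword clauses
(disease, protein, GO-term, tissue, species, free-text) joined by
AND/OR/NOT.  Each non-free-text keyword is expanded against an OBO
ontology — the keyword's node plus its synonyms plus the names and
synonyms of its *direct* children (one level down only) — and, for
proteins, against gene-catalog synonyms.  The expanded expression is
serialized as a PubMed-style query string in which every term carries a
configurable field tag (default ``[tw]``, the Text Fields tag that
searches title, abstract body and MeSH terms).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

CATEGORIES = frozenset(
    {"disease", "protein", "go_term", "tissue", "species", "free_text"}
)
OPERATORS = ("AND", "OR", "NOT")

#: ontology relations that count as child links for one-level expansion
CHILD_RELATIONS = frozenset({"is_a", "part_of"})


class OboParseError(ValueError):
    """Raised when an OBO file cannot be parsed into term stanzas."""


@dataclass(frozen=True)
class QueryClause:
    """One keyword clause of a boolean context query.

    ``operator`` joins this clause to the *previous* one; by convention
    the first clause's operator is AND.
    """

    category: str
    term: str
    operator: str = "AND"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown clause category: {self.category!r}")
        if self.operator not in OPERATORS:
            raise ValueError(f"unknown operator: {self.operator!r}")
        if not self.term.strip():
            raise ValueError("clause term is empty")
        object.__setattr__(self, "term", self.term.strip())


@dataclass(frozen=True)
class ExpandedTermSet:
    """A seed keyword with its ontology/catalog expansions.

    Invariants: the seed is a member of ``expansions``; expansions are
    de-duplicated case-insensitively (first-seen casing wins).
    """

    seed_term: str
    expansions: tuple[str, ...]
    source: str = "none"

    def __post_init__(self) -> None:
        if not any(t.casefold() == self.seed_term.casefold() for t in self.expansions):
            raise ValueError("seed_term must be contained in expansions")
        folded = [t.casefold() for t in self.expansions]
        if len(set(folded)) != len(folded):
            raise ValueError("expansions must be case-insensitively unique")

    @classmethod
    def identity(cls, term: str) -> "ExpandedTermSet":
        return cls(seed_term=term, expansions=(term,), source="none")


@dataclass
class QueryExpression:
    """A serialized boolean query with per-category term counts."""

    clauses: list[tuple[QueryClause, ExpandedTermSet]]
    emitted: str
    field_tag: str = "[tw]"
    term_counts: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# ontology loading


def load_ontology(path) -> nx.DiGraph:
    """Parse an OBO 1.2/1.4 file into a directed graph of terms.

    Returns a :class:`networkx.DiGraph` whose nodes are term ids carrying
    ``name`` and ``synonyms`` attributes, with a parent->child edge for
    every is_a / part_of relation (edge attribute ``relation``).
    Obsolete terms are excluded.
    """

    try:
        raw = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # obonet raises assorted ValueError subtypes
        raise OboParseError(f"cannot parse OBO file {path}: {exc}") from exc
    if raw.number_of_nodes() == 0:
        raise OboParseError(f"OBO file {path} contains no [Term] stanzas")

    graph = nx.DiGraph()
    for term_id, data in raw.nodes(data=True):
        graph.add_node(
            term_id,
            name=data.get("name", ""),
            synonyms=tuple(_parse_synonyms(data.get("synonym", ()))),
        )
    # obonet edges run child -> parent keyed by relation; invert so that
    # successors(parent) are the direct children we expand into.
    for child, parent, rel in raw.edges(keys=True):
        if rel in CHILD_RELATIONS and parent in graph:
            graph.add_edge(parent, child, relation=rel)
    return graph


def _parse_synonyms(synonym_lines) -> list[str]:
    out = []
    for line in synonym_lines:
        m = re.match(r'\s*"((?:[^"\\]|\\.)*)"', line)
        if m:
            out.append(m.group(1).replace('\\"', '"'))
    return out


# ---------------------------------------------------------------------------
# term expansion


def _find_term_node(term: str, ontology: nx.DiGraph) -> str | None:
    """Case-insensitive match on name, then synonyms; ties -> first id."""

    folded = term.casefold()
    name_hits = sorted(
        n for n, d in ontology.nodes(data=True) if d.get("name", "").casefold() == folded
    )
    if name_hits:
        return name_hits[0]
    syn_hits = sorted(
        n
        for n, d in ontology.nodes(data=True)
        if any(s.casefold() == folded for s in d.get("synonyms", ()))
    )
    return syn_hits[0] if syn_hits else None


def expand_term(
    term: str,
    category: str,
    ontology: nx.DiGraph | None = None,
    gene_synonyms=None,
) -> ExpandedTermSet:
    """Expand a query keyword one ontology level down.

    The expansion set is the term itself, the synonyms of its matched
    ontology node, and the names + synonyms of the node's direct is_a /
    part_of children.  Protein terms additionally pull synonyms of the
    matched symbol from a gene catalog.  Free-text and species terms are
    returned unexpanded.
    """

    term = term.strip()
    if category in ("free_text", "species"):
        return ExpandedTermSet.identity(term)
    if ontology is None and gene_synonyms is None:
        raise ValueError(f"category {category!r} requires an ontology or gene catalog")

    expansions: list[str] = []
    seen: set[str] = set()

    def add(text: str) -> None:
        if text and text.casefold() not in seen:
            seen.add(text.casefold())
            expansions.append(text)

    add(term)
    source = "none"

    if ontology is not None:
        node = _find_term_node(term, ontology)
        if node is None:
            logger.warning("query term %r not found in ontology; not expanded", term)
        else:
            source = node
            data = ontology.nodes[node]
            add(data.get("name", ""))
            for syn in data.get("synonyms", ()):
                add(syn)
            for child in sorted(ontology.successors(node)):
                cdata = ontology.nodes[child]
                add(cdata.get("name", ""))
                for syn in cdata.get("synonyms", ()):
                    add(syn)

    if category == "protein" and gene_synonyms is not None:
        for syn in gene_synonyms.synonyms_of(term):
            add(syn)
        if source == "none":
            source = "gene_catalog"

    return ExpandedTermSet(seed_term=term, expansions=tuple(expansions), source=source)


# ---------------------------------------------------------------------------
# serialization

_NEEDS_QUOTES = re.compile(r"\s")


def _emit_term(term: str, field_tag: str) -> str:
    if _NEEDS_QUOTES.search(term):
        return f'"{term}"{field_tag}'
    return f"{term}{field_tag}"


def build_query(
    clauses: list[QueryClause],
    expansions: list[ExpandedTermSet] | None = None,
    field_tag: str = "[tw]",
) -> QueryExpression:
    """Serialize clauses + expansions into a tagged boolean query string.

    Grammar: within a clause the expanded terms are OR-joined, every term
    suffixed with ``field_tag`` and double-quoted when multiword; each
    clause is parenthesized; clauses are joined by their operators with
    NOT binding to its single following clause and AND/OR left-associative.
    """

    if not clauses:
        raise ValueError("query requires at least one clause")
    if expansions is None:
        expansions = [ExpandedTermSet.identity(c.term) for c in clauses]
    if len(expansions) != len(clauses):
        raise ValueError("one ExpandedTermSet required per clause")

    parts: list[str] = []
    term_counts: dict[str, int] = {}
    for i, (clause, exp) in enumerate(zip(clauses, expansions)):
        if not exp.expansions:
            raise ValueError(f"clause {clause.term!r} has an empty expansion")
        body = " OR ".join(_emit_term(t, field_tag) for t in exp.expansions)
        if i > 0:
            parts.append(clause.operator)
        parts.append(f"({body})")
        term_counts[clause.category] = term_counts.get(clause.category, 0) + len(
            exp.expansions
        )

    return QueryExpression(
        clauses=list(zip(clauses, expansions)),
        emitted=" ".join(parts),
        field_tag=field_tag,
        term_counts=term_counts,
    )


def parse_query(emitted: str, field_tag: str = "[tw]") -> list[list[str]]:
    """Round-trip parser: recover the per-clause term lists from a query.

    Returns one list of terms per clause, in clause order.  Used to check
    that serialization is lossless; raises ValueError on strings not in
    this module's grammar.
    """

    clause_re = re.compile(r"\(([^()]*)\)")
    ops_between = re.split(r"\([^()]*\)", emitted)
    bodies = clause_re.findall(emitted)
    if not bodies:
        raise ValueError("no clauses found")
    for i, gap in enumerate(ops_between):
        gap = gap.strip()
        if i == 0 or i == len(ops_between) - 1:
            if gap:
                raise ValueError(f"unexpected text outside clauses: {gap!r}")
        elif gap not in OPERATORS:
            raise ValueError(f"bad operator between clauses: {gap!r}")

    tag_re = re.escape(field_tag)
    term_re = re.compile(rf'(?:"([^"]+)"|(\S+)){tag_re}$')
    clauses = []
    for body in bodies:
        terms = []
        for chunk in body.split(" OR "):
            m = term_re.match(chunk.strip())
            if not m:
                raise ValueError(f"unparseable term chunk: {chunk!r}")
            terms.append(m.group(1) or m.group(2))
        clauses.append(terms)
    return clauses
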