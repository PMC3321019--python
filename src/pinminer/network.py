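"""Build, filter, summarize, and export the context-specific PIN.

The network is a multigraph over normalized proteins: every retained
scored interaction contributes one edge, so repeated literature findings
for a pair become parallel edges (edge multiplicity = literature
support).  Directed edges run actor → target; interactions whose word
carries no direction are stored as undirected edges.  Summary statistics
come in three tables: neighbor ranking (hub property), edge-strength
ranking (pair support), and per-node out/in/undirected degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from pinminer.relation import LR, NONE, RL, ScoredInteraction
from pinminer.tagger import Mention

#: a node with at least this many distinct neighbors is reported as a hub
HUB_MIN_NEIGHBORS = 2


@dataclass
class FilterSpec:
    """Filters applied while building or querying a network."""

    min_probability: float = 0.95
    interaction_types: set[str] | None = None
    date_range: tuple[str, str] | None = None
    max_abstracts: int | None = None
    context_granularity: str = "document"  # document | sentence
    focus_protein: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_probability <= 1.0:
            raise ValueError("min_probability must lie in [0, 1]")
        if self.context_granularity not in ("document", "sentence"):
            raise ValueError("granularity must be 'document' or 'sentence'")


@dataclass
class InteractionNetwork:
    """A multigraph of normalized proteins with typed, directed edges.

    ``graph`` is a :class:`networkx.MultiDiGraph`; each edge carries
    interaction_type, direction (``directed``/``none``), probability,
    pmid, sentence_index and evidence attributes.  Undirected edges are
    stored once with direction ``none`` (endpoint order = sentence
    order).
    """

    graph: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)
    granularity: str = "document"

    @property
    def nodes(self):
        return self.graph.nodes

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors_of(self, node: str) -> set[str]:
        return set(self.graph.successors(node)) | set(self.graph.predecessors(node))

    def edge_records(self) -> list[dict]:
        out = []
        for u, v, data in self.graph.edges(data=True):
            rec = {"source": u, "target": v}
            rec.update(data)
            out.append(rec)
        return out

    def hub_nodes(self) -> list[str]:
        return sorted(n for n in self.graph.nodes
                      if len(self.neighbors_of(n)) >= HUB_MIN_NEIGHBORS)


@dataclass
class SummaryTables:
    neighbors: pd.DataFrame
    edge_strength: pd.DataFrame
    direction_degree: pd.DataFrame


# ---------------------------------------------------------------------------
# construction


def _context_keys(context_mentions: list[Mention] | None, granularity: str):
    """Set of (pmid,) or (pmid, sentence_index) keys with a context hit."""
    if context_mentions is None:
        return None
    keys = set()
    for m in context_mentions:
        pmid, index = m.sentence_ref
        if granularity == "document":
            keys.add(pmid)
        elif index is not None:
            keys.add((pmid, index))
    return keys


def build_network(interactions: list[ScoredInteraction],
                  context_mentions: list[Mention] | None = None,
                  spec: FilterSpec | None = None) -> InteractionNetwork:
    """Assemble the PIN from scored, normalized interactions.

    An interaction enters iff its probability meets ``min_probability``,
    its type is allowed, and a context term co-occurs at the configured
    granularity (document: same abstract; sentence: same sentence).
    Passing ``context_mentions=None`` disables the co-occurrence filter
    (query had no context clauses).
    """

    spec = spec or FilterSpec()
    keys = _context_keys(context_mentions, spec.context_granularity)
    graph = nx.MultiDiGraph()

    for si in interactions:
        if si.probability < spec.min_probability:
            continue
        if spec.interaction_types is not None and \
                si.interaction_type not in spec.interaction_types:
            continue
        pmid, sent_index = si.triplet.sentence_ref
        if keys is not None:
            probe = pmid if spec.context_granularity == "document" \
                else (pmid, sent_index)
            if probe not in keys:
                continue

        a = _node_key(si.normalized_a, si.triplet.protein_a.surface)
        b = _node_key(si.normalized_b, si.triplet.protein_b.surface)
        for node, norm in ((a, si.normalized_a), (b, si.normalized_b)):
            if node not in graph:
                graph.add_node(node,
                               gene_ids="|".join(getattr(norm, "gene_ids", ()) or ()),
                               taxon_id=getattr(norm, "taxon_id", None) or "")
        if si.direction == RL:
            source, target = b, a
        else:  # LR flows first -> second; NONE keeps sentence order
            source, target = a, b
        graph.add_edge(
            source, target,
            interaction_type=si.interaction_type,
            direction="none" if si.direction == NONE else "directed",
            probability=si.probability,
            direction_probability=si.direction_probability,
            pmid=pmid,
            sentence_index=sent_index,
            evidence=si.evidence,
        )

    net = InteractionNetwork(graph=graph, granularity=spec.context_granularity)
    if spec.focus_protein:
        net = focus_subnetwork(net, spec.focus_protein)
    return net


def _node_key(normalized, surface: str) -> str:
    if normalized is not None and getattr(normalized, "resolved", False):
        return normalized.official_symbol
    return surface


def focus_subnetwork(net: InteractionNetwork, protein: str) -> InteractionNetwork:
    """Induced subgraph on a protein and its direct neighbors.

    Only edges incident to the focus protein are retained; an unknown
    protein yields an empty network.
    """

    if protein not in net.graph:
        return InteractionNetwork(graph=nx.MultiDiGraph(), granularity=net.granularity)
    sub = nx.MultiDiGraph()
    sub.add_node(protein, **net.graph.nodes[protein])
    for u, v, key, data in net.graph.edges(keys=True, data=True):
        if protein in (u, v):
            for node in (u, v):
                if node not in sub:
                    sub.add_node(node, **net.graph.nodes[node])
            sub.add_edge(u, v, key=key, **data)
    return InteractionNetwork(graph=sub, granularity=net.granularity)


# ---------------------------------------------------------------------------
# summary tables


def neighbor_table(net: InteractionNetwork) -> pd.DataFrame:
    """Nodes ranked by distinct-neighbor count (hub property).

    ``percent_coverage`` = neighbors / total network nodes, as a
    percentage rounded to 2 decimals; ties break alphabetically.
    """

    total = net.graph.number_of_nodes()
    rows = []
    for node in net.graph.nodes:
        n = len(net.neighbors_of(node))
        rows.append({
            "protein": node,
            "n_neighbors": n,
            "percent_coverage": round(100.0 * n / total, 2) if total else 0.0,
        })
    table = pd.DataFrame(rows, columns=["protein", "n_neighbors", "percent_coverage"])
    return table.sort_values(
        ["n_neighbors", "protein"], ascending=[False, True]
    ).reset_index(drop=True)


def edge_strength_table(net: InteractionNetwork) -> pd.DataFrame:
    """Unordered node pairs ranked by parallel-edge count."""

    counts: dict[tuple[str, str], int] = {}
    for u, v in net.graph.edges():
        pair = tuple(sorted((u, v)))
        counts[pair] = counts.get(pair, 0) + 1
    rows = [{"protein_1": p1, "protein_2": p2, "n_links": n}
            for (p1, p2), n in counts.items()]
    table = pd.DataFrame(rows, columns=["protein_1", "protein_2", "n_links"])
    return table.sort_values(
        ["n_links", "protein_1", "protein_2"], ascending=[False, True, True]
    ).reset_index(drop=True)


def direction_degree_table(net: InteractionNetwork) -> pd.DataFrame:
    """Per-node outbound, inbound, and undirected edge counts.

    Parallel edges count individually; for every node
    outward + inward + undirected equals its incident-edge count.
    """

    rows = {node: {"protein": node, "outward": 0, "inward": 0, "undirected": 0}
            for node in net.graph.nodes}
    for u, v, data in net.graph.edges(data=True):
        if data.get("direction") == "directed":
            rows[u]["outward"] += 1
            rows[v]["inward"] += 1
        else:
            rows[u]["undirected"] += 1
            rows[v]["undirected"] += 1
    table = pd.DataFrame(list(rows.values()),
                         columns=["protein", "outward", "inward", "undirected"])
    return table.sort_values("protein").reset_index(drop=True)


def summarize(net: InteractionNetwork) -> SummaryTables:
    return SummaryTables(
        neighbors=neighbor_table(net),
        edge_strength=edge_strength_table(net),
        direction_degree=direction_degree_table(net),
    )


# ---------------------------------------------------------------------------
# export


def highlight_sentence(text: str, spans: list[tuple[int, int]],
                       markers: tuple[str, str] = ("[[", "]]")) -> str:
    """Wrap the given [start, end) spans of text in marker strings."""

    open_m, close_m = markers
    out = text
    for start, end in sorted(spans, key=lambda s: -s[0]):
        out = out[:start] + open_m + out[start:end] + close_m + out[end:]
    return out


def export_network(net: InteractionNetwork, path, format: str = "GraphML",
                   evidence: dict | None = None,
                   markers: tuple[str, str] = ("[[", "]]")) -> None:
    """Write the network as SIF, GraphML, or a TSV interaction report.

    SIF: one ``source <type> target`` line per edge.  GraphML: edges
    carry probability/direction/type/pmid attributes.  TSV: one report
    row per edge with provenance; when ``evidence`` maps (pmid,
    sentence_index) to (sentence_text, highlight_spans), the evidence
    sentence is included with the triplet terms marked.
    """

    fmt = format.upper()
    if fmt == "SIF":
        with open(path, "w", encoding="utf-8") as out:
            for u, v, data in net.graph.edges(data=True):
                out.write(f"{u}\t{data['interaction_type']}\t{v}\n")
    elif fmt == "GRAPHML":
        graph = net.graph.copy()
        for _, _, data in graph.edges(data=True):
            for k, v in list(data.items()):
                if v is None:
                    data[k] = ""
        nx.write_graphml(graph, path)
    elif fmt == "TSV":
        rows = []
        for u, v, data in net.graph.edges(data=True):
            sentence_text = data.get("evidence", "")
            key = (data.get("pmid"), data.get("sentence_index"))
            if not sentence_text and evidence and key in evidence:
                text, spans = evidence[key]
                sentence_text = highlight_sentence(text, spans, markers)
            rows.append({
                "protein_a": u, "protein_b": v,
                "probability": data.get("probability"),
                "interaction_type": data.get("interaction_type"),
                "direction": data.get("direction"),
                "pmid": data.get("pmid"),
                "sentence_index": data.get("sentence_index"),
                "evidence": sentence_text,
            })
        pd.DataFrame(rows, columns=[
            "protein_a", "protein_b", "probability", "interaction_type",
            "direction", "pmid", "sentence_index", "evidence",
        ]).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format: {format!r}")
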