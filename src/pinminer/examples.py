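"""Bundled worked-example datasets.

Two small published datasets ship with the package so the summary-table
and query-building machinery can be exercised on real inputs:

* the hub-incident edge list of a protein interaction network mined for
  IL13 in human asthma (nine protein-pair rows with literature link
  counts) — note this list covers only edges touching hub nodes, so it
  is a partial view of the full network;
* the differentially expressed genes (fold change > 3) from a microarray
  comparison of alveolar macrophages in smokers vs non-smokers with
  COPD (GEO series GSE3212), split into up- and down-regulated sets.
"""

from __future__ import annotations

from importlib import resources

import networkx as nx
import pandas as pd

from pinminer.query_builder import (
    ExpandedTermSet,
    QueryClause,
    QueryExpression,
    build_query,
)


def _data_path(name: str):
    return resources.files("pinminer.data").joinpath(name)


def load_asthma_hub_edges() -> pd.DataFrame:
    """Edge-strength rows (protein_1, protein_2, n_links) of the asthma PIN."""
    with resources.as_file(_data_path("asthma_il13_hub_edges.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def asthma_hub_multigraph() -> nx.MultiGraph:
    """The asthma hub edge list expanded into parallel edges."""
    graph = nx.MultiGraph()
    for row in load_asthma_hub_edges().itertuples():
        for _ in range(int(row.n_links)):
            graph.add_edge(row.protein_1, row.protein_2)
    return graph


def asthma_hub_network() -> "InteractionNetwork":
    """The asthma hub edge list as an InteractionNetwork.

    The published edge list carries no per-edge direction or probability,
    so every parallel edge is stored as undirected.
    """
    from pinminer.network import InteractionNetwork

    graph = nx.MultiDiGraph()
    for row in load_asthma_hub_edges().itertuples():
        for _ in range(int(row.n_links)):
            graph.add_edge(row.protein_1, row.protein_2, direction="none",
                           interaction_type="interacts")
    return InteractionNetwork(graph=graph)


def load_copd_deg_table() -> dict[str, list[str]]:
    """Up/down regulated gene identifiers from the COPD smoker study."""
    with resources.as_file(_data_path("copd_smoker_degs.tsv")) as path:
        table = pd.read_csv(path, sep="\t")
    out: dict[str, list[str]] = {}
    for row in table.itertuples():
        out[row.regulation] = [g.strip() for g in row.gene_ids.split(",") if g.strip()]
    return out


def copd_query() -> QueryExpression:
    """The COPD case-study query: 28 DEGs OR-joined, AND disease, AND free text.

    Gene clauses are not ontology-expanded here (the identifiers come
    straight from the expression experiment), so the gene-category term
    count equals the number of differentially expressed genes.
    """

    degs = load_copd_deg_table()
    genes = degs["up"] + degs["down"]
    clauses = [QueryClause(category="protein", term=genes[0], operator="AND")]
    clauses += [QueryClause(category="protein", term=g, operator="OR") for g in genes[1:]]
    clauses.append(QueryClause(category="disease", term="COPD", operator="AND"))
    clauses.append(QueryClause(category="free_text", term="smokers", operator="AND"))
    expansions = [ExpandedTermSet.identity(c.term) for c in clauses[:-1]]
    expansions.append(ExpandedTermSet(
        seed_term="smokers",
        expansions=("smokers", "non-smokers", "nonsmokers"),
    ))
    return build_query(clauses, expansions)
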