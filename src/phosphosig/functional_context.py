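"""Functional-context summaries: annotation enrichment and network filtering.

Replaces the web-service steps of a typical phosphoproteomics workflow with
local, exactly-testable equivalents:

* **Annotation enrichment** -- plain hypergeometric over-representation of
  each annotation term in a query protein set against an explicit
  background, with Benjamini-Hochberg correction across the tested terms.

* **High-confidence subnetwork** -- the subgraph induced by a protein set
  over a scored interaction edge list, keeping only edges whose combined
  confidence is *strictly above* the threshold (default 0.9), decomposed
  into connected components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .phosphodata import AnnotationMap, NetworkEdge
from .significance import bh_adjust

__all__ = [
    "EnrichedTerm",
    "Subnetwork",
    "term_enrichment",
    "high_confidence_subnetwork",
    "component_enrichment",
    "enrichment_table",
]


@dataclass
class EnrichedTerm:
    """Hypergeometric over-representation of one term in one query."""

    term: str
    k: int  # annotated proteins in the query
    n: int  # query size
    K: int  # term size in the background
    M: int  # background size
    p: float  # upper-tail P(X >= k)
    q: float  # BH-adjusted


@dataclass
class Subnetwork:
    """Strict-threshold filtered interaction subgraph over a protein set."""

    nodes: Set[str]
    edges: List[NetworkEdge]
    components: List[Tuple[str, ...]]  # sorted by size desc, then lexicographic


def term_enrichment(query: Iterable[str], annotations: AnnotationMap) -> List[EnrichedTerm]:
    """Hypergeometric over-representation of every annotation term hit by the query.

    For a term with K annotated proteins in a background of M, and a query
    of n proteins of which k carry the term, p = P(X >= k) under
    hypergeometric(M, K, n).  Terms with k = 0 are omitted.  q-values are BH
    over all tested terms.  The query must be non-empty and contained in the
    background.
    """
    query = set(query)
    if not query:
        raise ValueError("query is empty")
    stray = query - annotations.background
    if stray:
        raise ValueError(f"query proteins outside background: {sorted(stray)[:10]}")
    M = len(annotations.background)
    n = len(query)
    rows: List[EnrichedTerm] = []
    for term in sorted(annotations.terms):
        members = annotations.terms[term]
        k = len(query & members)
        if k == 0:
            continue
        p = float(hypergeom.sf(k - 1, M, len(members), n))
        rows.append(EnrichedTerm(term=term, k=k, n=n, K=len(members), M=M, p=min(p, 1.0), q=1.0))
    if rows:
        qs = bh_adjust([r.p for r in rows])
        for r, q in zip(rows, qs):
            r.q = float(q)
    rows.sort(key=lambda r: (r.p, r.term))
    return rows


def high_confidence_subnetwork(
    proteins: Iterable[str], edges: Sequence[NetworkEdge], threshold: float = 0.9
) -> Subnetwork:
    """Induced subgraph keeping only edges scored strictly above ``threshold``.

    Both endpoints must lie in the protein set.  Components are sorted by
    size descending, ties by the lexicographically smallest member; each
    component's nodes are sorted.  Isolated query proteins form singleton
    components.
    """
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must lie in [0, 1)")
    nodes = set(proteins)
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    kept: List[NetworkEdge] = []
    for e in edges:
        if e.score > threshold and e.protein_a in nodes and e.protein_b in nodes:
            graph.add_edge(e.protein_a, e.protein_b, score=e.score)
            kept.append(e)
    components = [tuple(sorted(c)) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-len(c), c[0]))
    return Subnetwork(nodes=nodes, edges=sorted(kept, key=lambda e: e.key), components=components)


def component_enrichment(
    subnetwork: Subnetwork,
    annotations: AnnotationMap,
    min_component_size: int = 2,
) -> Dict[Tuple[str, ...], List[EnrichedTerm]]:
    """Annotation enrichment per connected component.

    Components smaller than ``min_component_size`` are skipped; component
    members absent from the annotation background are ignored for the test
    (a component entirely outside the background yields an empty list).
    """
    out: Dict[Tuple[str, ...], List[EnrichedTerm]] = {}
    for comp in subnetwork.components:
        if len(comp) < min_component_size:
            continue
        in_bg = set(comp) & annotations.background
        out[comp] = term_enrichment(in_bg, annotations) if in_bg else []
    return out


def enrichment_table(terms: Sequence[EnrichedTerm]) -> pd.DataFrame:
    """Flatten enrichment results for TSV export."""
    return pd.DataFrame(
        [
            {"term": t.term, "k": t.k, "n": t.n, "K": t.K, "M": t.M, "p": t.p, "q": t.q}
            for t in terms
        ],
        columns=["term", "k", "n", "K", "M", "p", "q"],
    )
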