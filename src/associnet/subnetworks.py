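"""Annotation transfer and per-term subnetwork analysis.

Query proteins inherit GO/KEGG terms from the template proteins in their
co-ortholog group. A subnetwork for a term is the induced subgraph of the
constructed network over the term's annotated query proteins, with an
adjustable LLS threshold on the edges, and its proteins are ranked by
total weighted within-term connectivity (sum of incident edge LLS) —
high-ranking proteins are the term's hubs and the most promising
candidates for the molecular concept.
"""

from __future__ import annotations

import difflib
import logging
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from associnet.io import AnnotationSet
from associnet.orthologs import OrthologPair
from associnet.transfer import AssocialogEdge, AssocialogNetwork

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QueryAnnotation:
    """A term inherited by a query protein, with the template proteins
    (``via``) whose annotation it was inherited from."""

    query_id: str
    term_id: str
    via: frozenset[str]

    def __post_init__(self) -> None:
        if not self.via:
            raise ValueError(f"annotation ({self.query_id}, {self.term_id}) without provenance")


@dataclass(frozen=True)
class Subnetwork:
    """A per-term induced subnetwork with its hub ranking."""

    term_id: str
    nodes: frozenset[str]
    edges: tuple[AssocialogEdge, ...]
    ranking: tuple[tuple[str, float], ...]


def transfer_annotations(
    orthologs: Sequence[OrthologPair],
    template_sets: Sequence[AnnotationSet],
    mode: str = "group",
) -> list[QueryAnnotation]:
    """Transfer template annotations to query proteins by orthology.

    In the default ``"group"`` mode each query protein inherits the union
    of the terms annotated to any template member of its co-ortholog
    group; ``"seed"`` restricts inheritance to the group's seed template
    protein.
    """
    if mode not in ("group", "seed"):
        raise ValueError(f"unknown inheritance mode {mode!r}")

    group_templates: dict[str, set[str]] = {}
    group_queries: dict[str, set[str]] = {}
    for p in orthologs:
        if mode == "group" or p.is_seed:
            group_templates.setdefault(p.group_id, set()).add(p.template_id)
        group_queries.setdefault(p.group_id, set()).add(p.query_id)

    annotations: list[QueryAnnotation] = []
    for group_id in sorted(group_queries):
        templates = group_templates.get(group_id, set())
        for term in template_sets:
            via = frozenset(templates & term.members)
            if not via:
                continue
            for q in sorted(group_queries[group_id]):
                annotations.append(QueryAnnotation(q, term.term_id, via))
    # one record per (query, term): merge via sets across groups
    merged: dict[tuple[str, str], set[str]] = {}
    for a in annotations:
        merged.setdefault((a.query_id, a.term_id), set()).update(a.via)
    return [
        QueryAnnotation(q, t, frozenset(via))
        for (q, t), via in sorted(merged.items())
    ]


def annotated_proteins(annotations: Iterable[QueryAnnotation], term_id: str) -> frozenset[str]:
    return frozenset(a.query_id for a in annotations if a.term_id == term_id)


def extract_subnetwork(
    net: AssocialogNetwork,
    term_id: str,
    annotations: Sequence[QueryAnnotation],
    lls_threshold: float = 0.0,
) -> Subnetwork:
    """Induced subnetwork over a term's annotated query proteins.

    Edges must have both endpoints annotated to the term and an adjusted
    LLS of at least ``lls_threshold`` (0 keeps every qualified edge).
    Annotated proteins with no surviving edge are still listed as nodes
    (and ranked with score 0). An unknown term raises with near-miss
    suggestions.
    """
    known_terms = sorted({a.term_id for a in annotations})
    nodes = annotated_proteins(annotations, term_id)
    if not nodes:
        near = difflib.get_close_matches(term_id, known_terms, n=5, cutoff=0.4)
        raise KeyError(
            f"term {term_id!r} not found in transferred annotations"
            + (f"; did you mean one of {near}?" if near else "")
        )
    edges = tuple(
        sorted(
            (
                e
                for e in net
                if e.query_a in nodes and e.query_b in nodes and e.adjusted_lls >= lls_threshold
            ),
            key=lambda e: (-e.adjusted_lls, e.pair),
        )
    )
    sub = Subnetwork(term_id, nodes, edges, ())
    return Subnetwork(term_id, nodes, edges, tuple(rank_hubs(sub)))


def rank_hubs(sub: Subnetwork) -> list[tuple[str, float]]:
    """Rank subnetwork proteins by sum of incident edge LLS, descending.

    Isolated nodes score 0 and sort last; ties break lexicographically so
    the ranking is stable across runs.
    """
    score = {n: 0.0 for n in sub.nodes}
    for e in sub.edges:
        score[e.query_a] += e.adjusted_lls
        score[e.query_b] += e.adjusted_lls
    return sorted(score.items(), key=lambda kv: (-kv[1], kv[0]))


def search_terms(
    terms: Sequence[AnnotationSet],
    keyword: str = "",
    category: str | None = None,
) -> list[str]:
    """Case-insensitive substring search over term names.

    An empty keyword matches every term; ``category`` optionally
    restricts to one GO namespace or KEGG.
    """
    kw = keyword.lower()
    return sorted(
        t.term_id
        for t in terms
        if kw in t.term_name.lower() and (category is None or t.category == category)
    )


def to_graphml(sub: Subnetwork, path: str | os.PathLike) -> None:
    """Export a subnetwork for external visualization tools."""
    g = nx.Graph()
    ranks = dict(sub.ranking)
    for n in sorted(sub.nodes):
        g.add_node(n, weighted_connectivity=ranks.get(n, 0.0))
    for e in sub.edges:
        g.add_edge(e.query_a, e.query_b, lls=e.adjusted_lls)
    nx.write_graphml(g, str(path))


def write_subnetwork(
    sub: Subnetwork,
    path: str | os.PathLike,
    header_comments: Sequence[str] = (),
) -> None:
    """Write subnetwork edges then the hub ranking as commented TSV blocks."""
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write(f"# subnetwork for term {sub.term_id}\n")
        fh.write("# query_a\tquery_b\tadjusted_lls\n")
        for e in sub.edges:
            a, b = e.pair
            fh.write(f"{a}\t{b}\t{e.adjusted_lls:.6f}\n")
        fh.write("# ranking: protein\tsum_lls\n")
        for node, s in sub.ranking:
            fh.write(f"{node}\t{s:.6f}\n")
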