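"""GO semantic similarity (Wang method) and the functional similarity score.

The Wang measure scores a GO term pair by how much of their ancestor graphs
they share, with each ancestor's contribution decaying along ``is_a`` (weight
0.8) and ``part_of`` (weight 0.6) edges.  Gene-level similarity combines term
pairs by best-match averaging (BMA).  The functional similarity score (FSS)
of a gene pair is the geometric mean of its molecular-function and
cellular-component gene similarities; a pair missing annotation in either
namespace has no FSS and is treated as failing the similarity screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

__all__ = [
    "DEFAULT_EDGE_WEIGHTS",
    "FssRecord",
    "validate_go_graph",
    "term_svalues",
    "term_sim",
    "gene_sim",
    "fss",
]

DEFAULT_EDGE_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


@dataclass(frozen=True)
class FssRecord:
    """Gene-pair functional similarity in MF and CC and their geometric mean.

    ``fss`` is ``None`` when either namespace similarity is undefined
    (i.e. one gene lacks annotation there).
    """

    gene_a: str
    gene_b: str
    ss_mf: float | None
    ss_cc: float | None

    @property
    def fss(self) -> float | None:
        if self.ss_mf is None or self.ss_cc is None:
            return None
        return math.sqrt(self.ss_mf * self.ss_cc)


def validate_go_graph(graph: nx.DiGraph) -> None:
    """Check acyclicity, namespace-homogeneous edges and one root per namespace."""
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError(f"GO graph has a cycle: {nx.find_cycle(graph)}")
    roots: dict[str, list[str]] = {}
    for node, data in graph.nodes(data=True):
        ns = data.get("namespace", "")
        if graph.out_degree(node) == 0:
            roots.setdefault(ns, []).append(node)
    for node, parent, data in graph.edges(data=True):
        ns_c = graph.nodes[node].get("namespace")
        ns_p = graph.nodes[parent].get("namespace")
        if ns_c != ns_p:
            raise ValueError(
                f"edge {node}->{parent} crosses namespaces {ns_c!r}/{ns_p!r}"
            )
        if data.get("etype") not in DEFAULT_EDGE_WEIGHTS:
            raise ValueError(f"edge {node}->{parent} has unknown type {data.get('etype')!r}")
    for ns, r in roots.items():
        if len(r) != 1:
            raise ValueError(f"namespace {ns!r} has {len(r)} roots: {sorted(r)}")


def term_svalues(
    term: str,
    graph: nx.DiGraph,
    weights: dict[str, float] = DEFAULT_EDGE_WEIGHTS,
) -> dict[str, float]:
    """S-values of ``term`` over its ancestor closure (including itself).

    S(term) = 1; for an ancestor t, S(t) is the maximum over edges (c -> t)
    with c inside the closure of w_edge * S(c).  Computed by dynamic
    programming in topological order of the closure, which realises exactly
    that recursion.
    """
    if term not in graph:
        raise KeyError(f"unknown term {term!r}")
    closure = {term} | nx.descendants(graph, term)  # edges point child->parent
    s: dict[str, float] = {term: 1.0}
    # topological order of the closure subgraph guarantees each child is
    # finalized before any of its parents
    sub = graph.subgraph(closure)
    for node in nx.topological_sort(sub):
        if node == term:
            continue
        best = 0.0
        for child, _, data in sub.in_edges(node, data=True):
            if child in s:
                w = weights[data["etype"]]
                best = max(best, w * s[child])
        s[node] = best
    return s


def term_sim(
    a: str,
    b: str,
    graph: nx.DiGraph,
    weights: dict[str, float] = DEFAULT_EDGE_WEIGHTS,
) -> float:
    """Wang similarity of two terms in the same namespace, in (0, 1]."""
    ns_a = graph.nodes[a].get("namespace")
    ns_b = graph.nodes[b].get("namespace")
    if ns_a != ns_b:
        raise ValueError(f"terms {a!r} ({ns_a}) and {b!r} ({ns_b}) differ in namespace")
    sa = term_svalues(a, graph, weights)
    sb = term_svalues(b, graph, weights)
    common = set(sa) & set(sb)
    num = sum(sa[t] + sb[t] for t in common)
    den = sum(sa.values()) + sum(sb.values())
    return num / den


def gene_sim(
    gene_a: str,
    gene_b: str,
    namespace: str,
    graph: nx.DiGraph,
    ann: dict,
    weights: dict[str, float] = DEFAULT_EDGE_WEIGHTS,
) -> float | None:
    """Best-match-average gene similarity in one namespace; None if unannotated.

    BMA over annotation sets A, B:
    (sum_a max_b sim(a,b) + sum_b max_a sim(a,b)) / (|A| + |B|).
    """
    terms_a = sorted(ann.get(gene_a, {}).get(namespace, ()))
    terms_b = sorted(ann.get(gene_b, {}).get(namespace, ()))
    if not terms_a or not terms_b:
        return None
    sim = {
        (ta, tb): term_sim(ta, tb, graph, weights)
        for ta in terms_a
        for tb in terms_b
    }
    fwd = sum(max(sim[(ta, tb)] for tb in terms_b) for ta in terms_a)
    rev = sum(max(sim[(ta, tb)] for ta in terms_a) for tb in terms_b)
    return (fwd + rev) / (len(terms_a) + len(terms_b))


def fss(
    gene_a: str,
    gene_b: str,
    graph: nx.DiGraph,
    ann: dict,
    weights: dict[str, float] = DEFAULT_EDGE_WEIGHTS,
) -> FssRecord:
    """Functional similarity score: sqrt(SsMF * SsCC) of a gene pair."""
    ss_mf = gene_sim(gene_a, gene_b, "MF", graph, ann, weights)
    ss_cc = gene_sim(gene_a, gene_b, "CC", graph, ann, weights)
    return FssRecord(gene_a, gene_b, ss_mf, ss_cc)
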