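"""Disease/miRNA similarity constructions.

Four similarity sources feed the factorization:

* two MeSH-DAG semantic similarities for diseases — one with geometric decay
  of ancestor contributions (factor ``delta``), one weighting ancestors by
  -log of their frequency across all disease DAGs;
* the precomputed miRNA functional similarity matrix (consumed, not rebuilt);
* Gaussian interaction profile (GIP) kernels for both sides, computed from
  the binary association matrix.

The semantic similarities are averaged into SD1 and then combined with the
GIP kernels into the integrated matrices SM and SD used downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "DiseaseDAG",
    "GipBandwidth",
    "d1_contributions",
    "semantic_value_1",
    "semantic_similarity_1",
    "semantic_similarity_matrix_1",
    "d2_contribution",
    "semantic_value_2",
    "semantic_similarity_2",
    "semantic_similarity_matrix_2",
    "combine_semantic",
    "interaction_profiles",
    "gip_bandwidth",
    "gip_kernel",
    "gip_kernel_from_associations",
    "integrate_mirna_similarity",
    "integrate_disease_similarity",
]


class GraphError(ValueError):
    """The hierarchy is not a DAG."""


class LookupError_(KeyError):
    """Identifier not present in the DAG."""


@dataclass(frozen=True)
class GipBandwidth:
    """Normalized GIP kernel bandwidth beta = beta_prime / mean sq profile norm."""

    beta: float
    beta_prime: float = 1.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("bandwidth beta must be positive")


class DiseaseDAG:
    """Rooted ancestor structure of a disease hierarchy.

    Edges run child -> parent.  For every node d, ``ancestors(d)`` is the
    closure T_d (d itself plus everything reachable through parents);
    ``children_within(D, node)`` restricts a node's children to T_D, which is
    what the decaying-contribution recursion walks.
    """

    def __init__(self, graph: nx.DiGraph):
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise GraphError(f"hierarchy contains a cycle through {cycle[0][0]!r}")
        self._graph = graph
        # T_d for every node: d plus all nodes reachable along child->parent edges
        self._ancestors: dict[str, frozenset[str]] = {
            d: frozenset({d} | nx.descendants(graph, d)) for d in graph.nodes
        }

    @classmethod
    def from_edges(cls, edges, nodes=None) -> "DiseaseDAG":
        g = nx.DiGraph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        return cls(g)

    @property
    def diseases(self) -> list[str]:
        return list(self._graph.nodes)

    def __contains__(self, disease: str) -> bool:
        return disease in self._graph

    def __len__(self) -> int:
        return self._graph.number_of_nodes()

    def ancestors(self, disease: str) -> frozenset[str]:
        """T_d: the disease itself plus its ancestor closure."""
        try:
            return self._ancestors[disease]
        except KeyError:
            raise LookupError_(f"disease {disease!r} not in DAG") from None

    def children_within(self, disease: str, node: str) -> list[str]:
        """Children of ``node`` restricted to T_disease."""
        T = self.ancestors(disease)
        return [c for c in self._graph.predecessors(node) if c in T]

    def parents(self, node: str) -> list[str]:
        return list(self._graph.successors(node))


def d1_contributions(dag: DiseaseDAG, disease: str, delta: float = 0.5) -> dict[str, float]:
    """Decaying semantic contribution of every node of T_disease.

    The disease itself contributes 1; each ancestor contributes ``delta``
    times the largest contribution among its children inside T_disease, i.e.
    delta ** (shortest hop distance from the disease along the hierarchy).
    """
    if not 0 < delta <= 1:
        raise ValueError("delta must be in (0, 1]")
    T = dag.ancestors(disease)
    sub = dag._graph.subgraph(T)
    contrib: dict[str, float] = {}
    # child->parent edges: topological order visits children before parents
    for node in nx.topological_sort(sub):
        if node == disease:
            contrib[node] = 1.0
        else:
            children = dag.children_within(disease, node)
            contrib[node] = delta * max(contrib[c] for c in children)
    return contrib


def semantic_value_1(contributions: dict[str, float]) -> float:
    """DV1(D): total decayed contribution over T_D; >= 1."""
    if not contributions:
        raise ValueError("empty contribution map")
    return float(sum(contributions.values()))


def semantic_similarity_1(dag: DiseaseDAG, di: str, dj: str, delta: float = 0.5) -> float:
    ci = d1_contributions(dag, di, delta)
    cj = d1_contributions(dag, dj, delta)
    shared = set(ci) & set(cj)
    num = sum(ci[t] + cj[t] for t in shared)
    den = semantic_value_1(ci) + semantic_value_1(cj)
    return float(num / den)


def semantic_similarity_matrix_1(dag: DiseaseDAG, ids=None, delta: float = 0.5) -> np.ndarray:
    ids = list(ids) if ids is not None else dag.diseases
    contrib = {d: d1_contributions(dag, d, delta) for d in ids}
    dv = {d: semantic_value_1(contrib[d]) for d in ids}
    p = len(ids)
    S = np.eye(p)
    for a in range(p):
        ca = contrib[ids[a]]
        for b in range(a + 1, p):
            cb = contrib[ids[b]]
            shared = ca.keys() & cb.keys()
            if shared:
                S[a, b] = S[b, a] = sum(ca[t] + cb[t] for t in shared) / (
                    dv[ids[a]] + dv[ids[b]]
                )
    return S


def d2_contribution(dag: DiseaseDAG, node: str) -> float:
    """Frequency-weighted contribution: -log(#DAGs containing node / #diseases).

    A node present in every disease's ancestor set contributes 0; a node
    unique to a single disease contributes log(#diseases).  Natural log.
    """
    if node not in dag:
        raise LookupError_(f"node {node!r} not in DAG")
    count = sum(1 for d in dag.diseases if node in dag.ancestors(d))
    return float(-np.log(count / len(dag)))


def semantic_value_2(dag: DiseaseDAG, disease: str) -> float:
    return float(sum(d2_contribution(dag, t) for t in dag.ancestors(disease)))


def semantic_similarity_2(dag: DiseaseDAG, di: str, dj: str) -> float:
    Ti, Tj = dag.ancestors(di), dag.ancestors(dj)
    den = semantic_value_2(dag, di) + semantic_value_2(dag, dj)
    if den == 0:
        # 0/0 degenerate case: every ancestor is shared by all diseases
        warnings.warn(f"DV2({di}) + DV2({dj}) = 0; similarity set to 0")
        return 0.0
    num = sum(2.0 * d2_contribution(dag, t) for t in Ti & Tj)
    return float(num / den)


def semantic_similarity_matrix_2(dag: DiseaseDAG, ids=None) -> np.ndarray:
    ids = list(ids) if ids is not None else dag.diseases
    d2 = {t: d2_contribution(dag, t) for t in dag.diseases}
    dv = {d: sum(d2[t] for t in dag.ancestors(d)) for d in ids}
    p = len(ids)
    S = np.zeros((p, p))
    for a in range(p):
        Ta = dag.ancestors(ids[a])
        for b in range(a, p):
            den = dv[ids[a]] + dv[ids[b]]
            if den == 0:
                S[a, b] = S[b, a] = 0.0
                continue
            num = sum(2.0 * d2[t] for t in Ta & dag.ancestors(ids[b]))
            S[a, b] = S[b, a] = num / den
    return S


def combine_semantic(S1: np.ndarray, S2: np.ndarray,
                     alpha1: float = 0.5, alpha2: float = 0.5) -> np.ndarray:
    """SD1 = alpha1 * S1 + alpha2 * S2, convex weights summing to 1."""
    S1, S2 = np.asarray(S1, float), np.asarray(S2, float)
    if S1.shape != S2.shape:
        raise ValueError(f"shape mismatch: {S1.shape} vs {S2.shape}")
    if abs(alpha1 + alpha2 - 1.0) > 1e-9:
        raise ValueError("semantic weights must sum to 1")
    return alpha1 * S1 + alpha2 * S2


def interaction_profiles(Y: np.ndarray, axis: str) -> np.ndarray:
    """Binary interaction profiles: rows of Y for miRNAs, columns for diseases.

    Returned with one profile per row regardless of axis.
    """
    Y = np.asarray(Y, dtype=float)
    if axis == "mirna":
        return Y
    if axis == "disease":
        return Y.T
    raise ValueError("axis must be 'mirna' or 'disease'")


def gip_bandwidth(profiles: np.ndarray, beta_prime: float = 1.0) -> GipBandwidth:
    """beta = beta_prime / mean squared Euclidean norm of the profiles."""
    profiles = np.asarray(profiles, dtype=float)
    mean_sq = float(np.mean(np.sum(profiles**2, axis=1)))
    if mean_sq == 0:
        raise ZeroDivisionError(
            "all interaction profiles are zero; GIP bandwidth undefined "
            "(remove empty rows/columns or supply a nonzero association matrix)"
        )
    return GipBandwidth(beta=beta_prime / mean_sq, beta_prime=beta_prime)


def gip_kernel(profiles: np.ndarray, bandwidth: GipBandwidth) -> np.ndarray:
    """K(i,j) = exp(-beta * ||IP_i - IP_j||^2); symmetric, unit diagonal."""
    profiles = np.asarray(profiles, dtype=float)
    sq = squareform(pdist(profiles, metric="sqeuclidean"))
    K = np.exp(-bandwidth.beta * sq)
    np.fill_diagonal(K, 1.0)
    return K


def gip_kernel_from_associations(Y: np.ndarray, axis: str,
                                 beta_prime: float = 1.0) -> np.ndarray:
    profiles = interaction_profiles(Y, axis)
    return gip_kernel(profiles, gip_bandwidth(profiles, beta_prime))


def _masked_combination(S: np.ndarray, G: np.ndarray, w1: float, w2: float,
                        mask: np.ndarray | None) -> np.ndarray:
    S, G = np.asarray(S, float), np.asarray(G, float)
    if S.shape != G.shape:
        raise ValueError(f"shape mismatch: {S.shape} vs {G.shape}")
    if mask is None:
        mask = S > 0  # "have similarity": entry present (nonzero); diag is 1
    out = np.where(mask, w1 * S + w2 * G, G)
    return out


def integrate_mirna_similarity(S_functional: np.ndarray, GM: np.ndarray,
                               theta1: float = 1.0, theta2: float = 0.0,
                               mask: np.ndarray | None = None) -> np.ndarray:
    """SM: functional similarity where defined, GIP kernel elsewhere.

    With the default weights (theta1=1, theta2=0) the masked entries are the
    functional similarities themselves.
    """
    return _masked_combination(S_functional, GM, theta1, theta2, mask)


def integrate_disease_similarity(SD1: np.ndarray, GD: np.ndarray,
                                 gamma1: float = 1.0, gamma2: float = 0.0,
                                 mask: np.ndarray | None = None) -> np.ndarray:
    """SD: combined semantic similarity where defined, GIP kernel elsewhere."""
    return _masked_combination(SD1, GD, gamma1, gamma2, mask)
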