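"""Markov Cluster algorithm (MCL) on unweighted graphs.

MCL simulates flow on a graph: a column-stochastic transition matrix is
alternately *expanded* (squared — flow spreads along walks) and *inflated*
(raised element-wise to an exponent > 1 and renormalized — strong flow is
boosted, weak flow starved) until the flow distribution stops changing.
The limit matrix is sparse and block-structured: a few *attractor* rows
retain mass, and each node's residual column mass points at the attractor
system it belongs to, which defines the clustering.

This implementation follows the classic formulation:

1. adjacency matrix with self-loops of weight 1;
2. column-normalize to a stochastic matrix ``M``;
3. apply inflation once with the *preinflation* exponent;
4. iterate: ``M <- inflate(M @ M, inflation)`` with entries below
   ``prune_eps`` zeroed before renormalization, until the largest absolute
   entry change falls below ``convergence_tol`` (or ``max_iter`` is hit,
   in which case the current matrix is interpreted and flagged);
5. interpret: attractors are nodes with positive diagonal mass; an
   attractor system is a connected set of attractors (mutual positive
   flow); a cluster is an attractor system plus every node with positive
   flow towards it. A node reaching several systems is assigned to the
   larger cluster (ties broken towards the lower cluster index).

The procedure is fully deterministic for a fixed input graph, and invariant
to node relabelling because nodes are ordered by sorted id internally.
Dense exact expansion is used throughout: the target graphs (hundreds of
responder cells) are far below the scale where the original implementation's
resource schemes matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import networkx as nx
import numpy as np

from .errors import ValidationError

#: entries below this are treated as zero flow when reading clusters off the
#: converged matrix (iterates decay geometrically, so "zero" entries linger
#: as denormal-scale residue when pruning is disabled)
SUPPORT_EPS = 1e-8


@dataclass
class MclParams:
    """Tunable parameters of the Markov Cluster algorithm.

    ``preinflation`` and ``inflation`` control cluster granularity (larger
    exponents give finer clusters); both default to 1.8. ``min_cluster_size``
    (default 5) is the smallest cluster retained downstream. ``prune_eps``
    zeroes negligible flow entries between iterations for numerical hygiene.
    """

    preinflation: float = 1.8
    inflation: float = 1.8
    min_cluster_size: int = 5
    prune_eps: float = 1e-6
    max_iter: int = 200
    convergence_tol: float = 1e-9

    def validate(self) -> None:
        if self.inflation <= 1:
            raise ValidationError("inflation must exceed 1")
        if self.preinflation < 1:
            raise ValidationError("preinflation must be >= 1")
        if self.min_cluster_size < 1:
            raise ValidationError("min_cluster_size must be >= 1")
        if self.prune_eps < 0 or self.max_iter < 1 or self.convergence_tol <= 0:
            raise ValidationError("bad numerical parameters")


@dataclass
class MclResult:
    """Raw MCL output: a partition of the graph's nodes."""

    clusters: list[frozenset]
    converged: bool
    n_iter: int
    max_colsum_error: float  # worst |column sum - 1| seen after any normalize
    overlap_nodes: list = field(default_factory=list)


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    colsum = m.sum(axis=0)
    if (colsum == 0).any():
        # a pruned-out column would lose its node entirely; restore self-flow
        for j in np.flatnonzero(colsum == 0):
            m[j, j] = 1.0
        colsum = m.sum(axis=0)
    return m / colsum


def _inflate(m: np.ndarray, exponent: float) -> np.ndarray:
    return _normalize_columns(np.power(m, exponent))


def mcl(graph: nx.Graph, params: MclParams | None = None) -> MclResult:
    """Cluster an unweighted graph with the Markov Cluster algorithm.

    Edge weights are ignored (the graph is treated as unweighted, matching
    the thresholded-correlation construction upstream). Returns the raw
    clusters before any size filtering or merging.
    """
    params = params or MclParams()
    params.validate()
    if graph.number_of_nodes() == 0:
        raise ValidationError("cannot cluster an empty graph")

    nodes = sorted(graph.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for u, v in graph.edges():
        a[index[u], index[v]] = 1.0
        a[index[v], index[u]] = 1.0
    np.fill_diagonal(a, 1.0)  # self-loops

    max_colsum_error = 0.0

    def checked(m: np.ndarray) -> np.ndarray:
        nonlocal max_colsum_error
        err = float(np.abs(m.sum(axis=0) - 1.0).max())
        max_colsum_error = max(max_colsum_error, err)
        return m

    m = checked(_normalize_columns(a))
    m = checked(_inflate(m, params.preinflation))

    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        prev = m
        m = m @ m  # expansion
        m = np.power(m, params.inflation)  # inflation
        if params.prune_eps > 0:
            m[m < params.prune_eps] = 0.0
        m = checked(_normalize_columns(m))
        if float(np.abs(m - prev).max()) < params.convergence_tol:
            converged = True
            break

    clusters, overlaps = _interpret(m, nodes)
    return MclResult(
        clusters=clusters,
        converged=converged,
        n_iter=it,
        max_colsum_error=max_colsum_error,
        overlap_nodes=overlaps,
    )


def _interpret(
    m: np.ndarray, nodes: Sequence[Hashable]
) -> tuple[list[frozenset], list]:
    """Read clusters off a converged flow matrix (column-stochastic)."""
    n = len(nodes)
    diag = np.diag(m)
    attractors = np.flatnonzero(diag > SUPPORT_EPS)
    if attractors.size == 0:
        # fully non-converged pathological case: every node on its own
        return [frozenset([v]) for v in nodes], []

    # attractor systems: connected components of mutual flow among attractors
    att_set = set(attractors.tolist())
    sys_graph = nx.Graph()
    sys_graph.add_nodes_from(att_set)
    for i in att_set:
        for j in att_set:
            if i < j and (m[i, j] > SUPPORT_EPS or m[j, i] > SUPPORT_EPS):
                sys_graph.add_edge(i, j)
    systems = [sorted(c) for c in nx.connected_components(sys_graph)]
    systems.sort(key=lambda s: s[0])  # deterministic cluster indexing

    # membership: node v joins every system one of whose attractors receives
    # flow from v (column v, attractor row a)
    member_of: list[list[int]] = [[] for _ in range(n)]
    for k, system in enumerate(systems):
        rows = np.asarray(system)
        reached = np.flatnonzero((m[rows, :] > SUPPORT_EPS).any(axis=0))
        for v in reached:
            member_of[v].append(k)
        for a_node in system:
            if k not in member_of[a_node]:
                member_of[a_node].append(k)

    provisional: list[set[int]] = [set() for _ in systems]
    for v, ks in enumerate(member_of):
        for k in ks:
            provisional[k].add(v)

    overlaps = []
    assignment: dict[int, int] = {}
    for v, ks in enumerate(member_of):
        if not ks:
            continue  # handled below
        if len(ks) == 1:
            assignment[v] = ks[0]
        else:
            overlaps.append(nodes[v])
            # larger cluster wins; ties towards the lower cluster index
            assignment[v] = max(ks, key=lambda k: (len(provisional[k]), -k))

    clusters: list[set] = [set() for _ in systems]
    for v, k in assignment.items():
        clusters[k].add(nodes[v])
    # nodes whose column mass reaches no attractor (possible only without
    # convergence): keep them as singletons rather than dropping them
    stray = [nodes[v] for v in range(n) if v not in assignment]
    out = [frozenset(c) for c in clusters if c] + [frozenset([v]) for v in stray]
    return out, overlaps
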