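"""Clique Percolation Method (CPM) community detection.

A k-clique community is the union of all k-cliques reachable from one
another through a chain of adjacent k-cliques, where two k-cliques are
adjacent iff they share k-1 nodes.  Communities found at the same k may
overlap in nodes but never share a whole k-clique.

Implementation: maximal cliques are enumerated with a pivoting
Bron-Kerbosch search, expanded into their k-subsets, and merged with a
union-find keyed on shared (k-1)-subsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx

__all__ = ["CliqueModule", "find_k_cliques", "clique_percolation"]


@dataclass(frozen=True)
class CliqueModule:
    """One CPM community: its member nodes and the clique size used."""

    members: frozenset[str]
    k: int
    index: int

    def __len__(self) -> int:
        return len(self.members)


def find_k_cliques(graph: nx.Graph, k: int, max_maximal_cliques: int = 1_000_000) -> list[frozenset]:
    """All complete subgraphs of exactly ``k`` nodes, deduplicated.

    Every k-subset of every maximal clique is a k-clique, so the maximal
    cliques (pivoting search) are expanded into k-subsets.  A cap on the
    maximal-clique count guards against pathological inputs.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if graph.number_of_nodes() < k:
        return []
    out: set[frozenset] = set()
    for i, clique in enumerate(nx.find_cliques(graph)):
        if i >= max_maximal_cliques:
            raise RuntimeError(
                f"more than {max_maximal_cliques} maximal cliques; aborting"
            )
        if len(clique) < k:
            continue
        for subset in combinations(sorted(clique), k):
            out.add(frozenset(subset))
    return sorted(out, key=lambda c: tuple(sorted(c)))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def clique_percolation(graph: nx.Graph, k: int = 3) -> list[CliqueModule]:
    """CPM communities of ``graph`` at clique size ``k``.

    Two k-cliques are adjacent iff they share k-1 nodes, i.e. a common
    (k-1)-subset; communities are the connected components of this clique
    adjacency, projected back to node sets.  Nodes belonging to no
    k-clique belong to no module.  Modules are returned largest first
    (ties broken lexicographically).
    """
    cliques = find_k_cliques(graph, k)
    if not cliques:
        return []
    uf = _UnionFind(len(cliques))
    owner: dict[frozenset, int] = {}
    for idx, clique in enumerate(cliques):
        for sub in combinations(sorted(clique), k - 1):
            key = frozenset(sub)
            if key in owner:
                uf.union(owner[key], idx)
            else:
                owner[key] = idx
    groups: dict[int, set] = {}
    for idx, clique in enumerate(cliques):
        groups.setdefault(uf.find(idx), set()).update(clique)
    members = sorted(
        (frozenset(g) for g in groups.values()),
        key=lambda m: (-len(m), tuple(sorted(m))),
    )
    return [CliqueModule(members=m, k=k, index=i) for i, m in enumerate(members)]
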