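"""Co-target hypergeometric synergy test and miRNA-miRNA network assembly.

Two miRNAs are called functionally synergistic when the genes they target
in common (their co-targets) are over-represented in at least one pathway
gene set.  For a pair with ``n`` co-targets inside a target universe of
``N`` genes, the chance of seeing ``k`` or more of them inside a pathway of
``M_i`` genes is the hypergeometric upper tail

    p_i = sum_{x=k}^{min(n, M_i)} C(M_i, x) C(N - M_i, n - x) / C(N, n).

Per pair, the p-values are Benjamini-Hochberg adjusted across pathways and
an edge is created iff at least one adjusted p falls below alpha.  Edges
carry the pair's Pearson CE so the resulting graph doubles as the
correlation network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
from scipy.stats import hypergeom

from .containers import ExpressionMatrix, PathwayAnnotation, TargetMap
from .correlation import MiRNAPair, pairwise_ce
from .diffexpr import bh_adjust

__all__ = [
    "EnrichmentProblem",
    "SynergyEdge",
    "co_targets",
    "hypergeom_tail",
    "synergy_test_pair",
    "build_network",
]

log = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class EnrichmentProblem:
    """One pathway-enrichment instance for a pair's co-targets."""

    universe_size: int   # N: number of all targets
    pathway_size: int    # M_i: genes in pathway term i (within the universe)
    co_target_size: int  # n: size of the co-target set
    overlap: int         # k: co-targets annotated to pathway term i

    def validate(self) -> None:
        n_, m, n, k = self.universe_size, self.pathway_size, self.co_target_size, self.overlap
        if min(n_, m, n) < 0 or k < 0:
            raise ValueError("enrichment counts must be nonnegative")
        if m > n_ or n > n_:
            raise ValueError("pathway and co-target sets cannot exceed the universe")
        if k > min(n, m):
            raise ValueError("overlap cannot exceed min(co-target size, pathway size)")


@dataclass
class SynergyEdge:
    """A significant pair: its CE and the pathways that made it significant."""

    pair: MiRNAPair
    co_target_count: int
    pathways: list[tuple[str, float, float]] = field(default_factory=list)  # (id, p, fdr)

    @property
    def best_pathway(self) -> tuple[str, float, float]:
        return min(self.pathways, key=lambda t: (t[2], t[1], t[0]))


def co_targets(target_map: TargetMap, mirna_a: str, mirna_b: str) -> frozenset[str]:
    """Exact intersection of the two miRNAs' target sets."""
    return target_map[mirna_a] & target_map[mirna_b]


def hypergeom_tail(problem: EnrichmentProblem) -> float:
    """Upper-tail hypergeometric probability, including the observed overlap.

    Evaluated through the survival function (log-space internally), so it
    stays accurate for extreme tails; returns a value in (0, 1].
    """
    problem.validate()
    if problem.overlap == 0:
        return 1.0
    p = float(
        hypergeom.sf(
            problem.overlap - 1,
            problem.universe_size,
            problem.pathway_size,
            problem.co_target_size,
        )
    )
    return min(max(p, 0.0), 1.0)


def synergy_test_pair(
    pair: MiRNAPair | tuple[str, str],
    target_map: TargetMap,
    pathways: PathwayAnnotation,
    alpha: float = ALPHA,
) -> SynergyEdge | None:
    """Test one miRNA pair for pathway-enriched co-targets.

    One hypergeometric tail per pathway on the pair's co-targets, BH
    adjustment across pathways within the pair; returns an edge iff at
    least one adjusted p < alpha, else None.  Pairs with no co-targets
    never form an edge.
    """
    if isinstance(pair, tuple):
        pair = MiRNAPair(pair[0], pair[1], ce=0.0)
    shared = co_targets(target_map, pair.mirna_a, pair.mirna_b)
    if not shared:
        log.debug("pair (%s, %s) has no co-targets", pair.mirna_a, pair.mirna_b)
        return None
    universe = target_map.universe
    n_universe = len(universe)
    pathway_ids: list[str] = []
    raw: list[float] = []
    for pid, genes in sorted(pathways.items()):
        members = genes & universe
        if not members:
            continue
        k = len(shared & members)
        raw.append(
            hypergeom_tail(
                EnrichmentProblem(n_universe, len(members), len(shared), k)
            )
        )
        pathway_ids.append(pid)
    if not raw:
        return None
    adjusted = bh_adjust(raw)
    hits = [
        (pid, p, float(q))
        for pid, p, q in zip(pathway_ids, raw, adjusted)
        if q < alpha
    ]
    if not hits:
        return None
    return SynergyEdge(pair=pair, co_target_count=len(shared), pathways=hits)


def build_network(
    candidate_pairs: Iterable[tuple[str, str]] | Sequence[MiRNAPair],
    matrix: ExpressionMatrix,
    target_map: TargetMap,
    pathways: PathwayAnnotation,
    alpha: float = ALPHA,
) -> nx.Graph:
    """Assemble the miRNA-miRNA correlation/synergy network.

    Candidates (typically all unordered pairs of the DEmiR set) are tested
    for co-target pathway enrichment; surviving pairs become edges
    annotated with Pearson CE (all samples pooled), sign class, co-target
    count and the significant pathways.  Nodes are the miRNAs incident to
    at least one edge.  Candidates lacking target annotation are skipped
    with a log message.
    """
    keys: list[tuple[str, str]] = []
    for cand in candidate_pairs:
        a, b = (cand.mirna_a, cand.mirna_b) if isinstance(cand, MiRNAPair) else cand
        keys.append((a, b) if a < b else (b, a))
    keys = sorted(set(keys))

    feature_ids = sorted({m for key in keys for m in key})
    ce_of = {p.key: p.ce for p in pairwise_ce(matrix, feature_ids)} if feature_ids else {}

    graph = nx.Graph()
    n_pos = n_neg = 0
    for a, b in keys:
        if a not in target_map or b not in target_map:
            log.info("skipping pair (%s, %s): no target annotation", a, b)
            continue
        edge = synergy_test_pair((a, b), target_map, pathways, alpha=alpha)
        if edge is None:
            continue
        ce = ce_of.get((a, b))
        if ce is None:
            log.info("pair (%s, %s) significant but CE undefined; skipped", a, b)
            continue
        sign = "positive" if ce > 0 else "negative"
        if sign == "positive":
            n_pos += 1
        else:
            n_neg += 1
        best = min(edge.pathways, key=lambda t: (t[2], t[1], t[0]))
        graph.add_edge(
            a, b,
            ce=float(ce),
            sign_class=sign,
            co_target_count=edge.co_target_count,
            pathways=tuple(edge.pathways),
            best_pathway=best[0],
            best_adjusted_p=best[2],
        )
    graph.graph["n_positive_edges"] = n_pos
    graph.graph["n_negative_edges"] = n_neg
    if graph.number_of_edges() == 0:
        log.warning("no candidate pair survived the synergy test; network is empty")
    return graph
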