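"""Co-target hypergeometric synergy test and network assembly."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from mirsynet.containers import PathwayAnnotation, TargetMap
from mirsynet.simulate import AnnotationConfig, SimulationConfig, generate_annotation, generate_expression
from mirsynet.synergy import (
    EnrichmentProblem,
    build_network,
    co_targets,
    hypergeom_tail,
    synergy_test_pair,
)


def _tail_exact(N, M, n, k):
    """Arbitrary-precision upper tail by direct term summation."""
    total = Fraction(0)
    for x in range(k, min(n, M) + 1):
        total += Fraction(comb(M, x) * comb(N - M, n - x), comb(N, n))
    return total


# ---------------------------------------------------------------------------
# co-targets

def test_co_targets_intersection_cases():
    tm = TargetMap({
        "a": frozenset({"g1", "g2", "g3"}),
        "b": frozenset({"g4", "g5"}),
        "c": frozenset({"g1", "g2", "g3"}),
    })
    assert co_targets(tm, "a", "b") == frozenset()
    assert co_targets(tm, "a", "c") == frozenset({"g1", "g2", "g3"})


def test_co_targets_matches_double_loop_scan():
    rng = np.random.default_rng(2)
    genes = [f"g{i}" for i in range(100)]
    tm = TargetMap({
        m: frozenset(rng.choice(genes, size=30, replace=False).tolist())
        for m in ("a", "b")
    })
    naive = frozenset(x for x in tm["a"] for y in tm["b"] if x == y)
    assert co_targets(tm, "a", "b") == naive


def test_unknown_mirna_named_in_error():
    tm = TargetMap({"a": frozenset({"g1"})})
    with pytest.raises(KeyError, match="zzz"):
        co_targets(tm, "a", "zzz")


# ---------------------------------------------------------------------------
# hypergeometric tail

def test_tail_trivial_and_closed_form():
    assert hypergeom_tail(EnrichmentProblem(100, 10, 5, 0)) == 1.0
    # all 4 draws inside the 5-gene pathway: C(5,4)/C(10,4) = 5/210
    p = hypergeom_tail(EnrichmentProblem(10, 5, 4, 4))
    assert p == pytest.approx(5 / 210, rel=1e-12)


def test_tail_matches_enumeration_for_all_small_problems():
    for N in range(1, 13):
        for M in range(0, N + 1):
            for n in range(0, N + 1):
                for k in range(0, min(n, M) + 1):
                    expected = float(_tail_exact(N, M, n, k))
                    got = hypergeom_tail(EnrichmentProblem(N, M, n, k))
                    assert got == pytest.approx(expected, abs=1e-12), (N, M, n, k)


def test_tail_matches_exact_summation_on_large_problem():
    got = hypergeom_tail(EnrichmentProblem(2000, 50, 40, 8))
    expected = float(_tail_exact(2000, 50, 40, 8))
    assert got == pytest.approx(expected, rel=1e-12)


def test_tail_nonincreasing_in_overlap():
    previous = 1.1
    for k in range(0, 21):
        p = hypergeom_tail(EnrichmentProblem(500, 40, 20, k))
        assert p <= previous + 1e-15
        previous = p


def test_tail_invariant_violations_rejected():
    with pytest.raises(ValueError):
        hypergeom_tail(EnrichmentProblem(10, 11, 5, 2))
    with pytest.raises(ValueError):
        hypergeom_tail(EnrichmentProblem(10, 5, 4, 5))


# ---------------------------------------------------------------------------
# per-pair synergy test

def _toy_annotation():
    tm = TargetMap({
        "a": frozenset({f"g{i}" for i in range(20)}),
        "b": frozenset({f"g{i}" for i in range(10)} | {f"h{i}" for i in range(10)}),
        "c": frozenset({f"h{i}" for i in range(10, 30)}),
    })
    pathways = PathwayAnnotation({"pw1": frozenset({f"g{i}" for i in range(10)})})
    return tm, pathways


def test_enriched_pair_forms_edge_single_pathway_bh_identity():
    tm, pathways = _toy_annotation()
    edge = synergy_test_pair(("a", "b"), tm, pathways)
    assert edge is not None
    assert edge.co_target_count == 10
    ((pid, raw, adjusted),) = edge.pathways
    assert pid == "pw1"
    assert adjusted == pytest.approx(raw)  # BH of length 1 is identity


def test_empty_co_targets_give_no_edge():
    tm, pathways = _toy_annotation()
    assert synergy_test_pair(("a", "c"), tm, pathways) is None


def test_bh_within_pair_never_creates_significance():
    rng = np.random.default_rng(6)
    genes = [f"g{i}" for i in range(200)]
    tm = TargetMap({
        "a": frozenset(rng.choice(genes, 50, replace=False).tolist()),
        "b": frozenset(rng.choice(genes, 50, replace=False).tolist()),
    })
    pathways = PathwayAnnotation({
        f"pw{j}": frozenset(rng.choice(genes, 25, replace=False).tolist())
        for j in range(8)
    })
    edge = synergy_test_pair(("a", "b"), tm, pathways, alpha=1.1)
    assert edge is not None
    for _, raw, adjusted in edge.pathways:
        assert adjusted >= raw - 1e-15


def test_planted_pair_significant_with_designated_pathway():
    cfg = AnnotationConfig(
        mirna_ids=[f"miR-{i:02d}" for i in range(10)],
        n_genes=5000, targets_per_mirna=50, n_pathways=10, pathway_size=20,
        planted_synergy_pairs=[("miR-00", "miR-01")], co_target_overlap=10, seed=1,
    )
    targets, pathways, truth = generate_annotation(cfg)
    edge = synergy_test_pair(("miR-00", "miR-01"), targets, pathways)
    assert edge is not None
    assert truth.synergy_pairs[("miR-00", "miR-01")] in {pid for pid, _, _ in edge.pathways}


# ---------------------------------------------------------------------------
# network assembly

def _planted_study(seed=0):
    sim = SimulationConfig(n_mirnas=60, n_de=10, effect_log2=1.5,
                           missing_frac=0.0, seed=seed)
    matrix, truth = generate_expression(sim)
    de_ids = sorted(truth.de_effects)
    planted = [(de_ids[0], de_ids[1]), (de_ids[2], de_ids[3]), (de_ids[4], de_ids[5])]
    ann = AnnotationConfig(
        mirna_ids=matrix.mirna_ids, n_genes=5000, targets_per_mirna=50,
        n_pathways=40, pathway_size=60,
        planted_synergy_pairs=planted, co_target_overlap=10, seed=seed + 1,
    )
    targets, pathways, ann_truth = generate_annotation(ann)
    return matrix, de_ids, targets, pathways, set(ann_truth.synergy_pairs)


def test_planted_synergy_pairs_become_exactly_the_edges():
    matrix, de_ids, targets, pathways, planted = _planted_study(seed=0)
    candidates = list(itertools.combinations(de_ids, 2))
    graph = build_network(candidates, matrix, targets, pathways)
    assert {tuple(sorted(e)) for e in graph.edges} == planted
    for a, b, data in graph.edges(data=True):
        assert -1 <= data["ce"] <= 1
        assert data["sign_class"] == ("positive" if data["ce"] > 0 else "negative")
        assert data["co_target_count"] >= 10


def test_edge_set_invariant_to_candidate_order():
    matrix, de_ids, targets, pathways, _ = _planted_study(seed=3)
    candidates = list(itertools.combinations(de_ids, 2))
    g1 = build_network(candidates, matrix, targets, pathways)
    g2 = build_network(candidates[::-1], matrix, targets, pathways)
    assert set(g1.edges) == set(g2.edges)


def test_no_surviving_candidates_empty_network():
    matrix, de_ids, targets, pathways, _ = _planted_study(seed=5)
    graph = build_network([], matrix, targets, pathways)
    assert graph.number_of_edges() == 0
    assert graph.graph["n_positive_edges"] == 0
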