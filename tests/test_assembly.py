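"""assembly: scoring primitives, the DP, constraints and level assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_map, random_centered_map, symmetric
from hictad import (AssemblyParams, CandidateBoundarySet, TAD, TADForest,
                    assemble, assign_boundary_levels, assign_tad_levels,
                    deconvoluted_mean, delta_score)
from hictad.matrix import distance_center
from oracles import naive_block_mean, naive_delta, recursion_oracle


def _cands(*positions):
    pos = np.array(sorted(positions), dtype=int)
    return CandidateBoundarySet(positions=pos,
                                provenance={int(p): frozenset() for p in pos})


def _random_map(seed, n=24):
    return random_centered_map(np.random.default_rng(seed), n)


# ----------------------------------------------------------------------
# scoring primitives
# ----------------------------------------------------------------------

def test_deconvoluted_mean_matches_naive():
    m = _random_map(0)
    A = m.nan_values()
    assert deconvoluted_mean(m, 2, 12) == pytest.approx(
        naive_block_mean(A, 2, 12))
    assert deconvoluted_mean(m, 2, 12, [(3, 6), (8, 11)]) == pytest.approx(
        naive_block_mean(A, 2, 12, [(3, 6), (8, 11)]))


def test_deconvoluted_mean_nan_when_children_tile_block():
    m = _random_map(1)
    assert np.isnan(deconvoluted_mean(m, 4, 10, [(4, 10)]))


def test_deconvoluted_mean_rejects_child_outside_parent():
    m = _random_map(2)
    with pytest.raises(ValueError, match="outside"):
        deconvoluted_mean(m, 4, 10, [(2, 8)])


def test_delta_matches_naive():
    m = _random_map(3)
    A = m.nan_values()
    for a, b, kids in [(4, 10, []), (4, 10, [(5, 8)]), (0, 6, []), (18, 24, [])]:
        assert delta_score(m, a, b, kids, penalty=0.1, maxsz=24) == pytest.approx(
            naive_delta(A, m.n_bins, a, b, kids, 0.1))


def test_delta_truncated_flank_dropped():
    # block at the left edge: only the downstream flank exists
    m = _random_map(4)
    A = m.nan_values()
    d = delta_score(m, 0, 6, penalty=0.0, maxsz=24)
    down = np.mean([A[r, c] for r in range(0, 6) for c in range(6, 12)])
    block = naive_block_mean(A, 0, 6)
    assert d == pytest.approx(block - down)


def test_delta_no_flanks_is_neg_inf():
    m = _random_map(5, n=8)
    assert delta_score(m, 0, 8, penalty=0.1, maxsz=8) == float("-inf")


def test_delta_size_bounds_enforced():
    m = _random_map(6)
    with pytest.raises(ValueError):
        delta_score(m, 0, 2)           # below minsz
    with pytest.raises(ValueError):
        delta_score(m, 0, 20, maxsz=10)


def test_delta_decreases_with_penalty():
    m = _random_map(7)
    assert delta_score(m, 4, 10, penalty=0.0) > delta_score(m, 4, 10, penalty=0.5)


# ----------------------------------------------------------------------
# assembly on planted structure
# ----------------------------------------------------------------------

def test_single_planted_block_called():
    n = 30
    v = np.ones((n, n))
    v[8:20, 8:20] += 2.0
    m = distance_center(make_map(symmetric(v)))
    forest = assemble(m, _cands(0, 8, 20, n), AssemblyParams(maxsz=n))
    assert [(t.left, t.right) for t in forest.tads] == [(8, 20)]
    t = forest.tads[0]
    assert t.level == 1 and t.singleton and not t.children
    assert t.score > 0


def test_nested_hierarchy_called(planted_map):
    from hictad.matrix import log2_transform
    cmap, truth = planted_map
    m = distance_center(log2_transform(cmap))
    forest = assemble(m, _cands(0, 15, 32, 46, 60), AssemblyParams(maxsz=60))
    got = sorted((t.left, t.right) for t in forest.tads)
    assert got == [(0, 15), (0, 32), (15, 32), (32, 46), (32, 60), (46, 60)]
    parent = next(t for t in forest.tads if (t.left, t.right) == (0, 32))
    assert parent.level == 1 and not parent.singleton
    assert sorted((c.left, c.right) for c in parent.children) == [(0, 15), (15, 32)]
    assert all(c.level == 2 for c in parent.children)


def test_barren_map_calls_nothing():
    m = distance_center(make_map(symmetric(np.ones((20, 20)))))
    forest = assemble(m, _cands(0, 5, 10, 15, 20), AssemblyParams(maxsz=20))
    assert len(forest) == 0 and forest.total_score == 0.0


def test_fewer_than_two_candidates():
    m = _random_map(8)
    forest = assemble(m, _cands(7), AssemblyParams(maxsz=24))
    assert len(forest) == 0


def test_assembly_deterministic():
    m = _random_map(9)
    c = _cands(0, 3, 7, 12, 16, 20, 24)
    f1 = assemble(m, c, AssemblyParams(maxsz=24))
    f2 = assemble(m, c, AssemblyParams(maxsz=24))
    assert [(t.left, t.right, t.score) for t in f1.tads] == \
           [(t.left, t.right, t.score) for t in f2.tads]


# ----------------------------------------------------------------------
# constraints and invariants
# ----------------------------------------------------------------------

def test_minsz_respected():
    # strong 2-bin block must not be called (minsz = 3)
    n = 20
    v = np.ones((n, n))
    v[9:11, 9:11] += 50.0
    m = distance_center(make_map(symmetric(v)))
    forest = assemble(m, _cands(0, 9, 11, n), AssemblyParams(maxsz=n))
    assert all(t.size >= 3 for t in forest.tads)
    assert (9, 11) not in {(t.left, t.right) for t in forest.tads}


def test_maxsz_respected():
    n = 40
    v = np.ones((n, n))
    v[5:35, 5:35] += 3.0
    m = distance_center(make_map(symmetric(v)))
    forest = assemble(m, _cands(0, 5, 35, n), AssemblyParams(maxsz=20))
    assert all(t.size <= 20 for t in forest.tads)


def test_neighbor_span_respected():
    # the enriched block's ends are 6 candidate junctions apart -> unreachable
    n = 40
    v = np.ones((n, n))
    v[5:35, 5:35] += 3.0
    m = distance_center(make_map(symmetric(v)))
    cands = _cands(0, 5, 10, 15, 20, 25, 30, 35, n)
    forest = assemble(m, cands, AssemblyParams(maxsz=n, max_neighbor_span=5))
    pos = list(cands.positions)
    for t in forest.tads:
        assert pos.index(t.right) - pos.index(t.left) <= 5


@pytest.mark.parametrize("seed", range(8))
def test_invariants_on_random_maps(seed):
    rng = np.random.default_rng(100 + seed)
    n = int(rng.integers(15, 30))
    m = random_centered_map(rng, n)
    pos = np.sort(rng.choice(np.arange(n + 1), size=7, replace=False))
    forest = assemble(m, CandidateBoundarySet(
        positions=pos, provenance={int(p): frozenset() for p in pos}),
        AssemblyParams(maxsz=n))
    A = m.nan_values()
    seen = [(t.left, t.right) for t in forest.tads]
    # every emitted domain clears the margin given its direct children
    for t in forest.tads:
        kids = [(c.left, c.right) for c in t.children]
        assert naive_delta(A, n, t.left, t.right, kids, 0.1) > 0
    # laminar family: any two domains are disjoint or strictly nested
    for x in seen:
        for y in seen:
            if x == y:
                continue
            disjoint = x[1] <= y[0] or y[1] <= x[0]
            nested = (x[0] <= y[0] and y[1] <= x[1]) or \
                     (y[0] <= x[0] and x[1] <= y[1])
            assert disjoint or nested


def test_work_counter_bounded():
    rng = np.random.default_rng(42)
    n = 100
    m = random_centered_map(rng, n)
    pos = np.sort(rng.choice(np.arange(n + 1), size=30, replace=False))
    params = AssemblyParams(maxsz=n)
    forest = assemble(m, CandidateBoundarySet(
        positions=pos, provenance={int(p): frozenset() for p in pos}), params)
    M = pos.size
    span = params.max_neighbor_span
    assert 0 < forest.work <= 2 * span ** 3 * M


@given(seed=st.integers(0, 2_000))
@settings(max_examples=15)
def test_dp_matches_recursion_oracle_property(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 22))
    m = random_centered_map(rng, n)
    k = int(rng.integers(3, 7))
    pos = np.sort(rng.choice(np.arange(n + 1), size=k, replace=False))
    params = AssemblyParams(maxsz=n)
    forest = assemble(m, CandidateBoundarySet(
        positions=pos, provenance={int(p): frozenset() for p in pos}), params)
    score, called = recursion_oracle(m.nan_values(), pos, params.penalty,
                                     span=params.max_neighbor_span,
                                     minsz=params.minsz, maxsz=params.maxsz)
    assert forest.total_score == pytest.approx(score, abs=1e-9)
    assert frozenset((t.left, t.right) for t in forest.tads) == called


# ----------------------------------------------------------------------
# level assignment
# ----------------------------------------------------------------------

def _chain(depth):
    """depth nested TADs, outermost (0, 4*depth)."""
    tads = []
    outer = None
    for d in range(depth):
        t = TAD(left=d, right=4 * depth - d, score=1.0, mean=1.0)
        if outer is not None:
            outer.children.append(t)
        else:
            roots = [t]
        outer = t
        tads.append(t)
    return TADForest(tads=tads, roots=roots, n_bins=4 * depth)


def test_levels_count_outermost_in_and_cap_at_five():
    forest = assign_tad_levels(_chain(6), cap=5)
    assert [t.level for t in forest.tads] == [1, 2, 3, 4, 5, 5]
    assert not any(t.singleton for t in forest.tads)


def test_lone_tad_is_level_one_singleton():
    forest = assign_tad_levels(_chain(1), cap=5)
    assert forest.tads[0].level == 1 and forest.tads[0].singleton


def test_boundary_level_max_of_two_sides():
    # 2 domains end at junction 10; 3 start there -> boundary level 3
    tads = [TAD(2, 10, 1, 1), TAD(6, 10, 1, 1),
            TAD(10, 20, 1, 1), TAD(10, 16, 1, 1), TAD(10, 13, 1, 1)]
    forest = TADForest(tads=tads, roots=tads, n_bins=20)
    levels = assign_boundary_levels(forest, cap=5)
    lvl, hub = levels[10]
    assert lvl == 3 and not hub


def test_hub_boundary_at_cap():
    tads = [TAD(10, 13 + 2 * i, 1, 1) for i in range(5)]
    forest = TADForest(tads=tads, roots=tads, n_bins=30)
    levels = assign_boundary_levels(forest, cap=5)
    lvl, hub = levels[10]
    assert lvl == 5 and hub


def test_params_validation():
    with pytest.raises(ValueError):
        AssemblyParams(penalty=-0.1)
    with pytest.raises(ValueError):
        AssemblyParams(minsz=2)
    with pytest.raises(ValueError):
        AssemblyParams(minsz=10, maxsz=5)
    with pytest.raises(ValueError):
        AssemblyParams(max_neighbor_span=0)
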