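"""evaluation: adjusted R^2, reproducibility metrics, enrichment, diagnostics."""

import numpy as np
import pytest

from conftest import make_map, symmetric
from hictad import (StateAnnotation, TAD, TADForest, boundary_jaccard,
                    corner_quadrant_diagnostic, mean_signal_profile,
                    state_enrichment, tad_adj_r2, tad_rand_index)
from hictad.evaluation import (adj_r2_profile, innermost_labels,
                               rescale_boundaries)
from oracles import contingency_ari, naive_signal_profile


def _forest(spans, n_bins):
    tads = [TAD(left=a, right=b, score=1.0, mean=1.0) for a, b in spans]
    return TADForest(tads=tads, roots=tads, n_bins=n_bins)


def _block_map(n, spans, inside=5.0, outside=1.0):
    v = np.full((n, n), outside)
    for a, b in spans:
        v[a:b, a:b] = inside
    rng = np.random.default_rng(0)
    return make_map(symmetric(v))


# ----------------------------------------------------------------------
# TAD-adjusted R^2
# ----------------------------------------------------------------------

def test_adj_r2_is_one_when_groups_are_constant():
    n = 20
    cmap = _block_map(n, [(5, 15)])
    forest = _forest([(5, 15)], n)
    assert tad_adj_r2(cmap, forest, k=2) == pytest.approx(1.0)


def test_adj_r2_is_zero_for_empty_forest():
    rng = np.random.default_rng(1)
    cmap = make_map(symmetric(rng.gamma(2.0, 2.0, size=(20, 20))))
    # p = 0 predictors: the gap pool predicts the grand mean exactly
    assert tad_adj_r2(cmap, _forest([], 20), k=2) == pytest.approx(0.0)


def test_adj_r2_nan_when_overparameterized():
    n = 6
    cmap = _block_map(n, [(0, 3)])
    forest = _forest([(0, 6), (1, 5)], n)
    # at k=4 only 2 pairs exist but p >= 2 -> n - p - 1 <= 0
    assert np.isnan(tad_adj_r2(cmap, forest, k=4))


def test_adj_r2_nan_when_variance_zero():
    cmap = make_map(symmetric(np.ones((10, 10)) * 3.0))
    assert np.isnan(tad_adj_r2(cmap, _forest([(2, 6)], 10), k=1))


def test_adj_r2_rejects_bad_distance():
    cmap = _block_map(10, [])
    with pytest.raises(ValueError):
        tad_adj_r2(cmap, _forest([], 10), k=0)
    assert np.isnan(tad_adj_r2(cmap, _forest([], 10), k=10))


def test_adj_r2_profile_weighted_average():
    n = 20
    cmap = _block_map(n, [(5, 15)])
    forest = _forest([(5, 15)], n)
    prof = adj_r2_profile(cmap, forest, [1, 2, 3])
    assert np.allclose(prof.r2[np.isfinite(prof.r2)], 1.0)
    assert prof.weighted_average == pytest.approx(1.0)
    assert list(prof.distances) == [1, 2, 3]


# ----------------------------------------------------------------------
# boundary Jaccard and Rand index
# ----------------------------------------------------------------------

def test_jaccard_worked_example():
    assert boundary_jaccard({10, 20}, {20, 30}) == pytest.approx(1 / 3)


def test_jaccard_identical_and_empty_conventions():
    assert boundary_jaccard({3, 9}, {3, 9}) == 1.0
    assert boundary_jaccard(set(), set()) == 1.0
    assert boundary_jaccard({3}, set()) == 0.0


def test_jaccard_tolerance_matching():
    assert boundary_jaccard({10}, {11}, tol=1) == 1.0
    assert boundary_jaccard({10}, {12}, tol=1) == 0.0
    # one-to-one: two left boundaries cannot both claim one right boundary
    assert boundary_jaccard({10, 11}, {11}, tol=1) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        boundary_jaccard({1}, {2}, tol=-1)


def test_rand_index_identical_is_one():
    f = _forest([(2, 8), (10, 16)], 20)
    assert tad_rand_index(f, f, 20) == pytest.approx(1.0)


def test_rand_index_matches_contingency_oracle():
    n = 20
    fa = _forest([(0, 8), (8, 16)], n)
    fb = _forest([(0, 6), (6, 16), (16, 20)], n)
    la, lb = innermost_labels(fa, n), innermost_labels(fb, n)
    keep = (la >= 0) & (lb >= 0)
    assert tad_rand_index(fa, fb, n) == pytest.approx(
        contingency_ari(la[keep], lb[keep]))
    # gap-as-cluster variant against the oracle on relabeled gaps
    got = tad_rand_index(fa, fb, n, gap_as_cluster=True)
    assert got == pytest.approx(contingency_ari(la, lb))


def test_rand_index_nan_when_no_overlap():
    fa = _forest([(0, 5)], 20)
    fb = _forest([(10, 15)], 20)
    assert np.isnan(tad_rand_index(fa, fb, 20))


def test_innermost_labels_inner_wins():
    f = _forest([(2, 18), (5, 10)], 20)
    lab = innermost_labels(f, 20)
    assert lab[0] == -1 and lab[3] == 0 and lab[7] == 1 and lab[12] == 0


def test_rescale_boundaries():
    assert rescale_boundaries([10, 19, 20], 10) == [1, 2]


# ----------------------------------------------------------------------
# signal profile and state enrichment
# ----------------------------------------------------------------------

def test_signal_profile_matches_naive():
    rng = np.random.default_rng(2)
    sig = rng.normal(size=50)
    bs = [0, 7, 23, 49]
    got = mean_signal_profile(sig, bs, flank=5)
    assert np.allclose(got, naive_signal_profile(sig, bs, 5), equal_nan=True)


def test_signal_profile_edge_truncation():
    sig = np.arange(10, dtype=float)
    prof = mean_signal_profile(sig, [0], flank=3)
    assert np.all(np.isnan(prof[:3]))          # offsets -3..-1 never in range
    assert prof[3] == 0.0 and prof[6] == 3.0


def test_signal_profile_rejects_empty_boundaries():
    with pytest.raises(ValueError, match="empty"):
        mean_signal_profile(np.ones(10), [])
    with pytest.raises(ValueError):
        mean_signal_profile(np.ones(10), [3], flank=-1)


def _annotation():
    # 100 windows of 100 bp; 50 labeled A (B_A = 0.5)
    states = ["A"] * 19 + ["B"] * 21 + ["A"] * 31 + ["B"] * 29
    starts = np.arange(100) * 100
    return StateAnnotation(starts=starts, ends=starts + 100,
                           states=np.array(states, dtype=object))


def test_state_enrichment_worked_example():
    ann = _annotation()
    assert ann.proportion("A") == pytest.approx(0.5)
    # region covering 40 windows, 19 of them state A: (19+1)/(0.5*40+1)
    assert state_enrichment(ann, [(0, 4000)], "A") == pytest.approx(20 / 21)


def test_state_enrichment_empty_region_limit():
    ann = _annotation()
    # no window midpoint inside: (0+1)/(B_s*0+1) = 1
    assert state_enrichment(ann, [(10_000, 10_050)], "A") == pytest.approx(1.0)


def test_state_enrichment_state_absent_from_region():
    ann = _annotation()
    # windows 19..39 are all B: total=21, total_A=0
    assert state_enrichment(ann, [(1900, 4000)], "A") == pytest.approx(
        1.0 / (0.5 * 21 + 1.0))


def test_state_enrichment_unknown_state_raises():
    with pytest.raises(KeyError):
        state_enrichment(_annotation(), [(0, 1000)], "Z")


# ----------------------------------------------------------------------
# corner diagnostic
# ----------------------------------------------------------------------

def test_corner_diagnostic_on_planted_block():
    n = 30
    cmap = _block_map(n, [(8, 22)])
    forest = _forest([(8, 22)], n)
    diag = corner_quadrant_diagnostic(cmap, forest, q=3)
    assert diag.means.shape == (1, 4)
    assert diag.means[0, 0] == pytest.approx(5.0)       # inside the corner
    assert diag.means[0, 3] == pytest.approx(1.0)       # fully outside
    assert diag.fraction_consistent == 1.0
    with pytest.raises(ValueError):
        corner_quadrant_diagnostic(cmap, forest, q=0)


def test_corner_diagnostic_truncates_at_edges():
    n = 12
    cmap = _block_map(n, [(0, 12)])
    diag = corner_quadrant_diagnostic(cmap, _forest([(0, 12)], n), q=4)
    # quadrants outside the chromosome have zero entries and NaN means
    assert diag.counts[0, 1] == 0 and np.isnan(diag.means[0, 1])
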