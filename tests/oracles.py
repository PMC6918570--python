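"""Independent reference implementations (oracles) for derived quantities.

Every oracle here is written in the most literal way possible — double
loops, explicit recursion, exhaustive enumeration — and shares no code
with the package internals it checks.
"""

from __future__ import annotations

from functools import lru_cache
from math import comb
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

NEG_INF = float("-inf")


# ----------------------------------------------------------------------
# diamond statistic
# ----------------------------------------------------------------------

def naive_diamond(values: np.ndarray, mask: np.ndarray, W: int) -> np.ndarray:
    """Double-loop diamond means: rows [i-W, i), cols [i, i+W)."""
    n = values.shape[0]
    A = values.astype(float).copy()
    A[mask, :] = np.nan
    A[:, mask] = np.nan
    stats = np.full(n + 1, np.nan)
    for i in range(n + 1):
        vals = []
        for r in range(max(0, i - W), i):
            for c in range(i, min(n, i + W)):
                if np.isfinite(A[r, c]):
                    vals.append(A[r, c])
        if vals:
            stats[i] = float(np.mean(vals))
    return stats


# ----------------------------------------------------------------------
# block / flank means and the margin score
# ----------------------------------------------------------------------

def naive_block_mean(A: np.ndarray, a: int, b: int,
                     children: Sequence[Tuple[int, int]] = ()) -> float:
    """Mean over [a,b)^2 skipping entries inside any child block."""
    tot, cnt = 0.0, 0
    for r in range(a, b):
        for c in range(a, b):
            if any(l <= r < rr and l <= c < rr for l, rr in children):
                continue
            v = A[r, c]
            if np.isfinite(v):
                tot += v
                cnt += 1
    return tot / cnt if cnt else float("nan")


def naive_delta(A: np.ndarray, n: int, a: int, b: int,
                children: Sequence[Tuple[int, int]], penalty: float) -> float:
    """Margin score: deconvoluted mean minus max flank mean minus penalty."""
    m = naive_block_mean(A, a, b, children)
    if not np.isfinite(m):
        return NEG_INF
    sz = b - a
    flanks = []
    r0 = max(0, a - sz)
    if r0 < a:
        vals = [A[r, c] for r in range(r0, a) for c in range(a, b)
                if np.isfinite(A[r, c])]
        if vals:
            flanks.append(float(np.mean(vals)))
    c1 = min(n, b + sz)
    if c1 > b:
        vals = [A[r, c] for r in range(a, b) for c in range(b, c1)
                if np.isfinite(A[r, c])]
        if vals:
            flanks.append(float(np.mean(vals)))
    if not flanks:
        return NEG_INF
    return m - max(flanks) - penalty


# ----------------------------------------------------------------------
# exhaustive forest enumeration
# ----------------------------------------------------------------------

class Tree:
    __slots__ = ("ai", "bi", "children")

    def __init__(self, ai: int, bi: int, children: Tuple["Tree", ...]):
        self.ai, self.bi, self.children = ai, bi, children


def _pair_ok(cand: np.ndarray, k: int, j: int, span: int,
             minsz: int, maxsz: int) -> bool:
    return (j - k <= span) and (minsz <= cand[j] - cand[k] <= maxsz)


def enumerate_optimal_forest(A: np.ndarray, cand: Sequence[int],
                             penalty: float, span: int = 5,
                             minsz: int = 3, maxsz: int = 200):
    """Exhaustive search over every valid disjoint-or-nested configuration.

    A configuration is a laminar family of candidate-junction pairs (each
    within the size and neighbor-span limits); its score is the sum over
    members of the margin score given the member's direct children in the
    family, and a configuration is admissible only if every member's
    margin is positive (called domains must clear the penalty).  Returns
    ``(best_score, best_set)`` where the set contains (left_bin,
    right_bin) pairs; the empty configuration scores 0.
    """
    cand = np.asarray(cand, dtype=int)
    M = cand.size
    n = A.shape[0]

    @lru_cache(maxsize=None)
    def forests(lo: int, hi: int, exclude_full: bool) -> Tuple[Tuple[Tree, ...], ...]:
        """All forests (tuples of disjoint trees, left to right) over
        candidate indices lo..hi."""
        if hi <= lo:
            return ((),)
        out: List[Tuple[Tree, ...]] = []
        # junction hi is not the right end of any called pair
        out.extend(forests(lo, hi - 1, False))
        # or it ends a called pair (k, hi)
        for k in range(max(lo, hi - span), hi):
            if exclude_full and k == lo and hi == hi and (k, hi) == (lo, hi):
                continue
            if not _pair_ok(cand, k, hi, span, minsz, maxsz):
                continue
            for inner in forests(k, hi, True):
                for left in forests(lo, k, False):
                    out.append(left + (Tree(k, hi, inner),))
        return tuple(out)

    best_score, best_set = 0.0, frozenset()

    def score_tree(t: Tree) -> Optional[Tuple[float, frozenset]]:
        total, members = 0.0, set()
        for ch in t.children:
            sub = score_tree(ch)
            if sub is None:
                return None
            total += sub[0]
            members |= sub[1]
        kids = [(int(cand[c.ai]), int(cand[c.bi])) for c in t.children]
        d = naive_delta(A, n, int(cand[t.ai]), int(cand[t.bi]), kids, penalty)
        if not d > 0:
            return None          # every called domain must clear the margin
        members.add((int(cand[t.ai]), int(cand[t.bi])))
        return total + d, frozenset(members)

    for forest in forests(0, M - 1, False):
        total, members = 0.0, set()
        ok = True
        for t in forest:
            sub = score_tree(t)
            if sub is None:
                ok = False
                break
            total += sub[0]
            members |= sub[1]
        if ok and total > best_score:
            best_score, best_set = total, frozenset(members)
    forests.cache_clear()
    return best_score, best_set


# ----------------------------------------------------------------------
# adjusted Rand index from the contingency table
# ----------------------------------------------------------------------

def contingency_ari(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Closed-form ARI: (sum_ij C(n_ij,2) - E) / (max - E)."""
    la = np.asarray(labels_a)
    lb = np.asarray(labels_b)
    ua, ub = np.unique(la), np.unique(lb)
    table = np.zeros((ua.size, ub.size), dtype=int)
    for i, x in enumerate(ua):
        for j, y in enumerate(ub):
            table[i, j] = int(np.sum((la == x) & (lb == y)))
    nij = sum(comb(int(v), 2) for v in table.ravel())
    ai = sum(comb(int(v), 2) for v in table.sum(axis=1))
    bj = sum(comb(int(v), 2) for v in table.sum(axis=0))
    npairs = comb(la.size, 2)
    expected = ai * bj / npairs if npairs else 0.0
    maximum = 0.5 * (ai + bj)
    if maximum == expected:
        return 1.0
    return (nij - expected) / (maximum - expected)


# ----------------------------------------------------------------------
# signal profile
# ----------------------------------------------------------------------

def naive_signal_profile(signal: np.ndarray, boundaries: Sequence[int],
                         flank: int) -> np.ndarray:
    out = np.full(2 * flank + 1, np.nan)
    signal = np.asarray(signal, dtype=float)
    for idx, off in enumerate(range(-flank, flank + 1)):
        vals = []
        for b in boundaries:
            pos = b + off
            if 0 <= pos < signal.size and np.isfinite(signal[pos]):
                vals.append(signal[pos])
        if vals:
            out[idx] = float(np.mean(vals))
    return out


# ----------------------------------------------------------------------
# unmemoized transliteration of the recursive scoring definition
# ----------------------------------------------------------------------

def recursion_oracle(A: np.ndarray, cand: Sequence[int], penalty: float,
                     span: int = 5, minsz: int = 3, maxsz: int = 200):
    """Direct transliteration of the recursive score definition.

    ``g(a,b)`` scans every binary partition point, ``t = max(g, h)``,
    ``h = g + delta`` where delta's direct children are the maximal
    members of the forest chosen by ``g``; a block is called only when
    its margin is positive.  Returns ``(root_score, called_set)`` with
    the set in (left_bin, right_bin) pairs.  Caching is keyed on the
    pair only (the recursion is deterministic), kept separate from the
    production prefix-sum DP.
    """
    cand = np.asarray(cand, dtype=int)
    M = cand.size
    n = A.shape[0]
    if M < 2:
        return 0.0, frozenset()

    memo_g: Dict[Tuple[int, int], Tuple[float, frozenset]] = {}
    memo_t: Dict[Tuple[int, int], Tuple[float, frozenset]] = {}

    def maximal(members: frozenset) -> List[Tuple[int, int]]:
        out = []
        for x in members:
            if not any(y != x and y[0] <= x[0] and x[1] <= y[1] for y in members):
                out.append(x)
        return out

    def g(ai: int, bi: int) -> Tuple[float, frozenset]:
        key = (ai, bi)
        if key not in memo_g:
            best, best_set = 0.0, frozenset()
            for i in range(ai + 1, bi):
                v1, s1 = t(ai, i)
                v2, s2 = t(i, bi)
                if v1 + v2 > best + 1e-12:
                    best, best_set = v1 + v2, s1 | s2
            memo_g[key] = (best, best_set)
        return memo_g[key]

    def t(ai: int, bi: int) -> Tuple[float, frozenset]:
        key = (ai, bi)
        if key not in memo_t:
            gv, gs = g(ai, bi)
            result = (gv, gs)
            if bi - ai <= span and minsz <= cand[bi] - cand[ai] <= maxsz:
                d = naive_delta(A, n, int(cand[ai]), int(cand[bi]),
                                maximal(gs), penalty)
                if d > 0:
                    result = (gv + d, gs | {(int(cand[ai]), int(cand[bi]))})
            memo_t[key] = result
        return memo_t[key]

    return t(0, M - 1)
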