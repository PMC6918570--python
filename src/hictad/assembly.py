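"""Optimal nested TAD assembly by dynamic programming over candidate junctions.

Given a distance-centered contact matrix and a set of candidate boundary
junctions, the assembler finds the forest of domains (any two domains are
disjoint — possibly sharing one junction — or strictly nested) that
maximizes a recursive score.  For a diagonal block between junctions
``a < b``:

* ``g(a, b)`` — best total score of domains strictly inside the block,
  obtained by scanning partition points over the candidate junctions;
* ``delta(a, b | subTADs)`` — the block's own margin: its de-convoluted
  mean (entries of called inner domains removed) minus the larger of the
  two flanking off-diagonal block means of the same side length, minus the
  penalty ``lambda``;
* ``h(a, b) = g(a, b) + delta`` — score with the block itself called;
* ``t(a, b) = max(g, h)`` — best of calling or not calling it.

A block is emitted as a domain exactly when its ``delta`` is positive and
its ``h`` was selected by the traceback.  Negative partial scores are
clamped at zero, so barren regions contribute nothing.  Domains may only
form between junctions no more than ``max_neighbor_span`` candidates apart
and within the size limits; partition points in ``g`` are unrestricted, so
large outer domains remain reachable through their children.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Tuple

import numpy as np

from .boundaries import CandidateBoundarySet, integral_tables, rect_sum
from .matrix import ContactMap

__all__ = [
    "AssemblyParams",
    "TAD",
    "TADForest",
    "deconvoluted_mean",
    "delta_score",
    "assemble",
    "assign_tad_levels",
    "assign_boundary_levels",
]

NEG_INF = float("-inf")
_TIE_EPS = 1e-12


@dataclasses.dataclass
class AssemblyParams:
    """Assembly knobs with the shipped defaults.

    ``penalty`` is the margin lambda by which a domain's de-convoluted
    mean must exceed both flank means; ``minsz``/``maxsz`` bound the
    domain size in bins (200 bins = 2 Mb at 10 kb resolution);
    ``max_neighbor_span`` limits how many candidate junctions apart a
    domain's two ends may be; ``max_level_cap`` pools deeper nesting
    levels in reports.
    """

    penalty: float = 0.1
    minsz: int = 3
    maxsz: int = 200
    max_neighbor_span: int = 5
    max_level_cap: int = 5

    def __post_init__(self) -> None:
        if self.penalty < 0:
            raise ValueError("penalty must be nonnegative")
        if not (3 <= self.minsz <= self.maxsz):
            raise ValueError("need 3 <= minsz <= maxsz")
        if self.max_neighbor_span < 1:
            raise ValueError("max_neighbor_span must be >= 1")


@dataclasses.dataclass
class TAD:
    """A called domain covering bins ``left .. right-1`` (junction pair)."""

    left: int
    right: int
    score: float
    mean: float
    level: int = 0
    singleton: bool = False
    children: List["TAD"] = dataclasses.field(default_factory=list)

    @property
    def size(self) -> int:
        return self.right - self.left

    def __repr__(self) -> str:  # compact, children elided
        return (f"TAD({self.left},{self.right},score={self.score:.4g},"
                f"level={self.level})")


@dataclasses.dataclass
class TADForest:
    """All called domains (flattened) plus the top-level roots."""

    tads: List[TAD]
    roots: List[TAD]
    n_bins: int
    total_score: float = 0.0
    #: partition/pair visits during assembly, for complexity accounting
    work: int = 0

    def __len__(self) -> int:
        return len(self.tads)

    def boundaries(self) -> np.ndarray:
        """Sorted unique junctions used by any called domain."""
        js = {t.left for t in self.tads} | {t.right for t in self.tads}
        return np.array(sorted(js), dtype=int)


# ----------------------------------------------------------------------
# scoring primitives
# ----------------------------------------------------------------------

def _block_stats(S, C, a: int, b: int, subtads) -> Tuple[float, float]:
    """Sum and count of the diagonal block [a,b)^2 minus child blocks."""
    s = rect_sum(S, a, b, a, b)
    c = rect_sum(C, a, b, a, b)
    for t in subtads:
        l, r = (t.left, t.right) if isinstance(t, TAD) else t
        if l < a or r > b:
            raise ValueError("subTAD extends outside the parent block")
        s -= rect_sum(S, l, r, l, r)
        c -= rect_sum(C, l, r, l, r)
    return s, c


def deconvoluted_mean(cmap: ContactMap, a: int, b: int, subtads=()) -> float:
    """Mean of block [a,b)^2 excluding entries inside any subTAD block.

    Returns NaN when no unmasked entries remain (e.g. subTADs tile the
    whole block).
    """
    A = cmap.nan_values()
    S, C = integral_tables(A)
    s, c = _block_stats(S, C, a, b, subtads)
    return s / c if c > 0 else float("nan")


def delta_score(cmap: ContactMap, a: int, b: int, subtads=(),
                penalty: float = 0.1, minsz: int = 3, maxsz: int = 200) -> float:
    """Margin score of block (a, b) given its called subTADs.

    ``deconvoluted_mean - max(flank means) - penalty``; flanks are the two
    off-diagonal blocks of the same side length immediately up/downstream,
    truncated at the matrix edges.  A fully truncated flank is dropped; if
    both flanks are empty or the de-convoluted mean is undefined the block
    can never be a domain (-inf).
    """
    if not (minsz <= b - a <= maxsz):
        raise ValueError("block size outside [minsz, maxsz]")
    A = cmap.nan_values()
    S, C = integral_tables(A)
    return _delta_from_tables(S, C, cmap.n_bins, a, b, subtads, penalty)


def _delta_from_tables(S, C, n: int, a: int, b: int, subtads, penalty: float) -> float:
    s, c = _block_stats(S, C, a, b, subtads)
    if c <= 0:
        return NEG_INF
    m = s / c
    sz = b - a
    flanks = []
    r0 = max(0, a - sz)
    if r0 < a:
        cnt = rect_sum(C, r0, a, a, b)
        if cnt > 0:
            flanks.append(rect_sum(S, r0, a, a, b) / cnt)
    c1 = min(n, b + sz)
    if c1 > b:
        cnt = rect_sum(C, a, b, b, c1)
        if cnt > 0:
            flanks.append(rect_sum(S, a, b, b, c1) / cnt)
    if not flanks:
        return NEG_INF
    return m - max(flanks) - penalty


# ----------------------------------------------------------------------
# the dynamic program
# ----------------------------------------------------------------------

@dataclasses.dataclass
class _PairRecord:
    g: float
    delta: float
    h: float
    mean: float
    callable: bool
    children: List[Tuple[int, int]]  # candidate-index pairs of direct children


def assemble(cmap: ContactMap, candidates: CandidateBoundarySet,
             params: Optional[AssemblyParams] = None) -> TADForest:
    """Build the optimal nested domain forest over the candidate junctions.

    The matrix should be distance-centered (the flank comparison is only
    distance-fair after removing the decay trend).  Traceback emits exactly
    the domains whose ``h`` was selected with a positive margin; levels and
    singleton flags are assigned before returning.
    """
    if params is None:
        params = AssemblyParams()
    n = cmap.n_bins
    cand = np.asarray(candidates.positions, dtype=int)
    forest = TADForest(tads=[], roots=[], n_bins=n)
    if cand.size < 2:
        return assign_tad_levels(forest, params.max_level_cap)
    A = cmap.nan_values()
    S, C = integral_tables(A)
    M = cand.size
    span = params.max_neighbor_span
    work = 0

    records: Dict[Tuple[int, int], _PairRecord] = {}

    def local_dp(lo: int, hi: int, exclude_self: bool):
        """Prefix DP for the best forest over candidate indices lo..hi.

        Returns (score, choice) where choice[j] is None (skip) or the
        start index k of a called domain (k, j).  Only previously scored
        callable pairs participate; the pair (lo, hi) itself is excluded
        when scoring its own interior.
        """
        nonlocal work
        G = {lo: 0.0}
        choice: Dict[int, Optional[int]] = {lo: None}
        for j in range(lo + 1, hi + 1):
            best = G[j - 1]
            pick: Optional[int] = None
            for k in range(max(lo, j - span), j):
                if exclude_self and k == lo and j == hi:
                    continue
                rec = records.get((k, j))
                work += 1
                if rec is None or not rec.callable:
                    continue
                v = G[k] + rec.h
                if v > best + _TIE_EPS:
                    # strict improvement; with ascending k the first (i.e.
                    # smallest-k, largest right-most) maximizer is kept
                    best = v
                    pick = k
                elif pick is None and v >= best - _TIE_EPS:
                    # ties against skipping are resolved in favor of calling
                    pick = k
            G[j] = best
            choice[j] = pick
        return G, choice

    def traceback(choice, lo: int, hi: int) -> List[Tuple[int, int]]:
        out: List[Tuple[int, int]] = []
        j = hi
        while j > lo:
            k = choice[j]
            if k is None:
                j -= 1
            else:
                out.append((k, j))
                j = k
        out.reverse()
        return out

    # score pairs in order of increasing candidate-index span
    for s_idx in range(1, span + 1):
        for ai in range(0, M - s_idx):
            bi = ai + s_idx
            a, b = int(cand[ai]), int(cand[bi])
            if not (params.minsz <= b - a <= params.maxsz):
                continue
            G, choice = local_dp(ai, bi, exclude_self=True)
            g = G[bi]
            kids_idx = traceback(choice, ai, bi)
            kids = [(int(cand[k]), int(cand[j])) for k, j in kids_idx]
            delta = _delta_from_tables(S, C, n, a, b, kids, params.penalty)
            m_s, m_c = _block_stats(S, C, a, b, kids)
            mean = m_s / m_c if m_c > 0 else float("nan")
            h = g + delta
            records[(ai, bi)] = _PairRecord(
                g=g, delta=delta, h=h, mean=mean,
                callable=bool(delta > 0), children=kids_idx,
            )

    # root pass over the whole junction range
    G, choice = local_dp(0, M - 1, exclude_self=False)
    top_idx = traceback(choice, 0, M - 1)

    def materialize(pair: Tuple[int, int]) -> TAD:
        rec = records[pair]
        kids = [materialize(p) for p in rec.children]
        return TAD(
            left=int(cand[pair[0]]), right=int(cand[pair[1]]),
            score=rec.h, mean=rec.mean, children=kids,
        )

    roots = [materialize(p) for p in top_idx]

    def flatten(ts: List[TAD], acc: List[TAD]):
        for t in ts:
            acc.append(t)
            flatten(t.children, acc)

    flat: List[TAD] = []
    flatten(roots, flat)
    forest = TADForest(tads=flat, roots=roots, n_bins=n,
                       total_score=G[M - 1], work=work)
    return assign_tad_levels(forest, params.max_level_cap)


# ----------------------------------------------------------------------
# level assignment
# ----------------------------------------------------------------------

def assign_tad_levels(forest: TADForest, cap: int = 5) -> TADForest:
    """Levels count outermost-in: 1 + number of called ancestors, capped.

    A domain with neither ancestors nor descendants is a singleton (level
    1); everything participating in a hierarchy is flagged hierarchical.
    """

    def walk(t: TAD, depth: int):
        t.level = min(depth, cap)
        t.singleton = depth == 1 and not t.children
        for ch in t.children:
            walk(ch, depth + 1)

    for r in forest.roots:
        walk(r, 1)
    return forest


def assign_boundary_levels(forest: TADForest, cap: int = 5) -> Dict[int, Tuple[int, bool]]:
    """Per-junction boundary level and hub flag.

    The level of a junction is the larger of the number of domains ending
    on its left side and starting on its right side, capped; junctions
    used by ``cap`` or more domains on one side are hub-boundaries.
    """
    ends: Dict[int, int] = {}
    starts: Dict[int, int] = {}
    for t in forest.tads:
        starts[t.left] = starts.get(t.left, 0) + 1
        ends[t.right] = ends.get(t.right, 0) + 1
    out: Dict[int, Tuple[int, bool]] = {}
    for j in set(ends) | set(starts):
        raw = max(ends.get(j, 0), starts.get(j, 0))
        out[j] = (min(raw, cap), raw >= cap)
    return out
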