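"""Evaluation statistics for domain calls.

* ``tad_adj_r2`` — proportion of contact-frequency variance at a fixed
  genomic distance explained by the domain/gap classification, penalized
  for the number of domains (an adjusted R^2).
* ``boundary_jaccard`` / ``tad_rand_index`` — reproducibility of boundary
  sets and of the bin partition induced by the innermost covering domain.
* ``mean_signal_profile`` — average of a per-bin track (e.g. CTCF or
  cohesin ChIP-seq signal) around boundaries.
* ``state_enrichment`` — pseudocounted fold-enrichment of a genome-state
  label (e.g. an IDEAS epigenetic state) inside a set of regions.
* ``corner_quadrant_diagnostic`` — contact means in the four q x q
  quadrants around each domain corner, a check of the disjoint-or-nested
  assumption.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .assembly import TAD, TADForest
from .matrix import ContactMap

__all__ = [
    "AdjR2Profile",
    "StateAnnotation",
    "tad_adj_r2",
    "adj_r2_profile",
    "boundary_jaccard",
    "tad_rand_index",
    "mean_signal_profile",
    "state_enrichment",
    "corner_quadrant_diagnostic",
]


# ----------------------------------------------------------------------
# TAD-adjusted R^2
# ----------------------------------------------------------------------

def innermost_labels(forest: TADForest, n_bins: int) -> np.ndarray:
    """Label each bin by the index of the innermost covering domain (-1 = gap)."""
    labels = np.full(n_bins, -1, dtype=int)
    # sorted outer-to-inner so inner assignments overwrite outer ones
    order = sorted(range(len(forest.tads)),
                   key=lambda i: -(forest.tads[i].size))
    for idx in order:
        t = forest.tads[idx]
        labels[t.left:t.right] = idx
    return labels


def _pair_groups(forest: TADForest, n_bins: int, k: int) -> np.ndarray:
    """Group id for each bin-pair (i, i+k): innermost domain containing both
    endpoints, or -1 for the gap pool."""
    n_pairs = n_bins - k
    groups = np.full(n_pairs, -1, dtype=int)
    order = sorted(range(len(forest.tads)),
                   key=lambda i: -(forest.tads[i].size))
    for idx in order:
        t = forest.tads[idx]
        lo, hi = t.left, t.right - k  # i in [lo, hi) keeps i+k <= right-1
        if hi > lo:
            groups[lo:hi] = idx
    return groups


def tad_adj_r2(cmap: ContactMap, forest: TADForest, k: int) -> float:
    """Adjusted R^2 of the domain classification at genomic distance ``k``.

    Each pair ``(i, i+k)`` is predicted by the mean of its group — the
    innermost domain containing both endpoints (pairs covered by a deeper
    domain belong to that deeper domain) or the gap pool.  ``n`` is the
    number of pairs at distance ``k`` and ``p`` the number of domains of
    size >= ``k``.  Returns NaN when ``n - p - 1 <= 0``.
    """
    if k < 1:
        raise ValueError("distance k must be >= 1")
    n_bins = cmap.n_bins
    if k >= n_bins:
        return float("nan")
    A = cmap.nan_values()
    i = np.arange(n_bins - k)
    Y = A[i, i + k]
    finite = np.isfinite(Y)
    Y = Y[finite]
    groups = _pair_groups(forest, n_bins, k)[finite]
    n = Y.size
    p = sum(1 for t in forest.tads if t.size >= k)
    if n - p - 1 <= 0 or n < 2:
        return float("nan")
    ybar = Y.mean()
    yhat = np.empty_like(Y)
    for gid in np.unique(groups):
        sel = groups == gid
        yhat[sel] = Y[sel].mean()
    sse = float(np.sum((Y - yhat) ** 2))
    sst = float(np.sum((Y - ybar) ** 2))
    if sst == 0:
        return float("nan")
    return 1.0 - (sse / (n - p - 1)) / (sst / (n - 1))


@dataclasses.dataclass
class AdjR2Profile:
    """Per-distance adjusted R^2 values plus a pair-count-weighted average."""

    distances: np.ndarray
    n_pairs: np.ndarray
    n_tads: np.ndarray
    r2: np.ndarray
    weighted_average: float


def adj_r2_profile(cmap: ContactMap, forest: TADForest,
                   distances: Iterable[int]) -> AdjR2Profile:
    """Evaluate ``tad_adj_r2`` over a distance range; the summary average
    is weighted by the number of pairs at each distance."""
    ks = np.array(sorted(distances), dtype=int)
    n_bins = cmap.n_bins
    r2 = np.array([tad_adj_r2(cmap, forest, int(k)) for k in ks])
    n_pairs = np.array([max(n_bins - k, 0) for k in ks], dtype=float)
    n_tads = np.array([sum(1 for t in forest.tads if t.size >= k) for k in ks])
    ok = np.isfinite(r2)
    wavg = float(np.average(r2[ok], weights=n_pairs[ok])) if ok.any() else float("nan")
    return AdjR2Profile(ks, n_pairs, n_tads, r2, wavg)


# ----------------------------------------------------------------------
# reproducibility metrics
# ----------------------------------------------------------------------

def boundary_jaccard(a: Iterable[int], b: Iterable[int], tol: int = 0) -> float:
    """Jaccard index of two boundary sets.

    With ``tol = 0`` this is the exact set Jaccard; with ``tol > 0`` the
    intersection size is a greedy one-to-one matching of boundaries within
    ``tol`` bins.  Two empty sets score 1 by convention.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    A = sorted(set(int(x) for x in a))
    B = sorted(set(int(x) for x in b))
    if not A and not B:
        return 1.0
    if tol == 0:
        inter = len(set(A) & set(B))
    else:
        used = np.zeros(len(B), dtype=bool)
        inter = 0
        for x in A:
            best_j, best_d = -1, tol + 1
            for j, y in enumerate(B):
                if used[j]:
                    continue
                d = abs(x - y)
                if d < best_d:
                    best_j, best_d = j, d
            if best_j >= 0 and best_d <= tol:
                used[best_j] = True
                inter += 1
    union = len(A) + len(B) - inter
    return inter / union if union else 1.0


def tad_rand_index(a: TADForest, b: TADForest, n_bins: int,
                   gap_as_cluster: bool = False) -> float:
    """Adjusted Rand index of the bin partitions induced by two forests.

    Bins are labeled by their innermost covering domain.  By default bins
    uncovered in either forest are dropped from the pair counts; with
    ``gap_as_cluster`` the uncovered bins form one extra cluster each.
    Returns NaN when no bins remain.
    """
    la = innermost_labels(a, n_bins)
    lb = innermost_labels(b, n_bins)
    if gap_as_cluster:
        keep = np.ones(n_bins, dtype=bool)
    else:
        keep = (la >= 0) & (lb >= 0)
    if not keep.any():
        return float("nan")
    return float(adjusted_rand_score(la[keep], lb[keep]))


def rescale_boundaries(positions: Iterable[int], factor: int) -> List[int]:
    """Map junctions to a coarser binning by floor division (for
    cross-resolution comparisons)."""
    return sorted({int(p) // factor for p in positions})


# ----------------------------------------------------------------------
# signal and annotation enrichment
# ----------------------------------------------------------------------

def mean_signal_profile(signal: np.ndarray, boundaries: Iterable[int],
                        flank: int = 10) -> np.ndarray:
    """Position-wise mean of a per-bin track around boundaries.

    Offsets run ``-flank .. +flank``; boundaries near the track ends
    contribute only their in-range offsets.  NaN where no boundary covers
    an offset.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    bs = [int(b) for b in boundaries]
    if not bs:
        raise ValueError("empty boundary set")
    signal = np.asarray(signal, dtype=float)
    n = signal.size
    sums = np.zeros(2 * flank + 1)
    counts = np.zeros(2 * flank + 1)
    for b in bs:
        for off in range(-flank, flank + 1):
            pos = b + off
            if 0 <= pos < n and np.isfinite(signal[pos]):
                sums[off + flank] += signal[pos]
                counts[off + flank] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / counts, np.nan)


@dataclasses.dataclass
class StateAnnotation:
    """Genome tiling with a state label per window.

    ``starts``/``ends`` are window coordinates in bp, ``states`` the label
    per window; ``background`` maps each state to its genome-wide
    proportion ``B_s`` (computed from the windows when omitted).
    """

    starts: np.ndarray
    ends: np.ndarray
    states: np.ndarray
    background: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=int)
        self.ends = np.asarray(self.ends, dtype=int)
        self.states = np.asarray(self.states, dtype=object)
        if self.background is None:
            labels, counts = np.unique(self.states, return_counts=True)
            total = counts.sum()
            self.background = {str(s): c / total for s, c in zip(labels, counts)}

    def proportion(self, state: str) -> float:
        if state not in self.background:
            raise KeyError(f"unknown state label {state!r}")
        return self.background[state]


def state_enrichment(annotation: StateAnnotation,
                     regions: Sequence[Tuple[int, int]], state: str) -> float:
    """Pseudocounted enrichment of one state over a region set.

    ``(sum_i n_{s,i} + 1) / (B_s * sum_i n_i + 1)`` where ``n_i`` counts
    annotated windows in region ``i`` and ``n_{s,i}`` those labeled with
    the state; the added 1's guard against empty regions.  A window
    belongs to a region when its midpoint falls inside.
    """
    B_s = annotation.proportion(state)
    mids = (annotation.starts + annotation.ends) / 2.0
    total = 0
    total_s = 0
    for lo, hi in regions:
        inside = (mids >= lo) & (mids < hi)
        total += int(inside.sum())
        total_s += int((inside & (annotation.states == state)).sum())
    return (total_s + 1.0) / (B_s * total + 1.0)


# ----------------------------------------------------------------------
# hierarchy-assumption diagnostic
# ----------------------------------------------------------------------

@dataclasses.dataclass
class CornerDiagnostic:
    """Quadrant means around each domain corner.

    Quadrant 1 sits just inside the domain corner; 2 extends upstream of
    the left boundary, 3 downstream of the right boundary, 4 outside both.
    Under the disjoint-or-nested assumption quadrant 1 is high and at
    least one of 2/3 is low.
    """

    means: np.ndarray        # (n_tads, 4)
    counts: np.ndarray       # (n_tads, 4) entries per quadrant after truncation
    fraction_consistent: float


def corner_quadrant_diagnostic(cmap: ContactMap, forest: TADForest,
                               q: int = 5) -> CornerDiagnostic:
    """Mean contact in the four q x q quadrants at every domain corner."""
    if q < 1:
        raise ValueError("q must be >= 1")
    A = cmap.nan_values()
    n = cmap.n_bins
    means = np.full((len(forest.tads), 4), np.nan)
    counts = np.zeros((len(forest.tads), 4))
    for ti, t in enumerate(forest.tads):
        a, b = t.left, t.right
        quads = [
            (a, min(n, a + q), max(0, b - q), b),      # 1: inside corner
            (max(0, a - q), a, max(0, b - q), b),      # 2: upstream outside
            (a, min(n, a + q), b, min(n, b + q)),      # 3: downstream outside
            (max(0, a - q), a, b, min(n, b + q)),      # 4: outside both
        ]
        for qi, (r0, r1, c0, c1) in enumerate(quads):
            if r0 >= r1 or c0 >= c1:
                continue
            block = A[r0:r1, c0:c1]
            finite = np.isfinite(block)
            counts[ti, qi] = finite.sum()
            if finite.any():
                means[ti, qi] = block[finite].mean()
    with np.errstate(invalid="ignore"):
        q1, q2, q3 = means[:, 0], means[:, 1], means[:, 2]
        valid = np.isfinite(q1) & (np.isfinite(q2) | np.isfinite(q3))
        low = np.fmin(q2, q3)
        consistent = valid & (q1 > low)
    frac = float(consistent.sum() / valid.sum()) if valid.any() else float("nan")
    return CornerDiagnostic(means=means, counts=counts, fraction_consistent=frac)
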