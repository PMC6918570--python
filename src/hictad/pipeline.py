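"""High-level convenience: matrix -> boundaries -> assembled domain forest."""

from __future__ import annotations

from typing import Dict, Optional, Tuple

from .assembly import AssemblyParams, TADForest, assemble, assign_boundary_levels
from .boundaries import CandidateBoundarySet, DetectionParams, candidate_boundaries
from .matrix import ContactMap, distance_center, log2_transform

__all__ = ["call_tads"]


def call_tads(
    cmap: ContactMap,
    detection: Optional[DetectionParams] = None,
    params: Optional[AssemblyParams] = None,
    center: bool = True,
    log2: bool = True,
) -> Tuple[TADForest, Dict[int, Tuple[int, bool]], CandidateBoundarySet]:
    """Run the full calling pipeline on one chromosome.

    log2(1+x)-transforms the counts (the default: the penalty margin is a
    log-scale quantity — 0.1 corresponds to a ~7% fold-change — and on the
    raw count scale it would be dwarfed by sampling noise), distance-centers
    the matrix, detects candidate boundaries at all window sizes and
    assembles the optimal nested forest.  Returns the forest, the
    per-junction boundary levels and the candidate set.  Matrices that are
    already distance-centered are used as-is.
    """
    if params is None:
        params = AssemblyParams()
    if detection is None:
        detection = DetectionParams(K=min(params.maxsz, cmap.n_bins))
    work = cmap
    if log2 and work.norm_state != "distance_centered":
        work = log2_transform(work)
    if center and work.norm_state != "distance_centered":
        work = distance_center(work)
    cands = candidate_boundaries(work, detection)
    forest = assemble(work, cands, params)
    levels = assign_boundary_levels(forest, params.max_level_cap)
    return forest, levels, cands
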