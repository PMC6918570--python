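"""Writers and readers for domain calls: TSV, bedgraph and boundary BED.

Bin coordinates are 0-based; genomic coordinates are 0-based half-open
(bin ``b`` spans ``[b*resolution, (b+1)*resolution)``), the BED/bedgraph
convention.
"""

from __future__ import annotations

from typing import Dict, Tuple

import pandas as pd

from .assembly import TAD, TADForest
from .matrix import ContactMap

__all__ = [
    "forest_to_dataframe",
    "write_tad_table",
    "read_tad_table",
    "write_bedgraph",
    "write_boundary_bed",
    "write_calibration_report",
]

TAD_COLUMNS = [
    "start_bin", "end_bin", "level", "deconvoluted_mean", "score",
    "is_singleton", "chrom", "start_bp", "end_bp",
]


def forest_to_dataframe(forest: TADForest, cmap: ContactMap) -> pd.DataFrame:
    rows = []
    for t in sorted(forest.tads, key=lambda t: (t.left, -(t.size))):
        rows.append({
            "start_bin": t.left,
            "end_bin": t.right,
            "level": t.level,
            "deconvoluted_mean": t.mean,
            "score": t.score,
            "is_singleton": int(t.singleton),
            "chrom": cmap.chrom,
            "start_bp": cmap.bin_to_bp(t.left),
            "end_bp": cmap.bin_to_bp(t.right),
        })
    return pd.DataFrame(rows, columns=TAD_COLUMNS)


def write_tad_table(forest: TADForest, cmap: ContactMap, path) -> None:
    forest_to_dataframe(forest, cmap).to_csv(path, sep="\t", index=False,
                                             float_format="%.6g")


def read_tad_table(path) -> TADForest:
    """Rebuild a (flat-parentage) forest from a call table.

    Nesting links are reconstructed from containment, which is exact under
    the disjoint-or-nested output invariant.
    """
    df = pd.read_csv(path, sep="\t")
    tads = [
        TAD(left=int(r.start_bin), right=int(r.end_bin), score=float(r.score),
            mean=float(r.deconvoluted_mean), level=int(r.level),
            singleton=bool(r.is_singleton))
        for r in df.itertuples()
    ]
    # outer-to-inner: attach each domain to the smallest strict container
    order = sorted(range(len(tads)), key=lambda i: -tads[i].size)
    roots = []
    for rank, i in enumerate(order):
        parent = None
        for j in order[:rank][::-1]:  # smallest containers tried first
            if tads[j].left <= tads[i].left and tads[i].right <= tads[j].right \
                    and tads[j].size > tads[i].size:
                if parent is None or tads[j].size < parent.size:
                    parent = tads[j]
        if parent is None:
            roots.append(tads[i])
        else:
            parent.children.append(tads[i])
    n_bins = max((t.right for t in tads), default=0)
    return TADForest(tads=tads, roots=roots, n_bins=n_bins)


def write_bedgraph(forest: TADForest, cmap: ContactMap, path) -> None:
    """One interval per domain, value = level, outer-to-inner order."""
    with open(path, "w") as fh:
        for t in sorted(forest.tads, key=lambda t: (t.level, t.left)):
            fh.write(f"{cmap.chrom}\t{cmap.bin_to_bp(t.left)}\t"
                     f"{cmap.bin_to_bp(t.right)}\t{t.level}\n")


def write_boundary_bed(levels: Dict[int, Tuple[int, bool]], cmap: ContactMap,
                       path) -> None:
    """Boundary junctions with their boundary level in the score column."""
    with open(path, "w") as fh:
        for j in sorted(levels):
            lvl, hub = levels[j]
            name = "hub_boundary" if hub else "boundary"
            fh.write(f"{cmap.chrom}\t{cmap.bin_to_bp(j)}\t"
                     f"{cmap.bin_to_bp(j) + 1}\t{name}\t{lvl}\n")


def write_calibration_report(result, path) -> None:
    """TSV mirroring the calibration sweep: value, #real, #null, FDR."""
    with open(path, "w") as fh:
        fh.write(f"{result.swept}\tn_real_tads\tn_null_tads\tfdr\n")
        for val in result.fdr:
            fh.write(f"{val}\t{result.n_real[val]}\t{result.n_null[val]}\t"
                     f"{result.fdr[val]:.6g}\n")
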