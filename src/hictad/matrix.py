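"""Contact-matrix container, I/O, distance centering and the permutation null.

A per-chromosome Hi-C contact matrix is held as a dense symmetric array
together with a per-bin mask of unmappable bins.  Three on-disk formats are
supported: whitespace-delimited dense text, 3-column (or 5-column) sparse
text, and a minimal single-resolution ``.cool`` HDF5 container.

The two transformations that matter downstream are

* :func:`distance_center` — subtract the mean contact at each genomic
  distance, removing the distance-decay trend so that block enrichment can
  be compared across distances, and
* :func:`permute_within_distance` — shuffle entries within each diagonal to
  build a null matrix with the same per-distance marginal distribution but
  no domain structure.
"""

from __future__ import annotations

import dataclasses
import pathlib
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ContactMap",
    "load_contact_map",
    "save_contact_map",
    "distance_center",
    "permute_within_distance",
    "log2_transform",
]

NORM_STATES = ("raw", "balanced", "distance_centered")

#: relative tolerance for the symmetry check
SYMMETRY_RTOL = 1e-9

PathLike = Union[str, pathlib.Path]


@dataclasses.dataclass
class ContactMap:
    """Square symmetric per-chromosome binned contact matrix.

    Parameters
    ----------
    values
        ``n_bins x n_bins`` symmetric matrix; entry ``(i, j)`` is the
        contact strength between bins ``i`` and ``j``.
    resolution
        Bin width in base pairs.
    chrom
        Chromosome label used in genomic-coordinate output.
    mask
        Boolean per-bin flag; ``True`` marks an unmappable bin whose
        entries are excluded (treated as missing) from every mean,
        standard deviation and permutation pool downstream.
    norm_state
        One of ``raw``, ``balanced`` or ``distance_centered``.  Entries
        must be nonnegative unless distance-centered.
    """

    values: np.ndarray
    resolution: int
    chrom: str = "chr0"
    mask: Optional[np.ndarray] = None
    norm_state: str = "raw"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"contact matrix must be square, got shape {v.shape}")
        if self.resolution <= 0:
            raise ValueError("resolution must be a positive integer")
        if self.norm_state not in NORM_STATES:
            raise ValueError(f"unknown norm_state {self.norm_state!r}")
        self.values = v
        if self.mask is None:
            self.mask = np.zeros(v.shape[0], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (v.shape[0],):
                raise ValueError("mask must be a per-bin boolean vector")
        _check_symmetry(v)
        if self.norm_state != "distance_centered":
            finite = np.isfinite(v)
            if np.any(v[finite] < 0):
                raise ValueError(
                    "negative entries in a raw/balanced contact matrix; "
                    "distance-centered matrices are the only signed state"
                )

    # ------------------------------------------------------------------
    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def nan_values(self) -> np.ndarray:
        """Copy of the matrix with masked bins (rows and columns) set to NaN.

        Downstream statistics use NaN-aware means, so this is the canonical
        "missing entries excluded" view of the data.
        """
        out = self.values.astype(float).copy()
        out[self.mask, :] = np.nan
        out[:, self.mask] = np.nan
        return out

    def replace(self, **kw) -> "ContactMap":
        return dataclasses.replace(self, **kw)

    def bin_to_bp(self, b: int) -> int:
        """Genomic start coordinate (0-based) of bin/junction ``b``."""
        return int(b) * self.resolution


def _check_symmetry(v: np.ndarray) -> None:
    finite = np.isfinite(v) & np.isfinite(v.T)
    diff = np.abs(v - v.T)
    tol = SYMMETRY_RTOL * np.maximum(1.0, np.abs(v))
    if np.any(diff[finite] > tol[finite]):
        raise ValueError(
            "matrix is asymmetric beyond tolerance; pass symmetrize=True to "
            "average (i,j) and (j,i) on load"
        )


def _auto_mask(values: np.ndarray) -> np.ndarray:
    """Mask bins whose row is entirely zero or missing."""
    with np.errstate(invalid="ignore"):
        nonzero = np.isfinite(values) & (values != 0)
    return ~nonzero.any(axis=1)


# ----------------------------------------------------------------------
# loading / saving
# ----------------------------------------------------------------------

def load_contact_map(
    path: PathLike,
    format: str,
    resolution: int,
    chrom: str = "chr0",
    n_bins: Optional[int] = None,
    symmetrize: bool = False,
    norm_state: str = "raw",
) -> ContactMap:
    """Read a per-chromosome contact matrix.

    ``format`` is one of ``dense`` (whitespace-delimited square text),
    ``sparse3`` (``bin_i  bin_j  value`` rows, or the 5-column
    ``chrom start chrom start value`` dialect) or ``container`` (a
    single-resolution ``.cool`` HDF5 file).  All-zero rows/columns are
    auto-masked.
    """
    if format == "dense":
        values = np.atleast_2d(np.loadtxt(path, dtype=float))
    elif format == "sparse3":
        values = _read_sparse3(path, resolution, n_bins)
    elif format == "container":
        values, resolution = _read_cool(path, chrom, resolution)
    else:
        raise ValueError(f"unknown format {format!r}")

    if values.shape[0] != values.shape[1]:
        raise ValueError("dense input is not square")
    finite = np.isfinite(values)
    if np.any(values[finite] < 0) and norm_state != "distance_centered":
        raise ValueError("negative contact values in input")
    if symmetrize:
        values = 0.5 * (values + values.T)
    mask = _auto_mask(values)
    return ContactMap(values, resolution, chrom=chrom, mask=mask, norm_state=norm_state)


def _read_sparse3(path: PathLike, resolution: int, n_bins: Optional[int]) -> np.ndarray:
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    # tolerate a single header line
    try:
        float(df.iloc[0, df.shape[1] - 1])
    except (ValueError, TypeError):
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] == 3:
        i = df[0].astype(int).to_numpy()
        j = df[1].astype(int).to_numpy()
        val = df[2].astype(float).to_numpy()
    elif df.shape[1] == 5:
        i = (df[1].astype(int) // resolution).to_numpy()
        j = (df[3].astype(int) // resolution).to_numpy()
        val = df[4].astype(float).to_numpy()
    else:
        raise ValueError("sparse input must have 3 or 5 columns")
    if len(i) == 0:
        raise ValueError("empty sparse matrix file")
    if np.any(i < 0) or np.any(j < 0):
        raise ValueError("negative bin index in sparse input")
    n = n_bins if n_bins is not None else int(max(i.max(), j.max())) + 1
    if np.any(i >= n) or np.any(j >= n):
        raise ValueError("bin index out of range for declared n_bins")
    values = np.zeros((n, n), dtype=float)
    values[i, j] = val
    values[j, i] = val
    return values


def save_contact_map(cmap: ContactMap, path: PathLike, format: str) -> None:
    """Write a contact map in any of the supported formats."""
    if format == "dense":
        np.savetxt(path, cmap.values, fmt="%.10g")
    elif format == "sparse3":
        iu, ju = np.triu_indices(cmap.n_bins)
        v = cmap.values[iu, ju]
        keep = v != 0
        pd.DataFrame({"bin1": iu[keep], "bin2": ju[keep], "value": v[keep]}).to_csv(
            path, sep="\t", header=False, index=False
        )
    elif format == "container":
        _write_cool(cmap, path)
    else:
        raise ValueError(f"unknown format {format!r}")


# ----------------------------------------------------------------------
# minimal single-resolution .cool support (HDF5 via h5py)
# ----------------------------------------------------------------------

def _write_cool(cmap: ContactMap, path: PathLike) -> None:
    n = cmap.n_bins
    iu, ju = np.triu_indices(n)
    v = cmap.values[iu, ju]
    keep = v != 0
    iu, ju, v = iu[keep], ju[keep], v[keep]
    order = np.lexsort((ju, iu))
    iu, ju, v = iu[order], ju[order], v[order]
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "HDF5::Cooler"
        f.attrs["bin-size"] = cmap.resolution
        f.attrs["nbins"] = n
        chroms = f.create_group("chroms")
        chroms.create_dataset("name", data=np.array([cmap.chrom], dtype="S32"))
        chroms.create_dataset("length", data=np.array([n * cmap.resolution], dtype=np.int64))
        bins = f.create_group("bins")
        bins.create_dataset("chrom", data=np.zeros(n, dtype=np.int32))
        bins.create_dataset("start", data=np.arange(n, dtype=np.int64) * cmap.resolution)
        bins.create_dataset("end", data=(np.arange(n, dtype=np.int64) + 1) * cmap.resolution)
        pixels = f.create_group("pixels")
        pixels.create_dataset("bin1_id", data=iu.astype(np.int64))
        pixels.create_dataset("bin2_id", data=ju.astype(np.int64))
        pixels.create_dataset("count", data=v.astype(float))
        indexes = f.create_group("indexes")
        indexes.create_dataset("chrom_offset", data=np.array([0, n], dtype=np.int64))
        bin1_offset = np.searchsorted(iu, np.arange(n + 1))
        indexes.create_dataset("bin1_offset", data=bin1_offset.astype(np.int64))


def _read_cool(path: PathLike, chrom: str, resolution: Optional[int]):
    with h5py.File(path, "r") as f:
        root = f
        if "pixels" not in f:
            # multi-resolution layout: resolutions/<res>/...
            if "resolutions" in f:
                if resolution is None:
                    raise ValueError("resolution required for multi-resolution container")
                key = f"resolutions/{resolution}"
                if key not in f:
                    raise ValueError(f"resolution {resolution} not in container")
                root = f[key]
            else:
                raise ValueError("not a recognizable binned-matrix container")
        res = int(root.attrs.get("bin-size", resolution or 0))
        names = [s.decode() if isinstance(s, bytes) else str(s) for s in root["chroms/name"][:]]
        if chrom not in names:
            raise ValueError(f"chromosome {chrom!r} not in container (has {names})")
        ci = names.index(chrom)
        bchrom = root["bins/chrom"][:]
        binsel = np.flatnonzero(bchrom == ci)
        lo, hi = int(binsel[0]), int(binsel[-1]) + 1
        n = hi - lo
        b1 = root["pixels/bin1_id"][:]
        b2 = root["pixels/bin2_id"][:]
        cnt = root["pixels/count"][:].astype(float)
        sel = (b1 >= lo) & (b1 < hi) & (b2 >= lo) & (b2 < hi)
        values = np.zeros((n, n), dtype=float)
        values[b1[sel] - lo, b2[sel] - lo] = cnt[sel]
        values[b2[sel] - lo, b1[sel] - lo] = cnt[sel]
        # inter-chromosomal pixels touching this chrom are rejected implicitly;
        # a container with no intra pixels for the chrom yields an all-zero map
    return values, res


# ----------------------------------------------------------------------
# transforms
# ----------------------------------------------------------------------

def distance_center(cmap: ContactMap) -> ContactMap:
    """Subtract the mean contact at each genomic distance.

    After centering, the mean over unmasked entries at every diagonal
    offset is exactly zero; masked entries are left untouched.
    """
    if cmap.norm_state == "distance_centered":
        raise ValueError("matrix is already distance-centered")
    n = cmap.n_bins
    A = cmap.nan_values()
    out = cmap.values.astype(float).copy()
    for k in range(n):
        d = np.diagonal(A, offset=k)
        valid = np.isfinite(d)
        if not valid.any():
            continue
        mu = d[valid].mean()
        r = np.flatnonzero(valid)
        c = r + k
        out[r, c] -= mu
        if k > 0:
            out[c, r] -= mu
    return cmap.replace(values=out, norm_state="distance_centered")


def log2_transform(cmap: ContactMap) -> ContactMap:
    """``log2(1 + x)`` transform for raw counts (apply before centering)."""
    if cmap.norm_state == "distance_centered":
        raise ValueError("log transform must precede distance centering")
    return cmap.replace(values=np.log2(1.0 + cmap.values))


def permute_within_distance(cmap: ContactMap, seed: int) -> ContactMap:
    """Shuffle unmasked entries within each diagonal; symmetric output.

    The per-distance multiset of entries is preserved exactly, destroying
    domain structure while keeping the marginal signal distribution — the
    permutation null used for penalty calibration.
    """
    rng = np.random.default_rng(seed)
    n = cmap.n_bins
    A = cmap.nan_values()
    out = cmap.values.astype(float).copy()
    for k in range(n):
        d = np.diagonal(A, offset=k)
        valid = np.flatnonzero(np.isfinite(d))
        if valid.size < 2:
            continue
        vals = d[valid]
        perm = rng.permutation(vals)
        r = valid
        c = valid + k
        out[r, c] = perm
        if k > 0:
            out[c, r] = perm
    return cmap.replace(values=out)
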