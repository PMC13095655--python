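"""Minimal single-resolution cooler (.cool) reader/writer built on h5py.

Implements the subset of the cooler HDF5 schema needed here: the
``chroms``, ``bins``, ``pixels`` and ``indexes`` tables of a
single-resolution file, upper-triangle pixel storage, and optional
balancing weights in ``bins/weight``.  Multi-resolution ``.mcool`` files
are supported by addressing a group path of the form
``path.mcool::/resolutions/10000``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

__all__ = ["write_cool", "CoolReader", "split_cool_uri"]


def split_cool_uri(uri: str) -> tuple[str, str]:
    """Split ``file.mcool::/resolutions/10000`` into (path, group)."""
    if "::" in uri:
        path, grp = uri.split("::", 1)
        return path, grp or "/"
    return uri, "/"


def write_cool(
    path: str | Path,
    chrom_sizes: dict[str, int],
    resolution: int,
    pixels: np.ndarray,
    weights: np.ndarray | None = None,
    group: str = "/",
) -> None:
    """Write a single-resolution cooler file.

    Parameters
    ----------
    pixels:
        Array of shape (n, 3): columns ``bin1_id, bin2_id, count`` with
        ``bin1_id <= bin2_id`` (upper triangle), bin ids global over the
        genome-wide bin table.
    weights:
        Optional per-bin balancing weights (NaN for masked bins), stored
        as ``bins/weight``.
    """
    chrom_names = list(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chrom_names], dtype=np.int64)

    bin_chrom, bin_start, bin_end = [], [], []
    for ci, c in enumerate(chrom_names):
        starts = np.arange(0, lengths[ci], resolution, dtype=np.int64)
        ends = np.minimum(starts + resolution, lengths[ci])
        bin_chrom.append(np.full(len(starts), ci, dtype=np.int32))
        bin_start.append(starts)
        bin_end.append(ends)
    bin_chrom = np.concatenate(bin_chrom)
    bin_start = np.concatenate(bin_start)
    bin_end = np.concatenate(bin_end)
    n_bins = len(bin_chrom)

    px = np.asarray(pixels)
    if px.size == 0:
        px = np.zeros((0, 3))
    b1 = px[:, 0].astype(np.int64)
    b2 = px[:, 1].astype(np.int64)
    cnt = px[:, 2].astype(np.float64)
    if np.any(b1 > b2):
        raise ValueError("pixels must be upper-triangle: bin1_id <= bin2_id")
    order = np.lexsort((b2, b1))
    b1, b2, cnt = b1[order], b2[order], cnt[order]

    bin1_offset = np.searchsorted(b1, np.arange(n_bins + 1), side="left")
    chrom_offset = np.searchsorted(bin_chrom, np.arange(len(chrom_names) + 1),
                                   side="left")

    with h5py.File(path, "a") as fh:
        grp = fh.require_group(group)
        for name in ("chroms", "bins", "pixels", "indexes"):
            if name in grp:
                del grp[name]
        grp.attrs["format"] = "HDF5::Cooler"
        grp.attrs["format-version"] = 3
        grp.attrs["bin-size"] = resolution
        grp.attrs["bin-type"] = "fixed"
        grp.attrs["nbins"] = n_bins
        grp.attrs["nchroms"] = len(chrom_names)
        grp.attrs["nnz"] = len(b1)
        g = grp.create_group("chroms")
        g.create_dataset("name", data=np.array(chrom_names, dtype="S32"))
        g.create_dataset("length", data=lengths)
        g = grp.create_group("bins")
        g.create_dataset("chrom", data=bin_chrom)
        g.create_dataset("start", data=bin_start)
        g.create_dataset("end", data=bin_end)
        if weights is not None:
            if len(weights) != n_bins:
                raise ValueError("weights length must equal the number of bins")
            g.create_dataset("weight", data=np.asarray(weights, dtype=np.float64))
        g = grp.create_group("pixels")
        g.create_dataset("bin1_id", data=b1)
        g.create_dataset("bin2_id", data=b2)
        g.create_dataset("count", data=cnt)
        g = grp.create_group("indexes")
        g.create_dataset("bin1_offset", data=bin1_offset)
        g.create_dataset("chrom_offset", data=chrom_offset)


class CoolReader:
    """Random access to a (single group of a) cooler file."""

    def __init__(self, uri: str | Path):
        path, group = split_cool_uri(str(uri))
        self._fh = h5py.File(path, "r")
        self._grp = self._fh[group]
        self.resolution = int(self._grp.attrs["bin-size"])
        names = self._grp["chroms/name"][:]
        self.chrom_names = [n.decode() if isinstance(n, bytes) else str(n)
                            for n in names]
        self.chrom_lengths = dict(zip(self.chrom_names,
                                      self._grp["chroms/length"][:].tolist()))
        self._chrom_offset = self._grp["indexes/chrom_offset"][:]
        self.has_weights = "weight" in self._grp["bins"]

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "CoolReader":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def _bin_range(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        ci = self.chrom_names.index(chrom)
        c0 = int(self._chrom_offset[ci])
        lo = c0 + start // self.resolution
        hi = c0 + (end + self.resolution - 1) // self.resolution
        return lo, min(hi, int(self._chrom_offset[ci + 1]))

    def fetch_dense(self, chrom: str, start: int, end: int,
                    balance: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(matrix, masked)`` for a region.

        ``matrix`` is the dense symmetric submatrix (balanced when weights
        are present and ``balance`` is true); ``masked`` is a boolean vector
        marking bins whose balancing weight is NaN (no-coverage bins).
        """
        if chrom not in self.chrom_names:
            raise KeyError(f"chromosome {chrom!r} not in file "
                           f"(available: {', '.join(self.chrom_names)})")
        lo, hi = self._bin_range(chrom, start, end)
        n = hi - lo
        b1off = self._grp["indexes/bin1_offset"]
        p0, p1 = int(b1off[lo]), int(b1off[hi])
        b1 = self._grp["pixels/bin1_id"][p0:p1]
        b2 = self._grp["pixels/bin2_id"][p0:p1]
        cnt = self._grp["pixels/count"][p0:p1].astype(np.float64)
        keep = (b2 >= lo) & (b2 < hi)
        i = (b1[keep] - lo).astype(np.intp)
        j = (b2[keep] - lo).astype(np.intp)
        v = cnt[keep]
        mat = np.zeros((n, n))
        mat[i, j] = v
        mat[j, i] = v
        masked = np.zeros(n, dtype=bool)
        if self.has_weights and balance:
            w = self._grp["bins/weight"][lo:hi]
            masked = ~np.isfinite(w)
            ww = np.where(masked, 0.0, w)
            mat = mat * ww[:, None] * ww[None, :]
            mat[masked, :] = np.nan
            mat[:, masked] = np.nan
        return mat, masked
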