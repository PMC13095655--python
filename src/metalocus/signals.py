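"""Binning of an epigenetic signal track over a region and attachment to
the layout.

The statistic analyzed downstream is the log10-transformed per-bin
coverage (mean by default, sum for count-like tracks) of a signal such as
H3K27ac ChIP enrichment.  No peak calling takes place: raw coverage per
bin is the input.  Bases without data count as zero coverage; a
pseudocount (default +1 on the raw scale) handles log of zero; negative
values (possible in control-subtracted tracks) are clamped to zero and
counted.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pyBigWig

from .layout import GaudiLayout
from .regions import LocusRegion

__all__ = ["SignalTrack", "bin_signal", "bin_signal_intervals",
           "attach_signal", "write_signal_tsv", "write_bedgraph",
           "write_bigwig"]

DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class SignalTrack:
    """Per-bin raw coverage and its log10 value over a region.

    ``value = log10(raw + pseudocount)``.  ``missing`` flags bins that had
    no data at all (raw set to 0).  NaN entries in ``raw`` mark bins
    removed by a perturbation, not zero coverage.
    """

    region: LocusRegion
    raw: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    signal_name: str = "signal"
    missing: np.ndarray | None = None
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.shape != (self.region.n_bins,):
            raise ValueError("raw must have one entry per region bin")
        if np.nanmin(self.raw, initial=0.0) < 0:
            raise ValueError("raw coverage must be non-negative (clamp on read)")
        if self.missing is None:
            self.missing = np.zeros(self.region.n_bins, dtype=bool)

    @property
    def value(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.log10(self.raw + self.pseudocount)


def _read_bedgraph(path: str | Path, chrom: str) -> pd.DataFrame:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep=r"\s+", header=None, comment="#",
                         names=["chrom", "start", "end", "value"],
                         dtype={"chrom": str})
    df = df[~df["chrom"].isin(["track", "browser"])]
    avail = df["chrom"].unique()
    if chrom not in avail:
        raise KeyError(f"chromosome {chrom!r} absent from track "
                       f"(available: {', '.join(map(str, avail))})")
    sub = df[df["chrom"] == chrom].copy()
    sub[["start", "end"]] = sub[["start", "end"]].astype(int)
    sub["value"] = sub["value"].astype(float)
    return sub


def bin_signal_intervals(
    intervals: pd.DataFrame,
    region: LocusRegion,
    stat: str = "mean",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    signal_name: str = "signal",
) -> SignalTrack:
    """Bin an in-memory interval table (columns start/end/value, one chrom).

    ``mean``: base-weighted mean over the bin with uncovered bases as 0.
    ``sum``: total of value x covered bases.
    """
    if stat not in ("mean", "sum"):
        raise ValueError("stat must be 'mean' or 'sum'")
    n = region.n_bins
    res = region.resolution
    total = np.zeros(n)
    covered = np.zeros(n, dtype=bool)
    n_clamped = 0
    for s, e, v in intervals[["start", "end", "value"]].itertuples(index=False):
        s = max(int(s), region.start)
        e = min(int(e), region.end)
        if e <= s:
            continue
        if v < 0:
            n_clamped += 1
            v = 0.0
        b0 = (s - region.start) // res
        b1 = (e - 1 - region.start) // res
        for b in range(b0, b1 + 1):
            bs, be = region.bin_interval(b)
            ov = min(e, be) - max(s, bs)
            total[b] += v * ov
            covered[b] = True
    raw = total / res if stat == "mean" else total
    missing = ~covered
    if missing.any():
        warnings.warn(f"{int(missing.sum())} bins had no signal data "
                      "(treated as zero coverage)", stacklevel=2)
    return SignalTrack(region=region, raw=raw, pseudocount=pseudocount,
                       signal_name=signal_name, missing=missing,
                       n_clamped=n_clamped)


def _bin_signal_bigwig(path: str | Path, region: LocusRegion, stat: str,
                       pseudocount: float, signal_name: str) -> SignalTrack:
    bw = pyBigWig.open(str(path))
    try:
        chroms = bw.chroms()
        if region.chrom not in chroms:
            raise KeyError(f"chromosome {region.chrom!r} absent from track "
                           f"(available: {', '.join(chroms)})")
        clen = chroms[region.chrom]
        end = min(region.end, clen)
        vals = np.array(bw.values(region.chrom, region.start, end), dtype=float)
    finally:
        bw.close()
    if end < region.end:
        vals = np.concatenate([vals, np.full(region.end - end, np.nan)])
    has_data = np.isfinite(vals)
    n_clamped = int((vals[has_data] < 0).sum())
    vals = np.where(has_data, np.clip(vals, 0, None), 0.0)
    per_bin = vals.reshape(region.n_bins, region.resolution)
    raw = per_bin.mean(axis=1) if stat == "mean" else per_bin.sum(axis=1)
    missing = ~has_data.reshape(region.n_bins, region.resolution).any(axis=1)
    if missing.any():
        warnings.warn(f"{int(missing.sum())} bins had no signal data "
                      "(treated as zero coverage)", stacklevel=2)
    return SignalTrack(region=region, raw=raw, pseudocount=pseudocount,
                       signal_name=signal_name, missing=missing,
                       n_clamped=n_clamped)


def bin_signal(
    track_source: str | Path,
    region: LocusRegion,
    stat: str = "mean",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    signal_name: str | None = None,
) -> SignalTrack:
    """Bin a genome-wide signal file (bigWig or bedGraph[.gz]) over a region.

    Format is chosen by file extension (.bw/.bigwig vs .bedgraph/.bdg[.gz]).
    """
    if stat not in ("mean", "sum"):
        raise ValueError("stat must be 'mean' or 'sum'")
    path = str(track_source)
    name = signal_name or Path(path).stem
    low = path.lower()
    if low.endswith((".bw", ".bigwig")):
        return _bin_signal_bigwig(path, region, stat, pseudocount, name)
    if low.endswith((".bedgraph", ".bdg", ".bedgraph.gz", ".bdg.gz", ".gz")):
        ivals = _read_bedgraph(path, region.chrom)
        return bin_signal_intervals(ivals, region, stat=stat,
                                    pseudocount=pseudocount, signal_name=name)
    raise ValueError(f"unrecognized track format: {path}")


def attach_signal(layout: GaudiLayout, sig: SignalTrack,
                  expected_missing: int = 0) -> GaudiLayout:
    """Return a copy of the layout decorated with the track's log10 values.

    Values are keyed by bin index; region bins absent from the layout
    (masked bins) are dropped with a warning unless the caller declares
    them expected (``expected_missing``, e.g. deliberately deleted bins).
    """
    if sig.region.n_bins != (layout.region.n_bins if layout.region else len(sig.raw)):
        raise ValueError("signal track and layout cover different bin sets")
    dropped = sig.region.n_bins - layout.n
    if dropped > expected_missing:
        warnings.warn(f"{dropped} region bins are absent from the layout and "
                      "carry no polygon", stacklevel=2)
    values = sig.value[layout.bins]
    if not np.all(np.isfinite(values)):
        raise ValueError("signal undefined (NaN) on layout bins; deleted bins "
                         "must be excluded from the layout")
    return replace(layout, signal=values, signal_name=sig.signal_name)


# ---------------------------------------------------------------------------
# writers


def write_signal_tsv(sig: SignalTrack, path: str | Path) -> None:
    r = sig.region
    rows = [{"bin": i, "chrom": r.chrom, "start": r.bin_interval(i)[0],
             "end": r.bin_interval(i)[1], "raw": sig.raw[i],
             "value": sig.value[i]} for i in range(r.n_bins)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.10g")


def write_bedgraph(sig: SignalTrack, path: str | Path) -> None:
    """Write per-bin raw coverage as a bedGraph (one interval per bin)."""
    r = sig.region
    with open(path, "w") as fh:
        for i in range(r.n_bins):
            if np.isnan(sig.raw[i]):
                continue
            s, e = r.bin_interval(i)
            fh.write(f"{r.chrom}\t{s}\t{e}\t{sig.raw[i]:.10g}\n")


def write_bigwig(sig: SignalTrack, path: str | Path,
                 chrom_sizes: dict[str, int] | None = None) -> None:
    """Write per-bin raw coverage as a bigWig (fixed-step per bin)."""
    r = sig.region
    if chrom_sizes is None:
        chrom_sizes = {r.chrom: r.end}
    bw = pyBigWig.open(str(path), "w")
    try:
        bw.addHeader(sorted(chrom_sizes.items()))
        keep = ~np.isnan(sig.raw)
        starts = np.array(r.bin_starts())[keep]
        bw.addEntries([r.chrom] * int(keep.sum()),
                      [int(s) for s in starts],
                      ends=[int(s) + r.resolution for s in starts],
                      values=[float(v) for v in sig.raw[keep]])
    finally:
        bw.close()
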