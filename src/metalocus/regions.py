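"""TSS-centered analysis windows and the shared bin coordinate system.

Every downstream step (contact submatrix, layout, signal, statistics, the
deletion scan) operates on the bins of a :class:`LocusRegion`: a fixed-span
window centered on a gene's transcription start site, divided into
fixed-width bins.  Coordinates are 0-based half-open (BED convention)
throughout; bin ``i`` spans ``[start + i*resolution, start + (i+1)*resolution)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "LocusRegion",
    "TssRecord",
    "build_regions",
    "read_bed6_tss",
    "read_gtf_tss",
    "write_region_manifest",
    "read_region_manifest",
]


@dataclass(frozen=True)
class LocusRegion:
    """A binned genomic window anchored on a TSS.

    Attributes
    ----------
    chrom, start, end:
        Genomic span, 0-based half-open. ``end - start`` is always an exact
        multiple of ``resolution``.
    resolution:
        Bin width in bp.
    anchor_index:
        Index of the bin containing the anchor point (the TSS).
    gene_id:
        Optional label carried through all outputs.
    strand:
        Metadata only; window construction ignores it.
    truncated:
        True when the nominal window overran a chromosome edge and was cut.
    """

    chrom: str
    start: int
    end: int
    resolution: int
    anchor_index: int
    gene_id: str | None = None
    strand: str | None = None
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if (self.end - self.start) % self.resolution != 0:
            raise ValueError("region span must be a multiple of the resolution")
        if not (0 <= self.anchor_index < self.n_bins):
            raise ValueError(
                f"anchor_index {self.anchor_index} outside [0, {self.n_bins})"
            )

    @property
    def n_bins(self) -> int:
        return (self.end - self.start) // self.resolution

    def bin_interval(self, i: int) -> tuple[int, int]:
        """Genomic half-open interval of bin ``i``."""
        if not (0 <= i < self.n_bins):
            raise IndexError(f"bin {i} outside [0, {self.n_bins})")
        s = self.start + i * self.resolution
        return s, s + self.resolution

    def bin_of(self, pos: int) -> int:
        """Index of the bin containing genomic position ``pos``."""
        if not (self.start <= pos < self.end):
            raise ValueError(f"position {pos} outside region [{self.start}, {self.end})")
        return (pos - self.start) // self.resolution

    def bin_starts(self) -> list[int]:
        return [self.start + i * self.resolution for i in range(self.n_bins)]


@dataclass(frozen=True)
class TssRecord:
    gene_id: str
    chrom: str
    tss: int
    strand: str | None = None


def build_regions(
    tss_table: Iterable[TssRecord],
    flank: int = 2_000_000,
    resolution: int = 10_000,
    chrom_sizes: dict[str, int] | None = None,
) -> tuple[list[LocusRegion], list[dict]]:
    """Build one TSS-centered window per gene record.

    The region start is snapped to the resolution grid
    (``floor(TSS/resolution)*resolution - flank``) so the anchor is a whole
    bin; an untruncated region has ``2*flank/resolution + 1`` bins with the
    anchor in the middle.  Windows overrunning a chromosome edge are clipped
    to the grid-aligned chromosome extent and flagged.

    Returns ``(regions, rejected)`` where ``rejected`` lists skipped records
    with a ``reason`` entry (unknown chromosome, TSS out of range).
    """
    if flank % resolution != 0:
        raise ValueError("flank must be a multiple of the resolution")
    regions: list[LocusRegion] = []
    rejected: list[dict] = []
    for rec in tss_table:
        if chrom_sizes is not None and rec.chrom not in chrom_sizes:
            rejected.append({"gene_id": rec.gene_id, "chrom": rec.chrom,
                             "tss": rec.tss, "reason": "unknown chromosome"})
            continue
        size = chrom_sizes[rec.chrom] if chrom_sizes is not None else None
        if rec.tss < 0 or (size is not None and rec.tss >= size):
            rejected.append({"gene_id": rec.gene_id, "chrom": rec.chrom,
                             "tss": rec.tss, "reason": "TSS beyond chromosome length"})
            continue
        anchor_start = (rec.tss // resolution) * resolution
        start = anchor_start - flank
        end = anchor_start + resolution + flank
        truncated = False
        if start < 0:
            start = 0
            truncated = True
        if size is not None:
            chrom_end = (size // resolution) * resolution
            if chrom_end <= anchor_start:
                # anchor bin is the (partial) last bin; keep it whole
                chrom_end = anchor_start + resolution
            if end > chrom_end:
                end = chrom_end
                truncated = True
        regions.append(
            LocusRegion(
                chrom=rec.chrom,
                start=start,
                end=end,
                resolution=resolution,
                anchor_index=(anchor_start - start) // resolution,
                gene_id=rec.gene_id,
                strand=rec.strand,
                truncated=truncated,
            )
        )
    return regions, rejected


# ---------------------------------------------------------------------------
# readers / writers


def read_bed6_tss(path: str | Path) -> list[TssRecord]:
    """Read a BED6 table of TSS positions (one per gene).

    The TSS is the interval start for ``+``/unstranded records and
    ``end - 1`` for ``-`` records, following the BED convention of
    orienting features 5'→3'.
    """
    recs: list[TssRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else f"{chrom}:{start}"
            strand = f[5] if len(f) > 5 else None
            tss = end - 1 if strand == "-" else start
            recs.append(TssRecord(gene_id=name, chrom=chrom, tss=tss, strand=strand))
    return recs


def read_gtf_tss(path: str | Path, feature: str = "gene") -> list[TssRecord]:
    """Extract gene_id + TSS from a GTF file.

    GTF is 1-based inclusive; positions are converted to 0-based on read.
    The TSS is the 5' end of the feature according to its strand.
    """
    recs: list[TssRecord] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != feature:
                continue
            chrom, start1, end1, strand, attrs = f[0], int(f[3]), int(f[4]), f[6], f[8]
            gene_id = None
            for chunk in attrs.split(";"):
                chunk = chunk.strip()
                if chunk.startswith("gene_id"):
                    gene_id = chunk.split(None, 1)[1].strip().strip('"')
                    break
            if gene_id is None:
                continue
            tss = (end1 - 1) if strand == "-" else (start1 - 1)
            recs.append(TssRecord(gene_id=gene_id, chrom=chrom, tss=tss, strand=strand))
    return recs


_MANIFEST_COLS = ["gene_id", "chrom", "start", "end", "resolution",
                  "anchor_index", "strand", "truncated"]


def write_region_manifest(regions: Sequence[LocusRegion], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id or "",
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "resolution": r.resolution,
                "anchor_index": r.anchor_index,
                "strand": r.strand or ".",
                "truncated": int(r.truncated),
            }
            for r in regions
        ],
        columns=_MANIFEST_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_region_manifest(path: str | Path) -> list[LocusRegion]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    return [
        LocusRegion(
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            resolution=int(row.resolution),
            anchor_index=int(row.anchor_index),
            gene_id=str(row.gene_id) if row.gene_id else None,
            strand=None if row.strand in (".", "nan") else str(row.strand),
            truncated=bool(row.truncated),
        )
        for row in df.itertuples(index=False)
    ]
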