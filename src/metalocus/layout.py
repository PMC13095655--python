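"""Kamada–Kawai embedding of the distance graph and the bounded per-bin
polygon geometry ("Gaudí" layout).

The embedding places each bin in 2D so that pairwise geometric distances
match the graph's target distances as closely as possible (Kamada–Kawai
stress).  Each embedded bin then receives a finite polygon: its Voronoi
cell — closed at the edges by eight dummy generators on an expanded
bounding box — intersected with a disk of radius 1.5x the mean spatial
distance between consecutive bins.  Overall scale and orientation of the
embedding are arbitrary; every downstream quantity either scales with the
mean step or is scale-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial import Voronoi
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import Point, Polygon, mapping

from .contacts import DistanceGraph
from .regions import LocusRegion

__all__ = [
    "GaudiLayout",
    "compute_layout",
    "build_gaudi",
    "layout_stress",
    "write_layout_tsv",
    "write_geojson",
]

BUFFER_MULTIPLIER = 1.5


@dataclass
class GaudiLayout:
    """2D coordinates plus bounded polygons for the present bins.

    ``bins`` are original region bin indices (ascending); ``coords`` rows
    align with them, as do ``polygons``.  ``signal`` (optional) carries the
    per-bin statistic value attached by the signal module.
    """

    region: LocusRegion | None
    bins: np.ndarray
    coords: np.ndarray
    polygons: list[Polygon]
    buffer_distance: float
    mean_step: float
    signal: np.ndarray | None = None
    signal_name: str | None = None

    @property
    def n(self) -> int:
        return len(self.bins)

    def index_of(self, bin_id: int) -> int:
        pos = int(np.searchsorted(self.bins, bin_id))
        if pos >= self.n or self.bins[pos] != bin_id:
            raise KeyError(f"bin {bin_id} not in layout")
        return pos


def _target_distance_matrix(dg: DistanceGraph) -> tuple[np.ndarray, np.ndarray]:
    nodes = np.array(dg.nodes, dtype=int)
    idx = {v: k for k, v in enumerate(nodes)}
    n = len(nodes)
    rows, cols, data = [], [], []
    for a, b, attrs in dg.graph.edges(data=True):
        d = attrs["distance"]
        if not np.isfinite(d) or d <= 0:
            raise ValueError(f"non-finite or non-positive target distance on "
                             f"edge ({a}, {b})")
        rows.append(idx[a]); cols.append(idx[b]); data.append(d)
    A = csr_matrix((data, (rows, cols)), shape=(n, n))
    D = shortest_path(A, method="D", directed=False)
    if not np.all(np.isfinite(D)):
        raise ValueError("distance graph is disconnected")
    return nodes, D


def _circular_init(n: int) -> np.ndarray:
    theta = 2 * np.pi * np.arange(n) / n
    return np.column_stack([np.cos(theta), np.sin(theta)])


def compute_layout(dg: DistanceGraph, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Embed the distance graph in 2D by Kamada–Kawai stress minimization.

    Deterministic: initialization is circular by genomic order, and the
    final coordinates are returned at the stress-optimal global scale (the
    optimizer's unit-box normalization is undone by a closed-form rescale),
    so a graph with an exactly embeddable distance matrix — e.g. three nodes
    with equal pairwise targets — is reproduced at its true size.  ``seed``
    is accepted for interface stability; the algorithm draws no random
    numbers.

    Returns ``(bins, coords)`` with coords rows aligned to ascending bins.
    """
    nodes, D = _target_distance_matrix(dg)
    n = len(nodes)
    if n < 2:
        raise ValueError("need at least two bins to lay out")
    pos0 = {int(v): p for v, p in zip(nodes, _circular_init(n))}
    dist = {int(nodes[i]): {int(nodes[j]): float(D[i, j]) for j in range(n)}
            for i in range(n)}
    pos = nx.kamada_kawai_layout(dg.graph, dist=dist, pos=pos0)
    P = np.array([pos[int(v)] for v in nodes], dtype=float)
    # networkx rescales to a unit box; restore the stress-optimal scale
    iu, ju = np.triu_indices(n, k=1)
    emb = np.linalg.norm(P[iu] - P[ju], axis=1)
    tgt = D[iu, ju]
    denom = np.sum(emb**2 / tgt**2)
    if denom > 0:
        P = P * (np.sum(emb / tgt) / denom)
    return nodes, P


def layout_stress(dg: DistanceGraph, bins: np.ndarray, coords: np.ndarray) -> float:
    """Kamada–Kawai stress of an embedding against the graph's targets."""
    nodes, D = _target_distance_matrix(dg)
    if not np.array_equal(nodes, np.asarray(bins)):
        raise ValueError("bins do not match the graph's node set")
    n = len(nodes)
    iu, ju = np.triu_indices(n, k=1)
    emb = np.linalg.norm(coords[iu] - coords[ju], axis=1)
    tgt = D[iu, ju]
    return float(np.sum((emb - tgt) ** 2 / tgt**2))


def mean_consecutive_step(bins: np.ndarray, coords: np.ndarray) -> float:
    """Mean embedded distance between genomically consecutive present bins.

    Pairs separated by missing bins are excluded; if every consecutive pair
    spans a gap (pathological), all consecutive present pairs are used.
    """
    bins = np.asarray(bins)
    steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    adjacent = np.diff(bins) == 1
    if adjacent.any():
        return float(steps[adjacent].mean())
    return float(steps.mean())


def build_gaudi(
    coords: np.ndarray,
    bins: np.ndarray | None = None,
    region: LocusRegion | None = None,
    buffer_multiplier: float = BUFFER_MULTIPLIER,
) -> GaudiLayout:
    """Construct bounded per-bin polygons from embedded coordinates.

    Eight dummy generators (corners + edge midpoints of the bounding box,
    expanded by twice the buffer distance) close every Voronoi cell; each
    bin's polygon is its cell intersected with the disk of radius
    ``buffer_multiplier x mean_step`` around the bin's point.  Dummy
    placement cannot affect the result as long as the dummies lie outside
    all buffer disks, which the expansion guarantees.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if bins is None:
        bins = np.arange(n)
    bins = np.asarray(bins, dtype=int)
    if n < 3:
        raise ValueError("need at least 3 points for a polygon tessellation")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-12 * max(1.0, np.abs(centered).max())) < 2:
        raise ValueError("points are collinear; no 2D tessellation exists")

    mean_step = mean_consecutive_step(bins, coords)
    buffer_distance = buffer_multiplier * mean_step

    lo = coords.min(axis=0) - 2.0 * buffer_distance
    hi = coords.max(axis=0) + 2.0 * buffer_distance
    cx, cy = (lo + hi) / 2.0
    dummies = np.array([
        [lo[0], lo[1]], [cx, lo[1]], [hi[0], lo[1]], [hi[0], cy],
        [hi[0], hi[1]], [cx, hi[1]], [lo[0], hi[1]], [lo[0], cy],
    ])
    vor = Voronoi(np.vstack([coords, dummies]))
    polygons: list[Polygon] = []
    for i in range(n):
        verts_idx = vor.regions[vor.point_region[i]]
        if -1 in verts_idx:  # pragma: no cover - dummies guarantee finiteness
            raise RuntimeError(f"bin {bins[i]} has an unbounded Voronoi cell")
        verts = vor.vertices[verts_idx]
        # sort counterclockwise around the generator (cells are convex)
        ang = np.arctan2(verts[:, 1] - coords[i, 1], verts[:, 0] - coords[i, 0])
        cell = Polygon(verts[np.argsort(ang)])
        disk = Point(coords[i]).buffer(buffer_distance, quad_segs=32)
        polygons.append(cell.intersection(disk))
    return GaudiLayout(region=region, bins=bins, coords=coords,
                       polygons=polygons, buffer_distance=buffer_distance,
                       mean_step=mean_step)


# ---------------------------------------------------------------------------
# writers


def write_layout_tsv(layout: GaudiLayout, path: str | Path) -> None:
    rows = []
    for k, b in enumerate(layout.bins):
        if layout.region is not None:
            s, e = layout.region.bin_interval(int(b))
            chrom = layout.region.chrom
        else:
            s = e = -1
            chrom = "."
        rows.append({"bin": int(b), "chrom": chrom, "start": s, "end": e,
                     "x": layout.coords[k, 0], "y": layout.coords[k, 1]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.10g")


def write_geojson(layout: GaudiLayout, path: str | Path) -> None:
    feats = []
    for k, b in enumerate(layout.bins):
        props: dict = {"bin": int(b)}
        if layout.region is not None:
            s, e = layout.region.bin_interval(int(b))
            props.update(chrom=layout.region.chrom, start=s, end=e)
        if layout.signal is not None:
            props["signal"] = float(layout.signal[k])
        feats.append({"type": "Feature", "properties": props,
                      "geometry": mapping(layout.polygons[k])})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
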