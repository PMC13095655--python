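"""Contact-matrix loading, log-transform/cutoff selection, and the
restrained distance graph.

The pipeline treats a normalized Hi-C submatrix as a similarity matrix:
interaction frequencies are log10-transformed, entries whose score falls
below a cutoff (default 1.0, or chosen automatically from the score
distribution) are discarded, and surviving scores are inverted into target
2D distances.  A "persistence length" parameter adds a stiff backbone of
consecutive-bin edges that keeps the chain connected and counteracts the
contact-derived restraints: large values straighten the layout, small
values let it zig-zag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .cool import CoolReader
from .regions import LocusRegion

__all__ = [
    "ContactMatrix",
    "DistanceGraph",
    "load_cool_matrix",
    "load_dense_tsv",
    "load_coo_tsv",
    "write_dense_tsv",
    "write_coo_tsv",
    "transform_and_select",
    "auto_cutoff",
    "build_distance_graph",
]

DEFAULT_CUTOFF = 1.0
DEFAULT_PERSISTENCE_LENGTH = 10.0
REFERENCE_STIFFNESS = 10.0


@dataclass
class ContactMatrix:
    """Symmetric normalized interaction matrix over the bins of a region.

    ``values`` holds NaN for absent entries (masked bins, or interactions
    dropped by the cutoff after transformation); absent is never conflated
    with zero.  ``transformed`` records whether values are log10 scores.
    """

    region: LocusRegion
    values: np.ndarray
    bad_bins: frozenset[int] = frozenset()
    transformed: bool = False
    cutoff: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = self.region.n_bins
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} != ({n}, {n})")
        diff = v - v.T
        finite = np.isfinite(diff)
        if finite.any():
            scale = max(1.0, float(np.abs(v[np.isfinite(v)]).max()))
            if np.abs(diff[finite]).max() > 1e-8 * scale:
                raise ValueError("contact matrix is not symmetric")
        if not self.transformed and np.isfinite(v).any() \
                and v[np.isfinite(v)].min() < 0:
            raise ValueError("untransformed contact values must be non-negative")
        self.values = v

    @property
    def n_bins(self) -> int:
        return self.region.n_bins

    def present_bins(self) -> np.ndarray:
        return np.array([i for i in range(self.n_bins) if i not in self.bad_bins],
                        dtype=int)


def _bad_from_nan_rows(mat: np.ndarray) -> frozenset[int]:
    return frozenset(int(i) for i in np.where(np.all(np.isnan(mat), axis=1))[0])


def load_cool_matrix(uri: str | Path, region: LocusRegion,
                     balance: bool = True) -> ContactMatrix:
    """Load the region submatrix from a (single-resolution) cooler file.

    Balancing weights in ``bins/weight`` are applied when present; bins with
    NaN weight are recorded as bad bins.  In files without weights, bins with
    an all-zero row are taken as absent from the store.
    """
    with CoolReader(uri) as cr:
        if cr.resolution != region.resolution:
            raise ValueError(
                f"store resolution {cr.resolution} != region resolution "
                f"{region.resolution}")
        if region.chrom not in cr.chrom_lengths:
            raise KeyError(f"chromosome {region.chrom!r} not in store")
        if region.end > cr.chrom_lengths[region.chrom]:
            raise ValueError("region extends beyond the store's chromosome extent")
        mat, masked = cr.fetch_dense(region.chrom, region.start, region.end,
                                     balance=balance)
        if mat.shape[0] != region.n_bins:
            raise ValueError("store returned unexpected bin count")
        if cr.has_weights and balance:
            bad = frozenset(int(i) for i in np.where(masked)[0])
        else:
            bad = frozenset(int(i) for i in
                            np.where(np.nansum(mat, axis=1) == 0)[0])
            mat = mat.copy()
            for i in bad:
                mat[i, :] = np.nan
                mat[:, i] = np.nan
    return ContactMatrix(region=region, values=mat, bad_bins=bad)


def load_dense_tsv(path: str | Path, region: LocusRegion) -> ContactMatrix:
    """Read a square dense TSV (n_bins × n_bins, NaN = absent).

    Comment lines starting with ``#`` are ignored; no row/column labels.
    """
    mat = pd.read_csv(path, sep="\t", comment="#", header=None).to_numpy(float)
    if mat.shape != (region.n_bins, region.n_bins):
        raise ValueError(f"dense matrix shape {mat.shape} does not match the "
                         f"region ({region.n_bins} bins)")
    return ContactMatrix(region=region, values=mat,
                         bad_bins=_bad_from_nan_rows(mat))


def load_coo_tsv(path: str | Path, region: LocusRegion) -> ContactMatrix:
    """Read a COO-triplet TSV with header columns ``bin1  bin2  value``.

    Indices are region-local; only the upper triangle need be listed.
    Bins appearing in no triplet are recorded as bad bins.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"bin1", "bin2", "value"}
    if not need.issubset(df.columns):
        raise ValueError(f"COO TSV must have columns {sorted(need)}")
    n = region.n_bins
    mat = np.full((n, n), np.nan)
    i = df["bin1"].to_numpy(int)
    j = df["bin2"].to_numpy(int)
    if (i < 0).any() or (j >= n).any() or (i >= n).any() or (j < 0).any():
        raise ValueError("COO indices outside the region bin range")
    v = df["value"].to_numpy(float)
    mat[i, j] = v
    mat[j, i] = v
    seen = np.zeros(n, dtype=bool)
    seen[i] = True
    seen[j] = True
    mat[~seen, :] = np.nan
    mat[:, ~seen] = np.nan
    # unlisted pairs among present bins are zero-interaction, not absent
    present = np.where(seen)[0]
    sub = mat[np.ix_(present, present)]
    sub[np.isnan(sub)] = 0.0
    mat[np.ix_(present, present)] = sub
    return ContactMatrix(region=region, values=mat,
                         bad_bins=frozenset(int(b) for b in np.where(~seen)[0]))


def write_dense_tsv(cm: ContactMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# chrom={cm.region.chrom} start={cm.region.start} "
                 f"resolution={cm.region.resolution}\n")
        np.savetxt(fh, cm.values, delimiter="\t", fmt="%.17g")


def write_coo_tsv(cm: ContactMatrix, path: str | Path) -> None:
    n = cm.n_bins
    iu, ju = np.triu_indices(n)
    v = cm.values[iu, ju]
    keep = ~np.isnan(v) & (v != 0)
    df = pd.DataFrame({"bin1": iu[keep], "bin2": ju[keep], "value": v[keep]})
    with open(path, "w") as fh:
        fh.write(f"# chrom={cm.region.chrom} start={cm.region.start} "
                 f"resolution={cm.region.resolution}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# transform / cutoff


def transform_and_select(cm: ContactMatrix,
                         cutoff: float | str = DEFAULT_CUTOFF) -> ContactMatrix:
    """log10-transform the matrix and drop interactions scoring below cutoff.

    Zero and absent entries are treated as absent interactions (NaN), never
    as -inf.  Ties (score exactly equal to the cutoff) are retained.
    Idempotent: re-applying with the same cutoff changes nothing.
    ``cutoff="auto"`` delegates to :func:`auto_cutoff`.
    """
    if cm.transformed:
        scores = cm.values.copy()
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = np.where(np.nan_to_num(cm.values, nan=0.0) > 0,
                              np.log10(np.where(cm.values > 0, cm.values, 1.0)),
                              np.nan)
    if cutoff == "auto":
        cutoff = auto_cutoff(cm)
    cutoff = float(cutoff)
    scores[scores < cutoff] = np.nan
    n = cm.n_bins
    off = ~np.eye(n, dtype=bool)
    adjacent = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) == 1
    if not np.isfinite(scores[off & ~adjacent]).any():
        warnings.warn("cutoff removed all off-backbone interactions; the "
                      "layout will rely on the backbone alone", stacklevel=2)
    return ContactMatrix(region=cm.region, values=scores, bad_bins=cm.bad_bins,
                         transformed=True, cutoff=cutoff)


GRID_STEP = 0.05


def auto_cutoff(cm: ContactMatrix, target_density: float = 0.15,
                grid_step: float = GRID_STEP) -> float:
    """Choose a log10-score cutoff from the matrix's score distribution.

    Rule: the smallest cutoff on a ``grid_step`` grid (multiples of the
    step) such that the fraction of retained positive off-diagonal entries
    is at most ``target_density``, floored at the 50th-percentile score.
    A grid anchored at multiples of the step makes the choice covariant
    with rescaling: multiplying the matrix by 10 shifts the cutoff by +1.
    """
    v = cm.values[~np.eye(cm.n_bins, dtype=bool)]
    if cm.transformed:
        scores = v[np.isfinite(v)]
    else:
        pos = v[np.isfinite(v) & (v > 0)]
        scores = np.log10(pos)
    if scores.size == 0:
        raise ValueError("matrix has no positive off-diagonal entry")
    lo, hi = scores.min(), scores.max()
    if hi - lo < 1e-12:
        warnings.warn("degenerate all-equal matrix; returning the minimum "
                      "score as cutoff", stacklevel=2)
        return float(lo)
    median = float(np.median(scores))
    sorted_scores = np.sort(scores)
    k0 = int(np.ceil(round(lo / grid_step, 9)))
    k1 = int(np.ceil(round(hi / grid_step, 9))) + 1
    chosen = None
    for k in range(k0, k1 + 1):
        c = k * grid_step
        frac = (sorted_scores.size
                - np.searchsorted(sorted_scores, c, side="left")) / scores.size
        if frac <= target_density:
            chosen = c
            break
    if chosen is None:  # pragma: no cover - loop always terminates above max
        chosen = k1 * grid_step
    return float(max(chosen, median))


# ---------------------------------------------------------------------------
# distance graph


@dataclass
class DistanceGraph:
    """Target-distance graph fed to the 2D embedding.

    ``graph`` is an undirected networkx graph over present bin indices whose
    edges carry a ``distance`` attribute (contact edges: 1/score; backbone
    edges between consecutive present bins: ``1/(max_score *
    persistence_length)``).  ``gap_joined`` lists backbone edges that bridge
    runs of missing bins.
    """

    region: LocusRegion
    graph: nx.Graph
    backbone_strength: float
    gap_joined: list[tuple[int, int]] = field(default_factory=list)

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)


def build_distance_graph(
    cm: ContactMatrix,
    persistence_length: float = DEFAULT_PERSISTENCE_LENGTH,
) -> DistanceGraph:
    """Invert retained scores into target distances and add the backbone.

    Requires a transformed/filtered matrix.  Retained pairs (i, j) with
    score s get an edge of target distance 1/s; consecutive present bins are
    joined by a backbone edge whose distance is the shortest contact
    distance divided by ``persistence_length``, so the chain is always
    connected and stiffer than any single restraint for
    ``persistence_length`` > 1.  Retained non-positive scores (possible only
    with a cutoff <= 0) cannot be inverted into a positive distance and are
    ignored with a warning.
    """
    if not cm.transformed:
        raise ValueError("build_distance_graph needs a transformed matrix; "
                         "call transform_and_select first")
    if persistence_length <= 0:
        raise ValueError("persistence_length must be positive")
    present = cm.present_bins()
    g = nx.Graph()
    g.add_nodes_from(int(i) for i in present)

    vals = cm.values
    iu, ju = np.triu_indices(cm.n_bins, k=1)
    s = vals[iu, ju]
    finite = np.isfinite(s)
    if (finite & (s <= 0)).any():
        warnings.warn("retained scores <= 0 cannot become positive distances "
                      "and were ignored", stacklevel=2)
    keep = finite & (s > 0)
    max_score = float(s[keep].max()) if keep.any() else 1.0
    bad = cm.bad_bins
    for i, j, sc in zip(iu[keep], ju[keep], s[keep]):
        if i in bad or j in bad:
            continue
        g.add_edge(int(i), int(j), distance=1.0 / float(sc), kind="contact")

    # Calibrated so the field-standard stiffness of 10 places the backbone
    # step at the strongest-contact distance: consecutive bins are then at
    # least as close as the tightest retained restraint, and the 3x-step
    # neighbor band can reach strong sequence-distal contacts.  Larger
    # values shorten the step proportionally (straighter chain), smaller
    # values lengthen it (contacts dominate; zig-zag).
    backbone_dist = REFERENCE_STIFFNESS / (max_score * persistence_length)
    gap_joined: list[tuple[int, int]] = []
    for a, b in zip(present[:-1], present[1:]):
        a, b = int(a), int(b)
        if g.has_edge(a, b):
            d = min(g[a][b]["distance"], backbone_dist)
        else:
            d = backbone_dist
        g.add_edge(a, b, distance=d, kind="backbone")
        if b - a > 1:
            gap_joined.append((a, b))
    return DistanceGraph(region=cm.region, graph=g,
                         backbone_strength=persistence_length,
                         gap_joined=gap_joined)
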