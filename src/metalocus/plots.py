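"""The three standard figures: Gaudí plot, LMI scatter, volcano, plus the
deletion-scan profile.

Quadrant colors follow the method's convention — HH red, LH cyan, LL
blue, HL orange — with non-significant bins desaturated.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import PatchCollection
from matplotlib.patches import Polygon as MplPolygon

from .dynamics import LMI_THRESHOLD, LOGP_THRESHOLD, VolcanoPoint
from .layout import GaudiLayout
from .perturbation import PerturbationScan
from .spatial import LmiTable

__all__ = ["QUADRANT_COLORS", "gaudi_plot", "lmi_scatter", "volcano_plot",
           "scan_plot"]

QUADRANT_COLORS = {"HH": "#d62728", "LH": "#17becf",
                   "LL": "#1f77b4", "HL": "#ff7f0e"}
_DESATURATED = "#d9d9d9"


def _save(fig, path):
    fig.savefig(path, dpi=150)
    plt.close(fig)


def gaudi_plot(layout: GaudiLayout, lmi: LmiTable | None = None,
               path: str | Path | None = None, highlight: str = "HH"):
    """Polygons colored by signal, or by LMI quadrant when a table is given.

    With an LMI table, significant bins take their quadrant's solid color
    and non-significant bins are desaturated; significant bins of the
    ``highlight`` quadrant get an outline.
    """
    fig, ax = plt.subplots(figsize=(6, 6))
    patches, colors, edge = [], [], []
    sig_map = {}
    quad_map = {}
    if lmi is not None:
        for _, row in lmi.table.iterrows():
            sig_map[int(row["bin"])] = bool(row["significant"])
            quad_map[int(row["bin"])] = str(row["quadrant"])
    vals = layout.signal
    for k, b in enumerate(layout.bins):
        poly = layout.polygons[k]
        if poly.is_empty:
            continue
        patches.append(MplPolygon(np.asarray(poly.exterior.coords)))
        if lmi is not None:
            q = quad_map.get(int(b), "")
            if sig_map.get(int(b), False) and q in QUADRANT_COLORS:
                colors.append(QUADRANT_COLORS[q])
                edge.append("black" if q == highlight else "none")
            else:
                colors.append(_DESATURATED)
                edge.append("none")
    if lmi is not None:
        pc = PatchCollection(patches, facecolor=colors, edgecolor=edge,
                             linewidth=1.2)
        ax.add_collection(pc)
    else:
        pc = PatchCollection(patches, cmap="viridis", edgecolor="white",
                             linewidth=0.3)
        if vals is not None:
            pc.set_array(np.asarray(vals))
            fig.colorbar(pc, ax=ax, label=layout.signal_name or "signal")
        ax.add_collection(pc)
    ax.plot(*layout.coords.T, lw=0.4, color="black", alpha=0.4)
    ax.set_aspect("equal")
    ax.autoscale_view()
    ax.set_axis_off()
    if path:
        _save(fig, path)
    return fig


def lmi_scatter(lmi: LmiTable, path: str | Path | None = None):
    """Moran scatter: z against spatial lag, colored by quadrant."""
    fig, ax = plt.subplots(figsize=(5, 5))
    df = lmi.table
    for q, c in QUADRANT_COLORS.items():
        sub = df[df["quadrant"] == q]
        sig = sub["significant"].to_numpy(bool)
        ax.scatter(sub["z"][~sig], sub["lag"][~sig], s=14, color=_DESATURATED,
                   edgecolor=c, linewidth=0.5)
        ax.scatter(sub["z"][sig], sub["lag"][sig], s=18, color=c, label=q)
    ax.axhline(0, color="gray", lw=0.6)
    ax.axvline(0, color="gray", lw=0.6)
    ax.set_xlabel("z (normalized signal)")
    ax.set_ylabel("spatial lag")
    ax.legend(frameon=False, fontsize=8)
    if path:
        _save(fig, path)
    return fig


def volcano_plot(points: list[VolcanoPoint], path: str | Path | None = None,
                 lmi_threshold: float = LMI_THRESHOLD,
                 logp_threshold: float = LOGP_THRESHOLD):
    """Signed LMI vs signed log-significance with threshold guides."""
    fig, ax = plt.subplots(figsize=(5, 5))
    u = np.array([p.u for p in points])
    v = np.array([p.v for p in points])
    cols = [QUADRANT_COLORS.get(p.quadrant, _DESATURATED) for p in points]
    ax.scatter(u, v, s=12, c=cols, alpha=0.8)
    for t in (-lmi_threshold, lmi_threshold):
        ax.axvline(t, color="gray", ls="--", lw=0.7)
    for t in (-logp_threshold, logp_threshold):
        ax.axhline(t, color="gray", ls="--", lw=0.7)
    ax.set_xlabel("signed LMI")
    ax.set_ylabel("signed -log10(p)")
    if path:
        _save(fig, path)
    return fig


def scan_plot(scan_result: PerturbationScan, path: str | Path | None = None):
    """Post-deletion anchor LMI per window, with the mean +/- 1 sd band and
    flagged windows marked."""
    fig, ax = plt.subplots(figsize=(8, 3))
    rec = scan_result.records
    ok = ~rec["skipped"]
    x = rec.loc[ok, "start_bp"] / 1e6
    y = rec.loc[ok, "anchor_lmi"]
    mu = y.mean()
    sd = y.std(ddof=0)
    ax.axhspan(mu - sd, mu + sd, color="lightgray", alpha=0.7,
               label="mean ± 1 sd")
    ax.plot(x, y, lw=0.9, color="black")
    fl = rec["flagged"].fillna(False) if "flagged" in rec else ok & False
    ax.scatter(rec.loc[fl, "start_bp"] / 1e6, rec.loc[fl, "anchor_lmi"],
               color="tab:blue", s=14, zorder=3, label="flagged deletion")
    ax.axhline(scan_result.threshold, color="tab:red", lw=0.7, ls="--")
    ax.set_xlabel("deletion window start (Mb)")
    ax.set_ylabel("anchor LMI after deletion")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        _save(fig, path)
    return fig
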