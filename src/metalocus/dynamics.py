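"""Volcano-plane coordinates and signed gene transitions between states.

A gene's anchor-bin LMI result is mapped to a point in a signed
"inverted volcano" plane: the horizontal coordinate is the LMI score with
its sign flipped for LH and LL quadrant bins, the vertical coordinate is
-log10(p) with its sign flipped for HL and LL — the canonical orientation
puts HH at (+, +) and LL at (-, -).  The transition of a gene between two
biological states is the Euclidean displacement of its point; its sign is
positive when the displacement vector points toward the HH corner
(positive projection on the main diagonal) and negative toward LL.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .spatial import LmiTable

__all__ = ["VolcanoPoint", "TransitionRecord", "volcano_coords",
           "gene_transition", "write_transitions_tsv"]

LMI_THRESHOLD = 1.0
LOGP_THRESHOLD = 1.3  # |log10 p| > 1.3 ~ p < 0.05

_U_FLIP = {"LH", "LL"}
_V_FLIP = {"HL", "LL"}


@dataclass(frozen=True)
class VolcanoPoint:
    u: float
    v: float
    quadrant: str
    lmi: float
    p: float
    significant_volcano: bool
    flagged_origin: bool = False  # undefined quadrant collapsed to (0, 0)


def volcano_coords(
    lmi: float,
    p: float,
    quadrant: str,
    lmi_threshold: float = LMI_THRESHOLD,
    logp_threshold: float = LOGP_THRESHOLD,
) -> VolcanoPoint:
    """Signed volcano coordinates of one anchor-bin LMI record.

    u = lmi, sign flipped for LH/LL; v = -log10(p), sign flipped for HL/LL.
    The point is "volcano-significant" when |u| exceeds ``lmi_threshold``
    and |v| exceeds ``logp_threshold`` (defaults 1.0 and 1.3, i.e. p<0.05).
    An undefined quadrant (constant signal) maps to the origin, flagged.
    """
    if quadrant == "" or not np.isfinite(lmi) or not np.isfinite(p):
        return VolcanoPoint(0.0, 0.0, quadrant, float(lmi), float(p),
                            significant_volcano=False, flagged_origin=True)
    u = -lmi if quadrant in _U_FLIP else lmi
    v = -np.log10(p)
    if quadrant in _V_FLIP:
        v = -v
    sig = abs(u) > lmi_threshold and abs(v) > logp_threshold
    return VolcanoPoint(float(u), float(v), quadrant, float(lmi), float(p),
                        significant_volcano=sig)


def volcano_from_table(lmi_table: LmiTable, **kw) -> VolcanoPoint:
    """Volcano point of the region's anchor bin."""
    e = lmi_table.anchor_entry
    return volcano_coords(float(e["lmi"]), float(e["p"]), str(e["quadrant"]),
                          **kw)


@dataclass(frozen=True)
class TransitionRecord:
    gene_id: str | None
    point_a: VolcanoPoint
    point_b: VolcanoPoint
    length: float
    sign: int

    @property
    def signed_length(self) -> float:
        return self.sign * self.length


def gene_transition(a: VolcanoPoint, b: VolcanoPoint,
                    gene_id: str | None = None) -> TransitionRecord:
    """Displacement of a gene in the volcano plane between two states.

    Length is the Euclidean distance (arbitrary units); sign is
    sign(du + dv): +1 toward the HH corner, -1 toward LL, 0 for a purely
    lateral move (or no move).
    """
    du, dv = b.u - a.u, b.v - a.v
    length = float(np.hypot(du, dv))
    sign = int(np.sign(du + dv))
    if length == 0.0:
        sign = 0
    return TransitionRecord(gene_id=gene_id, point_a=a, point_b=b,
                            length=length, sign=sign)


def write_transitions_tsv(records: Iterable[TransitionRecord],
                          path: str | Path) -> None:
    rows = [{"gene_id": r.gene_id or "", "u_a": r.point_a.u, "v_a": r.point_a.v,
             "u_b": r.point_b.u, "v_b": r.point_b.v, "length": r.length,
             "sign": r.sign} for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.10g")
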