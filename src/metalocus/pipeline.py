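"""End-to-end per-locus analysis: contacts -> layout -> weights -> LMI ->
metaloci.

:func:`analyze_locus` runs the whole chain on one region with a single
configuration object whose defaults are the method's standard settings
(10-kb bins, 2-Mb flank handled upstream, log10 cutoff 1.0, persistence
length 10, buffer 1.5x, band 3x, 50,000 permutations, alpha 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import contacts as _contacts
from . import layout as _layout
from . import signals as _signals
from . import spatial as _spatial
from .contacts import ContactMatrix
from .signals import SignalTrack
from .spatial import LmiTable, Metalocus, SpatialWeights

__all__ = ["PipelineConfig", "LocusResult", "analyze_locus"]


@dataclass
class PipelineConfig:
    """All tunables of a per-locus run, at the method's defaults."""

    cutoff: float | str = _contacts.DEFAULT_CUTOFF  # log10 score, or "auto"
    persistence_length: float = _contacts.DEFAULT_PERSISTENCE_LENGTH
    buffer_multiplier: float = _layout.BUFFER_MULTIPLIER
    band_multiplier: float = _spatial.BAND_MULTIPLIER
    n_perm: int = _spatial.DEFAULT_N_PERM
    alpha: float = _spatial.DEFAULT_ALPHA
    seed: int = 1
    mode: str = "maximal_cardinality"
    alternative: str = "two-sided"
    adjust: str | None = None
    linearity: bool = False
    quadrant: str = "HH"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LocusResult:
    """Everything one locus run produces."""

    config: PipelineConfig
    matrix: ContactMatrix          # transformed/filtered
    layout: "_layout.GaudiLayout"  # with signal attached
    weights: SpatialWeights
    lmi: LmiTable
    metaloci: list[Metalocus]

    @property
    def anchor_entry(self):
        return self.lmi.anchor_entry


def analyze_locus(cm: ContactMatrix, sig: SignalTrack,
                  config: PipelineConfig | None = None) -> LocusResult:
    """Run the full spatial-autocorrelation analysis for one region.

    ``cm`` may be raw (it is transformed/filtered here) or already
    transformed; ``sig`` supplies the per-bin log10 signal.  Bins that are
    bad in the matrix or NaN in the signal (deleted) are excluded from the
    layout and the statistics.
    """
    cfg = config or PipelineConfig()
    if cm.region.n_bins != sig.region.n_bins or cm.region.chrom != sig.region.chrom:
        raise ValueError("contact matrix and signal track cover different regions")

    if not cm.transformed:
        cm = _contacts.transform_and_select(cm, cutoff=cfg.cutoff)

    # signal-deleted bins (NaN raw) are treated like bad matrix bins
    sig_deleted = frozenset(int(i) for i in np.where(np.isnan(sig.raw))[0])
    if sig_deleted - cm.bad_bins:
        cm = ContactMatrix(region=cm.region, values=_mask(cm.values, sig_deleted),
                           bad_bins=cm.bad_bins | sig_deleted,
                           transformed=True, cutoff=cm.cutoff)

    dg = _contacts.build_distance_graph(cm, persistence_length=cfg.persistence_length)
    bins, coords = _layout.compute_layout(dg, seed=cfg.seed)
    gl = _layout.build_gaudi(coords, bins=bins, region=cm.region,
                             buffer_multiplier=cfg.buffer_multiplier)
    gl = _signals.attach_signal(gl, sig, expected_missing=len(cm.bad_bins))
    w = _spatial.build_weights(gl, band_multiplier=cfg.band_multiplier)
    lmi = _spatial.lmi_analysis(gl.signal, w, n_perm=cfg.n_perm, seed=cfg.seed,
                                alpha=cfg.alpha, mode=cfg.mode,
                                alternative=cfg.alternative, adjust=cfg.adjust,
                                region=cm.region, linearity=cfg.linearity)
    metaloci = _spatial.call_metaloci(lmi, w, quadrant=cfg.quadrant)
    return LocusResult(config=cfg, matrix=cm, layout=gl, weights=w,
                       lmi=lmi, metaloci=metaloci)


def _mask(values: np.ndarray, bins: frozenset[int]) -> np.ndarray:
    out = values.copy()
    idx = list(bins)
    out[idx, :] = np.nan
    out[:, idx] = np.nan
    return out
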