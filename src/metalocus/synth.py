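"""Deterministic synthetic loci: distance-decaying contact matrices with
planted interaction hubs and correlated signal tracks.

The generator emulates the two features the method exploits — a polymer
contact-frequency decay with genomic distance, and a compact set of bins
that both interact more among themselves (a 3D hub) and carry elevated
signal — and records the planted truth in a sidecar structure, so every
statistical test has a ground truth without any download.  It is not a
biophysical chromatin simulator: no TADs, loops or loop extrusion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import cool as _cool
from . import contacts as _contacts
from . import signals as _signals
from .contacts import ContactMatrix
from .regions import LocusRegion
from .signals import SignalTrack

__all__ = ["HubSpec", "make_locus", "write_fixture", "read_truth"]

DEFAULT_N_BINS = 101
DEFAULT_RESOLUTION = 10_000
DEFAULT_DECAY_EXPONENT = 1.0
DEFAULT_NOISE_CV = 0.2
DEFAULT_BACKGROUND_SIGNAL = 5.0
DEFAULT_CONTACT_BOOST = 5.0
DEFAULT_SIGNAL_LEVEL = 50.0
REFERENCE_DECAY_BINS = 25  # 250 kb at 10-kb resolution
FIXTURE_CHROM = "chrS"


@dataclass(frozen=True)
class HubSpec:
    """A planted 3D hub: bins that co-interact and share elevated signal."""

    member_bins: tuple[int, ...]
    contact_boost: float = DEFAULT_CONTACT_BOOST
    signal_level: float = DEFAULT_SIGNAL_LEVEL
    anchor_in_hub: bool = False

    def __post_init__(self) -> None:
        if self.contact_boost <= 1:
            raise ValueError("contact_boost must exceed 1")


def make_locus(
    n_bins: int = DEFAULT_N_BINS,
    resolution: int = DEFAULT_RESOLUTION,
    decay_exponent: float = DEFAULT_DECAY_EXPONENT,
    hubs: "list[HubSpec] | None" = None,
    noise_cv: float = DEFAULT_NOISE_CV,
    background_signal: float = DEFAULT_BACKGROUND_SIGNAL,
    seed: int = 0,
    gene_id: str = "geneS",
    bad_bins: "set[int] | None" = None,
) -> tuple[ContactMatrix, SignalTrack, dict]:
    """Generate one synthetic locus and its ground truth.

    Contacts: ``c_ij = A * (|i-j|+1)^(-decay_exponent)``, with A chosen so
    that log10 of mid-range contacts straddles the standard cutoff of 1.0
    (short/mid-range restraints survive the filter, long-range ones drop).
    Intra-hub pairs are multiplied by their hub's ``contact_boost``.
    Multiplicative log-normal noise with coefficient of variation
    ``noise_cv`` is applied symmetrically.  Signal: ``background_signal``
    everywhere, elevated to ``signal_level`` on hub bins, with Poisson
    jitter when ``noise_cv > 0`` (exact levels when 0).  Fully determined
    by ``seed``.
    """
    if n_bins < 21:
        raise ValueError("n_bins must be at least 21")
    hubs = list(hubs or [])
    for h in hubs:
        if any(b < 0 or b >= n_bins for b in h.member_bins):
            raise ValueError("hub member bins outside the region")
    claimed: dict[int, float] = {}
    for h in hubs:
        for b in h.member_bins:
            if b in claimed and claimed[b] != h.contact_boost:
                raise ValueError(f"bin {b} belongs to hubs with conflicting "
                                 "contact boosts")
            claimed[b] = h.contact_boost

    anchor = n_bins // 2
    region = LocusRegion(chrom=FIXTURE_CHROM, start=0,
                         end=n_bins * resolution, resolution=resolution,
                         anchor_index=anchor, gene_id=gene_id)
    rng = np.random.default_rng(seed)

    d = np.abs(np.subtract.outer(np.arange(n_bins), np.arange(n_bins)))
    # magnitude anchored to a fixed genomic reference, not the window width:
    # contacts at REFERENCE_DECAY_BINS separation score exactly at the
    # standard log10 cutoff of 1.0, so the filter is exercised identically
    # whatever the region size
    scale = 10.0 * (REFERENCE_DECAY_BINS + 1.0) ** decay_exponent
    base = scale * (d + 1.0) ** (-decay_exponent)
    boost = np.ones((n_bins, n_bins))
    for h in hubs:
        mb = np.array(sorted(set(h.member_bins)))
        sub = np.ix_(mb, mb)
        boost[sub] = h.contact_boost
    np.fill_diagonal(boost, 1.0)
    mat = base * boost
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        noise = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma,
                              size=(n_bins, n_bins))
        noise = np.triu(noise) + np.triu(noise, k=1).T
        mat = mat * noise

    level = np.full(n_bins, float(background_signal))
    for h in hubs:
        level[list(h.member_bins)] = h.signal_level
    raw = rng.poisson(level).astype(float) if noise_cv > 0 else level.copy()

    bad = frozenset(int(b) for b in (bad_bins or set()))
    if bad:
        idx = sorted(bad)
        mat[idx, :] = np.nan
        mat[:, idx] = np.nan
    cm = ContactMatrix(region=region, values=mat, bad_bins=bad)
    sig = SignalTrack(region=region, raw=raw, signal_name="synthetic")

    truth = {
        "n_bins": n_bins, "resolution": resolution,
        "decay_exponent": decay_exponent, "noise_cv": noise_cv,
        "background_signal": background_signal, "contact_scale": scale,
        "seed": seed, "anchor_index": anchor, "gene_id": gene_id,
        "bad_bins": sorted(bad),
        "hubs": [asdict(h) | {"member_bins": list(h.member_bins)}
                 for h in hubs],
    }
    return cm, sig, truth


def write_fixture(
    cm: ContactMatrix,
    sig: SignalTrack,
    truth: dict,
    outdir: str | Path,
    formats: tuple[str, ...] = ("cool", "bedgraph", "json"),
    stem: str = "fixture",
) -> dict[str, Path]:
    """Write a generated locus in on-disk formats that round-trip.

    Supported formats: ``cool``, ``dense_tsv``, ``coo_tsv`` (contacts);
    ``bedgraph``, ``bigwig`` (signal); ``json`` (ground-truth sidecar).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    region = cm.region
    paths: dict[str, Path] = {}
    for fmt in formats:
        if fmt == "cool":
            p = outdir / f"{stem}.cool"
            if p.exists():
                p.unlink()
            n = region.n_bins
            iu, ju = np.triu_indices(n)
            v = cm.values[iu, ju]
            keep = np.isfinite(v) & (v != 0)
            pixels = np.column_stack([iu[keep], ju[keep], v[keep]])
            weights = np.ones(n)
            for b in cm.bad_bins:
                weights[b] = np.nan
            _cool.write_cool(p, {region.chrom: region.end},
                             region.resolution, pixels, weights=weights)
        elif fmt == "dense_tsv":
            p = outdir / f"{stem}.matrix.tsv"
            _contacts.write_dense_tsv(cm, p)
        elif fmt == "coo_tsv":
            p = outdir / f"{stem}.coo.tsv"
            _contacts.write_coo_tsv(cm, p)
        elif fmt == "bedgraph":
            p = outdir / f"{stem}.bedgraph"
            _signals.write_bedgraph(sig, p)
        elif fmt == "bigwig":
            p = outdir / f"{stem}.bw"
            _signals.write_bigwig(sig, p)
        elif fmt == "json":
            p = outdir / f"{stem}.truth.json"
            with open(p, "w") as fh:
                json.dump(truth, fh, indent=1)
        else:
            raise ValueError(f"unsupported fixture format: {fmt!r}")
        paths[fmt] = p
    return paths


def read_truth(path: str | Path) -> dict:
    """Parse a ground-truth sidecar back, with hubs as HubSpec objects."""
    with open(path) as fh:
        truth = json.load(fh)
    truth["hubs"] = [
        HubSpec(member_bins=tuple(h["member_bins"]),
                contact_boost=h["contact_boost"],
                signal_level=h["signal_level"],
                anchor_in_hub=h.get("anchor_in_hub", False))
        for h in truth["hubs"]
    ]
    return truth
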