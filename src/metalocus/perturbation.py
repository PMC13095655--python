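"""In-silico sliding-deletion scan.

A fixed-width window (default 5 bins = 50 kb at 10-kb resolution) slides
across the region in 1-bin steps; at each position the window's bins are
removed from both the contact matrix and the signal track — data removal,
not zeroing — and the full analysis (transform, layout, weights, LMI) is
re-run with identical configuration.  Windows whose post-deletion anchor
LMI falls below mean - sd_multiplier x sd of the scan distribution are
flagged as predicted critical regulatory regions.  Windows covering the
anchor bin itself are skipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .contacts import ContactMatrix
from .pipeline import LocusResult, PipelineConfig, analyze_locus
from .regions import LocusRegion
from .signals import SignalTrack

__all__ = ["PerturbationScan", "delete_bins", "scan", "flag_disruptive",
           "write_scan_tsv", "write_flagged_bed"]

DEFAULT_WINDOW_BINS = 5
DEFAULT_STEP_BINS = 1
DEFAULT_N_PERM_SCAN = 999
DEFAULT_SD_MULTIPLIER = 1.0


def delete_bins(
    cm: ContactMatrix,
    sig: SignalTrack,
    bins: "set[int] | frozenset[int] | list[int]",
) -> tuple[ContactMatrix, SignalTrack, dict[int, int]]:
    """Remove a set of bins' interactions and signal entirely.

    Deleted rows/columns become absent (NaN) and the bins join
    ``bad_bins``; the signal entries become NaN.  Survivor bins keep their
    original indices; the returned index map sends each survivor to its
    compact position (0..n_survivors-1), deletion-order independent, so
    deleting two disjoint sets in either order equals deleting their union.
    The anchor bin may never be deleted.
    """
    bins = frozenset(int(b) for b in bins)
    n = cm.region.n_bins
    if any(b < 0 or b >= n for b in bins):
        raise ValueError("deletion bins outside the region")
    if cm.region.anchor_index in bins:
        raise ValueError("refusing to delete the anchor bin")
    vals = cm.values.copy()
    idx = sorted(bins)
    vals[idx, :] = np.nan
    vals[:, idx] = np.nan
    cm2 = ContactMatrix(region=cm.region, values=vals,
                        bad_bins=cm.bad_bins | bins,
                        transformed=cm.transformed, cutoff=cm.cutoff)
    raw = sig.raw.copy()
    raw[idx] = np.nan
    sig2 = replace(sig, raw=raw)
    survivors = [i for i in range(n) if i not in cm2.bad_bins]
    index_map = {b: k for k, b in enumerate(survivors)}
    return cm2, sig2, index_map


@dataclass
class PerturbationScan:
    """Scan output: one record per deletion window.

    ``records`` columns: window_start (bin), window_end (exclusive bin),
    start_bp, end_bp, anchor_lmi, anchor_p, in_metaloci_before, skipped.
    ``threshold`` = mean - sd_multiplier x sd of anchor_lmi over evaluated
    windows; flagged windows fall strictly below it.
    """

    gene_id: str | None
    region: LocusRegion
    window_bins: int
    step_bins: int
    records: pd.DataFrame
    baseline_lmi: float
    baseline_p: float
    sd_multiplier: float = DEFAULT_SD_MULTIPLIER
    threshold: float = np.nan
    threshold_mode: str = "scan_distribution"

    def flagged_records(self) -> pd.DataFrame:
        return self.records[self.records["flagged"]]


def scan(
    cm: ContactMatrix,
    sig: SignalTrack,
    config: PipelineConfig | None = None,
    window_bins: int = DEFAULT_WINDOW_BINS,
    step_bins: int = DEFAULT_STEP_BINS,
    n_perm_scan: int = DEFAULT_N_PERM_SCAN,
    seed: int = 1,
    sd_multiplier: float = DEFAULT_SD_MULTIPLIER,
    threshold_mode: str = "scan_distribution",
    baseline: LocusResult | None = None,
) -> PerturbationScan:
    """Slide a deletion window across the region and re-analyze each time.

    Each window gets a deterministic seed derived from ``(seed,
    window_start)``, so results are independent of evaluation order.
    ``n_perm_scan`` (default 999) keeps the ~n_bins re-analyses tractable;
    flagging relies on the LMI value, not on the per-window p.  Windows
    covering the anchor are recorded as skipped.
    """
    cfg = config or PipelineConfig()
    base_cfg = replace_config(cfg, n_perm=cfg.n_perm, seed=seed)
    if baseline is None:
        baseline = analyze_locus(cm, sig, base_cfg)
    base_entry = baseline.lmi.anchor_entry
    metaloci_bins: set[int] = set()
    for m in baseline.metaloci:
        metaloci_bins |= set(m.member_bins)

    region = cm.region
    n = region.n_bins
    anchor = region.anchor_index
    rows = []
    for ws in range(0, n - window_bins + 1, step_bins):
        we = ws + window_bins
        rec = {
            "window_start": ws, "window_end": we,
            "start_bp": region.bin_interval(ws)[0],
            "end_bp": region.bin_interval(we - 1)[1],
            "in_metaloci_before": bool(set(range(ws, we)) & metaloci_bins),
            "skipped": False, "anchor_lmi": np.nan, "anchor_p": np.nan,
        }
        if ws <= anchor < we:
            rec["skipped"] = True
            rows.append(rec)
            continue
        win_seed = int(np.random.SeedSequence(
            entropy=(int(seed), int(ws))).generate_state(1)[0] % (2**31))
        cm2, sig2, _ = delete_bins(cm, sig, set(range(ws, we)))
        win_cfg = replace_config(cfg, n_perm=n_perm_scan, seed=win_seed)
        res = analyze_locus(cm2, sig2, win_cfg)
        e = res.lmi.anchor_entry
        rec["anchor_lmi"] = float(e["lmi"])
        rec["anchor_p"] = float(e["p"])
        rows.append(rec)
    records = pd.DataFrame(rows)
    out = PerturbationScan(
        gene_id=region.gene_id, region=region, window_bins=window_bins,
        step_bins=step_bins, records=records,
        baseline_lmi=float(base_entry["lmi"]),
        baseline_p=float(base_entry["p"]),
        sd_multiplier=sd_multiplier, threshold_mode=threshold_mode,
    )
    return flag_disruptive(out, sd_multiplier=sd_multiplier,
                           threshold_mode=threshold_mode)


def replace_config(cfg: PipelineConfig, **kw) -> PipelineConfig:
    d = cfg.to_dict()
    d.update(kw)
    return PipelineConfig(**d)


def flag_disruptive(
    scan_result: PerturbationScan,
    sd_multiplier: float = DEFAULT_SD_MULTIPLIER,
    threshold_mode: str = "scan_distribution",
) -> PerturbationScan:
    """(Re)compute the disruption threshold and per-window flags.

    ``scan_distribution`` (default): flag windows whose post-deletion
    anchor LMI falls strictly below mean - sd_multiplier x sd of all
    evaluated windows' post-deletion LMI.  ``drop_from_baseline``: flag
    windows whose LMI drop from the unperturbed baseline exceeds
    sd_multiplier x sd of all drops.  Monotone: a larger multiplier never
    flags more windows.
    """
    if threshold_mode not in ("scan_distribution", "drop_from_baseline"):
        raise ValueError("threshold_mode must be 'scan_distribution' or "
                         "'drop_from_baseline'")
    rec = scan_result.records.copy()
    ok = ~rec["skipped"] & np.isfinite(rec["anchor_lmi"])
    vals = rec.loc[ok, "anchor_lmi"].to_numpy()
    if len(vals) < 10:
        warnings.warn(f"only {len(vals)} evaluated windows; the sd estimate "
                      "is unstable", stacklevel=2)
    if threshold_mode == "scan_distribution":
        mu, sd = float(vals.mean()), float(vals.std())
        threshold = mu - sd_multiplier * sd
        flagged = ok & (rec["anchor_lmi"] < threshold)
    else:
        drops = scan_result.baseline_lmi - vals
        sd = float(drops.std())
        threshold = scan_result.baseline_lmi - sd_multiplier * sd
        flagged = ok & ((scan_result.baseline_lmi - rec["anchor_lmi"])
                        > sd_multiplier * sd)
    if sd == 0:
        flagged = flagged & False
    rec["flagged"] = flagged.fillna(False)
    return replace(scan_result, records=rec, threshold=float(threshold),
                   sd_multiplier=sd_multiplier, threshold_mode=threshold_mode)


# ---------------------------------------------------------------------------
# writers


def write_scan_tsv(scan_result: PerturbationScan, path) -> None:
    scan_result.records.to_csv(path, sep="\t", index=False,
                               float_format="%.10g")


def write_flagged_bed(scan_result: PerturbationScan, path) -> None:
    """Merged genomic intervals of flagged windows."""
    rec = scan_result.flagged_records().sort_values("start_bp")
    merged: list[list] = []
    for _, r in rec.iterrows():
        if merged and r["start_bp"] <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], int(r["end_bp"]))
        else:
            merged.append([int(r["start_bp"]), int(r["end_bp"])])
    name = f"{scan_result.gene_id or 'region'}|disruptive"
    with open(path, "w") as fh:
        for s, e in merged:
            fh.write(f"{scan_result.region.chrom}\t{s}\t{e}\t{name}\t0\t.\n")
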