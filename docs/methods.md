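# Methods

This note records the model, the conventions and the genuinely open
design choices behind `metalocus`, in enough detail to reproduce or
challenge any of them.

## Analysis windows

Regions are TSS-centered, 0-based half-open, snapped to the bin grid:
`start = floor(TSS/resolution)·resolution − flank`. Defaults: flank 2 Mb,
resolution 10 kb → 401 bins with the anchor (TSS bin) at index 200.
Strand is metadata only; the window is symmetric around the TSS bin.
Windows overrunning a chromosome edge are truncated and flagged rather
than rejected. GTF input (1-based) is converted on read; everything
internal is BED-convention.

## From contacts to a distance graph

Input is an already-normalized (balanced) contact matrix; no balancing is
performed here. Values are log10-transformed into scores; entries with
score below the cutoff are **absent**, not zero (ties at the cutoff are
retained; zeros and missing entries are always absent — never −∞).
Default cutoff 1.0.

**Automatic cutoff.** When asked for, the cutoff is the smallest value on
a 0.05-step grid (anchored at multiples of the step, so rescaling the
matrix by 10 shifts the choice by exactly +1) at which at most 15% of
positive off-diagonal entries survive, floored at the median score. This
is a reproducible proxy for picking the signal tail of the score
distribution; both the target density and the grid are configurable.

**Distance graph.** Retained scores *s* become target distances 1/*s*.
Consecutive present bins are additionally joined by a backbone edge of
target distance

    d_bb = 10 / (s_max · pl)

where `s_max` is the largest retained score and `pl` the persistence
length (default 10). The calibration constant makes the reference
stiffness `pl = 10` place the backbone step exactly at the
strongest-contact distance `1/s_max` — consecutive genomic bins are
assumed at least as close in space as the tightest interaction restraint.
Larger `pl` shortens the step proportionally: shortest-path target
distances become backbone-dominated and the layout straightens (the
end-to-end/contour ratio of a test chain rises monotonically to 1.0 by
`pl ≈ 1000`); smaller `pl` lets contact restraints dominate and the chain
zig-zags.

*Why not a backbone of `(1/s_max)/pl`?* That encoding makes the mean
consecutive step — and with it the 3×-step neighbor band — ten times
shorter than the shortest possible contact-derived distance at the
default stiffness. No sequence-distal bin could then ever enter a spatial
neighborhood, which contradicts the phenomenon the method exists to
detect (noncontinuous metaloci; distal enhancer hubs driving a TSS's
status) and, empirically, leaves the deletion scan sensitive only to
normalization side effects. Under the calibrated encoding, a distal
contact of score ≥ s_max/3 falls inside the default band — with the
standard cutoff of 1.0 and typical score maxima near 3, roughly the
retained-interaction range.

Bins marked bad (masked balancing weights, all-missing rows) are excluded
from the graph; the backbone is re-joined across the gap and the joins
recorded. Upstream coverage-based masking is the matrix producer's job.

## Embedding and geometry

The Kamada–Kawai stress over weighted-shortest-path target distances is
minimized (networkx implementation) from a deterministic circular-by-
genomic-order initialization; no randomness is consumed. Because the
optimizer normalizes its output to a unit box, coordinates are rescaled
by the closed-form stress-optimal global factor, restoring the solver's
own scale — an exactly embeddable input (e.g. an equilateral triangle of
target side *d*) is reproduced at side *d* to optimizer precision.
Overall scale and orientation remain arbitrary and every downstream
quantity is either scale-covariant (buffer, band) or scale-free
(neighbor sets, LMI): rigid motions leave all statistics unchanged
(asserted in tests).

Polygons: eight dummy generators on the bounding box (corners + edge
midpoints, expanded by 2× the buffer distance) guarantee every real
Voronoi cell is finite; each bin's polygon is its cell intersected with
the disk of radius 1.5 × mean-step around its point. Dummy placement is
immaterial as long as dummies lie outside all buffer disks, which the
expansion guarantees (asserted). The mean step is computed over
consecutive present-bin pairs only, skipping pairs that span masked-bin
gaps. Fewer than 3 points or collinear points are a hard error.

## Signal

Per-bin raw coverage (mean by default; sum offered for count-like
tracks) with uncovered bases counting as zero; bigWig and bedGraph
readers agree exactly on this convention. Negative inputs (possible in
control-subtracted tracks) are clamped to zero and counted. The analyzed
value is `log10(raw + 1)`; the pseudocount (on the raw scale) is
configurable and exists only to make zero coverage finite — it never
changes ranks.

## Local Moran's I and significance

Signal values are centered and scaled by the population standard
deviation; scaling does not affect quadrants or p-values but makes LMI
magnitudes comparable across loci, which the volcano threshold |LMI| > 1
requires. With binary distance-band weights (band = 3 × mean step, ties
at the boundary included — this yields ≥ 2 up- and downstream neighbors
on a regular chain), the lag is the plain mean of neighbor z, LMI the
product of z and lag, and the global Moran's I the average of per-bin
LMIs (identity asserted to 1e-10). Constant signal yields all-zero LMI
with undefined quadrants; isolated bins (empty neighbor set) get
undefined lag and are excluded from calls.

**Permutation test.** Conditional randomization: the focal bin's value is
held fixed and its k neighbors redrawn without replacement from the
remaining n−1 values; p = (count-as-extreme + 1)/(n_perm + 1), default
n_perm 50,000, fully seeded and bit-reproducible. "As extreme" is
**two-sided on the magnitude** by default: |permuted| ≥ |observed|. The
directional convention (counting one tail in the direction of the
observed sign) is available as an option, but it is a two-tailed
selection at α per tail and rejects ≈ 2α under an i.i.d. null (measured
≈ 0.11–0.12 at α = 0.05), whereas the magnitude rule is calibrated
(measured 0.04–0.05 over 4,000 null bins). A "maximal cardinality" mode
divides every lag by the maximum neighbor count rather than the per-bin
count; since that denominator is constant per bin it provably yields the
same p-values as the per-bin mode, and both are kept only for interface
completeness. An opt-in linearity mode excludes bins within a
configurable sequence distance (default 3 bins) of the focal bin from
the permutation pool, discounting purely linear signal continuity; it is
off by default because linear runs of enhancer signal are biology, not
confounding. Significance is per-bin at α = 0.05 with no multiple-testing
correction (the method's convention); Benjamini–Hochberg is available
off by default.

**Metaloci.** Cores are connected components of significant same-quadrant
bins under the spatial neighbor graph (spatial, not sequence,
contiguity); halos are their direct neighbors. Exported genomic intervals
merge member bins and may be discontinuous in sequence.

## Volcano plane and transitions

u = LMI with sign flipped for LH/LL; v = −log10(p) with sign flipped for
HL/LL; HH therefore sits at (+,+) and LL at (−,−). A point is
volcano-significant when |u| > 1.0 and |v| > 1.3 (p < 0.05). The axis
orientation for HL/LH is a convention — those points cluster near the
origin and their corner assignment carries no interpretation. A gene
transition between two states has length ‖Δ(u,v)‖₂ and sign
sign(Δu + Δv): +1 toward the HH corner, −1 toward LL, 0 for an exactly
lateral move. Undefined quadrants (constant signal) map to the origin,
flagged.

## Deletion scan

Window default 5 bins (50 kb), step 1 bin. Deletion removes the bins'
rows/columns and signal (absent, not zeroed); survivors keep their
original indices, so deleting disjoint sets commutes. The layout,
weights and statistics are recomputed per window (a deletion changes the
geometry, so reusing the unperturbed layout would understate its
effect); each window's permutation seed derives from (master seed,
window start), making results order-independent and reproducible. Scan
permutations default to 999 — flagging uses the LMI value, not p, and
~400 full re-analyses per gene must stay tractable; the full 50,000 is
one config field away. Windows covering the anchor are skipped (deleting
the gene's own bin tests nothing regulatory). Flagging: post-deletion
anchor LMI < mean − m·sd of all evaluated windows (m default 1.0); an
alternative mode flags drops from the unperturbed baseline exceeding
m·sd of all drops. With zero spread nothing is flagged; below 10 windows
the sd is declared unstable.

## Synthetic loci

The generator emulates exactly two features real data force on the
method: power-law contact decay `c_ij ∝ (|i−j|+1)^(−1)` and a planted
hub — a bin set with multiplicatively enriched mutual contacts (default
×5) and elevated signal (default 50 vs background 5, Poisson-jittered).
Contact magnitude is anchored to a fixed genomic reference — contacts at
25 bins (250 kb) separation score exactly at the 1.0 cutoff — because
decay magnitude is a property of the data, not of the analysis window;
the filter is thereby exercised identically at any region width.
Multiplicative log-normal noise (CV default 0.2) is applied
symmetrically; everything is a deterministic function of the seed, and
the planted truth is written as a JSON sidecar.

Not emulated: TADs and insulation structure, loop-extrusion stripes,
coverage biases surviving normalization, replicate variability, and
signal that correlates with contacts for reasons other than the planted
hub. Passing tests therefore demonstrate that the statistics recover
planted spatial structure under realistic decay and noise — not that any
particular biological locus will show one.

Default test scales: 101-bin loci for unit and scan tests (the scan
re-analyzes ~92 windows per locus), the standard 401-bin window for
hub-recovery checks, 9,999–50,000 permutations where p-value resolution
matters and 199–999 where only the statistic's value is consumed.

## Known limitations

- The backbone encoding and automatic-cutoff rule are documented
  policies, not reconstructions of any other implementation; results are
  comparable across runs of this package, not across tools.
- The two-sided permutation convention is more conservative for hub
  bins than the directional one; hub calls here may be a strict subset
  of a directional analysis at the same α.
- The deletion scan removes data; it does not model re-ligation or new
  contacts across the deleted gap.
- cooler support covers single-resolution files (and `.mcool` via group
  URIs) with optional balancing weights; Juicer `.hic` files must be
  converted upstream.
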