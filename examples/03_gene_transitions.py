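"""Track a gene between two biological states in the volcano plane.

Each state gives the gene's anchor bin (the TSS bin) a point (u, v):
u is the LMI score with sign flipped for LH/LL quadrants, v the signed
-log10(p) — HH sits at (+, +), LL at (-, -).  The gene transition is the
Euclidean displacement between states; positive sign points toward the HH
corner (hub gain), negative toward LL (hub loss).
"""

import metalocus as ml
from metalocus.dynamics import volcano_from_table

cfg = ml.PipelineConfig(n_perm=999, seed=1)

# state A: the anchor sits inside an active hub; state B: hub dissolved
hub_a = ml.HubSpec(member_bins=tuple(range(46, 56)), anchor_in_hub=True)
cm_a, sig_a, _ = ml.make_locus(seed=5, hubs=[hub_a])
cm_b, sig_b, _ = ml.make_locus(seed=5, hubs=[])

point_a = volcano_from_table(ml.analyze_locus(cm_a, sig_a, cfg).lmi)
point_b = volcano_from_table(ml.analyze_locus(cm_b, sig_b, cfg).lmi)

for name, p in [("hub state", point_a), ("no-hub state", point_b)]:
    print(f"{name}: (u, v) = ({p.u:+.2f}, {p.v:+.2f})  quadrant={p.quadrant} "
          f"volcano-significant={p.significant_volcano}")

t = ml.gene_transition(point_a, point_b, gene_id="geneS")
print(f"transition length {t.length:.2f} (arbitrary units), sign {t.sign:+d} "
      f"-> signed transition {t.signed_length:+.2f}")
print("negative sign = the gene moved toward the LL corner: it lost its hub")
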