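"""Call 3D regulatory hubs (metaloci) on a synthetic locus.

Generates a 101-bin locus (10-kb bins) whose contacts decay with distance
except for a planted 8-bin hub with 5x enriched interactions and elevated
signal, then runs the full analysis: log/cutoff filtering, 2D embedding,
distance-band weights, Local Moran's I with permutation significance, and
metalocus calling.
"""

import metalocus as ml

hub = ml.HubSpec(member_bins=tuple(range(60, 68)))
cm, sig, truth = ml.make_locus(seed=3, hubs=[hub])

res = ml.analyze_locus(cm, sig, ml.PipelineConfig(n_perm=999, seed=1))

table = res.lmi.table
n_sig = int(table["significant"].sum())
print(f"{res.layout.n} bins analyzed; {n_sig} significant at "
      f"alpha={res.config.alpha}")
print(f"planted hub bins: {truth['hubs'][0]['member_bins']}")
for m in res.metaloci:
    print(f"called {m.quadrant} metalocus: core={m.core_bins}")
    print(f"  genomic intervals: {m.genomic_intervals}")

# Per-bin detail for the hub: z (normalized signal), lag (neighborhood
# mean), their product LMI, and the permutation pseudo p-value.  HH means
# a high-signal bin in a high-signal spatial neighborhood — a hub member.
cols = ["bin", "z", "lag", "lmi", "quadrant", "p"]
print(table[table["bin"].isin(hub.member_bins)][cols].to_string(index=False))
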