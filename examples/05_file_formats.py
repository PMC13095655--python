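"""Write a locus in standard formats and show the readers agree.

Contacts go to a single-resolution cooler file (with balancing weights)
and to dense/COO TSV; signal goes to bedGraph and bigWig.  All readers
return the same in-memory objects, so the downstream statistics are
identical whichever encoding a dataset arrives in.
"""

import tempfile

import numpy as np

import metalocus as ml
from metalocus.contacts import load_cool_matrix, load_dense_tsv
from metalocus.signals import bin_signal

cm, sig, truth = ml.make_locus(seed=5,
                               hubs=[ml.HubSpec(member_bins=tuple(range(30, 36)))])

with tempfile.TemporaryDirectory() as tmp:
    paths = ml.write_fixture(cm, sig, truth, tmp,
                             formats=("cool", "dense_tsv", "bedgraph",
                                      "bigwig", "json"))
    for fmt, p in paths.items():
        print(f"wrote {fmt:>10}: {p.name}")

    cool = load_cool_matrix(paths["cool"], cm.region)
    dense = load_dense_tsv(paths["dense_tsv"], cm.region)
    print("cooler == in-memory matrix:",
          bool(np.allclose(cool.values, cm.values, rtol=1e-12)))
    print("dense TSV == cooler:",
          bool(np.allclose(dense.values, cool.values, rtol=1e-12, equal_nan=True)))

    s_bg = bin_signal(paths["bedgraph"], cm.region)
    s_bw = bin_signal(paths["bigwig"], cm.region)
    print("bedGraph == bigWig coverage:",
          bool(np.allclose(s_bg.raw, s_bw.raw, rtol=1e-6)))
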