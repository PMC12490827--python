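"""Show how footprint width determines its label.

Noise-free fixtures carry a single protected stretch of exact width on a
1 bp cytosine grid; detection on each shows where the TF (5-75 bp),
unclassified (76-120 bp) and nucleosome (>120 bp) classes begin and end.
"""

import numpy as np

import fpcharter as fp

print("width_bp\tlabel")
for width in (4, 5, 20, 75, 76, 120, 121, 150):
    calls, region = fp.make_boundary_fixture(width=width, spacing=1, n_molecules=10)
    mat = fp.read_meth_calls(calls, region)
    clusters = fp.ClusterResult(
        assignments=np.ones(mat.n_molecules, dtype=int),
        medoids=np.array([0]),
        k_requested=1,
        k_final=1,
    )
    (footprint,) = fp.detect_all(mat, clusters)
    print(f"{width}\t{footprint.label}")
print("-> stretches under 5 bp are noise artifacts; 5-75 bp is the TF range; "
      "above 120 bp the stretch is wide enough to be a nucleosome")
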