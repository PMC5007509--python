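"""Principal-coordinates view of the published distance matrix.

Classical scaling of the 16-population Nei DA matrix; the first two
axes give the familiar two-dimensional population scatter.
"""

import strpop as sp

res = sp.pcoa(sp.load_nei_da_matrix(), k=2)
print("explained variance:",
      ", ".join(f"{f:.1%}" for f in res.proportion_explained), "\n")
print(res.coordinates.round(4).to_string())
print("\nPopulations close in the plot are genetically similar; the "
      "highland/East-Asian samples and the lowlander Indian samples "
      "separate along the leading axes.")
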