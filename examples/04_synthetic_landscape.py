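"""Synthetic landscape bundle: rasters the enrollment model runs on.

Generates the default desk-scale landscape and prints its structure; the
bundle can be written to ESRI ASCII grids for exchange.
"""

import numpy as np

from fallowsim import LandUse, LandscapeConfig, generate_landscape

ls = generate_landscape(LandscapeConfig(), seed=1)
n = ls.landuse.size
print(f"grid {ls.shape[0]}x{ls.shape[1]} at {ls.cell_size:.0f} m, "
      f"{ls.n_parcels} parcels")
for code in LandUse:
    frac = (ls.landuse == code).sum() / n
    print(f"  {code.name:<8s} {frac:6.1%}")
print(f"soil rental rate: {ls.srr.min():.0f}-{ls.srr.max():.0f} $/acre/yr")
print(f"benefit-index range: {ls.ebi_layers.min():.0f}-{ls.ebi_layers.max():.0f} points")
corr = np.corrcoef(ls.ebi_layers.reshape(6, -1))[np.triu_indices(6, 1)]
print(f"EBI layer correlations: {corr.min():.2f}-{corr.max():.2f}")
# ls.save("landscape_bundle")  # writes .asc rasters + manifest.json
# The six benefit layers are alternative composite scorings of the same
# terrain; their positive correlation mirrors real composite surfaces.
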