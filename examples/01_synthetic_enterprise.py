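"""Generate a synthetic forest enterprise and inspect its heterogeneity.

Builds the default 24-unit enterprise (areas 5,500-19,000 ha, smooth
climate gradients, per-species site indices) and prints the unit table plus
the site-index spread that drives the spatial diversification results.
"""

import numpy as np

from forestfolio import generate_enterprise
from forestfolio.synthetic import SPECIES

enterprise = generate_enterprise(n_units=24, region_side=250.0, seed=0)
frame = enterprise.to_frame()
print(frame.round(2).to_string(index=False))
print(f"\ntotal area: {enterprise.total_area:,.0f} ha across {len(enterprise.units)} units")
for sp in SPECIES:
    si = np.array([u.site_index[sp] for u in enterprise.units])
    print(f"site index {sp:12s} {si.min():5.1f} - {si.max():5.1f} m "
          f"({si.max() / si.min():.1f}-fold spread)")
print(
    "\nNeighbouring units share similar climate covariates, so productivity"
    "\nand survival vary smoothly in space - the raw material for"
    "\ndiversification across planning units."
)
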