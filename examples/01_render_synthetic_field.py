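"""Render a synthetic two-channel micrograph with ground truth.

Builds a field of non-touching elliptical T-cell-like objects whose CD44
channel carries a polarized membrane cap (von Mises kappa = 4 at each
cell's own rear pole) and whose LFA-1 channel is nearly uniform, then
prints the per-cell truth table. The mask and truth values are what every
downstream example measures itself against.
"""

import numpy as np

from polarscore import random_field_spec, render_field

rng = np.random.default_rng(0)
spec = random_field_spec(rng, n_cells=8, field_id="demo")
field, mask, truth = render_field(spec, rng)

print(f"field {field.field_id}: shape {field.shape}, channels {field.channel_names}")
print(f"ground-truth mask: {mask.max()} cells, {int((mask > 0).sum())} foreground px")
print(truth[["cell_label", "center_row", "center_col", "semi_a", "semi_b",
             "kappa_cd44", "kappa_lfa1"]].round(1).to_string(index=False))
# kappa_cd44 = 4 on every cell: each CD44 stain is a tight cap at the cell's
# rear pole; kappa_lfa1 = 1: LFA-1 is spread almost uniformly around the ring.
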