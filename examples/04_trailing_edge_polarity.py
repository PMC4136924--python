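"""Call trailing-edge localization of a marker, as in uropod biology.

CD44 marks the uropod (rear) of a migrating T cell, so the axis from a
cell's geometric centroid toward its CD44-weighted centroid points rear.
A marker (here an idealized low-affinity LFA-1 surface stain) is called
trailing-edge localized when >= 60% of its in-cell signal falls in the
rear half-plane. Rear-capped and front-capped populations separate cleanly.
"""

import numpy as np

from polarscore import classify_field, random_field_spec, render_field

for mode in ("rear", "front"):
    rng = np.random.default_rng(11)
    spec = random_field_spec(
        rng, n_cells=12,
        channel_stains={"cd44": {"kappa": 4.0, "mu": "rear"},
                        "lfa1_2d7": {"kappa": 8.0, "mu": mode,
                                     "amplitude": 80.0, "cytoplasm": 8.0}},
    )
    field, mask, _ = render_field(spec, rng)
    calls, summary = classify_field(field, mask, reference_channel="cd44",
                                    marker_channel="lfa1_2d7", threshold=0.6)
    ev = calls[calls.excluded_reason == ""]
    print(f"{mode}-capped marker: {summary['n_localized']}/{summary['n_evaluable']} "
          f"cells localized (mean rear fraction {ev.rear_fraction.mean():.2f})")
# rear-capped cells -> rear fraction ~0.8, all called localized;
# front-capped cells -> ~0.2, none called localized.
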