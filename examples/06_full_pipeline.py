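"""End-to-end run: simulate two conditions, segment, score, compare.

The "wt_like" condition carries a tight CD44 uropod cap (kappa = 4), the
"mutant_like" condition only a weak one (kappa = 1) — a polarized versus
polarization-defective contrast. The pipeline writes CSVs plus a JSON
summary with the per-channel two-group comparison (Shapiro-Wilk-branched
Student's t or Mann-Whitney).
"""

import json
import tempfile
from pathlib import Path

from polarscore import run_pipeline

config = {
    "simulate": {"n_fields": 2, "cells_per_field": 12, "tracks_per_condition": 30},
    "analysis": {"reference_channel": "cd44", "marker_channel": "lfa1",
                 "polarity_threshold": 0.6, "dt": 10.0, "pixel_size": 1.0},
}

with tempfile.TemporaryDirectory() as tmp:
    summary = run_pipeline(config, Path(tmp) / "results", seed=1)
    print(f"cells scored: {summary['n_cells_scored']}")
    for cmp in summary["clustering_comparisons"]:
        print(f"  {cmp['channel']}: {cmp['group_b']} vs {cmp['group_a']} -> "
              f"{cmp['test_used']}, p = {cmp['p_value']:.3g}")
    print("polarity:", json.dumps(summary["polarity"]))
# cd44 separates the conditions (wt_like cells cluster CD44 strongly);
# lfa1 (kappa = 1 in both) does not.
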