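"""Trailing-edge marker localization.

A migrating lymphocyte is polarized: CD44 accumulates in the uropod (the
trailing projection), so the vector from a cell's geometric centroid toward
the CD44 intensity-weighted centroid points to the rear. Given that rear
axis, a second marker (for example the low-affinity LFA-1 conformation
stained by clone 2D7) is called "trailing-edge localized" when the fraction
of its in-cell signal falling in the rear half-plane exceeds a threshold
(default 0.6). Pixels exactly on the dividing line count half to each side,
which makes rear_fraction(axis) + rear_fraction(-axis) = 1.

The rear axis can instead come from a matched migration track (rear =
opposite of net motion) or be supplied directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import CellRegion, extract_regions
from .io import Field
from .tracks import Track

__all__ = [
    "PolarityCall",
    "UndefinedAxisError",
    "polarity_axis",
    "axis_from_track",
    "rear_fraction",
    "classify_field",
]

MIN_AXIS_OFFSET = 0.5  # px; below this the reference offset is noise, axis undefined
DEFAULT_THRESHOLD = 0.6


class UndefinedAxisError(ValueError):
    """Reference-channel centroid indistinguishable from the geometric centroid."""


@dataclass
class PolarityCall:
    cell_label: int
    axis: tuple[float, float]  # unit vector (row, col), pointing to the rear
    axis_source: str  # "reference_channel" | "motion" | "user"
    rear_fraction: float
    localized: bool


def polarity_axis(field: Field, region: CellRegion, reference_channel: str) -> np.ndarray:
    """Unit (row, col) vector from geometric centroid toward the reference
    channel's intensity-weighted centroid; points to the cell's rear when the
    reference marks the uropod.

    Raises :class:`UndefinedAxisError` when the offset is below half a pixel
    (e.g. a uniformly stained, unpolarized cell).
    """
    intensities = field.channel(reference_channel)[region.pixel_index]
    total = intensities.sum()
    if total <= 0:
        raise UndefinedAxisError(f"cell {region.label}: zero reference signal")
    geo = np.asarray(region.centroid)
    weighted = (region.pixels * intensities[:, None]).sum(axis=0) / total
    offset = weighted - geo
    norm = float(np.hypot(*offset))
    if norm < MIN_AXIS_OFFSET:
        raise UndefinedAxisError(
            f"cell {region.label}: reference offset {norm:.3f} px < {MIN_AXIS_OFFSET}"
        )
    return offset / norm


def axis_from_track(track: Track) -> np.ndarray:
    """Rear axis from motion: the unit vector opposite the net displacement.

    Track coordinates are (x, y) = (col, row); the returned axis is (row, col).
    """
    dx = track.x[-1] - track.x[0]
    dy = track.y[-1] - track.y[0]
    norm = float(np.hypot(dx, dy))
    if norm == 0:
        raise UndefinedAxisError(f"track {track.track_id!r}: zero net motion")
    return np.array([-dy, -dx]) / norm


def rear_fraction(
    field: Field, region: CellRegion, axis: np.ndarray, marker_channel: str
) -> float:
    """Fraction of the marker's in-cell signal in the rear half-plane.

    The region is split by the line through its geometric centroid
    perpendicular to ``axis``; "rear" is the side the axis points to. Pixels
    with signed distance exactly zero contribute half their intensity to
    each side.
    """
    axis = np.asarray(axis, dtype=float)
    marker = field.channel(marker_channel)[region.pixel_index]
    total_pos = marker.sum()
    if total_pos <= 0:
        raise ValueError(f"cell {region.label}: zero total marker signal")
    d = (region.pixels - np.asarray(region.centroid)) @ axis
    rear = marker[d > 0].sum()
    on_line = marker[d == 0].sum()
    front = marker[d < 0].sum()
    total = rear + front + on_line
    return float((rear + 0.5 * on_line) / total)


def classify_field(
    field: Field,
    mask: np.ndarray,
    reference_channel: str,
    marker_channel: str,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    regions: list[CellRegion] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-cell trailing-edge calls plus the per-field summary fraction.

    Returns (table, summary). The table has one row per cell, including
    excluded ones (reason codes ``undefined_axis`` / ``no_marker_signal``).
    summary = {"n_evaluable", "n_localized", "n_excluded", "fraction_localized"};
    the fraction is NaN when no cell is evaluable.
    """
    if regions is None:
        regions = extract_regions(mask, field)
    rows = []
    n_loc = n_eval = 0
    for region in regions:
        base = {"field_id": field.field_id, "cell_label": region.label}
        try:
            axis = polarity_axis(field, region, reference_channel)
        except UndefinedAxisError:
            rows.append({**base, "axis_row": np.nan, "axis_col": np.nan,
                         "rear_fraction": np.nan, "localized": pd.NA,
                         "excluded_reason": "undefined_axis"})
            continue
        try:
            rf = rear_fraction(field, region, axis, marker_channel)
        except ValueError:
            rows.append({**base, "axis_row": axis[0], "axis_col": axis[1],
                         "rear_fraction": np.nan, "localized": pd.NA,
                         "excluded_reason": "no_marker_signal"})
            continue
        loc = rf >= threshold
        n_eval += 1
        n_loc += int(loc)
        rows.append({**base, "axis_row": axis[0], "axis_col": axis[1],
                     "rear_fraction": rf, "localized": loc, "excluded_reason": ""})
    cols = ["field_id", "cell_label", "axis_row", "axis_col",
            "rear_fraction", "localized", "excluded_reason"]
    table = pd.DataFrame(rows, columns=cols)
    summary = {
        "n_evaluable": n_eval,
        "n_localized": n_loc,
        "n_excluded": len(regions) - n_eval,
        "fraction_localized": (n_loc / n_eval) if n_eval else float("nan"),
    }
    return table, summary
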