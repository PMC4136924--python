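"""Per-cell receptor clustering index.

The statistic asks how spatially concentrated the brightest signal inside a
cell is. For each cell and channel, the top decile of pixels by intensity is
selected and its mean pairwise Euclidean distance is computed (``D_alpha``).
That raw distance is normalized between two reference configurations of the
same number of points n:

* ``S_l`` — n points packed row-major into a ``ceil(sqrt(n))``-sided square
  lattice block: the maximally clustered arrangement (for n = 100 this is a
  10 x 10 pixel square);
* ``S_u`` — n points spread at equal arclength intervals along the cell's
  outer boundary: the maximally dispersed, perimeter-uniform arrangement.

The clustering index is ``ci = (S_u - D_alpha) / (S_u - S_l)``: about 1 for
a tight cap of signal, about 0 for signal smeared uniformly around the
membrane. The value is deliberately not clipped; excursions outside [0, 1]
(possible for unusual geometries) are flagged, not hidden.

All selection rules are deterministic, including tie-breaks, so a given
image always produces the same score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .detect import CellRegion, contour_step_lengths
from .io import Field

__all__ = [
    "ClusteringResult",
    "mean_pairwise_distance",
    "select_top_decile",
    "packed_square_bound",
    "perimeter_scatter_bound",
    "perimeter_scatter_points",
    "clustering_index",
    "score_field",
]

MIN_REGION_AREA = 20  # below this the top decile cannot hold 2 distinct pixels sensibly
TOP_FRACTION = 0.10


@dataclass
class ClusteringResult:
    cell_label: int
    channel: str
    n: int
    selected_pixels: np.ndarray
    d_alpha: float
    s_l: float
    s_u: float
    ci: float
    flag: str = ""  # "" ok; "ci_out_of_range" when ci outside [0, 1]


def mean_pairwise_distance(points: np.ndarray) -> float:
    """Mean Euclidean distance over all n(n-1)/2 unordered pairs of points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if np.unique(pts, axis=0).shape[0] < 2:
        raise ValueError("need at least 2 distinct points")
    return float(pdist(pts).mean())


def select_top_decile(
    channel: np.ndarray, region: CellRegion, fraction: float = TOP_FRACTION
) -> np.ndarray:
    """Coordinates of the brightest ``max(2, round(fraction * area))`` pixels.

    Ties at the cut intensity are resolved deterministically: higher
    intensity first, then (row, col) lexicographic order.
    """
    if region.area < MIN_REGION_AREA:
        raise ValueError(f"region {region.label}: area {region.area} < {MIN_REGION_AREA}")
    n = max(2, int(math.floor(fraction * region.area + 0.5)))
    coords = region.pixels
    vals = channel[coords[:, 0], coords[:, 1]]
    # lexsort: last key is primary -> (-intensity, row, col)
    order = np.lexsort((coords[:, 1], coords[:, 0], -vals))
    return coords[order[:n]]


@lru_cache(maxsize=4096)
def _packed_square(n: int) -> float:
    s = math.isqrt(n - 1) + 1  # ceil(sqrt(n))
    pts = np.array([(k // s, k % s) for k in range(n)], dtype=float)
    return float(pdist(pts).mean())


def packed_square_bound(n: int) -> float:
    """``S_l``: mean pairwise distance of n unit-spaced lattice points filling,
    row-major, a square block of side ``ceil(sqrt(n))``. The most-clustered
    reference; for n = 100 it is exactly the 10 x 10 square."""
    if n < 2:
        raise ValueError("need n >= 2")
    return _packed_square(int(n))


def perimeter_scatter_points(region: CellRegion, n: int) -> np.ndarray:
    """n contour pixels at (as close as the lattice allows) equal arclength.

    Arclength along the closed Moore contour uses step lengths 1 and sqrt(2)
    for lateral and diagonal steps. Target positions k*L/n (k = 0..n-1,
    starting at the canonical contour start) are snapped to the nearest
    contour vertex in the circular arclength metric; collisions advance to
    the next unused vertex, so the n points are always distinct.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    contour = region.boundary
    m = contour.shape[0]
    if m < n:
        raise ValueError(f"region {region.label}: boundary has {m} steps < n = {n}")
    steps = contour_step_lengths(contour)
    arc = np.concatenate([[0.0], np.cumsum(steps[:-1])])  # arclength at each vertex
    total = float(steps.sum())
    targets = np.arange(n) * total / n
    used: set[int] = set()
    idx: list[int] = []
    for t in targets:
        d = np.abs(arc - t)
        d = np.minimum(d, total - d)  # circular distance
        # earliest vertex within a hair of the minimum: a tie rule that does
        # not depend on float summation order
        j = int(np.nonzero(d <= d.min() + 1e-6)[0][0])
        while j in used:
            j = (j + 1) % m
        used.add(j)
        idx.append(j)
    return contour[np.array(idx)]


def perimeter_scatter_bound(region: CellRegion, n: int) -> float:
    """``S_u``: mean pairwise distance of n points uniformly scattered (at
    equal arclength) along the cell's outer boundary. The most-dispersed
    reference. Deterministic — no random placement."""
    return mean_pairwise_distance(perimeter_scatter_points(region, n))


def clustering_index(
    channel: np.ndarray, region: CellRegion, fraction: float = TOP_FRACTION, channel_name: str = ""
) -> ClusteringResult:
    """Full per-cell clustering score for one channel.

    ci = (S_u - D_alpha) / (S_u - S_l); 1 = maximally packed, 0 =
    perimeter-uniform; values outside [0, 1] are kept and flagged.
    """
    sel = select_top_decile(channel, region, fraction)
    n = sel.shape[0]
    d_alpha = mean_pairwise_distance(sel)
    s_l = packed_square_bound(n)
    s_u = perimeter_scatter_bound(region, n)
    if not s_l < s_u:
        raise ValueError(
            f"region {region.label}: degenerate bounds s_l={s_l:.3f} >= s_u={s_u:.3f}"
        )
    ci = (s_u - d_alpha) / (s_u - s_l)
    flag = "" if 0.0 <= ci <= 1.0 else "ci_out_of_range"
    return ClusteringResult(
        cell_label=region.label,
        channel=channel_name,
        n=n,
        selected_pixels=sel,
        d_alpha=d_alpha,
        s_l=s_l,
        s_u=s_u,
        ci=ci,
        flag=flag,
    )


def score_field(
    field: Field,
    mask: np.ndarray,
    channels: list[str] | None = None,
    *,
    regions: list[CellRegion] | None = None,
    fraction: float = TOP_FRACTION,
) -> pd.DataFrame:
    """Score every (cell, channel) pair in a field.

    Returns one row per pair with columns field_id, cell_label, channel, n,
    d_alpha, s_l, s_u, ci, flag. Cells failing a precondition (too small,
    boundary shorter than n) are recorded with a reason code in ``flag`` and
    NaN statistics rather than silently dropped.
    """
    from .detect import extract_regions

    channels = channels or field.channel_names
    for ch in channels:
        field.channel(ch)  # raises on absent channel
    if regions is None:
        regions = extract_regions(mask, field)
    rows = []
    for region in regions:
        for ch in channels:
            base = {"field_id": field.field_id, "cell_label": region.label, "channel": ch}
            if region.area < MIN_REGION_AREA:
                rows.append({**base, "n": 0, "d_alpha": np.nan, "s_l": np.nan,
                             "s_u": np.nan, "ci": np.nan, "flag": "too_small"})
                continue
            try:
                res = clustering_index(field.channel(ch), region, fraction, channel_name=ch)
            except ValueError as exc:
                reason = "short_boundary" if "boundary" in str(exc) else "degenerate"
                rows.append({**base, "n": 0, "d_alpha": np.nan, "s_l": np.nan,
                             "s_u": np.nan, "ci": np.nan, "flag": reason})
                continue
            rows.append({**base, "n": res.n, "d_alpha": res.d_alpha, "s_l": res.s_l,
                         "s_u": res.s_u, "ci": res.ci, "flag": res.flag})
    cols = ["field_id", "cell_label", "channel", "n", "d_alpha", "s_l", "s_u", "ci", "flag"]
    return pd.DataFrame(rows, columns=cols)
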