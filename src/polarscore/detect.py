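"""Single-cell detection in fluorescence fields.

Classical threshold-and-components segmentation: Gaussian smoothing, global
Otsu threshold, hole filling, 8-connected labeling, then filters on area,
solidity and border contact. Touching cells are not split — low-solidity
clumps are rejected outright, so only singly detected cells reach the
downstream per-cell statistics.

The outer boundary of each region is traced at pixel resolution with
Moore-neighbor tracing (clockwise, starting at the topmost-then-leftmost
boundary pixel), which gives the ordered closed contour the perimeter
scatter bound needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import relabel_sequential

from .io import Field

__all__ = [
    "DetectionParams",
    "CellRegion",
    "segment_field",
    "extract_regions",
    "moore_trace",
    "contour_step_lengths",
]

_EIGHT = np.ones((3, 3), dtype=int)

# Moore neighborhood in clockwise order on screen (row down, col right):
# E, SE, S, SW, W, NW, N, NE
_RING = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
_RING_INDEX = {off: i for i, off in enumerate(_RING)}


@dataclass
class DetectionParams:
    """Segmentation knobs; every filter the detector applies is exposed here."""

    detection_channel: str = "sum"
    min_area: int = 200
    max_area: int = 10000
    min_solidity: float = 0.7
    exclude_border: bool = True
    smoothing_sigma: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.min_area < self.max_area):
            raise ValueError("need 0 < min_area < max_area")
        if not (0 < self.min_solidity <= 1):
            raise ValueError("need 0 < min_solidity <= 1")


@dataclass
class CellRegion:
    """One detected cell: pixel set, ordered outer contour, shape descriptors."""

    label: int
    pixels: np.ndarray  # (N, 2) int (row, col), lexicographically sorted
    boundary: np.ndarray  # (M, 2) int, ordered closed contour (first != last)
    centroid: tuple[float, float]
    area: int
    major_axis: float
    minor_axis: float
    elongation: float
    touches_border: bool

    @property
    def pixel_index(self) -> tuple[np.ndarray, np.ndarray]:
        """Fancy-index tuple for pulling this region's pixels from an image."""
        return self.pixels[:, 0], self.pixels[:, 1]


def segment_field(field: Field, params: DetectionParams | None = None) -> np.ndarray:
    """Segment one field into a label mask (0 background, 1..K cells).

    Deterministic: smoothing -> Otsu -> fill holes -> 8-connected components
    -> area/solidity/border filters -> sequential relabel. An image where no
    component survives yields an empty mask with a warning; a constant image
    (no threshold definable) is an error.
    """
    params = params or DetectionParams()
    if params.detection_channel == "sum":
        img = field.sum_channel()
    else:
        img = field.channel(params.detection_channel)
    if img.max() == img.min():
        raise ValueError("constant detection image: no threshold definable")
    smoothed = gaussian(img, sigma=params.smoothing_sigma, preserve_range=True)
    thresh = threshold_otsu(smoothed)
    binary = ndi.binary_fill_holes(smoothed > thresh)
    labeled, n = ndi.label(binary, structure=_EIGHT)

    keep = np.zeros(n + 1, dtype=bool)
    h, w = labeled.shape
    for prop in regionprops(labeled):
        ok = params.min_area <= prop.area <= params.max_area
        ok = ok and prop.solidity >= params.min_solidity
        if ok and params.exclude_border:
            r0, c0, r1, c1 = prop.bbox
            ok = r0 > 0 and c0 > 0 and r1 < h and c1 < w
        keep[prop.label] = ok
    labeled[~keep[labeled]] = 0
    relabeled, _, _ = relabel_sequential(labeled)
    if relabeled.max() == 0:
        warnings.warn("segmentation kept zero cells", stacklevel=2)
    return relabeled.astype(np.int32)


def moore_trace(binary: np.ndarray) -> np.ndarray:
    """Ordered clockwise outer contour of a connected foreground region.

    Starts at the topmost-then-leftmost foreground pixel. For one-pixel-wide
    arms the path legitimately revisits pixels; the returned array is the
    closed path with the start pixel listed once. Termination uses Jacob's
    criterion (re-entering the start pixel from the initial direction).
    """
    rows, cols = np.nonzero(binary)
    if rows.size == 0:
        raise ValueError("empty region")
    order = np.lexsort((cols, rows))
    start = (int(rows[order[0]]), int(cols[order[0]]))
    if rows.size == 1:
        return np.array([start])

    fg = set(zip(rows.tolist(), cols.tolist()))
    backtrack = (start[0], start[1] - 1)  # west neighbor is background by start choice
    contour = [start]
    p, b = start, backtrack
    first_state = None
    for _ in range(8 * rows.size + 8):
        off_b = (b[0] - p[0], b[1] - p[1])
        k = _RING_INDEX[off_b]
        nxt = None
        for step in range(1, 9):
            off = _RING[(k + step) % 8]
            q = (p[0] + off[0], p[1] + off[1])
            if q in fg:
                nxt = q
                break
            b = q  # last background neighbor examined becomes the backtrack
        if nxt is None:  # isolated pixel cluster fallback (should not happen)
            break
        state = (nxt, b)
        if first_state is None:
            first_state = state
        elif state == first_state:
            break
        p = nxt
        contour.append(p)
    # drop trailing duplicate of start, if the loop appended it before stopping
    while len(contour) > 1 and contour[-1] == start and contour[0] == start:
        contour.pop()
    return np.array(contour, dtype=np.int64)


def contour_step_lengths(contour: np.ndarray) -> np.ndarray:
    """Step lengths along the closed contour (1 for 4-neighbor, sqrt2 diagonal).

    Length m for an m-vertex contour; the last entry closes the loop.
    """
    nxt = np.roll(contour, -1, axis=0)
    d = np.abs(nxt - contour)
    return np.where(d.sum(axis=1) == 2, np.sqrt(2.0), 1.0) * (d.sum(axis=1) > 0)


def extract_regions(mask: np.ndarray, field: Field | None = None) -> list[CellRegion]:
    """Build a CellRegion per label: pixel set, traced contour, ellipse axes.

    Labels with fewer than 3 pixels cannot support a contour and are skipped
    with a warning. Ellipse axes come from second central moments; a
    degenerate (collinear) region gets elongation = inf.
    """
    if field is not None and mask.shape != field.shape:
        raise ValueError(f"mask shape {mask.shape} != field shape {field.shape}")
    regions: list[CellRegion] = []
    h, w = mask.shape
    for prop in regionprops(mask.astype(np.int32)):
        if prop.area < 3:
            warnings.warn(f"label {prop.label}: fewer than 3 pixels, skipped", stacklevel=2)
            continue
        r0, c0, r1, c1 = prop.bbox
        sub = prop.image  # binary within bbox
        contour = moore_trace(sub) + np.array([r0, c0])
        coords = prop.coords[np.lexsort((prop.coords[:, 1], prop.coords[:, 0]))]
        major = float(prop.axis_major_length)
        minor = float(prop.axis_minor_length)
        elong = major / minor if minor > 1e-12 else float("inf")
        regions.append(
            CellRegion(
                label=int(prop.label),
                pixels=coords.astype(np.int64),
                boundary=contour,
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                area=int(prop.area),
                major_axis=major,
                minor_axis=minor,
                elongation=elong,
                touches_border=bool(r0 == 0 or c0 == 0 or r1 == h or c1 == w),
            )
        )
    return regions
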