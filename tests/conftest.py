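"""Shared fixtures: small synthetic regions and fields with known geometry."""

from __future__ import annotations

import numpy as np
import pytest

from polarscore.detect import extract_regions
from polarscore.io import Field


def disk_mask(shape, center, radius, label=1):
    """Integer mask with one filled digitized disk."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    m = ((rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2).astype(np.int32)
    return m * label


def region_from_mask(mask, label=1):
    regs = [r for r in extract_regions(mask) if r.label == label]
    assert len(regs) == 1
    return regs[0]


@pytest.fixture
def disk_region():
    """A digitized disk of radius 12 (area ~450) away from the border."""
    return region_from_mask(disk_mask((64, 64), (32, 32), 12))


@pytest.fixture
def square_region():
    mask = np.zeros((20, 20), dtype=np.int32)
    mask[5:15, 5:15] = 1
    return region_from_mask(mask)


def flat_field(shape, value=1.0, channels=("ch",)):
    return Field({c: np.full(shape, float(value)) for c in channels})


def brute_mean_pairwise(points) -> float:
    """Independent double-loop oracle for the mean pairwise distance."""
    pts = np.asarray(points, dtype=float)
    total, count = 0.0, 0
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            total += float(np.hypot(*(pts[i] - pts[j])))
            count += 1
    return total / count


def oracle_perimeter_scatter(contour, n) -> float:
    """Pure-Python re-derivation of the perimeter-uniform reference distance:
    arclength accumulation, circular nearest-vertex snapping with collision
    advance, then the double-loop distance mean."""
    import math

    contour = [tuple(p) for p in contour]
    m = len(contour)
    steps = []
    for i in range(m):
        a, b = contour[i], contour[(i + 1) % m]
        steps.append(math.hypot(a[0] - b[0], a[1] - b[1]))
    total = sum(steps)
    arc = [0.0]
    for s in steps[:-1]:
        arc.append(arc[-1] + s)
    chosen = []
    for k in range(n):
        t = k * total / n
        dists = [min(abs(a - t), total - abs(a - t)) for a in arc]
        cut = min(dists) + 1e-6  # same order-insensitive tie rule as the library
        j = next(i for i, d in enumerate(dists) if d <= cut)
        while j in chosen:
            j = (j + 1) % m
        chosen.append(j)
    return brute_mean_pairwise([contour[j] for j in chosen])
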