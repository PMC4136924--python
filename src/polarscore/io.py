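"""Reading and writing the on-disk formats the pipeline touches.

Every image enters and leaves through this module so the coordinate
convention is fixed in exactly one place: arrays are indexed 0-based as
(row, col) with pixel centers at integer coordinates; the only (x, y)
surface is the track CSV boundary, where x = col and y = row.

Intensities are never rescaled or normalized on read — the clustering
statistic's top-decile selection is rank-based, but other thresholds in the
pipeline are not, so raw relative values must survive I/O.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio
from skimage.segmentation import relabel_sequential

from .tracks import Track

__all__ = [
    "Field",
    "read_field",
    "write_field",
    "read_mask",
    "write_mask",
    "read_tracks",
    "write_tracks",
]


@dataclass
class Field:
    """A multi-channel 2D fluorescence field.

    channels maps channel name -> 2D float array (all the same shape,
    finite, non-negative). pixel_size is physical length per pixel
    (arbitrary units when uncalibrated).
    """

    channels: dict[str, np.ndarray]
    pixel_size: float = 1.0
    field_id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("Field needs at least one channel")
        shapes = set()
        for name, arr in list(self.channels.items()):
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2D")
            if not np.isfinite(arr).all():
                raise ValueError(f"channel {name!r} has non-finite values")
            if (arr < 0).any():
                raise ValueError(f"channel {name!r} has negative intensities")
            self.channels[name] = arr
            shapes.add(arr.shape)
        if len(shapes) != 1:
            raise ValueError(f"channels differ in shape: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"channel {name!r} not in field (has {self.channel_names})")
        return self.channels[name]

    def sum_channel(self) -> np.ndarray:
        """Pixelwise sum over all channels (the default detection image)."""
        return np.sum(list(self.channels.values()), axis=0)


def _load_pages(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return iio.imread(path)


def read_field(path: str | os.PathLike, channel_names: list[str], *, pixel_size: float = 1.0) -> Field:
    """Read a single- or multi-page TIFF (or PNG) into a named-channel Field.

    Integer pixel data are converted to float without rescaling. A 2D file
    must be matched by exactly one channel name; a (C, H, W) stack by C names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = np.asarray(_load_pages(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected 2D pages, got array of shape {arr.shape}")
    if arr.shape[0] != len(channel_names):
        raise ValueError(
            f"{path}: {arr.shape[0]} pages but {len(channel_names)} channel names {channel_names}"
        )
    channels = {name: arr[i].astype(float) for i, name in enumerate(channel_names)}
    return Field(channels=channels, pixel_size=pixel_size, field_id=path.stem)


def write_field(field: Field, path: str | os.PathLike) -> Path:
    """Write a Field as a multi-page float64 TIFF (lossless for integer data)."""
    path = Path(path)
    stack = np.stack([field.channels[n] for n in field.channel_names]).astype(np.float64)
    tifffile.imwrite(path, stack)
    return path


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read an integer label mask; labels are relabeled to contiguous 1..K.

    Relabeling preserves the order of the original labels (e.g. {1, 3}
    becomes {1, 2}).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = np.asarray(_load_pages(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: mask must be 2D, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.floating):
        if not np.all(arr == np.round(arr)):
            raise ValueError(f"{path}: mask has non-integer values")
    mask = arr.astype(np.int32)
    if (mask < 0).any():
        raise ValueError(f"{path}: mask has negative labels")
    relabeled, _, _ = relabel_sequential(mask)
    return relabeled.astype(np.int32)


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> Path:
    """Write a label mask as 16-bit TIFF or PNG."""
    path = Path(path)
    mask = np.asarray(mask)
    if mask.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; cannot store as 16-bit")
    out = mask.astype(np.uint16)
    if path.suffix.lower() == ".png":
        iio.imwrite(path, out)
    else:
        tifffile.imwrite(path, out)
    return path


_REQUIRED_TRACK_COLS = ("track_id", "frame", "x", "y")


def read_tracks(
    path: str | os.PathLike,
    *,
    dt: float | None = None,
    pixel_size: float = 1.0,
) -> list[Track]:
    """Read a track CSV (header: track_id, frame, x, y[, dt]) into Tracks.

    Rows are sorted by frame within each track; frame gaps are allowed and
    exposed via ``Track.has_gaps``. A ``dt`` column (constant per file) or
    the ``dt`` argument supplies the frame interval; the argument wins.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_TRACK_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df[["x", "y"]].isna().any().any():
        raise ValueError(f"{path}: non-numeric or missing coordinates")
    dup = df.duplicated(subset=["track_id", "frame"])
    if dup.any():
        bad = df.loc[dup, ["track_id", "frame"]].iloc[0]
        raise ValueError(f"{path}: duplicate (track_id, frame) = ({bad.track_id}, {bad.frame})")
    if dt is None:
        dt = float(df["dt"].iloc[0]) if "dt" in df.columns else 1.0
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(
            Track(
                track_id=str(tid),
                frames=grp["frame"].to_numpy(dtype=np.int64),
                x=grp["x"].to_numpy(dtype=float),
                y=grp["y"].to_numpy(dtype=float),
                dt=dt,
                pixel_size=pixel_size,
            )
        )
    return tracks


def write_tracks(tracks: list[Track], path: str | os.PathLike) -> Path:
    """Write tracks to the canonical CSV layout (track_id, frame, x, y, dt)."""
    path = Path(path)
    rows = []
    for t in tracks:
        for f, x, y in zip(t.frames, t.x, t.y):
            rows.append({"track_id": t.track_id, "frame": int(f), "x": x, "y": y, "dt": t.dt})
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
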