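"""Synthetic fluorescence micrographs and migration tracks with ground truth.

Every pipeline stage is testable without external data: this module renders
fields of elliptical membrane-stained cells whose receptor distribution
around the membrane follows a von Mises angular density — concentration
``kappa = 0`` gives a uniform ring (an unpolarized cell), large kappa a
tight cap at direction ``mu`` (a polarized cell with the receptor gathered
at one pole, as CD44 gathers in the uropod). Cytoplasmic signal, a flat
background, Poisson shot noise and additive Gaussian read noise complete a
standard fluorescence camera model.

Tracks are persistent random walks: per-step headings evolve by a wrapped
normal turn whose spread is set by a persistence parameter in [0, 1), and
step lengths are speed * dt with mean-one lognormal jitter.

All randomness flows from a single seed; no global state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import i0

from .io import Field, write_field, write_mask, write_tracks
from .tracks import Track

__all__ = [
    "MembraneStain",
    "SyntheticCellSpec",
    "SyntheticFieldSpec",
    "render_field",
    "random_field_spec",
    "generate_tracks",
    "make_benchmark",
]

# Default photon-scale intensities (arbitrary camera counts). Chosen as a
# well-exposed confocal operating point: cells clearly above background so a
# global threshold separates them, membrane ring ~2x brighter than cytosol.
DEFAULT_BACKGROUND = 8.0
DEFAULT_CYTOPLASM = 40.0
DEFAULT_AMPLITUDE = 80.0
DEFAULT_READ_NOISE = 2.0  # sd, ~2% of membrane amplitude
DEFAULT_MEMBRANE_WIDTH = 2.5

MAX_PLACEMENT_ATTEMPTS = 1000


@dataclass
class MembraneStain:
    """One channel's staining of one cell.

    The membrane term has a von Mises angular density proportional to
    exp(kappa*cos(theta - mu)), normalized to angular mean 1 so total
    membrane signal is kappa-independent (kappa = 0 is a uniform ring), and
    a radially Gaussian profile (sd = membrane_width / 2) peaked one
    membrane-width inside the cell outline, emulating the PSF-blurred image
    of a thin membrane whose mask is drawn at the cell's outer envelope.
    ``cytoplasm`` adds a flat in-cell level (nonspecific antibody signal).
    """

    kappa: float = 0.0
    mu: float = 0.0
    amplitude: float = DEFAULT_AMPLITUDE
    cytoplasm: float = DEFAULT_CYTOPLASM

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.amplitude < 0 or self.cytoplasm < 0:
            raise ValueError("intensities must be >= 0")


@dataclass
class SyntheticCellSpec:
    """Geometry plus per-channel membrane stains for one synthetic cell."""

    center: tuple[float, float]  # (row, col)
    semi_axes: tuple[float, float]  # (a, b), a = major
    orientation: float = 0.0  # radians, major axis vs +col
    membrane_width: float = DEFAULT_MEMBRANE_WIDTH
    stains: dict[str, MembraneStain] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if min(a, b) < 5:
            raise ValueError("semi-axes must be >= 5 px")
        if self.membrane_width < 1:
            raise ValueError("membrane_width must be >= 1 px")

    @property
    def radius(self) -> float:
        return max(self.semi_axes)


@dataclass
class SyntheticFieldSpec:
    shape: tuple[int, int] = (448, 448)
    cells: list[SyntheticCellSpec] = dc_field(default_factory=list)
    channel_names: tuple[str, ...] = ("cd44", "lfa1")
    background_level: float = DEFAULT_BACKGROUND
    read_noise_sd: float = DEFAULT_READ_NOISE
    shot_noise: bool = True
    min_gap: float = 10.0
    seed: int = 0
    pixel_size: float = 1.0
    field_id: str = "synthetic"


def _cell_expected(spec: SyntheticCellSpec, shape: tuple[int, int]):
    """Per-channel expected intensity contribution of one cell, plus its mask.

    Returns (rows, cols, inside_mask_bool, per-channel dict of values on the
    bounding-box grid).
    """
    a, b = spec.semi_axes
    cr, cc = spec.center
    pad = max(a, b) + spec.membrane_width + 2
    r0, r1 = max(0, int(cr - pad)), min(shape[0], int(cr + pad) + 1)
    c0, c1 = max(0, int(cc - pad)), min(shape[1], int(cc + pad) + 1)
    rr, cc_grid = np.mgrid[r0:r1, c0:c1]
    y = rr - cr  # row offset
    x = cc_grid - cc  # col offset
    cphi, sphi = math.cos(spec.orientation), math.sin(spec.orientation)
    u = x * cphi + y * sphi
    v = -x * sphi + y * cphi
    r = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    inside = r <= 1.0
    # distance from pixel to the boundary along its ray from the center
    rad = np.hypot(x, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        ray_to_edge = np.where(r > 0, rad * (1.0 - r) / np.where(r > 0, r, 1.0), np.inf)
    # membrane intensity peaks one width inside the outline (the mask is the
    # cell's outer envelope; the PSF-blurred stain centroid sits within it)
    sigma_m = spec.membrane_width / 2.0
    radial = np.exp(-((ray_to_edge - spec.membrane_width) ** 2) / (2.0 * sigma_m**2))
    theta = np.arctan2(y, x)
    per_channel = {}
    for name, stain in spec.stains.items():
        vals = np.zeros(rr.shape)
        vals[inside] += stain.cytoplasm
        if stain.amplitude > 0:
            weight = np.exp(stain.kappa * np.cos(theta - stain.mu)) / i0(stain.kappa)
            vals[inside] += stain.amplitude * (weight * radial)[inside]
        per_channel[name] = vals
    return (r0, r1, c0, c1), inside, per_channel


def render_field(spec: SyntheticFieldSpec, rng: np.random.Generator | None = None):
    """Render a field: (Field, ground-truth label mask, per-cell truth table).

    Expected intensity = background + cytoplasm (inside each ellipse) +
    membrane term with von Mises angular density; then Poisson shot noise on
    the expectation and additive Gaussian read noise, clipped at zero.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    shape = spec.shape
    expected = {name: np.full(shape, float(spec.background_level)) for name in spec.channel_names}
    mask = np.zeros(shape, dtype=np.int32)
    truth_rows = []
    for label, cell in enumerate(spec.cells, start=1):
        missing = set(spec.channel_names) - set(cell.stains)
        if missing:
            raise ValueError(f"cell {label}: no stain for channels {sorted(missing)}")
        (r0, r1, c0, c1), inside, per_channel = _cell_expected(cell, shape)
        if mask[r0:r1, c0:c1][inside].any():
            raise ValueError(f"cell {label}: overlaps a previously placed cell")
        mask[r0:r1, c0:c1][inside] = label
        for name in spec.channel_names:
            expected[name][r0:r1, c0:c1] += per_channel[name]
        row = {
            "cell_label": label,
            "center_row": cell.center[0],
            "center_col": cell.center[1],
            "semi_a": cell.semi_axes[0],
            "semi_b": cell.semi_axes[1],
            "orientation": cell.orientation,
            "area_true": int(inside.sum()),
        }
        for name, stain in cell.stains.items():
            row[f"kappa_{name}"] = stain.kappa
            row[f"mu_{name}"] = stain.mu
            row[f"amplitude_{name}"] = stain.amplitude
            row[f"cytoplasm_{name}"] = stain.cytoplasm
        truth_rows.append(row)

    channels = {}
    for name in spec.channel_names:
        img = expected[name]
        if spec.shot_noise:
            img = rng.poisson(img).astype(float)
        if spec.read_noise_sd > 0:
            img = img + rng.normal(0.0, spec.read_noise_sd, size=shape)
        channels[name] = np.clip(img, 0.0, None)
    field = Field(channels=channels, pixel_size=spec.pixel_size, field_id=spec.field_id)
    return field, mask, pd.DataFrame(truth_rows)


def random_field_spec(
    rng: np.random.Generator,
    n_cells: int,
    *,
    shape: tuple[int, int] = (448, 448),
    channel_stains: dict[str, dict] | None = None,
    semi_a_range: tuple[float, float] = (16.0, 21.0),
    semi_b_range: tuple[float, float] = (13.0, 16.0),
    min_gap: float = 10.0,
    field_id: str = "synthetic",
    **field_kwargs,
) -> SyntheticFieldSpec:
    """Place ``n_cells`` non-touching random cells and assign channel stains.

    ``channel_stains`` maps channel name -> {"kappa": float, "mu": "rear" |
    "front" | "random" | angle, "amplitude": float}. "rear"/"front" tie the
    cap to the cell's own random polarity angle (rear = the polarity angle,
    front = opposite), so a reference channel and a marker channel can be
    placed on the same or opposite poles of each cell.

    Placement is rejection sampling with pairwise center distance >=
    radius_i + radius_j + min_gap, capped at 1000 attempts per cell.
    """
    channel_stains = channel_stains or {
        "cd44": {"kappa": 4.0, "mu": "rear"},
        "lfa1": {"kappa": 1.0, "mu": "random"},
    }
    margin = semi_a_range[1] + DEFAULT_MEMBRANE_WIDTH + 4
    placed: list[tuple[float, float, float]] = []  # (row, col, radius)
    cells = []
    for _ in range(n_cells):
        a = rng.uniform(*semi_a_range)
        b = rng.uniform(*semi_b_range)
        radius = max(a, b)
        for attempt in range(MAX_PLACEMENT_ATTEMPTS):
            r = rng.uniform(margin, shape[0] - margin)
            c = rng.uniform(margin, shape[1] - margin)
            if all(np.hypot(r - pr, c - pc) >= radius + prad + min_gap
                   for pr, pc, prad in placed):
                break
        else:
            raise ValueError(
                f"could not place {n_cells} cells of radius ~{radius:.0f} in {shape} "
                f"after {MAX_PLACEMENT_ATTEMPTS} attempts"
            )
        placed.append((r, c, radius))
        polarity = rng.uniform(-math.pi, math.pi)
        stains = {}
        for name, cfg in channel_stains.items():
            mu = cfg.get("mu", "random")
            if mu == "rear":
                mu_val = polarity
            elif mu == "front":
                mu_val = polarity + math.pi
            elif mu == "random":
                mu_val = rng.uniform(-math.pi, math.pi)
            else:
                mu_val = float(mu)
            stains[name] = MembraneStain(
                kappa=float(cfg.get("kappa", 0.0)),
                mu=mu_val,
                amplitude=float(cfg.get("amplitude", DEFAULT_AMPLITUDE)),
                cytoplasm=float(cfg.get("cytoplasm", DEFAULT_CYTOPLASM)),
            )
        cells.append(
            SyntheticCellSpec(
                center=(r, c),
                semi_axes=(a, b),
                orientation=rng.uniform(-math.pi, math.pi),
                stains=stains,
            )
        )
    return SyntheticFieldSpec(
        shape=shape,
        cells=cells,
        channel_names=tuple(channel_stains),
        min_gap=min_gap,
        field_id=field_id,
        **field_kwargs,
    )


def generate_tracks(
    n: int,
    speed: float,
    persistence: float,
    n_frames: int,
    dt: float,
    seed: int | np.random.Generator,
    *,
    step_jitter_sd: float = 0.3,
    start_box: float = 200.0,
    pixel_size: float = 1.0,
) -> list[Track]:
    """Persistent random walks for ``n`` cells.

    Step length = speed*dt times mean-one lognormal jitter; heading evolves
    by a wrapped-normal turn with E[cos(turn)] = persistence (so turn sd =
    sqrt(-2 ln p); persistence 0 draws a fresh uniform heading each step).
    Positions are in pixels; speed is in length units per second.
    """
    if not (0 <= persistence < 1):
        raise ValueError("persistence must be in [0, 1)")
    if speed <= 0 or dt <= 0 or n_frames < 2:
        raise ValueError("need speed > 0, dt > 0, n_frames >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    turn_sd = math.sqrt(-2.0 * math.log(persistence)) if persistence > 0 else None
    mean_step = speed * dt / pixel_size  # pixels per frame
    tracks = []
    for i in range(n):
        pos = rng.uniform(0, start_box, size=2)
        heading = rng.uniform(-math.pi, math.pi)
        xs, ys = [pos[0]], [pos[1]]
        for _ in range(n_frames - 1):
            if turn_sd is None:
                heading = rng.uniform(-math.pi, math.pi)
            else:
                heading = heading + rng.normal(0.0, turn_sd)
            step = mean_step * rng.lognormal(-0.5 * step_jitter_sd**2, step_jitter_sd)
            pos = pos + step * np.array([math.cos(heading), math.sin(heading)])
            xs.append(pos[0])
            ys.append(pos[1])
        tracks.append(
            Track(
                track_id=f"t{i:04d}",
                frames=np.arange(n_frames),
                x=np.array(xs),
                y=np.array(ys),
                dt=dt,
                pixel_size=pixel_size,
            )
        )
    return tracks


def make_benchmark(
    out_dir: str | Path,
    conditions: dict[str, dict] | None = None,
    *,
    n_fields: int = 10,
    cells_per_field: int = 20,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    tracks_per_condition: int = 50,
    track_params: dict | None = None,
) -> Path:
    """Write a two-condition benchmark dataset directly consumable by the
    pipeline: per condition, ``n_fields`` TIFF fields with ground-truth masks
    and truth CSVs, plus persistent-random-walk tracks.

    Default conditions mirror a polarized-vs-depolarized contrast: "wt_like"
    cells carry a tight uropod cap (kappa = 4), "mutant_like" cells only a
    weak one (kappa = 1).
    """
    conditions = conditions or {
        "wt_like": {"kappa_cd44": 4.0, "kappa_lfa1": 1.0,
                    "speed": 0.12, "persistence": 0.7},
        "mutant_like": {"kappa_cd44": 1.0, "kappa_lfa1": 1.0,
                        "speed": 0.05, "persistence": 0.3},
    }
    track_params = track_params or {"n_frames": 60, "dt": 10.0}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_rng = np.random.default_rng(seed)
    manifest = {"seed": seed, "conditions": {}}
    for cond, cfg in sorted(conditions.items()):
        cdir = out / cond
        cdir.mkdir(exist_ok=True)
        cond_rng = np.random.default_rng(root_rng.integers(0, 2**31))
        fields = []
        for i in range(n_fields):
            spec = random_field_spec(
                cond_rng,
                cells_per_field,
                shape=shape,
                channel_stains={
                    "cd44": {"kappa": cfg.get("kappa_cd44", 4.0), "mu": "rear"},
                    "lfa1": {"kappa": cfg.get("kappa_lfa1", 1.0), "mu": "random"},
                },
                field_id=f"{cond}_{i:02d}",
            )
            field, mask, truth = render_field(spec, cond_rng)
            write_field(field, cdir / f"field_{i:02d}.tif")
            write_mask(mask, cdir / f"mask_{i:02d}.tif")
            truth.to_csv(cdir / f"truth_{i:02d}.csv", index=False)
            fields.append(f"field_{i:02d}.tif")
        tracks = generate_tracks(
            tracks_per_condition,
            speed=cfg.get("speed", 0.1),
            persistence=cfg.get("persistence", 0.5),
            seed=cond_rng,
            **track_params,
        )
        write_tracks(tracks, cdir / "tracks.csv")
        manifest["conditions"][cond] = {
            "fields": fields,
            "channels": ["cd44", "lfa1"],
            "tracks": "tracks.csv",
            **cfg,
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
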