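"""End-to-end orchestration: simulate or load fields, segment, score
clustering, call polarity, compute track metrics, compare conditions.

A run consumes a config (dict or TOML file) and writes a results directory:

    scores.csv         one row per (field, cell, channel) clustering result
    polarity.csv       one row per (field, cell) trailing-edge call
    track_metrics.csv  one row per track
    track_summary.csv  per-condition mean +/- SEM of the track metrics
    comparisons.json   per-channel two-group comparison of the clustering
                       index plus the per-condition polarity fractions
    provenance.json    full config, seed, package version

Config layout (TOML or an equivalent dict)::

    [simulate]                  # either this ...
    n_fields = 4
    cells_per_field = 15
    [simulate.conditions.wt_like]
    kappa_cd44 = 4.0
    kappa_lfa1 = 1.0

    data_dir = "bench/"         # ... or a make_benchmark directory

    [analysis]
    reference_channel = "cd44"
    marker_channel = "lfa1"
    polarity_threshold = 0.6
    dt = 10.0
    pixel_size = 1.0

    [detection]                 # any DetectionParams field
    min_area = 200

Any stage failure aborts with an error tagged by stage name.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import pandas as pd

from .cluster import score_field
from .detect import DetectionParams, extract_regions, segment_field
from .io import read_field, read_mask, read_tracks
from .polarity import classify_field
from .stats import compare_table
from .synth import make_benchmark
from .tracks import metrics_table, summarize_condition, track_metrics

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is prefixed with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, "rb") as fh:
            return tomllib.load(fh)
    return dict(config)


def run_pipeline(config, out_dir: str | Path, seed: int | None = None) -> dict:
    """Run the full analysis; returns the summary dict written to
    comparisons.json. ``seed`` overrides any seed in the config (simulation
    only — the analysis itself is deterministic)."""
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    analysis = cfg.get("analysis", {})
    det_cfg = cfg.get("detection", {})
    try:
        params = DetectionParams(**det_cfg)
    except (TypeError, ValueError) as exc:
        raise PipelineError("config", f"bad detection parameters: {exc}") from exc

    # ------------------------------------------------------------------ data
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        sim_seed = seed if seed is not None else int(sim.pop("seed", 0))
        conditions = sim.pop("conditions", None)
        try:
            data_dir = make_benchmark(out / "data", conditions, seed=sim_seed, **sim)
        except (ValueError, TypeError) as exc:
            raise PipelineError("simulate", str(exc)) from exc
    elif "data_dir" in cfg:
        data_dir = Path(cfg["data_dir"])
    else:
        raise PipelineError("config", "config needs a [simulate] block or data_dir")
    manifest_path = data_dir / "manifest.json"
    if not manifest_path.exists():
        raise PipelineError("data", f"no manifest.json in {data_dir}")
    manifest = json.loads(manifest_path.read_text())

    ref = analysis.get("reference_channel", "cd44")
    marker = analysis.get("marker_channel", "lfa1")
    threshold = float(analysis.get("polarity_threshold", 0.6))
    dt = float(analysis.get("dt", 1.0))
    pixel_size = float(analysis.get("pixel_size", 1.0))

    scores, polarity_rows, track_rows, track_summaries = [], [], [], []
    polarity_summary = {}
    for cond, info in sorted(manifest["conditions"].items()):
        cdir = data_dir / cond
        channels = info["channels"]
        for fname in info["fields"]:
            try:
                field = read_field(cdir / fname, channels, pixel_size=pixel_size)
            except (OSError, ValueError) as exc:
                raise PipelineError("read", f"{cond}/{fname}: {exc}") from exc
            try:
                mask = segment_field(field, params)
                regions = extract_regions(mask, field)
            except ValueError as exc:
                raise PipelineError("segment", f"{cond}/{fname}: {exc}") from exc
            try:
                tab = score_field(field, mask, channels, regions=regions)
            except (KeyError, ValueError) as exc:
                raise PipelineError("score", f"{cond}/{fname}: {exc}") from exc
            tab.insert(0, "condition", cond)
            scores.append(tab)
            try:
                calls, _ = classify_field(field, mask, ref, marker, threshold, regions=regions)
            except KeyError as exc:
                raise PipelineError("polarity", f"{cond}/{fname}: {exc}") from exc
            calls.insert(0, "condition", cond)
            polarity_rows.append(calls)
        if info.get("tracks"):
            try:
                tracks = read_tracks(cdir / info["tracks"], dt=dt, pixel_size=pixel_size)
                tms = [track_metrics(t) for t in tracks]
            except ValueError as exc:
                raise PipelineError("tracks", f"{cond}: {exc}") from exc
            tt = metrics_table(tms)
            tt.insert(0, "condition", cond)
            track_rows.append(tt)
            ts = summarize_condition(tms)
            ts.insert(0, "condition", cond)
            track_summaries.append(ts)

    scores_df = pd.concat(scores, ignore_index=True)
    polarity_df = pd.concat(polarity_rows, ignore_index=True)
    scores_df.to_csv(out / "scores.csv", index=False)
    polarity_df.to_csv(out / "polarity.csv", index=False)
    if track_rows:
        pd.concat(track_rows, ignore_index=True).to_csv(out / "track_metrics.csv", index=False)
        pd.concat(track_summaries, ignore_index=True).to_csv(out / "track_summary.csv", index=False)

    # ----------------------------------------------------------- comparisons
    evaluable = polarity_df[polarity_df["excluded_reason"] == ""]
    for cond, grp in evaluable.groupby("condition"):
        n_eval = len(grp)
        polarity_summary[cond] = {
            "n_evaluable": int(n_eval),
            "n_localized": int(grp["localized"].sum()),
            "fraction_localized": float(grp["localized"].mean()) if n_eval else None,
        }
    valid = scores_df[scores_df["flag"].isin(["", "ci_out_of_range"])]
    comparisons = []
    if valid["condition"].nunique() == 2:
        try:
            comparisons = compare_table(valid, value="ci", group_col="condition", by=["channel"])
        except ValueError as exc:
            raise PipelineError("compare", str(exc)) from exc
    summary = {
        "schema_version": 1,
        "n_cells_scored": int(scores_df["cell_label"].notna().sum()),
        "clustering_comparisons": comparisons,
        "polarity": polarity_summary,
    }
    (out / "comparisons.json").write_text(json.dumps(summary, indent=2))
    from importlib.metadata import version as _pkg_version

    try:
        _version = _pkg_version("polarscore")
    except Exception:
        _version = "unknown"
    provenance = {
        "config": cfg,
        "seed": seed,
        "polarscore_version": _version,
        "detection": det_cfg,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
    return summary
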