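"""Config-driven orchestration of the simulate -> segment -> quantify stages.

A run is described by a small mapping (usually loaded from a YAML file)
with a ``task``, a ``seed``, an ``output_dir`` and task-specific
``params``. Every output table carries provenance: the config hash, the
seed and the package version, written to ``provenance.json`` next to the
results so any run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cld import compute_cld, pool_chords
from .demixing import compare_histograms, compute_angle_histogram
from .errors import ConfigError
from .frap import aggregate_recovery, load_trace_csv, normalize_recovery
from .fusion import aspect_ratio_series, fit_relaxation, inverse_capillary_velocity
from .io import load_stack
from .segmentation import DEFAULT_MIN_AREA, label_and_measure, segment_image
from .sequences import kl_design_space
from .synthetic import (
    BleedMatrix,
    FieldSpec,
    generate_droplet_field,
    generate_frap_series,
    generate_fusion_series,
    generate_two_channel_field,
)

__all__ = ["run_pipeline", "load_config"]

TASKS = ("simulate", "segment", "cld", "demix", "frap", "fusion", "icv", "design-space")


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def _validate(config: dict) -> tuple[str, int, Path, dict]:
    if "task" not in config:
        raise ConfigError("missing required field: task")
    task = config["task"]
    if task not in TASKS:
        raise ConfigError(f"unknown task {task!r}; expected one of {TASKS}")
    seed = int(config.get("seed", 0))
    out_dir = Path(config.get("output_dir", "."))
    params = config.get("params", {})
    if not isinstance(params, dict):
        raise ConfigError("params must be a mapping")
    return task, seed, out_dir, params


def _write_provenance(out_dir: Path, config: dict, seed: int, outputs: list[str]) -> None:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    meta = {
        "config_hash": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "starphase_version": __version__,
        "outputs": outputs,
    }
    (out_dir / "provenance.json").write_text(json.dumps(meta, indent=2))


def _field_spec(params: dict, seed: int) -> FieldSpec:
    keys = {f for f in FieldSpec.__dataclass_fields__}
    kwargs = {k: v for k, v in params.items() if k in keys}
    if "image_shape" in kwargs:
        kwargs["image_shape"] = tuple(kwargs["image_shape"])
    if "radius_law" in kwargs:
        kwargs["radius_law"] = tuple(kwargs["radius_law"])
    kwargs["seed"] = seed
    return FieldSpec(**kwargs)


def _task_simulate(params: dict, seed: int, out_dir: Path) -> dict:
    preset = params.get("preset", "droplets")
    outputs: list[str] = []
    if preset == "droplets":
        stack, truth = generate_droplet_field(_field_spec(params, seed))
        stack.save(out_dir / "field.tiff")
        truth.to_csv(out_dir / "ground_truth.csv")
        outputs = ["field.tiff", "ground_truth.csv"]
        summary = {"n_droplets": truth.true_count}
    elif preset == "two-channel":
        bleed = BleedMatrix(params.get("bleed", [[1.0, 0.2], [0.15, 1.0]]))
        stack, truth = generate_two_channel_field(
            _field_spec(params, seed), mixing=float(params.get("mixing", 0.0)), bleed=bleed
        )
        stack.save(out_dir / "field.tiff")
        truth.to_csv(out_dir / "ground_truth.csv")
        outputs = ["field.tiff", "ground_truth.csv"]
        summary = {"n_droplets": truth.true_count}
    elif preset == "fusion":
        stack = generate_fusion_series(
            A=float(params.get("A", 0.6)),
            tau=float(params.get("tau", 120.0)),
            area=float(params.get("area", 900.0)),
            dt=float(params.get("dt", 15.0)),
            duration=float(params.get("duration", 240.0)),
            noise_sigma=float(params.get("noise_sigma", 0.0)),
            seed=seed,
        )
        stack.save(out_dir / "fusion.tiff")
        outputs = ["fusion.tiff"]
        summary = {"n_frames": stack.n_frames}
    elif preset == "frap":
        trace = generate_frap_series(
            bleach_depth=float(params.get("bleach_depth", 0.8)),
            recovery_amplitude=float(params.get("recovery_amplitude", 0.0)),
            tau_rec=float(params.get("tau_rec", 60.0)),
            photobleach_lambda=float(params.get("photobleach_lambda", 0.0)),
            noise_sigma=float(params.get("noise_sigma", 0.0)),
            seed=seed,
        )
        pd.DataFrame(
            {"time": trace.frame_times, "i_bleach": trace.i_bleach,
             "i_unbleach": trace.i_unbleach}
        ).to_csv(out_dir / "frap_trace.csv", index=False)
        outputs = ["frap_trace.csv"]
        summary = {"n_frames": len(trace.frame_times)}
    else:
        raise ConfigError(f"unknown simulate preset {preset!r}")
    return {"outputs": outputs, **summary}


def _task_segment(params: dict, out_dir: Path) -> dict:
    stack = load_stack(params["input"])
    frame = stack.frame(int(params.get("frame", 0)), int(params.get("channel", 0)))
    mask = segment_image(
        frame,
        pixel_size=stack.pixel_size,
        min_area=int(params.get("min_area", DEFAULT_MIN_AREA)),
        background=params.get("background", "median"),
        ball_radius=float(params.get("ball_radius", 50.0)),
    )
    mask.save(out_dir / "mask.tiff")
    regions = label_and_measure(mask)
    regions.records.to_csv(out_dir / "regions.csv", index=False)
    return {"outputs": ["mask.tiff", "regions.csv"], "n_regions": regions.n_regions}


def _task_cld(params: dict, out_dir: Path) -> dict:
    from .segmentation import BinaryMask
    import tifffile

    clds = {}
    for i, path in enumerate(params["inputs"]):
        arr = np.asarray(tifffile.imread(path)) > 0
        mask = BinaryMask(arr, pixel_size=float(params.get("pixel_size", 1.0)))
        clds[str(i)] = compute_cld(
            mask, include_border=bool(params.get("include_border", False))
        )
    pool_chords(clds, out_dir / "chords.csv")
    summary_rows = [
        {"replicate": k, "n_chords": c.n_chords,
         "mu_cld": c.mu_cld if c.n_chords else np.nan}
        for k, c in clds.items()
    ]
    pd.DataFrame(summary_rows).to_csv(out_dir / "cld_summary.csv", index=False)
    return {"outputs": ["chords.csv", "cld_summary.csv"],
            "n_chords_total": int(sum(c.n_chords for c in clds.values()))}


def _histogram_for(path: str, n_bins: int) -> Any:
    stack = load_stack(path)
    fitc = stack.frame(0, "FITC") if "FITC" in stack.channel_names else stack.frame(0, 0)
    cy3 = stack.frame(0, "Cy3") if "Cy3" in stack.channel_names else stack.frame(0, 1)
    roi = segment_image(fitc + cy3, pixel_size=stack.pixel_size)
    return compute_angle_histogram(fitc, cy3, roi=roi, n_bins=n_bins)


def _task_demix(params: dict, out_dir: Path) -> dict:
    n_bins = int(params.get("n_bins", 90))
    controls = [_histogram_for(p, n_bins) for p in params["controls"]]
    mixed = _histogram_for(params["mixed"], n_bins)
    report = compare_histograms(controls, mixed, tol=float(params.get("tol", 0.05)))
    centers = 0.5 * (mixed.bin_edges[:-1] + mixed.bin_edges[1:])
    pd.DataFrame({"theta": centers, "count": mixed.counts}).to_csv(
        out_dir / "mixed_histogram.csv", index=False
    )
    (out_dir / "demixing_report.json").write_text(json.dumps({
        "verdict": report.verdict,
        "reason": report.reason,
        "control_peaks": report.control_peaks,
        "mixed_peaks": report.mixed_peaks,
        "peak_distances": report.peak_distances,
    }, indent=2))
    return {"outputs": ["mixed_histogram.csv", "demixing_report.json"],
            "verdict": report.verdict}


def _task_frap(params: dict, out_dir: Path) -> dict:
    curves = []
    for i, path in enumerate(params["inputs"]):
        trace = load_trace_csv(path)
        curves.append(normalize_recovery(trace, replicate_id=str(i)))
    long_rows = [
        {"replicate": c.replicate_id, "time": t, "recovery": r}
        for c in curves for t, r in zip(c.frame_times, c.recovery)
    ]
    pd.DataFrame(long_rows).to_csv(out_dir / "recovery.csv", index=False)
    agg = aggregate_recovery(curves)
    agg.to_csv(out_dir / "recovery_aggregate.csv", index=False)
    return {"outputs": ["recovery.csv", "recovery_aggregate.csv"],
            "n_replicates": len(curves)}


def _task_fusion(params: dict, out_dir: Path) -> dict:
    stack = load_stack(params["input"])
    series = aspect_ratio_series(stack, min_area=int(params.get("min_area", DEFAULT_MIN_AREA)))
    fit = fit_relaxation(series)
    pd.DataFrame({"time": series.times, "aspect_ratio": series.aspect_ratio}).to_csv(
        out_dir / "aspect_ratio.csv", index=False
    )
    (out_dir / "fusion_fit.json").write_text(json.dumps({
        "A": fit.A, "tau": fit.tau, "residual_rms": fit.residual_rms,
        "converged": fit.converged, "reason": fit.reason,
        "characteristic_length_um": series.characteristic_length,
    }, indent=2))
    return {"outputs": ["aspect_ratio.csv", "fusion_fit.json"],
            "tau": fit.tau, "A": fit.A}


def _task_icv(params: dict, out_dir: Path) -> dict:
    pairs = []
    for path in params["inputs"]:
        fit = json.loads(Path(path).read_text())
        pairs.append((float(fit["tau"]), float(fit["characteristic_length_um"])))
    est = inverse_capillary_velocity(pairs)
    (out_dir / "icv.json").write_text(json.dumps({
        "eta_over_gamma_min_per_um": est.eta_over_gamma,
        "n_events": est.n_events,
        "residual_rms": est.residual_rms,
    }, indent=2))
    return {"outputs": ["icv.json"], "eta_over_gamma": est.eta_over_gamma}


def _task_design_space(params: dict, out_dir: Path) -> dict:
    k = int(params.get("k", 6))
    ds = kl_design_space(k)
    (out_dir / "design_space.json").write_text(json.dumps({
        "k": k, "total": ds.total, "palindromic": ds.palindromic,
        "fold_expansion": ds.fold_expansion,
    }, indent=2))
    return {"outputs": ["design_space.json"], "fold_expansion": ds.fold_expansion}


def run_pipeline(config: dict) -> dict:
    """Validate the config, dispatch the task and write provenance.

    Returns a run summary: the task, the outputs written and the task's
    headline numbers. Raises :class:`ConfigError` (or the stage's own
    error) on failure; the CLI maps any raised error to a nonzero exit.
    """
    task, seed, out_dir, params = _validate(config)
    out_dir.mkdir(parents=True, exist_ok=True)
    if task == "simulate":
        summary = _task_simulate(params, seed, out_dir)
    elif task == "segment":
        summary = _task_segment(params, out_dir)
    elif task == "cld":
        summary = _task_cld(params, out_dir)
    elif task == "demix":
        summary = _task_demix(params, out_dir)
    elif task == "frap":
        summary = _task_frap(params, out_dir)
    elif task == "fusion":
        summary = _task_fusion(params, out_dir)
    elif task == "icv":
        summary = _task_icv(params, out_dir)
    else:  # design-space
        summary = _task_design_space(params, out_dir)
    _write_provenance(out_dir, config, seed, summary.get("outputs", []))
    return {"task": task, "seed": seed, "output_dir": str(out_dir), **summary}
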