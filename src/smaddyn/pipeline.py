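"""Config-driven orchestration of simulate -> correct -> segment -> quantify ->
trajectory -> dynamics runs, with a manifest for reproducibility.

A run is described by a YAML/dict config with a global RNG seed. The seed is fanned
out to stages through ``numpy.random.SeedSequence(seed, spawn_key=(stage_index,))``,
so a stage's randomness does not depend on which other stages run. Identical config
and seed produce byte-identical tabular outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import correction, dynamics, quantify, segmentation, synth
from .core import ImageStack

__all__ = ["RunConfig", "validate_config", "run_pipeline", "STAGES"]

STAGES = ("simulate", "correct", "segment", "quantify", "trajectory", "dynamics")

# stage -> {key: (default, validator)}; None default means required
_SCHEMA = {
    "simulate": {
        "kind": ("adaptive", lambda v: v in ("adaptive", "stable")),
        "dose_ng_ml": (10.0, lambda v: v >= 0),
        "n_colonies": (3, lambda v: v >= 1),
        "n_cells_per_colony": (80, lambda v: v >= 0),
        "colony_radius_um": (160.0, lambda v: v > 0),
        "nucleus_radius_um": (8.0, lambda v: v > 0),
        "edge_decay_length_um": (None, lambda v: v is None or v > 0),
        "t_stim_hr": (1.0, lambda v: v >= 0),
        "times_hr": (
            [0.0, 0.5, 1.33, 1.72, 2.0, 2.5, 3.0, 4.0, 5.0, 7.0, 9.0, 10.0, 11.0, 12.0, 13.0],
            lambda v: len(v) >= 2,
        ),
        "vignette_amplitude": (0.2, lambda v: 0 <= v < 1),
        "background_offset": (50.0, lambda v: v >= 0),
        "photon_scale": (1.0, lambda v: v >= 0),
        "read_noise_sd": (5.0, lambda v: v >= 0),
    },
    "correct": {
        "percentile": (1.0, lambda v: 0 <= v <= 50),
    },
    "segment": {
        "nucleus_radius_px": (8.0, lambda v: v > 0),
        "threshold_method": ("otsu", lambda v: v in ("otsu", "fixed")),
        "fixed_threshold": (None, lambda v: v is None or v > 0),
        "h_maxima_frac": (0.10, lambda v: 0 < v < 1),
        "seed_dilation_px": (2, lambda v: v >= 0),
        "min_area_frac": (0.3, lambda v: 0 < v < 1),
        "max_area_frac": (3.0, lambda v: v > 1),
        "donut_inner_px": (2, lambda v: v >= 0),
        "donut_outer_px": (5, lambda v: v > 0),
    },
    "quantify": {
        "readout": ("nc_ratio", lambda v: v in ("nc_ratio", "h2b_normalized")),
    },
    "trajectory": {
        "condition": ("simulated", lambda v: isinstance(v, str)),
    },
    "dynamics": {
        "t_post_offset_hr": (8.0, lambda v: v > 0),
        "adapt_threshold": (0.5, lambda v: 0 < v < 1),
    },
}


@dataclass
class RunConfig:
    seed: int
    outdir: Path
    stages: list
    params: dict = field(default_factory=dict)

    def stage_params(self, stage: str) -> dict:
        return self.params.get(stage, {})

    def stage_rng_seed(self, stage: str) -> np.random.SeedSequence:
        return np.random.SeedSequence(self.seed, spawn_key=(STAGES.index(stage),))

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "outdir": str(self.outdir),
            "stages": list(self.stages),
            **{s: dict(self.params.get(s, {})) for s in self.stages},
        }


def validate_config(config) -> RunConfig:
    """Resolve a config file/dict into a RunConfig with defaults filled.

    Unknown keys (top-level or per-stage) are rejected by name; parameter ranges are
    checked; cross-parameter invariants (donut radii ordering) enforced.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    cfg = dict(config)
    seed = cfg.pop("seed", 0)
    outdir = Path(cfg.pop("outdir", "smaddyn_run"))
    stages = list(cfg.pop("stages", list(STAGES)))
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; valid stages: {STAGES}")
    params = {}
    for stage, block in cfg.items():
        if stage not in STAGES:
            raise ValueError(f"unknown config key {stage!r}")
        if block is None:
            block = {}
        schema = _SCHEMA[stage]
        resolved = {}
        for key, value in block.items():
            if key not in schema:
                raise ValueError(f"unknown key {stage}.{key}")
            default, check = schema[key]
            if not check(value):
                raise ValueError(f"invalid value for {stage}.{key}: {value!r}")
            resolved[key] = value
        params[stage] = resolved
    # fill defaults
    for stage in stages:
        schema = _SCHEMA[stage]
        block = params.setdefault(stage, {})
        for key, (default, _) in schema.items():
            block.setdefault(key, default)
    seg = params.get("segment", {})
    if seg and not seg["donut_inner_px"] < seg["donut_outer_px"]:
        raise ValueError("segment.donut_inner_px must be < segment.donut_outer_px")
    return RunConfig(seed=int(seed), outdir=outdir, stages=stages, params=params)


def _param_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns (and writes) the manifest.

    Outputs land in ``config.outdir``: ground-truth and per-cell CSVs, the trajectory
    CSV, a dynamics summary JSON, and ``manifest.json`` recording inputs, outputs,
    parameter hash, seed and wall time per stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "param_hash": _param_hash(config),
        "config": config.to_dict(),
        "stages": [],
        "outputs": [],
    }
    state: dict = {}
    for stage in config.stages:
        t0 = time.perf_counter()
        try:
            _STAGE_FNS[stage](config, state, outdir, manifest)
        except Exception as e:
            raise RuntimeError(f"stage {stage!r} failed: {e}") from e
        manifest["stages"].append(
            {"name": stage, "wall_s": round(time.perf_counter() - t0, 3)}
        )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _write_csv(df, path, manifest):
    df.to_csv(path, index=False)
    manifest["outputs"].append(str(path))


def _stage_simulate(config, state, outdir, manifest):
    p = config.stage_params("simulate")
    seeds = config.stage_rng_seed("simulate").generate_state(2 * p["n_colonies"] + 1)
    model = synth.ResponseModel(kind=p["kind"], t_stim=p["t_stim_hr"])
    stacks, truths = [], []
    for i in range(p["n_colonies"]):
        layout = synth.ColonyLayout.random(
            n_cells=p["n_cells_per_colony"],
            colony_radius_um=p["colony_radius_um"],
            nucleus_radius_um=p["nucleus_radius_um"],
            edge_decay_length_um=p["edge_decay_length_um"],
            rng=int(seeds[2 * i]),
        )
        artifacts = synth.ImagingArtifacts(
            vignette_amplitude=p["vignette_amplitude"],
            background_offset=p["background_offset"],
            photon_scale=p["photon_scale"],
            read_noise_sd=p["read_noise_sd"],
            seed=int(seeds[2 * i + 1]),
        )
        stack, truth = synth.generate_colony_timelapse(
            layout, model, artifacts, p["times_hr"], dose_ng_ml=p["dose_ng_ml"]
        )
        truth.insert(0, "colony", i + 1)
        stacks.append(stack)
        truths.append(truth)
    state["stacks"] = stacks
    state["model"] = model
    truth_all = pd.concat(truths, ignore_index=True)
    state["truth"] = truth_all
    _write_csv(truth_all, outdir / "ground_truth.csv", manifest)


def _stage_correct(config, state, outdir, manifest):
    stacks = state["stacks"]
    fields = {
        name: correction.derive_correction(
            stacks, name,
            nucleus_radius_px=config.stage_params("segment").get("nucleus_radius_px", 8.0)
            if "segment" in config.params else 8.0,
            percentile=config.stage_params("correct")["percentile"],
        )
        for name in stacks[0].channel_names
    }
    state["stacks"] = [correction.correct_stack(s, fields) for s in stacks]


def _stage_segment(config, state, outdir, manifest):
    p = config.stage_params("segment")
    params = segmentation.SegmentationParams(
        nucleus_radius_px=p["nucleus_radius_px"],
        threshold_method=p["threshold_method"],
        fixed_threshold=p["fixed_threshold"],
        h_maxima_frac=p["h_maxima_frac"],
        seed_dilation_px=p["seed_dilation_px"],
        min_area_frac=p["min_area_frac"],
        max_area_frac=p["max_area_frac"],
        donut_inner_px=p["donut_inner_px"],
        donut_outer_px=p["donut_outer_px"],
    )
    state["seg_params"] = params
    masks = []
    for stack in state["stacks"]:
        per_frame = []
        for t in range(stack.n_frames):
            nuc = stack.frame(t).get("H2B", stack.data[t, 0])
            per_frame.append(segmentation.segment_frame(nuc, params))
        masks.append(per_frame)
    state["masks"] = masks


def _stage_quantify(config, state, outdir, manifest):
    p = config.stage_params("quantify")
    tables = []
    for i, (stack, per_frame) in enumerate(zip(state["stacks"], state["masks"])):
        for t_idx in range(stack.n_frames):
            nuc_labels, donuts = per_frame[t_idx]
            t_hr = stack.times_hr[t_idx] if stack.times_hr is not None else t_idx
            df = quantify.measure_cells(
                stack.frame(t_idx), nuc_labels, donuts,
                pixel_size_um=stack.pixel_size_um, time_hr=t_hr,
            )
            df.insert(0, "colony", i + 1)
            tables.append(df)
    cells = pd.concat(tables, ignore_index=True)
    cells["nc_ratio"] = quantify.nc_ratio(cells)
    cells["h2b_normalized"] = quantify.h2b_normalized(cells)
    state["cells"] = cells
    state["readout"] = p["readout"]
    _write_csv(cells, outdir / "cells.csv", manifest)


def _stage_trajectory(config, state, outdir, manifest):
    p = config.stage_params("trajectory")
    traj = quantify.assemble_trajectory(
        state["cells"], state["readout"], condition=p["condition"],
        dose_ng_ml=config.stage_params("simulate").get("dose_ng_ml", float("nan"))
        if "simulate" in config.params else float("nan"),
    )
    state["trajectory"] = traj
    _write_csv(traj.to_frame(), outdir / "trajectory.csv", manifest)


def _stage_dynamics(config, state, outdir, manifest):
    p = config.stage_params("dynamics")
    t_stim = config.stage_params("simulate").get("t_stim_hr", 0.0) \
        if "simulate" in config.params else 0.0
    summary = dynamics.summarize_trajectory(
        state["trajectory"], t_stim=t_stim, t_post_offset=p["t_post_offset_hr"]
    )
    out = summary.as_dict()
    if summary.valid:
        out["classification"] = dynamics.classify_dynamics(summary, p["adapt_threshold"])
    path = Path(outdir) / "dynamics_summary.json"
    path.write_text(json.dumps(out, indent=1, sort_keys=True))
    manifest["outputs"].append(str(path))
    state["summary"] = summary


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "correct": _stage_correct,
    "segment": _stage_segment,
    "quantify": _stage_quantify,
    "trajectory": _stage_trajectory,
    "dynamics": _stage_dynamics,
}
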