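"""End-to-end orchestration: simulate/read → JIP table → pipeline figures → statistics.

A single YAML config drives the whole chain; every run writes a manifest
recording the config snapshot, seed, package version and SHA-256 digests of
all outputs, so identical config + seed reproduces identical result digests.
Config parsing is strict: unknown keys are errors, never silently ignored.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .design import ExperimentDesign
from .errors import ConfigError
from .jip import jip_table, write_jip_table
from .pipeline_model import build_pipeline_model, render_pipeline
from .simulate import GeneratorConfig, generate_experiment
from .stats import (
    DEFAULT_THRESHOLD_CLOCK_TIME,
    DEFAULT_THRESHOLD_PARAMETERS,
    parameter_comparisons,
    results_table,
    threshold_from_jip,
)
from .transients import read_transients, write_transients

log = logging.getLogger("ojip")

_TOP_KEYS = {"seed", "output_dir", "input", "simulate", "jip", "stats", "pipeline", "threshold"}
_JIP_KEYS = {"eps_flat"}
_STATS_KEYS = {"parameters", "stratify", "control"}
_PIPELINE_KEYS = {"n_circles", "control", "format"}
_THRESHOLD_KEYS = {"parameters", "control", "clock_time"}
_SIM_KEYS = {f.name for f in dataclasses.fields(GeneratorConfig)} | {"design"}
_DESIGN_KEYS = {f.name for f in dataclasses.fields(ExperimentDesign)}


@dataclass
class RunManifest:
    """Provenance record of one full analysis run."""

    config: dict
    seed: int
    version: str
    started_utc: str
    finished_utc: str = ""
    outputs: dict = field(default_factory=dict)
    threshold_rcr: float | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=str)


def _check_keys(block: dict, allowed: set, where: str) -> None:
    if not isinstance(block, dict):
        raise ConfigError(f"config section {where!r} must be a mapping")
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown config key(s) in {where}: {', '.join(sorted(unknown))}")


def load_config(path) -> dict:
    """Load and strictly validate a YAML analysis config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    _check_keys(cfg, _TOP_KEYS, "top level")
    if "simulate" not in cfg and "input" not in cfg:
        raise ConfigError("config must provide either a 'simulate' block or an 'input' CSV path")
    if "simulate" in cfg and cfg["simulate"] is not None:
        _check_keys(cfg["simulate"], _SIM_KEYS - {"seed"}, "simulate")
        if "design" in cfg["simulate"]:
            _check_keys(cfg["simulate"]["design"], _DESIGN_KEYS, "simulate.design")
    for name, allowed in (
        ("jip", _JIP_KEYS),
        ("stats", _STATS_KEYS),
        ("pipeline", _PIPELINE_KEYS),
        ("threshold", _THRESHOLD_KEYS),
    ):
        if name in cfg and cfg[name] is not None:
            _check_keys(cfg[name], allowed, name)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _generator_config(cfg: dict, seed: int) -> GeneratorConfig:
    sim = dict(cfg.get("simulate") or {})
    design_kwargs = sim.pop("design", None)
    kwargs: dict = dict(sim)
    for key in ("tau_s", "sigma_decades", "weights", "flat_groups", "flat_clock_times", "recovery_groups"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    for key in ("depression", "diurnal"):
        if key in kwargs:
            kwargs[key] = {type(k)(k): v for k, v in kwargs[key].items()}
    if design_kwargs:
        dk = dict(design_kwargs)
        for key in ("groups", "clock_times", "days"):
            if key in dk:
                dk[key] = tuple(dk[key])
        kwargs["design"] = ExperimentDesign(**dk)
    return GeneratorConfig(seed=seed, **kwargs)


def run_full_analysis(config_path, *, output_dir=None) -> RunManifest:
    """Run the full chain described by a YAML config; return the manifest.

    Stages: simulate (or read an input CSV), leaf-level JIP parameter table,
    per-group energy pipeline figures, per-parameter group comparisons, and
    pooled threshold detection.  All outputs land in ``output_dir`` (config
    key, overridable) together with ``manifest.json``.
    """
    cfg = load_config(config_path)
    seed = int(cfg.get("seed", 0))
    out = Path(output_dir or cfg.get("output_dir", "ojip_out"))
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=cfg,
        seed=seed,
        version=__version__,
        started_utc=time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
    )
    outputs: dict[str, Path] = {}

    if "simulate" in cfg:
        gen_cfg = _generator_config(cfg, seed)
        transients, truth = generate_experiment(gen_cfg)
        tr_path = out / "transients.csv"
        write_transients(transients, tr_path)
        truth_path = out / "truth.tsv"
        truth.to_csv(truth_path, sep="\t", index=False, float_format="%.10g")
        outputs["transients"] = tr_path
        outputs["truth"] = truth_path
        log.info("simulate: %d transients (%d leaves)", len(transients), len(truth))
        input_path = tr_path
    else:
        input_path = Path(cfg["input"])

    transients = read_transients(input_path)
    log.info("read: %d validated transients from %s", len(transients), input_path)

    jip_cfg = cfg.get("jip") or {}
    jip = jip_table(transients, eps_flat=jip_cfg.get("eps_flat"))
    n_flat = int(jip["flat"].sum())
    n_degen = int(jip["vj_degenerate"].sum())
    log.info("jip: %d leaf records (%d flat, %d VJ-degenerate excluded from ratios)", len(jip), n_flat, n_degen)
    jip_path = out / "jip_params.tsv"
    write_jip_table(jip, jip_path)
    outputs["jip_params"] = jip_path

    pipe_cfg = cfg.get("pipeline") or {}
    control = float(pipe_cfg.get("control", 0.0))
    fmt = pipe_cfg.get("format", "svg")
    n_circles = int(pipe_cfg.get("n_circles", 12))
    figs_dir = out / "figs"
    figs_dir.mkdir(exist_ok=True)
    control_records = jip[jip["rcr_percent"] == control]
    control_model = build_pipeline_model(
        control_records, control_records, n_circles=n_circles, group_label=control
    )
    for group, records in jip.groupby("rcr_percent"):
        model = build_pipeline_model(
            records, control_records, n_circles=n_circles, group_label=float(group)
        )
        fig_path = figs_dir / f"pipeline_rcr{group:g}.{fmt}"
        render_pipeline(model, fig_path, reference_abs=control_model.abs_cs0)
        outputs[f"pipeline_rcr{group:g}"] = fig_path

    stats_cfg = cfg.get("stats") or {}
    params = stats_cfg.get("parameters", list(DEFAULT_THRESHOLD_PARAMETERS))
    stratify = stats_cfg.get("stratify")
    stats_control = float(stats_cfg.get("control", control))
    comparisons = parameter_comparisons(jip, params, control=stats_control, stratify_by=stratify)
    res_path = out / "results.tsv"
    results_table(list(comparisons.values())).to_csv(
        res_path, sep="\t", index=False, na_rep="NA", float_format="%.10g"
    )
    outputs["results"] = res_path
    log.info("stats: %d parameters, stratify=%s", len(params), stratify)

    thr_cfg = cfg.get("threshold") or {}
    manifest.threshold_rcr = threshold_from_jip(
        jip,
        parameters=thr_cfg.get("parameters", list(DEFAULT_THRESHOLD_PARAMETERS)),
        control=float(thr_cfg.get("control", stats_control)),
        clock_time=thr_cfg.get("clock_time", DEFAULT_THRESHOLD_CLOCK_TIME),
    )
    log.info("threshold: %s", manifest.threshold_rcr)

    manifest.outputs = {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()}
    manifest.finished_utc = time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
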