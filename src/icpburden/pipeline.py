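"""End-to-end orchestration: simulate/read -> summarize -> stratify ->
associate -> model, as one configured, logged, reproducible run.

A run consumes either real data (traces + outcomes CSVs) or a simulation
config, never both, and writes into an output directory:

* ``traces.csv`` / ``outcomes.csv`` (simulated runs only)
* ``summaries.csv``  — per-patient burden metrics
* ``labels.csv``     — risk-band labels and flags
* ``association.json`` — the statistical battery
* ``model.json``     — classifier reports per (threshold, model)
* ``manifest.json``  — config hash, seed, package version, file checksums
* ``run.log``

All files are written atomically (temp file + rename) and JSON is emitted
with sorted keys, so rerunning an identical config reproduces the report
files byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .burden import summarize_cohort
from .exceptions import ConfigError
from .io import (
    Cohort,
    read_outcomes,
    read_traces,
    write_outcomes,
    write_summaries,
    write_traces,
)
from .models import build_features, crossval_evaluate
from .simulate import SimConfig, generate_cohort
from .stats import run_association_suite
from .stratify import RiskBands, classify_cohort

log = logging.getLogger("icpburden")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; exactly one input source."""

    outdir: Path
    seed: int
    sim: SimConfig | None = None
    traces_csv: Path | None = None
    outcomes_csv: Path | None = None
    window_h: float = 72.0
    thresholds: tuple[float, ...] = (15.0, 20.0)
    norm_mode: str = "actual"
    dose_mode: str = "excess"
    gap_tolerance_h: float = 1.0
    bands: RiskBands = field(default_factory=RiskBands)
    frac_cutoff: float = 0.30
    model_threshold: float = 20.0
    models: tuple[str, ...] = ("forest", "boosting")
    scheme: str = "loo"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        have_files = self.traces_csv is not None or self.outcomes_csv is not None
        if self.sim is not None and have_files:
            raise ConfigError("provide either a simulation config or data files, not both")
        if self.sim is None and (self.traces_csv is None or self.outcomes_csv is None):
            raise ConfigError("real-data runs need both traces_csv and outcomes_csv")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        d["traces_csv"] = None if self.traces_csv is None else str(self.traces_csv)
        d["outcomes_csv"] = None if self.outcomes_csv is None else str(self.outcomes_csv)
        d["thresholds"] = list(self.thresholds)
        d["models"] = list(self.models)
        return d

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load a flat key-value (YAML) config file.

        Simulation keys are prefixed ``sim_`` (e.g. ``sim_n_patients``),
        band keys ``band_`` (e.g. ``band_cutoff``); everything else maps
        directly onto :class:`RunConfig` fields.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must be a flat mapping")
        raw.update(overrides)

        sim_kwargs = {k[4:]: v for k, v in raw.items() if k.startswith("sim_")}
        band_kwargs = {k[5:]: v for k, v in raw.items() if k.startswith("band_")}
        rest = {
            k: v for k, v in raw.items()
            if not k.startswith("sim_") and not k.startswith("band_")
        }
        if "seed" not in rest:
            raise ConfigError("config must set 'seed'")
        if sim_kwargs:
            sim_kwargs.setdefault("seed", rest["seed"])
            rest["sim"] = SimConfig(**sim_kwargs)
        if band_kwargs:
            rest["bands"] = RiskBands(**band_kwargs)
        if "thresholds" in rest:
            rest["thresholds"] = tuple(float(t) for t in rest["thresholds"])
        if "models" in rest:
            rest["models"] = tuple(rest["models"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(rest) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**rest)


# ---------------------------------------------------------------------------
# atomic writers


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _atomic(writer, path: Path, *args) -> None:
    tmp = path.with_name(path.name + ".tmp")
    writer(*args, tmp)
    os.replace(tmp, path)


def _json_text(obj) -> str:
    return json.dumps(obj, indent=2, sort_keys=True) + "\n"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------


def _load_cohort(config: RunConfig) -> Cohort:
    if config.sim is not None:
        log.info("simulating cohort: n=%d seed=%d", config.sim.n_patients, config.sim.seed)
        return generate_cohort(config.sim)
    log.info("reading traces from %s", config.traces_csv)
    traces = read_traces(config.traces_csv, window_h=config.window_h)
    outcomes = read_outcomes(config.outcomes_csv)
    return Cohort(traces=traces, outcomes=outcomes)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the output directory.

    Any stage failure propagates with the stage named in the log; partial
    outputs are never left half-written (atomic renames).
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)

    logger = logging.getLogger("icpburden")
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    level = logger.level
    logger.setLevel(config.log_level)
    written: dict[str, Path] = {}
    try:
        stage = "input"
        cohort = _load_cohort(config)
        if config.sim is not None:
            _atomic(lambda tr, p: write_traces(tr, p), outdir / "traces.csv", cohort.traces)
            _atomic(lambda oc, p: write_outcomes(oc, p), outdir / "outcomes.csv", cohort.outcomes)
            written["traces.csv"] = outdir / "traces.csv"
            written["outcomes.csv"] = outdir / "outcomes.csv"

        stage = "summarize"
        summaries = summarize_cohort(
            cohort.traces,
            thresholds=config.thresholds,
            gap_tolerance_h=config.gap_tolerance_h,
            norm_mode=config.norm_mode,
            dose_mode=config.dose_mode,
            window_h=config.window_h,
        )
        _atomic(lambda s, p: write_summaries(s, p), outdir / "summaries.csv", summaries)
        written["summaries.csv"] = outdir / "summaries.csv"

        stage = "stratify"
        labels = classify_cohort(summaries, config.bands)
        label_df = pd.DataFrame(
            [
                (pid, lab.band, lab.certain_poor_flag, lab.time_rule_flag)
                for pid, lab in sorted(labels.items())
            ],
            columns=["patient_id", "band", "certain_poor_flag", "time_rule_flag"],
        )
        _atomic(lambda df, p: df.to_csv(p, index=False), outdir / "labels.csv", label_df)
        written["labels.csv"] = outdir / "labels.csv"

        stage = "associate"
        report = run_association_suite(
            summaries,
            cohort.outcomes,
            thresholds=config.thresholds,
            frac_cutoff=config.frac_cutoff,
        )
        _atomic_write_text(outdir / "association.json", _json_text(report.to_dict()))
        written["association.json"] = outdir / "association.json"

        stage = "model"
        rows = build_features(summaries, cohort.outcomes, threshold=config.model_threshold)
        model_reports = {}
        for model_name in config.models:
            rep = crossval_evaluate(
                rows,
                model_name=model_name,
                scheme=config.scheme,
                seed=config.seed,
                threshold_mmHg=config.model_threshold,
            )
            model_reports[model_name] = rep.to_dict()
        _atomic_write_text(outdir / "model.json", _json_text(model_reports))
        written["model.json"] = outdir / "model.json"

        stage = "manifest"
        config_text = _json_text(config.to_dict())
        manifest = {
            "package": "icpburden",
            "version": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
            "files": {name: _sha256(path) for name, path in sorted(written.items())},
        }
        _atomic_write_text(outdir / "manifest.json", _json_text(manifest))
    except Exception as exc:
        log.error("pipeline failed at stage %r: %s", stage, exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
        logger.setLevel(level)
    return outdir
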