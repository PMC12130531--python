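"""End-to-end orchestration: normalize → simulate → call DASCs, with manifests.

A :class:`RunConfig` (strictly validated; unknown keys rejected) drives the
stages.  Each stage is resumable: it is skipped when its outputs already
exist and are newer than its inputs.  A failing stage aborts the run with
the stage named, leaving any in-progress outputs behind with a
``.partial`` suffix.  The run manifest (inputs hashes, parameters, stage
outputs, package version, seed) suffices to reproduce the run bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .dasc import call_dasc, pool_by_group
from .dynamics import (
    ActivitySimulator,
    read_activities,
    write_activities,
    write_activity_summary,
)
from .expression import ExpressionMatrix, normalize_expression, read_labels
from .network import read_links_tsv

logger = logging.getLogger("netdasc")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _check_range(name: str, value, lo=None, hi=None, strict_lo=False):
    if lo is not None and (value <= lo if strict_lo else value < lo):
        raise ValueError(f"config field {name!r} out of range: {value}")
    if hi is not None and value > hi:
        raise ValueError(f"config field {name!r} out of range: {value}")


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    network: str
    expression: str
    labels: str
    outdir: str
    # model
    tau: float = 1.0
    hill_n: float = 3.0
    hill_k: float = 0.5
    default_capacity: float = 0.5
    lower_q: float = 0.01
    upper_q: float = 0.99
    # simulation
    n_init: int = 1000
    dt: float = 0.1
    t_max: float = 100.0
    tol: float = 1e-6
    seed: int = 0
    # dasc
    alpha: float = 0.05
    min_effect: float = 0.1
    max_per_group: int = 10_000
    effective_n: str = "samples"
    cohort: str = "cohort"

    def validate(self) -> "RunConfig":
        _check_range("tau", self.tau, lo=0, strict_lo=True)
        _check_range("hill_n", self.hill_n, lo=1)
        _check_range("hill_k", self.hill_k, lo=0, hi=1, strict_lo=True)
        _check_range("default_capacity", self.default_capacity, lo=0, hi=1)
        _check_range("lower_q", self.lower_q, lo=0, hi=1)
        _check_range("upper_q", self.upper_q, lo=0, hi=1)
        if not self.lower_q < self.upper_q:
            raise ValueError("config field 'lower_q' must be below 'upper_q'")
        _check_range("n_init", self.n_init, lo=1)
        _check_range("dt", self.dt, lo=0, strict_lo=True)
        _check_range("t_max", self.t_max, lo=0, strict_lo=True)
        _check_range("tol", self.tol, lo=0, strict_lo=True)
        if not 0 < self.alpha < 1:
            raise ValueError(f"config field 'alpha' out of range: {self.alpha}")
        _check_range("min_effect", self.min_effect, lo=0, hi=1)
        _check_range("max_per_group", self.max_per_group, lo=1)
        if self.effective_n not in ("samples", "draws"):
            raise ValueError("config field 'effective_n' must be 'samples' or 'draws'")
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d).validate()


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must define a mapping")
    return RunConfig.from_dict(raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _fresh(outputs: list[Path], inputs: list[Path]) -> bool:
    if not all(p.exists() for p in outputs):
        return False
    newest_in = max(p.stat().st_mtime for p in inputs)
    return all(p.stat().st_mtime >= newest_in for p in outputs)


def _run_stage(name: str, outputs: list[Path], inputs: list[Path], fn) -> bool:
    """Run one stage unless its outputs are newer than its inputs."""
    if _fresh(outputs, inputs):
        logger.info("stage=%s status=skipped (outputs up to date)", name)
        return False
    t0 = time.perf_counter()
    try:
        fn()
    except Exception as exc:
        for p in outputs:
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    logger.info("stage=%s status=done wall_clock=%.2fs", name, time.perf_counter() - t0)
    return True


def run_pipeline(config: RunConfig) -> dict:
    """Execute normalize → simulate → dasc and write a run manifest.

    Returns the manifest dictionary (also written to ``manifest.json`` in
    the output directory).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net_path, expr_path, labels_path = (
        Path(config.network),
        Path(config.expression),
        Path(config.labels),
    )
    for p in (net_path, expr_path, labels_path):
        if not p.exists():
            raise PipelineError(f"stage 'inputs' failed: missing input file {p}")

    norm_path = outdir / "normalized.tsv"
    act_path = outdir / "activities.tsv"
    act_summary_path = outdir / "activity_summary.tsv"
    dasc_path = outdir / "dasc.tsv"
    manifest_path = outdir / "manifest.json"

    logger.info(
        "run start: network=%s expression=%s labels=%s seed=%d n_init=%d "
        "dt=%g tol=%g alpha=%g min_effect=%g",
        net_path, expr_path, labels_path, config.seed, config.n_init,
        config.dt, config.tol, config.alpha, config.min_effect,
    )

    def stage_normalize():
        matrix = ExpressionMatrix.from_tsv(expr_path)
        norm = normalize_expression(matrix, lower_q=config.lower_q, upper_q=config.upper_q)
        norm.to_tsv(norm_path)

    def stage_simulate():
        net = read_links_tsv(net_path)
        norm = ExpressionMatrix.from_tsv(norm_path, normalized=True)
        sim = ActivitySimulator(
            network=net,
            n_init=config.n_init,
            dt=config.dt,
            t_max=config.t_max,
            tol=config.tol,
            tau=config.tau,
            hill_n=config.hill_n,
            hill_k=config.hill_k,
            default_capacity=config.default_capacity,
            random_state=config.seed,
        ).fit(norm.data.T)
        dists = sim.simulate(norm.data.T)
        write_activities(dists, act_path)
        write_activity_summary(dists, act_summary_path)

    def stage_dasc():
        labels = read_labels(labels_path)
        dists = read_activities(act_path)
        grouped = pool_by_group(
            dists, labels, max_per_group=config.max_per_group, cohort=config.cohort
        )
        res = call_dasc(
            grouped,
            alpha=config.alpha,
            min_effect=config.min_effect,
            effective_n=config.effective_n,
        )
        res.to_csv(dasc_path, sep="\t", index=False)

    stages = [
        ("normalize", [norm_path], [expr_path], stage_normalize),
        ("simulate", [act_path, act_summary_path], [norm_path, net_path], stage_simulate),
        ("dasc", [dasc_path], [act_path, labels_path], stage_dasc),
    ]
    executed = {}
    for name, outputs, inputs, fn in stages:
        executed[name] = _run_stage(name, outputs, inputs, fn)

    manifest = {
        "netdasc_version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "inputs": {str(p): _sha256(p) for p in (net_path, expr_path, labels_path)},
        "stages": {
            name: {"outputs": [str(p) for p in outputs], "executed": executed[name]}
            for name, outputs, _, _ in stages
        },
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    logger.info("run complete: manifest=%s", manifest_path)
    return manifest


def rerun_from_manifest(manifest_path) -> dict:
    """Re-execute a run from its manifest alone (bit-for-bit reproduction)."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    config = RunConfig.from_dict(manifest["parameters"])
    return run_pipeline(config)
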