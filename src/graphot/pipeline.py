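"""End-to-end orchestration: configuration, logging, pipeline runs.

A :class:`PipelineConfig` (optionally loaded from a YAML file) fixes the
font, rendering height, letter set, metrics, ROI, analysis windows, MCMC
settings and seeds.  :func:`run_pipeline` ties the stages together on
synthetic data: render letters, build model RDMs, generate synthetic
epochs, compute per-participant neural RDMs, run the Bayesian RSA, and
write all outputs plus a manifest (versions, seeds, config hash) to a
results directory.  Existing outputs are never overwritten unless
``overwrite=True``.

Exact Wasserstein RDMs are computed at a reduced working height
(``ot_height_px``) because the dense transport LP grows quadratically in
the glyph support; Jaccard RDMs use the full rendering height.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .design import DesignConfig, generate_trial_schedule, schedule_to_tsv
from .glyphs import GERMAN_LETTERS, render_letter_set
from .graphetic import build_model_rdm, rank_transform_rdm, rdm_to_csv
from .inference import MCMCConfig, run_planned_analysis
from .neural import DEFAULT_ROI, all_participant_rank_rdms
from .synth import SynthConfig, synth_epochs

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("graphot")


@dataclass(frozen=True)
class PipelineConfig:
    font: str | None = None  # None -> bundled open sans-serif
    render_height_px: int = 250
    ot_height_px: int = 32
    letters: tuple[str, ...] = GERMAN_LETTERS
    metrics: tuple[str, ...] = ("wasserstein", "jaccard")
    roi: tuple[str, ...] = DEFAULT_ROI
    planned_window_ms: tuple[float, float] = (150.0, 225.0)
    exploratory_window_ms: tuple[float, float] = (80.0, 130.0)
    run_exploratory_window: bool = False
    timecourse_bin_ms: int = 10
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for win in (self.planned_window_ms, self.exploratory_window_ms):
            lo, hi = self.synth.epoch_span_ms
            if not (lo <= win[0] < win[1] <= hi):
                raise ValueError(f"analysis window {win} outside epoch span")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str) -> PipelineConfig:
    """Load and validate a pipeline configuration from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "mcmc" in raw:
        raw["mcmc"] = MCMCConfig(**raw["mcmc"])
    if "synth" in raw:
        synth = dict(raw["synth"])
        for key in ("weights", "epoch_span_ms", "signal_window_ms"):
            if key in synth:
                synth[key] = tuple(synth[key])
        raw["synth"] = SynthConfig(**synth)
    for key in ("letters", "metrics", "roi"):
        if key in raw:
            raw[key] = tuple(raw[key])
    for key in ("planned_window_ms", "exploratory_window_ms"):
        if key in raw:
            raw[key] = tuple(float(v) for v in raw[key])
    return PipelineConfig(**raw)


def _prepare_out(path: str, overwrite: bool) -> None:
    if os.path.exists(path) and os.listdir(path) and not overwrite:
        raise FileExistsError(
            f"output directory {path} is not empty; pass overwrite=True"
        )
    os.makedirs(path, exist_ok=True)


def run_pipeline(config: PipelineConfig, overwrite: bool = False) -> str:
    """Run the synthetic end-to-end analysis; returns the results directory.

    Stages: model RDMs -> trial schedule -> synthetic epochs -> neural
    RDMs (planned window, optionally the earlier exploratory window) ->
    Bayesian RSA.  Each stage logs its timing; any stage error aborts the
    run with the stage name attached.
    """
    cfg = config
    _prepare_out(cfg.out_dir, overwrite)
    manifest: dict = {
        "graphot_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": dataclasses.asdict(cfg),
        "outputs": [],
        "stages": {},
    }

    def stage(name: str):
        class _Stage:
            def __enter__(self_inner):
                log.info("stage %s: start", name)
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                manifest["stages"][name] = round(dt, 3)
                if exc is not None:
                    log.error("stage %s failed after %.2fs: %s", name, dt, exc)
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                log.info("stage %s: done in %.2fs", name, dt)
                return False

        return _Stage()

    def emit(fname: str) -> str:
        manifest["outputs"].append(fname)
        return os.path.join(cfg.out_dir, fname)

    with stage("model_rdms"):
        images = render_letter_set(cfg.letters, cfg.font, cfg.render_height_px)
        model_rdms = {}
        for metric in cfg.metrics:
            height = cfg.ot_height_px if metric in ("wasserstein", "gw") else None
            if height is not None:
                small = render_letter_set(cfg.letters, cfg.font, height)
                rdm = build_model_rdm(small, metric=metric, seed=cfg.seed)
            else:
                rdm = build_model_rdm(images, metric=metric)
            model_rdms[metric] = rdm
            rdm_to_csv(rdm, emit(f"model_rdm_{metric}.csv"))
            rdm_to_csv(rank_transform_rdm(rdm), emit(f"model_rdm_{metric}_rank.csv"))

    with stage("design"):
        # the task design is fixed to the 30-letter session; skip for subsets
        if len(cfg.letters) == 30:
            schedule = generate_trial_schedule(DesignConfig(), seed=cfg.seed)
            schedule_to_tsv(schedule, emit("trial_schedule.tsv"))

    with stage("synth_epochs"):
        synth_cfg = dataclasses.replace(cfg.synth, seed=cfg.seed)
        epochs = synth_epochs(synth_cfg, list(model_rdms.values()))

    windows = [("planned", cfg.planned_window_ms)]
    if cfg.run_exploratory_window:
        windows.append(("exploratory", cfg.exploratory_window_ms))

    for win_name, win in windows:
        tag = f"{int(win[0])}-{int(win[1])}"
        with stage(f"neural_rdms_{tag}"):
            neural = all_participant_rank_rdms(epochs, roi=_roi_for(epochs, cfg), window_ms=win)
        with stage(f"rsa_{tag}"):
            models_rank = {
                name: rank_transform_rdm(rdm) for name, rdm in model_rdms.items()
            }
            result = run_planned_analysis(
                models_rank, neural,
                dataclasses.replace(cfg.mcmc, seed=cfg.seed),
            )
            with open(emit(f"rsa_{win_name}_{tag}.json"), "w", encoding="utf-8") as fh:
                json.dump(result.to_dict(), fh, indent=1)
            draws = {
                f"rho_neural_{m}": result.posterior.corr_samples("neural", m)
                for m in result.model_names
            }
            import pandas as pd

            pd.DataFrame(draws).to_csv(
                emit(f"rsa_{win_name}_{tag}_draws.csv"), index=False
            )

    with open(os.path.join(cfg.out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return cfg.out_dir


def _roi_for(epochs, cfg: PipelineConfig) -> tuple[str, ...]:
    # synthetic data may use generic channel names; fall back to all channels
    if all(ch in epochs.channel_names for ch in cfg.roi):
        return cfg.roi
    return epochs.channel_names
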