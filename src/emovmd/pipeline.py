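"""End-to-end pipeline: YAML config, stage orchestration, run manifest.

``run_all`` chains simulate -> preprocess -> featurize -> train ->
ablation -> explain (plus an optional window-length sweep), writing each
stage's artifact under the output directory and recording a manifest with
the config hash, per-stage seeds, artifact checksums and durations.  One
global seed deterministically derives a per-stage seed by hashing the stage
name, so a single knob reproduces the whole run.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import synth
from .errors import ConfigurationError
from .features import WindowSpec, extract_features
from .io import read_recording, write_recording
from .modeling import (
    CVSpec,
    ModelSpec,
    SplitSpec,
    ablation_table,
    build_model,
    explain,
    split_data,
    sweep_windows,
    train_eval,
)
from .preprocess import FilterSpec, ICAReport, SGSpec, bandpass_zero_phase, ica_remove_ocular, sg_detrend
from .vmd import VMDConfig

__all__ = ["PipelineConfig", "RunManifest", "run_all", "load_config", "stage_seed"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParadigmSection(_Strict):
    fs: float = 128.0
    n_channels: int = 32
    relax_initial_s: float = 10.0
    image_duration_s: float = 5.0
    images_per_emotion: int = 3
    inter_emotion_relax_s: float = 5.0
    emotion_order: list[str] = Field(default=["happy", "sad", "fear"])
    n_phases: int = 2


class ComponentSection(_Strict):
    band: str
    carrier_hz: float
    amplitude: float
    am_depth: float = 0.2
    am_freq_hz: float = 0.25


class EffectsSection(_Strict):
    preset: Literal["default", "null"] = "default"
    noise_pink_scale: float = 2.0
    components: dict[str, dict[str, ComponentSection]] | None = None
    drift_degree: int = 2
    drift_amplitude: float = 20.0
    blink_rate_per_min: float = 10.0
    blink_amplitude: float = 75.0
    blink_duration_s: float = 0.4


class FilterSection(_Strict):
    low_hz: float = 0.5
    high_hz: float = 45.0
    transition_hz: float = 0.5


class SGSection(_Strict):
    frame_length: int = 127
    poly_order: int = 5


class ICASection(_Strict):
    enabled: bool = True
    corr_threshold: float = 0.7
    frontal_channels: list[str] = Field(default=["Fp1", "Fp2"])


class VMDSection(_Strict):
    k: int = 5
    alpha: float = 2000.0
    tau: float = 0.0
    tol: float = 1.0e-7
    max_iter: int = 500
    init: str = "uniform"


class WindowSection(_Strict):
    length_s: float = 3.0
    overlap_frac: float = 0.5

    @field_validator("overlap_frac")
    @classmethod
    def _overlap_range(cls, v: float) -> float:
        if not (0 <= v < 1):
            raise ValueError(f"overlap_frac must lie in [0, 1), got {v}")
        return v


class ModelSection(_Strict):
    kind: str = "RF"
    params: dict = Field(default_factory=dict)


class SplitSection(_Strict):
    train_frac: float = 0.8
    stratified: bool = True
    grouping: Literal["none", "by_trial"] = "none"


class CVSection(_Strict):
    n_folds: int = 6
    shuffled: bool = True


class ExplainSection(_Strict):
    method: Literal["tree_path", "permutation"] = "tree_path"
    n_repeats: int = 20


class SweepSection(_Strict):
    enabled: bool = False
    lengths_s: list[float] = Field(default=[1, 2, 3, 4, 15])


class PipelineConfig(_Strict):
    """Validated, versioned configuration of the whole pipeline."""

    schema_version: int = 1
    seed: int = 0
    out_dir: str = "emovmd_run"
    format: Literal["csv", "edf"] = "csv"
    recording_path: str | None = None  # supply to skip the simulate stage
    paradigm: ParadigmSection = Field(default_factory=ParadigmSection)
    effects: EffectsSection = Field(default_factory=EffectsSection)
    filter: FilterSection = Field(default_factory=FilterSection)
    sg: SGSection = Field(default_factory=SGSection)
    ica: ICASection = Field(default_factory=ICASection)
    vmd: VMDSection = Field(default_factory=VMDSection)
    window: WindowSection = Field(default_factory=WindowSection)
    model: ModelSection = Field(default_factory=ModelSection)
    split: SplitSection = Field(default_factory=SplitSection)
    cv: CVSection = Field(default_factory=CVSection)
    explain: ExplainSection = Field(default_factory=ExplainSection)
    sweep: SweepSection = Field(default_factory=SweepSection)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config (unknown keys rejected); overrides win."""
    payload: dict = {}
    if path is not None:
        payload = yaml.safe_load(Path(path).read_text()) or {}
    payload.update(overrides)
    try:
        return PipelineConfig(**payload)
    except Exception as exc:
        raise ConfigurationError(f"invalid pipeline config: {exc}") from exc


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _effects_from_config(cfg: EffectsSection) -> synth.ClassEffectSpec:
    if cfg.components is not None:
        comps = {
            cls: {
                band: synth.ComponentSpec(
                    band=c.band,
                    carrier_hz=c.carrier_hz,
                    amplitude=c.amplitude,
                    am_depth=c.am_depth,
                    am_freq_hz=c.am_freq_hz,
                )
                for band, c in bandmap.items()
            }
            for cls, bandmap in cfg.components.items()
        }
    elif cfg.preset == "null":
        comps = {}
    else:
        comps = synth.default_effects().components
    return synth.ClassEffectSpec(
        components=comps,
        noise_pink_scale=cfg.noise_pink_scale,
        drift=synth.DriftSpec(degree=cfg.drift_degree, amplitude=cfg.drift_amplitude),
        blink=synth.BlinkSpec(
            rate_per_min=cfg.blink_rate_per_min,
            amplitude=cfg.blink_amplitude,
            duration_s=cfg.blink_duration_s,
        ),
    )


def _paradigm_from_config(cfg: ParadigmSection) -> synth.ParadigmSpec:
    return synth.ParadigmSpec(
        fs=cfg.fs,
        n_channels=cfg.n_channels,
        relax_initial_s=cfg.relax_initial_s,
        image_duration_s=cfg.image_duration_s,
        images_per_emotion=cfg.images_per_emotion,
        inter_emotion_relax_s=cfg.inter_emotion_relax_s,
        emotion_order=tuple(cfg.emotion_order),
        n_phases=cfg.n_phases,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    seed: int
    started: float
    stages: list[str] = dc_field(default_factory=list)
    stage_seconds: dict = dc_field(default_factory=dict)
    checksums: dict = dc_field(default_factory=dict)
    finished: float | None = None

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "started": self.started,
            "finished": self.finished,
            "stages": self.stages,
            "stage_seconds": self.stage_seconds,
            "checksums": self.checksums,
        }


def run_all(config: PipelineConfig, out_dir: str | Path | None = None) -> RunManifest:
    """Execute every configured stage; artifacts land under the output dir.

    A stage failure halts the run with the failing stage named; artifacts of
    completed stages are left in place.
    """
    tracker = {"stage": "simulate"}
    try:
        return _run_all(config, out_dir, tracker)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {tracker['stage']!r} failed: {exc}") from exc


def _run_all(
    config: PipelineConfig, out_dir: str | Path | None, tracker: dict
) -> RunManifest:
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_text = json.dumps(config.model_dump(), sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(config_text.encode()).hexdigest(),
        seed=config.seed,
        started=time.time(),
    )

    def checkpoint(stage: str, t0: float, *paths: Path) -> None:
        manifest.stages.append(stage)
        manifest.stage_seconds[stage] = round(time.time() - t0, 3)
        for p in paths:
            manifest.checksums[p.name] = _sha256(p)

    # -- simulate ----------------------------------------------------------
    t0 = time.time()
    if config.recording_path is not None:
        recording = read_recording(config.recording_path, fs=None)
        manifest.stages.append("simulate:skipped")
    else:
        spec = _paradigm_from_config(config.paradigm)
        effects = _effects_from_config(config.effects)
        recording, _truth = synth.generate_recording(
            spec, effects, seed=stage_seed(config.seed, "simulate")
        )
        rec_path = out / f"recording.{config.format}"
        write_recording(recording, rec_path, config.format)
        checkpoint("simulate", t0, rec_path, *[
            p for p in (out / "recording_events.csv", out / "recording.meta.json") if p.exists()
        ])

    # -- preprocess --------------------------------------------------------
    tracker["stage"] = "preprocess"
    t0 = time.time()
    cleaned = bandpass_zero_phase(
        recording, FilterSpec(config.filter.low_hz, config.filter.high_hz, config.filter.transition_hz)
    )
    cleaned = sg_detrend(cleaned, SGSpec(config.sg.frame_length, config.sg.poly_order))
    ica_report: ICAReport | None = None
    if config.ica.enabled:
        cleaned, ica_report = ica_remove_ocular(
            cleaned,
            frontal_channels=config.ica.frontal_channels,
            corr_threshold=config.ica.corr_threshold,
            seed=stage_seed(config.seed, "ica"),
        )
    clean_path = out / "cleaned.csv"
    write_recording(cleaned, clean_path, "csv")
    report_path = out / "ica_report.json"
    report_path.write_text(
        json.dumps(ica_report.to_dict() if ica_report else {"enabled": False}, indent=2)
    )
    checkpoint("preprocess", t0, clean_path, report_path)

    # -- featurize ---------------------------------------------------------
    tracker["stage"] = "featurize"
    t0 = time.time()
    vmd_cfg = VMDConfig(
        K=config.vmd.k,
        alpha=config.vmd.alpha,
        tau=config.vmd.tau,
        tol=config.vmd.tol,
        max_iter=config.vmd.max_iter,
        init=config.vmd.init,
        seed=stage_seed(config.seed, "vmd"),
    )
    features = extract_features(
        cleaned,
        WindowSpec(config.window.length_s, config.window.overlap_frac),
        vmd_cfg,
    )
    feat_path = out / "features.csv"
    features.to_csv(feat_path, index=False)
    checkpoint("featurize", t0, feat_path)

    split_spec = SplitSpec(
        train_frac=config.split.train_frac,
        stratified=config.split.stratified,
        seed=stage_seed(config.seed, "split"),
        grouping=config.split.grouping,
    )
    cv_spec = CVSpec(
        n_folds=config.cv.n_folds,
        shuffled=config.cv.shuffled,
        seed=stage_seed(config.seed, "cv"),
    )
    model_spec = ModelSpec(
        kind=config.model.kind,
        params=config.model.params,
        seed=stage_seed(config.seed, "model"),
    )

    # -- train -------------------------------------------------------------
    tracker["stage"] = "train"
    t0 = time.time()
    report = train_eval(features, model_spec, split_spec, cv_spec)
    report_json = out / "eval_report.json"
    report_json.write_text(json.dumps(report.to_dict(), indent=2))
    checkpoint("train", t0, report_json)

    # -- sweep (optional) --------------------------------------------------
    tracker["stage"] = "sweep"
    if config.sweep.enabled:
        t0 = time.time()
        table = sweep_windows(
            cleaned,
            lengths_s=config.sweep.lengths_s,
            vmd=vmd_cfg,
            overlap_frac=config.window.overlap_frac,
            split=split_spec,
            cv=cv_spec,
        )
        sweep_path = out / "sweep.csv"
        table.to_csv(sweep_path, index=False)
        checkpoint("sweep", t0, sweep_path)

    # -- ablation ----------------------------------------------------------
    tracker["stage"] = "ablation"
    t0 = time.time()
    table = ablation_table(features, model_spec, split_spec, cv_spec, n_modes=config.vmd.k)
    ablation_path = out / "ablation.csv"
    table.to_csv(ablation_path)
    checkpoint("ablation", t0, ablation_path)

    # -- explain -----------------------------------------------------------
    tracker["stage"] = "explain"
    t0 = time.time()
    train_part, _ = split_data(features, split_spec)
    clf = build_model(model_spec)
    cols = [c for c in features.columns if c.startswith("IMF")]
    clf.fit(train_part[cols].to_numpy(), train_part["label"].to_numpy())
    importance = explain(
        clf,
        features,
        method=config.explain.method,
        seed=stage_seed(config.seed, "explain"),
        n_repeats=config.explain.n_repeats,
    )
    imp_path = out / "importance.json"
    imp_path.write_text(json.dumps(importance.to_dict(), indent=2))
    checkpoint("explain", t0, imp_path)

    manifest.finished = time.time()
    (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2))
    return manifest
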