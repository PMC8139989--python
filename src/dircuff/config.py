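"""Validated run configuration and the end-to-end pipeline composition.

A :class:`RunConfig` gathers every stage's parameters (defaults are the
published protocol/processing constants: 700-µV artifact limit, 250 Hz–10 kHz
band, 41-sample windows, mean ± 3σ thresholds, 60/40 and 85/15 splits, 15-s
analysis bins, five 15-s obstructions separated by 1 min) behind a schema
that is validated before any stage runs. A single master seed fans out
deterministically to the stages, so a rerun with the same config is
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import classify, features, io, physio, pipeline
from .construct import compute_rnp
from .synth import (
    CONDITIONS,
    CuffGeometry,
    Protocol,
    ScenarioConfig,
    simulate_recording,
)

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


class SimulationSection(BaseModel):
    baseline_s: float = 60.0
    n_obstructions: int = 5
    obstruction_s: float = 15.0
    gap_s: float = 60.0
    post_s: float = 60.0
    conduction_velocity: float = 25.0
    target_snr_db: float = 6.05
    peak_amplitude_uv: float = 8.0
    afferent_rate: float = 300.0
    efferent_rate: float = 200.0
    respiratory_rate: float = 1.5
    obstruction_suppression: float = Field(0.05, ge=0.0, le=1.0)
    sampling_rate: float = 40_000.0

    @model_validator(mode="after")
    def _check(self):
        if min(self.baseline_s, self.obstruction_s, self.post_s) <= 0:
            raise ValueError("protocol durations must be positive")
        return self


class ProcessingSection(BaseModel):
    artifact_limit_uv: float = 700.0
    band_low_hz: float = 250.0
    band_high_hz: float = 10_000.0
    window_len: int = 41
    min_separation: int = 20
    threshold_k: float = 3.0

    @model_validator(mode="after")
    def _check(self):
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("band edges must satisfy 0 < low < high")
        if self.window_len != pipeline.WINDOW_LEN:
            raise ValueError(f"window_len is fixed at {pipeline.WINDOW_LEN} samples")
        return self


class ClassificationSection(BaseModel):
    algorithm: str = "svm_gaussian"
    scheme: str = "model1"
    weight_grid: tuple[float, ...] = (1.0, 1.25, 1.5, 2.0)
    tune_weights: bool = True

    @model_validator(mode="after")
    def _check(self):
        if self.algorithm not in classify.ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.scheme not in ("model1", "model2"):
            raise ValueError("scheme must be 'model1' or 'model2'")
        return self


class AnalysisSection(BaseModel):
    bin_s: float = Field(15.0, gt=0)


class RunConfig(BaseModel):
    simulation: SimulationSection = Field(default_factory=SimulationSection)
    processing: ProcessingSection = Field(default_factory=ProcessingSection)
    classification: ClassificationSection = Field(default_factory=ClassificationSection)
    analysis: AnalysisSection = Field(default_factory=AnalysisSection)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        ).hexdigest()[:16]

    def scenario(self, condition: str, seed: int | None = None) -> ScenarioConfig:
        s = self.simulation
        return ScenarioConfig(
            condition=condition,
            protocol=Protocol(
                baseline_s=s.baseline_s,
                n_obstructions=s.n_obstructions,
                obstruction_s=s.obstruction_s,
                gap_s=s.gap_s,
                post_s=s.post_s,
            ),
            geometry=CuffGeometry(sampling_rate=s.sampling_rate),
            conduction_velocity=s.conduction_velocity,
            target_snr_db=s.target_snr_db,
            peak_amplitude_uv=s.peak_amplitude_uv,
            afferent_rate=s.afferent_rate,
            efferent_rate=s.efferent_rate,
            respiratory_rate=s.respiratory_rate,
            obstruction_suppression=s.obstruction_suppression,
            seed=seed if seed is not None else stage_seed(self.seed, f"simulate:{condition}"),
        )


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """simulate → process → train → evaluate → analyze, writing all artifacts.

    One recording per transection paradigm is simulated; the proximal- and
    distal-transection windows form the labelled corpus, the
    complete-transection recording is the noise reference, and the intact
    recording supplies the obstruction analysis.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}

    recordings = {}
    for condition in CONDITIONS:
        rec = simulate_recording(config.scenario(condition))
        recordings[condition] = rec
        io.write_recording(out / f"rec_{condition}", rec, config_echo=stamp)
        logger.info("simulated %s: %d spikes", condition, rec.manifest.n_spikes)

    proc = config.processing
    noise_rec = recordings["complete_transection"]
    tables = []
    reports = {}
    tetras = {}
    for condition in CONDITIONS:
        rec = recordings[condition]
        windows, report, tetra = pipeline.process_recording(
            rec.contacts,
            noise_rec.contacts,
            condition=condition,
            artifact_limit_uv=proc.artifact_limit_uv,
            threshold_k=proc.threshold_k,
            min_separation=proc.min_separation,
        )
        reports[condition] = report
        tetras[condition] = tetra
        df = features.batch_extract(windows, rec.contacts.sampling_rate)
        df["experiment_id"] = condition
        df["peak_time_s"] = [w.peak_index / rec.contacts.sampling_rate for w in windows]
        tables.append(df)
        df.drop(columns=["peak_time_s"]).to_csv(out / f"features_{condition}.csv", index=False)
        logger.info("processed %s: %d windows", condition, report.n_windows)

    corpus = pd.concat(tables, ignore_index=True)
    labelled = corpus[corpus["label"].isin(["afferent", "efferent"])].reset_index(drop=True)

    cls = config.classification
    seed = stage_seed(config.seed, "split")
    if cls.scheme == "model1":
        train, val, test = classify.split_model1(labelled, seed=seed)
    else:
        held = sorted(labelled["experiment_id"].unique())[0]
        train, val, test = classify.split_model2(labelled, held, seed=seed)

    weights = {0: 1.0, 1: 1.0}
    if cls.tune_weights and len(val):
        ratio, _ = classify.tune_class_weights(
            cls.algorithm, train, val, grid=cls.weight_grid, seed=stage_seed(config.seed, "tune")
        )
        weights = {0: 1.0, 1: ratio}
    model = classify.train_classifier(
        train, cls.algorithm, class_weights=weights, seed=stage_seed(config.seed, "train")
    )
    report = classify.evaluate(model, test)
    with open(out / "eval_report.json", "w") as fh:
        json.dump(report.to_dict() | {"class_weights": {str(k): v for k, v in weights.items()}}, fh, indent=1)
    pd.DataFrame({"fpr": report.roc_fpr, "tpr": report.roc_tpr}).to_csv(out / "roc.csv", index=False)

    # obstruction analysis on the intact recording
    intact = recordings["intact"]
    fs = intact.contacts.sampling_rate
    protocol = config.scenario("intact").protocol
    bins = physio.make_bins(
        protocol.total_s, protocol.obstruction_intervals(), protocol.baseline_s, config.analysis.bin_s
    )
    rnp = compute_rnp(tetras["intact"], fs)
    results = []
    for name, binned in [
        ("RnP", physio.rnp_response(rnp, bins)),
        ("HR", physio.heart_rate(intact.ecg.data, intact.ecg.sampling_rate, bins)),
        ("BP", physio.mean_bp(intact.bp.data, intact.bp.sampling_rate, bins)),
        ("GGEMG", physio.ggemg_activity(intact.ggemg.data, intact.ggemg.sampling_rate, bins)),
    ]:
        resp = physio.percent_change(
            physio.epoch_values(binned, "baseline"), physio.epoch_values(binned, "obstruction"), name
        )
        results.append(resp.to_dict())
    pd.DataFrame(results).to_csv(out / "obstruction_responses.csv", index=False)

    with open(out / "run.json", "w") as fh:
        json.dump(
            stamp
            | {
                "elapsed_s": round(time.time() - t0, 2),
                "windows": {c: reports[c].n_windows for c in CONDITIONS},
                "thresholds_uv": {
                    c: [reports[c].thresholds.t_lower, reports[c].thresholds.t_upper]
                    for c in CONDITIONS
                },
                "accuracy": report.accuracy,
                "auc": report.auc,
            },
            fh,
            indent=1,
        )
    return out


def fixture_suite(seed: int, out_dir) -> dict[str, Path]:
    """Small deterministic fixtures: one 10-s recording per paradigm."""
    out = Path(out_dir)
    paths = {}
    protocol = Protocol(baseline_s=3.0, n_obstructions=1, obstruction_s=3.0, gap_s=1.0, post_s=4.0)
    for condition in CONDITIONS:
        cfg = ScenarioConfig(
            condition=condition, protocol=protocol, seed=stage_seed(seed, f"fixture:{condition}")
        )
        rec = simulate_recording(cfg)
        paths[condition] = io.write_recording(out / f"fixture_{condition}", rec)
    return paths
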