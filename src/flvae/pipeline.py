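"""End-to-end orchestration: phantom cohort -> preprocess -> VAE -> regions
-> scores -> paired comparison -> figures.

Every stochastic stage carries its own explicit seed (cohort generation,
training, region calibration), so a rerun with the same config reproduces all
numeric outputs exactly.  A config snapshot is written next to the outputs.
"""
from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import phantom as ph
from . import preprocess as pp
from . import report
from . import scoring
from . import stats as st
from . import vae
from .data import STATE_NO_THROMBUS, STATE_THROMBOSED, PatientSeries
from .latent_space import RegionSet, fit_regions, load_regions, save_regions

log = logging.getLogger("flvae.pipeline")

#: fraction of reference-state slices used to calibrate region polygons
DEFAULT_CALIBRATION_FRACTION = 0.2
#: hull dilation margin as a fraction of the distance between class centroids
DEFAULT_MARGIN_SCALE = 0.25


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    out_dir: str = "flvae_output"
    # phantom stage
    mix: Mapping[str, int] = field(default_factory=lambda: dict(ph.DEFAULT_MIX))
    n_slices: int = ph.DEFAULT_N_SLICES
    phantom_seed: Optional[int] = 0
    save_stacks: bool = False
    stack_format: str = "nifti"
    # vae stage
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    kl_weight: float = 10.0
    train_seed: Optional[int] = 0
    # region stage: either a region file or fit-from-labels calibration
    region_file: Optional[str] = None
    calibration_fraction: float = DEFAULT_CALIBRATION_FRACTION
    margin_scale: float = DEFAULT_MARGIN_SCALE
    calibration_seed: Optional[int] = 0
    # comparison + figures
    unchanged_tol: float = st.DEFAULT_UNCHANGED_TOL
    figure_dpi: int = 150
    make_figures: bool = True

    def validate(self) -> None:
        for name in ("phantom_seed", "train_seed", "calibration_seed"):
            if getattr(self, name) is None:
                raise ConfigError(f"config is missing required seed {name!r}")
        if not 0 < self.calibration_fraction <= 1:
            raise ConfigError("calibration_fraction must be in (0, 1]")
        if self.margin_scale < 0:
            raise ConfigError("margin_scale must be >= 0")
        if self.stack_format not in ("nifti", "tiff"):
            raise ConfigError("stack_format must be 'nifti' or 'tiff'")
        if sum(int(v) for v in dict(self.mix).values()) < 1:
            raise ConfigError("cohort mix must request at least one patient")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def snapshot(self, path: str) -> None:
        data = asdict(self)
        data["mix"] = dict(self.mix)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class PipelineResult:
    config: PipelineConfig
    patients: list[ph.PhantomPatient]
    truth: pd.DataFrame
    model: vae.TrainedModel
    regions: RegionSet
    patient_scores: pd.DataFrame
    slice_scores: pd.DataFrame
    comparison: st.CohortResult
    paths: dict[str, str]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


@_stage("phantom")
def _make_cohort(config: PipelineConfig):
    return ph.generate_cohort(
        mix=config.mix, n_slices=config.n_slices, rng_seed=config.phantom_seed
    )


@_stage("preprocess")
def _preprocess(patients: list[ph.PhantomPatient]) -> list[PatientSeries]:
    series: list[PatientSeries] = []
    for p in patients:
        for raw, labels in (
            (p.postop, p.postop_labels),
            (p.followup, p.followup_labels),
        ):
            processed, _ = pp.preprocess_series(raw, label_stack=labels)
            series.append(processed)
    return series


@_stage("train")
def _train(series: list[PatientSeries], config: PipelineConfig) -> vae.TrainedModel:
    images = [sl for s in series for sl in s.slices]
    cfg = vae.VaeConfig(
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        kl_weight=config.kl_weight,
        seed=int(config.train_seed),
    )
    log.info("training on %d images, %d epochs", len(images), cfg.epochs)
    return vae.train(images, cfg)


@_stage("calibrate_regions")
def calibrate_regions(
    model: vae.TrainedModel,
    series: list[PatientSeries],
    truth: pd.DataFrame,
    fraction: float = DEFAULT_CALIBRATION_FRACTION,
    margin_scale: float = DEFAULT_MARGIN_SCALE,
    rng_seed: int = 0,
) -> RegionSet:
    """Fit region polygons from a labeled calibration subset.

    Reference slices are those whose ground-truth state is unambiguous
    (thrombus fraction exactly 0 or exactly 1).  A stratified ``fraction`` of
    each class (at least 3 slices) is encoded and the two convex hulls,
    dilated by ``margin_scale`` times the distance between the class
    centroids, become the region polygons.

    Stray encodings are excluded before hull construction: a reference point
    that lies closer to the other class's centroid than to its own is treated
    as an outlier, just as a human drawing region boundaries around the two
    clouds would ignore stragglers.  This keeps the hulls disjoint when a few
    slices encode ambiguously.
    """
    by_key = {(s.patient_id, s.timepoint): s for s in series}
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed) & 0x7FFFFFFF, 7]))
    labeled = []
    for state in (STATE_NO_THROMBUS, STATE_THROMBOSED):
        sub = truth[truth["state"] == state]
        if len(sub) < 3:
            raise ValueError(
                f"cohort has only {len(sub)} reference slices of state {state!r}; "
                "need >= 3 to calibrate regions"
            )
        k = max(3, int(round(fraction * len(sub))))
        pick = sub.iloc[rng.choice(len(sub), size=min(k, len(sub)), replace=False)]
        for row in pick.itertuples():
            sl = by_key[(row.patient_id, row.timepoint)].slices[row.slice_index]
            labeled.append((model.encode(sl), state))
    pts = {s: np.array([p.as_array() for p, lab in labeled if lab == s])
           for s in (STATE_NO_THROMBUS, STATE_THROMBOSED)}
    cen = {s: pts[s].mean(0) for s in pts}
    centroid_dist = float(np.linalg.norm(cen[STATE_NO_THROMBUS] - cen[STATE_THROMBOSED]))
    margin = margin_scale * centroid_dist
    other = {
        STATE_NO_THROMBUS: STATE_THROMBOSED,
        STATE_THROMBOSED: STATE_NO_THROMBUS,
    }
    kept = []
    n_dropped = 0
    for point, label in labeled:
        p = point.as_array()
        own = np.linalg.norm(p - cen[label])
        if own < np.linalg.norm(p - cen[other[label]]):
            kept.append((point, label))
        else:
            n_dropped += 1
    log.info(
        "calibrating regions from %d labeled slices (%d outliers dropped, "
        "margin %.3f)",
        len(labeled), n_dropped, margin,
    )
    # If the dilated hulls collide in a narrow inter-class gap, retreat the
    # margin into the gap (a hand-drawn boundary would do the same); only a
    # genuine overlap of the undilated hulls is an error.
    for m in (margin, margin / 2, margin / 4, margin / 8, 0.0):
        try:
            return fit_regions(kept, margin=m)
        except ValueError as exc:
            if "overlap" not in str(exc) or m == 0.0:
                raise
            log.info("margin %.3f overlaps; retrying with %.3f", m, m / 2)
    raise AssertionError("unreachable")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run all stages and write the full output tree under ``config.out_dir``."""
    config.validate()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    config.snapshot(os.path.join(out, "config_snapshot.yaml"))
    paths: dict[str, str] = {"config": os.path.join(out, "config_snapshot.yaml")}

    patients, truth = _make_cohort(config)
    truth_path = os.path.join(out, "ground_truth.csv")
    truth.to_csv(truth_path, index=False)
    paths["ground_truth"] = truth_path

    if config.save_stacks:
        stack_dir = os.path.join(out, "stacks")
        for p in patients:
            pp.save_series(p.postop, stack_dir, config.stack_format, p.postop_labels)
            pp.save_series(p.followup, stack_dir, config.stack_format, p.followup_labels)
        paths["stacks"] = stack_dir

    series = _preprocess(patients)

    model = _train(series, config)
    model_path = os.path.join(out, "model.npz")
    model.save(model_path)
    history_path = os.path.join(out, "training_history.csv")
    model.history.to_csv(history_path, index=False)
    paths.update(model=model_path, history=history_path)

    if config.region_file is not None:
        regions = load_regions(config.region_file)
    else:
        regions = calibrate_regions(
            model,
            series,
            truth,
            fraction=config.calibration_fraction,
            margin_scale=config.margin_scale,
            rng_seed=config.calibration_seed,
        )
    regions_path = os.path.join(out, "regions.json")
    save_regions(regions, regions_path)
    paths["regions"] = regions_path

    patient_scores, slice_scores = scoring.score_cohort(model, regions, series)
    scores_path = os.path.join(out, "scores.csv")
    slice_scores_path = os.path.join(out, "slice_scores.csv")
    scoring.write_scores(patient_scores, slice_scores, scores_path, slice_scores_path)
    paths.update(scores=scores_path, slice_scores=slice_scores_path)

    comparison = st.run_comparison(patient_scores, tol=config.unchanged_tol)
    records_path = os.path.join(out, "paired_records.csv")
    comparison.records.round(6).to_csv(records_path, index=False)
    summary_path = os.path.join(out, "change_summary.csv")
    comparison.summary.to_csv(summary_path, index=False)
    tests_path = os.path.join(out, "test_results.json")
    with open(tests_path, "w") as fh:
        json.dump(comparison.to_json_dict(), fh, indent=2)
    paths.update(records=records_path, summary=summary_path, tests=tests_path)

    if config.make_figures:
        fig_dir = os.path.join(out, "figures")
        figs = report.render_cohort_figures(
            comparison.records, slice_scores, regions, fig_dir, dpi=config.figure_dpi
        )
        paths.update(figs)
        # lateral score maps for the first patient pair, for visual validation
        smax = slice_scores["score"].max()
        first = patients[0].patient_id
        for tp in ("postop", "followup"):
            sel = slice_scores[
                (slice_scores["patient_id"] == first)
                & (slice_scores["timepoint"] == tp)
            ].sort_values("slice_index")
            paths[f"lateral_{tp}"] = report.save_lateral_map(
                sel["score"].to_numpy(),
                smax if smax > 0 else 0.0,
                os.path.join(fig_dir, f"lateral_{first}_{tp}.png"),
                dpi=config.figure_dpi,
            )
        panel_imgs = [series[0].slices[i] for i in
                      np.linspace(0, len(series[0]) - 1, min(6, len(series[0]))).astype(int)]
        paths["reconstruction_panel"] = os.path.join(fig_dir, "reconstruction_panel.png")
        report.reconstruction_panel(model, panel_imgs, paths["reconstruction_panel"],
                                    dpi=config.figure_dpi)

    return PipelineResult(
        config=config,
        patients=patients,
        truth=truth,
        model=model,
        regions=regions,
        patient_scores=patient_scores,
        slice_scores=slice_scores,
        comparison=comparison,
        paths=paths,
    )
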