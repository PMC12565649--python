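"""Continuous thrombus score: per slice, per patient, and cohort-normalized.

For a slice encoded at latent position (x, y) with classified state s,

    score = 0                      if s = no_thrombus
    score = sqrt(x^2 + y^2)        if s = thrombosed
    score = sqrt(x^2 + y^2) / 3    if s = partial

i.e. radial distance from the latent origin, down-weighted for a partially
patent false lumen.  The per-patient score is the mean over all slices, which
makes it independent of scan length and slice thickness, and cohort scores
are normalized by the pooled maximum over both timepoints so the largest
burden maps to exactly 1 while zero stays zero.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import (
    STATE_NO_THROMBUS,
    STATE_PARTIAL,
    STATE_THROMBOSED,
    LatentPoint,
    PatientSeries,
)
from .latent_space import RegionSet, classify
from .vae import TrainedModel

PARTIAL_WEIGHT = 1.0 / 3.0
SCORE_DECIMALS = 3  # display precision in CSV outputs


@dataclass(frozen=True)
class SliceScore:
    patient_id: str
    timepoint: str
    slice_index: int
    state: str
    latent: LatentPoint
    score: float


def slice_score(point: LatentPoint | Sequence[float], state: str) -> float:
    """Piecewise radial score for one slice."""
    p = point if isinstance(point, LatentPoint) else LatentPoint(float(point[0]), float(point[1]))
    if state == STATE_NO_THROMBUS:
        return 0.0
    if state == STATE_THROMBOSED:
        return p.radius
    if state == STATE_PARTIAL:
        return p.radius / 3.0
    raise ValueError(f"unknown state label {state!r}")


def patient_score(slice_scores: Sequence[float | SliceScore]) -> float:
    """Mean slice score for one series (scan-length invariant)."""
    values = [s.score if isinstance(s, SliceScore) else float(s) for s in slice_scores]
    if not values:
        raise ValueError("cannot score an empty series")
    return float(np.mean(values))


def normalize_cohort(raw_scores: Sequence[float]) -> np.ndarray:
    """Divide by the pooled maximum so scores span [0, 1].

    All-zero cohorts are returned unchanged with a warning (no division).
    """
    raw = np.asarray(list(raw_scores), dtype=float)
    if raw.size == 0:
        raise ValueError("no scores to normalize")
    if (raw < 0).any():
        raise ValueError("raw scores must be nonnegative")
    m = raw.max()
    if m == 0:
        warnings.warn("all patient scores are zero; normalization is a no-op")
        return raw
    return raw / m


def score_series(
    model: TrainedModel, regions: RegionSet, series: PatientSeries
) -> list[SliceScore]:
    """Encode, classify and score every slice of one series."""
    out = []
    for sl in series.slices:
        point = model.encode(sl)
        state = classify(point, regions)
        out.append(
            SliceScore(
                patient_id=series.patient_id,
                timepoint=series.timepoint,
                slice_index=sl.slice_index,
                state=state,
                latent=point,
                score=slice_score(point, state),
            )
        )
    return out


def score_cohort(
    model: TrainedModel,
    regions: RegionSet,
    series_list: Iterable[PatientSeries],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a collection of series.

    Returns ``(patient_table, slice_table)``: the patient table has one row
    per (patient, timepoint) with raw and cohort-normalized scores; the slice
    table carries per-slice latent coordinates, states and scores.
    """
    slice_rows = []
    patient_rows = []
    for series in series_list:
        scores = score_series(model, regions, series)
        for s in scores:
            slice_rows.append(
                {
                    "patient_id": s.patient_id,
                    "timepoint": s.timepoint,
                    "slice_index": s.slice_index,
                    "latent_x": s.latent.x,
                    "latent_y": s.latent.y,
                    "state": s.state,
                    "score": s.score,
                }
            )
        patient_rows.append(
            {
                "patient_id": series.patient_id,
                "timepoint": series.timepoint,
                "n_slices": len(series),
                "raw_score": patient_score(scores),
            }
        )
    patients = pd.DataFrame(patient_rows)
    if patients.empty:
        raise ValueError("no series to score")
    patients["normalized_score"] = normalize_cohort(patients["raw_score"].to_numpy())
    return patients, pd.DataFrame(slice_rows)


def write_scores(
    patients: pd.DataFrame, slices: pd.DataFrame, patients_path: str, slices_path: str
) -> None:
    """Write score tables with 3-decimal display rounding."""
    pt = patients.copy()
    for col in ("raw_score", "normalized_score"):
        pt[col] = pt[col].round(SCORE_DECIMALS)
    sl = slices.copy()
    sl["score"] = sl["score"].round(SCORE_DECIMALS)
    pt.to_csv(patients_path, index=False)
    sl.to_csv(slices_path, index=False)
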