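"""Core data containers shared across the pipeline.

A *slice* is one grayscale cross-section of the aorta perpendicular to the
vessel centerline; a *series* is the ordered stack of slices for one patient
at one timepoint (early postoperative or follow-up).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

TIMEPOINTS = ("postop", "followup")

STATE_NO_THROMBUS = "no_thrombus"
STATE_PARTIAL = "partial"
STATE_THROMBOSED = "thrombosed"
STATES = (STATE_NO_THROMBUS, STATE_PARTIAL, STATE_THROMBOSED)


@dataclass(frozen=True)
class SliceImage:
    """One standardized grayscale cross-section with provenance.

    ``pixels`` is a 2-D float array with values in [0, 1]; after
    preprocessing its shape is exactly 64x64.
    """

    pixels: np.ndarray
    patient_id: str
    timepoint: str
    slice_index: int
    pixel_spacing: Optional[float] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"slice pixels must be 2-D, got shape {px.shape}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )
        if self.slice_index < 0:
            raise ValueError("slice_index must be >= 0")
        object.__setattr__(self, "pixels", px)


@dataclass
class PatientSeries:
    """Ordered slice stack for one patient at one timepoint."""

    patient_id: str
    timepoint: str
    slices: list[SliceImage] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )
        for i, sl in enumerate(self.slices):
            if sl.patient_id != self.patient_id or sl.timepoint != self.timepoint:
                raise ValueError(
                    f"slice {i} provenance ({sl.patient_id}, {sl.timepoint}) does "
                    f"not match series ({self.patient_id}, {self.timepoint})"
                )
            if sl.slice_index != i:
                raise ValueError(
                    f"slice_index must be contiguous from 0; "
                    f"position {i} has index {sl.slice_index}"
                )
            if sl.pixels.shape != self.slices[0].pixels.shape:
                raise ValueError(
                    f"inconsistent slice shapes in stack: {sl.pixels.shape} "
                    f"vs {self.slices[0].pixels.shape}"
                )

    def __len__(self) -> int:
        return len(self.slices)

    def stack(self) -> np.ndarray:
        """Pixels as an (n_slices, H, W) array."""
        if not self.slices:
            raise ValueError("empty series has no pixel stack")
        return np.stack([s.pixels for s in self.slices])


@dataclass(frozen=True)
class LatentPoint:
    """2-D encoder output (posterior mean) for one slice."""

    x: float
    y: float
    log_var: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"latent coordinates must be finite, got {self}")

    @property
    def radius(self) -> float:
        """Euclidean distance from the latent origin."""
        return float(np.hypot(self.x, self.y))

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


def series_from_stack(
    stack: Sequence[np.ndarray] | np.ndarray,
    patient_id: str,
    timepoint: str,
    pixel_spacing: Optional[float] = None,
) -> PatientSeries:
    """Build a :class:`PatientSeries` from an (n, H, W) pixel stack."""
    slices = [
        SliceImage(
            pixels=np.asarray(frame),
            patient_id=patient_id,
            timepoint=timepoint,
            slice_index=i,
            pixel_spacing=pixel_spacing,
        )
        for i, frame in enumerate(stack)
    ]
    return PatientSeries(patient_id=patient_id, timepoint=timepoint, slices=slices)
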