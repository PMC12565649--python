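"""Synthetic dissected-aorta cross-section phantoms.

Generates grayscale vessel cross-sections that mimic the CTA appearance of a
post-dissection aorta: an elliptical aortic wall, a dissection flap splitting
the lumen into a contrast-bright true lumen (TL) and a false lumen (FL), and a
low-attenuation thrombus crescent filling the FL from the outer wall inward to
a requested area fraction.  Every rendered slice carries a ground-truth record
(state and thrombus fraction), so parameter-recovery experiments can compare
pipeline output against known truth.

Label convention for mask stacks: 0 = background/wall, 1 = true lumen,
2 = patent false lumen, 3 = thrombus.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data import (
    STATE_NO_THROMBUS,
    STATE_PARTIAL,
    STATE_THROMBOSED,
    PatientSeries,
    SliceImage,
)

LABEL_BACKGROUND = 0
LABEL_TRUE_LUMEN = 1
LABEL_FL_PATENT = 2
LABEL_THROMBUS = 3

# Intensity model: contrast-enhanced blood is bright, thrombus is a
# low-attenuation filling defect, wall/flap are faint, background near zero.
INTENSITY_BACKGROUND = 0.05
INTENSITY_WALL = 0.20
DEFAULT_INTENSITY_CONTRAST = 0.90
DEFAULT_INTENSITY_THROMBUS = 0.35

CHANGE_CLASSES = ("progressor", "regressor", "stable")


@dataclass(frozen=True)
class PhantomSliceSpec:
    """Geometry and intensity parameters for one rendered cross-section.

    ``thrombus_fraction`` is the fraction of the false-lumen area occupied by
    thrombus; ``true_lumen_fraction`` the fraction of the total lumen that is
    true lumen.  ``rotation_deg`` orients the dissection flap.
    """

    thrombus_fraction: float
    outer_radius_px: float = 26.0
    true_lumen_fraction: float = 0.35
    intensity_contrast: float = DEFAULT_INTENSITY_CONTRAST
    intensity_thrombus: float = DEFAULT_INTENSITY_THROMBUS
    noise_sd: float = 0.02
    rotation_deg: float = 0.0
    frame_px: int = 96
    center_offset_px: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.thrombus_fraction <= 1.0:
            raise ValueError(
                f"thrombus_fraction must be in [0, 1], got {self.thrombus_fraction}"
            )
        if not 0.0 < self.true_lumen_fraction < 1.0:
            raise ValueError(
                f"true_lumen_fraction must be in (0, 1), got {self.true_lumen_fraction}"
            )
        if not 0.0 < self.intensity_contrast <= 1.0:
            raise ValueError("intensity_contrast must be in (0, 1]")
        if self.intensity_thrombus >= self.intensity_contrast:
            raise ValueError(
                "intensity_thrombus must be below intensity_contrast "
                f"({self.intensity_thrombus} >= {self.intensity_contrast})"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        max_off = max(abs(self.center_offset_px[0]), abs(self.center_offset_px[1]))
        if self.outer_radius_px + max_off > self.frame_px / 2 - 2:
            raise ValueError(
                f"vessel (radius {self.outer_radius_px} px, offset {max_off} px) "
                f"does not fit a {self.frame_px}x{self.frame_px} frame"
            )


@dataclass(frozen=True)
class GroundTruthEntry:
    """True per-slice thrombus state and fraction."""

    patient_id: str
    timepoint: str
    slice_index: int
    state: str
    thrombus_fraction: float


@dataclass(frozen=True)
class PhantomSlice:
    """A rendered slice with its label mask and ground-truth entry."""

    image: SliceImage
    labels: np.ndarray  # integer mask, same shape as image
    truth: GroundTruthEntry


@dataclass(frozen=True)
class TrajectorySpec:
    """Paired-timepoint thrombus-fraction profiles for one patient.

    Profiles hold one thrombus fraction per slice, ordered proximal to
    distal.  ``stable`` patients reuse the rendered baseline stack bitwise at
    follow-up, so their score change is exactly zero by construction.
    """

    change_class: str
    baseline_profile: tuple[float, ...]
    followup_profile: tuple[float, ...]
    n_slices: int

    def __post_init__(self) -> None:
        if self.change_class not in CHANGE_CLASSES:
            raise ValueError(
                f"change_class must be one of {CHANGE_CLASSES}, got {self.change_class!r}"
            )
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        for name, prof in (
            ("baseline_profile", self.baseline_profile),
            ("followup_profile", self.followup_profile),
        ):
            if len(prof) != self.n_slices:
                raise ValueError(
                    f"{name} has length {len(prof)}, expected n_slices={self.n_slices}"
                )
            if any(not 0.0 <= f <= 1.0 for f in prof):
                raise ValueError(f"{name} values must be in [0, 1]")
        mb = float(np.mean(self.baseline_profile))
        mf = float(np.mean(self.followup_profile))
        if self.change_class == "progressor" and not mf > mb:
            raise ValueError("progressor requires mean(followup) > mean(baseline)")
        if self.change_class == "regressor" and not mf < mb:
            raise ValueError("regressor requires mean(followup) < mean(baseline)")
        if self.change_class == "stable" and self.followup_profile != self.baseline_profile:
            raise ValueError("stable requires identical baseline/followup profiles")


def state_from_fraction(fraction: float) -> str:
    """Map a thrombus fraction to its categorical state."""
    if fraction == 0.0:
        return STATE_NO_THROMBUS
    if fraction == 1.0:
        return STATE_THROMBOSED
    return STATE_PARTIAL


def render_slice(
    spec: PhantomSliceSpec,
    rng_seed: int,
    patient_id: str = "phantom",
    timepoint: str = "postop",
    slice_index: int = 0,
) -> PhantomSlice:
    """Render one cross-section and its masks.

    The thrombus region is chosen pixel-exactly: false-lumen pixels are sorted
    by distance from the dissection flap (outer wall first) and the top
    ``round(thrombus_fraction * n_FL)`` become thrombus, so the rendered area
    fraction matches the request to within one pixel.
    """
    n = spec.frame_px
    cy = (n - 1) / 2 + spec.center_offset_px[0]
    cx = (n - 1) / 2 + spec.center_offset_px[1]
    yy, xx = np.mgrid[0:n, 0:n].astype(float)

    theta = np.deg2rad(spec.rotation_deg)
    ct, st = np.cos(theta), np.sin(theta)
    # u runs across the flap normal, v along it, in the rotated vessel frame
    u = ct * (xx - cx) + st * (yy - cy)
    v = -st * (xx - cx) + ct * (yy - cy)

    a = spec.outer_radius_px
    b = 0.85 * a  # mildly elliptical vessel
    aorta = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    lumen = (u / (0.88 * a)) ** 2 + (v / (0.88 * b)) ** 2 <= 1.0

    lumen_u = u[lumen]
    if lumen_u.size < 16:
        raise ValueError("lumen too small to render; increase outer_radius_px")
    # dissection flap: chord perpendicular to u placed so the TL side holds
    # true_lumen_fraction of the lumen area
    u0 = float(np.quantile(lumen_u, spec.true_lumen_fraction))
    flap_half = 1.0
    tl = lumen & (u < u0 - flap_half)
    fl = lumen & (u > u0 + flap_half)
    if tl.sum() == 0 or fl.sum() == 0:
        raise ValueError(
            "degenerate dissection geometry: true or false lumen empty; "
            "adjust true_lumen_fraction or outer_radius_px"
        )

    # thrombus fills the FL from the outer wall (largest u) inward
    fl_idx = np.flatnonzero(fl.ravel())
    order = np.argsort(-u.ravel()[fl_idx], kind="stable")
    n_thr = int(round(spec.thrombus_fraction * fl_idx.size))
    thrombus = np.zeros(n * n, dtype=bool)
    thrombus[fl_idx[order[:n_thr]]] = True
    thrombus = thrombus.reshape(n, n)
    fl_patent = fl & ~thrombus

    labels = np.full((n, n), LABEL_BACKGROUND, dtype=np.uint8)
    labels[tl] = LABEL_TRUE_LUMEN
    labels[fl_patent] = LABEL_FL_PATENT
    labels[thrombus] = LABEL_THROMBUS

    image = np.full((n, n), INTENSITY_BACKGROUND, dtype=np.float64)
    image[aorta] = INTENSITY_WALL
    image[tl] = spec.intensity_contrast
    image[fl_patent] = spec.intensity_contrast
    image[thrombus] = spec.intensity_thrombus

    if spec.noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    truth = GroundTruthEntry(
        patient_id=patient_id,
        timepoint=timepoint,
        slice_index=slice_index,
        state=state_from_fraction(spec.thrombus_fraction),
        thrombus_fraction=spec.thrombus_fraction,
    )
    sl = SliceImage(
        pixels=image,
        patient_id=patient_id,
        timepoint=timepoint,
        slice_index=slice_index,
    )
    return PhantomSlice(image=sl, labels=labels, truth=truth)


@dataclass
class PhantomPatient:
    """Paired phantom series with per-slice masks and ground truth."""

    patient_id: str
    postop: PatientSeries
    followup: PatientSeries
    postop_labels: np.ndarray  # (n_slices, H, W) uint8
    followup_labels: np.ndarray
    truth: list[GroundTruthEntry]


def generate_patient(
    traj: TrajectorySpec,
    base_spec: PhantomSliceSpec,
    rng_seed: int,
    patient_id: str = "phantom",
) -> PhantomPatient:
    """Render the paired postop/follow-up stacks for one patient.

    Each slice gets an independent noise realization and a small seeded
    in-plane offset (the centerline reconstruction upstream of a real pipeline
    is never pixel-perfect); stable patients duplicate the baseline stack
    bitwise rather than re-rendering.
    """
    ss = np.random.SeedSequence([int(rng_seed) & 0x7FFFFFFF])
    rng = np.random.default_rng(ss)
    offsets = rng.uniform(-3.0, 3.0, size=(traj.n_slices, 2))
    noise_seeds = rng.integers(0, 2**31 - 1, size=(traj.n_slices, 2))

    def _render_stack(timepoint: str, profile: Sequence[float], col: int):
        rendered = [
            render_slice(
                replace(
                    base_spec,
                    thrombus_fraction=float(profile[i]),
                    center_offset_px=(float(offsets[i, 0]), float(offsets[i, 1])),
                ),
                rng_seed=int(noise_seeds[i, col]),
                patient_id=patient_id,
                timepoint=timepoint,
                slice_index=i,
            )
            for i in range(traj.n_slices)
        ]
        series = PatientSeries(
            patient_id=patient_id,
            timepoint=timepoint,
            slices=[r.image for r in rendered],
        )
        labels = np.stack([r.labels for r in rendered])
        return series, labels, [r.truth for r in rendered]

    postop, postop_labels, truth_post = _render_stack("postop", traj.baseline_profile, 0)
    if traj.change_class == "stable":
        followup = PatientSeries(
            patient_id=patient_id,
            timepoint="followup",
            slices=[
                SliceImage(
                    pixels=s.pixels.copy(),
                    patient_id=patient_id,
                    timepoint="followup",
                    slice_index=s.slice_index,
                )
                for s in postop.slices
            ],
        )
        followup_labels = postop_labels.copy()
        truth_follow = [
            replace(t, timepoint="followup") for t in truth_post
        ]
    else:
        followup, followup_labels, truth_follow = _render_stack(
            "followup", traj.followup_profile, 1
        )
    return PhantomPatient(
        patient_id=patient_id,
        postop=postop,
        followup=followup,
        postop_labels=postop_labels,
        followup_labels=followup_labels,
        truth=truth_post + truth_follow,
    )


DEFAULT_MIX: dict[str, int] = {"progressor": 15, "regressor": 12, "stable": 3}
DEFAULT_N_SLICES = 40

# Thrombus-fraction profile design: each stack carries a thrombosis *front* —
# a steep monotone ramp clipped to [0, 1] — so proximal slices are fully
# thrombosed, distal slices fully patent, and a transition zone lies between.
# This mirrors the post-FET pattern of thrombosis concentrated in the stented
# proximal segment with predominantly patent distal FL, which also makes
# patent slices the most common state in a cohort.  The ``level`` parameter
# positions the front along the stack; class levels are evenly spaced over the
# ranges below so each cohort spans near-patent to near-complete thrombosis.
RAMP_SPAN = 1.5
PROGRESSOR_BASE_RANGE = (-0.15, 0.25)
REGRESSOR_BASE_RANGE = (0.35, 0.75)
STABLE_RANGE = (-0.10, 0.80)
EFFECT_RANGE = (0.25, 0.50)  # magnitude of the front shift between timepoints


def _ramp(level: float, n: int, span: float = RAMP_SPAN) -> tuple[float, ...]:
    t = np.linspace(0.5, -0.5, n) if n > 1 else np.zeros(1)
    return tuple(np.clip(level + span * t, 0.0, 1.0))


def _spread(lo: float, hi: float, k: int) -> np.ndarray:
    if k == 1:
        return np.array([(lo + hi) / 2])
    return np.linspace(lo, hi, k)


def build_trajectories(
    mix: Mapping[str, int], n_slices: int, rng: np.random.Generator
) -> list[TrajectorySpec]:
    """Per-patient trajectory specs realizing the requested class mix."""
    trajs: list[TrajectorySpec] = []
    for cls in CHANGE_CLASSES:
        k = int(mix.get(cls, 0))
        if k < 0:
            raise ValueError(f"negative count for class {cls!r}")
        if k == 0:
            continue
        if cls == "progressor":
            bases = _spread(*PROGRESSOR_BASE_RANGE, k)
        elif cls == "regressor":
            bases = _spread(*REGRESSOR_BASE_RANGE, k)
        else:
            bases = _spread(*STABLE_RANGE, k)
        effects = rng.permutation(_spread(*EFFECT_RANGE, k))
        jitter = rng.uniform(-0.03, 0.03, size=k)
        for i in range(k):
            m0 = float(np.clip(bases[i] + jitter[i], -0.2, 0.95))
            m1 = m0 if cls == "stable" else (
                m0 + float(effects[i]) if cls == "progressor" else m0 - float(effects[i])
            )
            # short stacks can saturate both profiles to the same clipped
            # values; flatten the ramp until the class contrast survives
            for span in (RAMP_SPAN, 0.8, 0.4, 0.2, 0.0):
                base = _ramp(m0, n_slices, span)
                follow = base if cls == "stable" else _ramp(m1, n_slices, span)
                mb, mf = float(np.mean(base)), float(np.mean(follow))
                if cls == "stable" or (cls == "progressor" and mf > mb) or (
                    cls == "regressor" and mf < mb
                ):
                    break
            trajs.append(
                TrajectorySpec(
                    change_class=cls,
                    baseline_profile=base,
                    followup_profile=follow,
                    n_slices=n_slices,
                )
            )
    if not trajs:
        raise ValueError("cohort mix must request at least one patient")
    return trajs


def generate_cohort(
    mix: Optional[Mapping[str, int]] = None,
    n_slices: int = DEFAULT_N_SLICES,
    rng_seed: int = 0,
) -> tuple[list[PhantomPatient], pd.DataFrame]:
    """Generate a paired phantom cohort.

    Returns the list of :class:`PhantomPatient` (one pair of series each) and
    a tidy ground-truth table with columns patient_id, timepoint, slice_index,
    state, thrombus_fraction, change_class.
    """
    mix = dict(DEFAULT_MIX if mix is None else mix)
    unknown = set(mix) - set(CHANGE_CLASSES)
    if unknown:
        raise ValueError(f"unknown change classes in mix: {sorted(unknown)}")
    ss = np.random.SeedSequence([int(rng_seed) & 0x7FFFFFFF, 17])
    rng = np.random.default_rng(ss)
    trajs = build_trajectories(mix, n_slices, rng)
    order = rng.permutation(len(trajs))  # interleave classes across patient ids

    geom_rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed) & 0x7FFFFFFF, 23]))
    patient_seeds = geom_rng.integers(0, 2**31 - 1, size=len(trajs))
    radii = geom_rng.uniform(22.0, 28.0, size=len(trajs))
    tl_fracs = geom_rng.uniform(0.25, 0.45, size=len(trajs))
    rotations = geom_rng.uniform(0.0, 360.0, size=len(trajs))

    patients: list[PhantomPatient] = []
    rows: list[dict] = []
    for new_idx, traj_idx in enumerate(order):
        traj = trajs[traj_idx]
        pid = f"P{new_idx + 1:03d}"
        spec = PhantomSliceSpec(
            thrombus_fraction=0.0,
            outer_radius_px=float(radii[new_idx]),
            true_lumen_fraction=float(tl_fracs[new_idx]),
            rotation_deg=float(rotations[new_idx]),
        )
        patient = generate_patient(
            traj, spec, rng_seed=int(patient_seeds[new_idx]), patient_id=pid
        )
        patients.append(patient)
        for t in patient.truth:
            rows.append(
                {
                    "patient_id": t.patient_id,
                    "timepoint": t.timepoint,
                    "slice_index": t.slice_index,
                    "state": t.state,
                    "thrombus_fraction": t.thrombus_fraction,
                    "change_class": traj.change_class,
                }
            )
    truth = pd.DataFrame(rows)
    return patients, truth


def thrombus_fraction_from_labels(labels: np.ndarray) -> float:
    """Recover the thrombus area fraction of the FL from a label mask."""
    n_thr = int((labels == LABEL_THROMBUS).sum())
    n_fl = n_thr + int((labels == LABEL_FL_PATENT).sum())
    if n_fl == 0:
        raise ValueError("mask contains no false-lumen pixels")
    return n_thr / n_fl
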