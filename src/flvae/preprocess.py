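"""Standardize segmented cross-sections into centered 64x64 model inputs.

The upstream steps of a clinical workflow (centerline extraction, curved
multiplanar reconstruction, TL/FL/thrombus segmentation) are assumed done:
inputs here are already per-slice cross-sections with an aorta mask, either
exported from a clinical workstation or produced by :mod:`flvae.phantom`.

Series I/O supports NIfTI (one 3-D volume per patient-timepoint) and
multi-page TIFF.  Label masks travel as parallel stacks with integer labels
0 = background, 1 = true lumen, 2 = patent false lumen, 3 = thrombus.
"""
from __future__ import annotations

import os
import re
from typing import Optional

import numpy as np
import nibabel as nib
import tifffile
from scipy import ndimage

from .data import PatientSeries, SliceImage, series_from_stack

DEFAULT_OUT_SIZE = 64
#: smallest allowed uniform downscale before a vessel is declared too large
MIN_SCALE = 0.25


def rescale_intensity(image: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Clip to ``window = (low, high)`` and map affinely onto [0, 1]."""
    low, high = float(window[0]), float(window[1])
    if not low < high:
        raise ValueError(f"degenerate intensity window {window}")
    out = np.clip(np.asarray(image, dtype=float), low, high)
    return (out - low) / (high - low)


def center_and_crop(
    image: np.ndarray,
    aorta_mask: np.ndarray,
    out_size: int = DEFAULT_OUT_SIZE,
    background: float = 0.0,
    patient_id: str = "unknown",
    timepoint: str = "postop",
    slice_index: int = 0,
    interp_order: int = 1,
) -> SliceImage:
    """Center the vessel and crop/pad to ``out_size`` square.

    The mask centroid is moved to the geometric frame center
    ((out_size-1)/2, (out_size-1)/2) by an integer-pixel translation, so a
    slice that is already centered passes through bit-exactly.  If the mask
    bounding box does not fit, the slice is uniformly downscaled (bilinear for
    the image, nearest for the mask, aspect ratio preserved) before
    translation; vessels needing more than a 1/``MIN_SCALE``-fold reduction
    are rejected.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(aorta_mask).astype(bool)
    if image.shape != mask.shape:
        raise ValueError(
            f"image shape {image.shape} and mask shape {mask.shape} differ"
        )
    if image.ndim != 2:
        raise ValueError("center_and_crop expects 2-D slices")
    if not mask.any():
        raise ValueError("aorta mask is empty; cannot center slice")

    ys, xs = np.nonzero(mask)
    extent = max(ys.max() - ys.min() + 1, xs.max() - xs.min() + 1)
    scale = 1.0
    if extent > out_size:
        scale = (out_size - 2) / extent
        if scale < MIN_SCALE:
            raise ValueError(
                f"vessel extent {extent} px cannot be represented at "
                f"{out_size} px within the allowed downscaling"
            )
        image = ndimage.zoom(image, scale, order=interp_order)
        mask = ndimage.zoom(mask.astype(np.uint8), scale, order=0).astype(bool)
        if not mask.any():  # pragma: no cover - extreme shrink of thin masks
            raise ValueError("aorta mask vanished during downscaling")
        ys, xs = np.nonzero(mask)

    cy, cx = ys.mean(), xs.mean()
    target = (out_size - 1) / 2
    shift_y = int(round(target - cy))
    shift_x = int(round(target - cx))

    out = np.full((out_size, out_size), float(background))
    # source window in the (possibly rescaled) input frame
    src_y0 = -shift_y
    src_x0 = -shift_x
    y0, y1 = max(0, src_y0), min(image.shape[0], src_y0 + out_size)
    x0, x1 = max(0, src_x0), min(image.shape[1], src_x0 + out_size)
    if y0 < y1 and x0 < x1:
        out[y0 - src_y0 : y1 - src_y0, x0 - src_x0 : x1 - src_x0] = image[y0:y1, x0:x1]
    return SliceImage(
        pixels=out,
        patient_id=patient_id,
        timepoint=timepoint,
        slice_index=slice_index,
    )


def crop_mask(
    mask: np.ndarray, aorta_mask: np.ndarray, out_size: int = DEFAULT_OUT_SIZE
) -> np.ndarray:
    """Apply the same centering transform to an integer label mask."""
    sl = center_and_crop(
        mask.astype(float), aorta_mask, out_size=out_size, background=0.0,
        interp_order=0,
    )
    return np.rint(sl.pixels).astype(mask.dtype)


def preprocess_series(
    series: PatientSeries,
    label_stack: Optional[np.ndarray] = None,
    out_size: int = DEFAULT_OUT_SIZE,
    window: Optional[tuple[float, float]] = None,
    background: float = 0.0,
    mask_background: bool = False,
) -> tuple[PatientSeries, Optional[np.ndarray]]:
    """Center/crop every slice of a series (and its label stack, if given).

    The aorta mask is taken from the label stack where available (any nonzero
    label) and otherwise thresholded from the image at the background level.
    ``window`` applies a fixed global intensity window before cropping; the
    default passes phantom intensities through unchanged.  With
    ``mask_background`` everything outside the (wall-dilated) vessel mask is
    set to zero; the default keeps the faint wall/background context, which
    preserves the vessel outline for the encoder.
    """
    out_slices = []
    out_labels = [] if label_stack is not None else None
    for i, sl in enumerate(series.slices):
        px = sl.pixels if window is None else rescale_intensity(sl.pixels, window)
        if label_stack is not None:
            # labels mark lumen compartments only; dilate to keep the wall ring
            aorta = ndimage.binary_dilation(label_stack[i] > 0, iterations=4)
        else:
            aorta = px > (background + 0.1)
        out = center_and_crop(
            px,
            aorta,
            out_size=out_size,
            background=background,
            patient_id=series.patient_id,
            timepoint=series.timepoint,
            slice_index=i,
        )
        if mask_background:
            aorta_out = crop_mask(aorta.astype(np.uint8), aorta, out_size=out_size)
            out = SliceImage(
                pixels=out.pixels * (aorta_out > 0),
                patient_id=out.patient_id,
                timepoint=out.timepoint,
                slice_index=out.slice_index,
            )
        out_slices.append(out)
        if out_labels is not None:
            out_labels.append(crop_mask(label_stack[i], aorta, out_size=out_size))
    new_series = PatientSeries(
        patient_id=series.patient_id, timepoint=series.timepoint, slices=out_slices
    )
    return new_series, (np.stack(out_labels) if out_labels is not None else None)


# ---------------------------------------------------------------------------
# series I/O

_FORMATS = ("nifti", "tiff")
_EXT = {"nifti": ".nii.gz", "tiff": ".tiff"}


def _series_path(directory: str, patient_id: str, timepoint: str, fmt: str) -> str:
    return os.path.join(directory, f"{patient_id}_{timepoint}{_EXT[fmt]}")


def save_series(
    series: PatientSeries,
    directory: str,
    fmt: str = "nifti",
    labels: Optional[np.ndarray] = None,
) -> str:
    """Write a series as one stack file, optionally with a label stack.

    NIfTI volumes are stored float32 with the slice axis last; TIFF stacks are
    multi-page float32.  Label stacks go to a sibling ``*_labels`` file.
    """
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    os.makedirs(directory, exist_ok=True)
    stack = series.stack().astype(np.float32)
    path = _series_path(directory, series.patient_id, series.timepoint, fmt)
    if fmt == "nifti":
        nib.save(nib.Nifti1Image(np.moveaxis(stack, 0, -1), affine=np.eye(4)), path)
        if labels is not None:
            lab_path = path.replace(".nii.gz", "_labels.nii.gz")
            nib.save(
                nib.Nifti1Image(
                    np.moveaxis(labels.astype(np.uint8), 0, -1), affine=np.eye(4)
                ),
                lab_path,
            )
    else:
        tifffile.imwrite(path, stack, photometric="minisblack")
        if labels is not None:
            tifffile.imwrite(
                path.replace(".tiff", "_labels.tiff"), labels.astype(np.uint8), photometric="minisblack"
            )
    return path


_NAME_RE = re.compile(r"^(?P<pid>.+)_(?P<tp>postop|followup)$")


def _parse_name(path: str) -> tuple[str, str]:
    base = os.path.basename(path)
    for ext in (".nii.gz", ".tiff", ".tif"):
        if base.endswith(ext):
            base = base[: -len(ext)]
            break
    m = _NAME_RE.match(base)
    if not m:
        raise ValueError(
            f"cannot parse patient/timepoint from file name {path!r}; "
            "expected '<patient>_<postop|followup>.<ext>'"
        )
    return m.group("pid"), m.group("tp")


def load_series(path: str, fmt: Optional[str] = None) -> PatientSeries:
    """Load one series stack written by :func:`save_series`."""
    if fmt is None:
        fmt = "nifti" if path.endswith((".nii", ".nii.gz")) else "tiff"
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt == "nifti":
        vol = np.asarray(nib.load(path).dataobj, dtype=np.float32)
        stack = np.moveaxis(vol, -1, 0)
    else:
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
    pid, tp = _parse_name(path)
    return series_from_stack(stack.astype(np.float64), pid, tp)


def load_cohort_dir(directory: str, fmt: str = "nifti") -> list[PatientSeries]:
    """Load every (non-label) series stack in a directory."""
    if not os.path.isdir(directory):
        raise FileNotFoundError(f"{directory!r} is not a directory")
    ext = _EXT[fmt] if fmt in _FORMATS else None
    if ext is None:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    names = sorted(
        f
        for f in os.listdir(directory)
        if f.endswith(ext) and "_labels" not in f
    )
    if not names:
        raise FileNotFoundError(
            f"no {fmt} series found in {directory!r}; expected files named "
            f"'<patient>_<postop|followup>{ext}'"
        )
    return [load_series(os.path.join(directory, n), fmt) for n in names]
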