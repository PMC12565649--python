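"""Qualitative-validation and cohort visualization outputs.

All functions are pure renderings of their inputs: the lateral score map
(grayscale strip along the aorta, black = no thrombus, white = maximum
burden), the latent scatter with region overlays, paired per-patient bars,
two-timepoint boxplots, the delta histogram with a kernel-density curve, and
original-vs-reconstruction panels for visual VAE validation.
"""
from __future__ import annotations

import os
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats as sps

from .latent_space import RegionSet
from .vae import TrainedModel

# Latent-region palette: no thrombus yellow, thrombosed blue, partial unshaded.
COLOR_NO_THROMBUS = "#f2d544"
COLOR_THROMBOSED = "#4472c4"


def render_lateral_map(
    slice_scores: Sequence[float], score_max: float, strip_height: int = 16
) -> np.ndarray:
    """Grayscale strip, one column per slice: intensity = score / score_max.

    An all-zero series renders all black; ``score_max`` must be positive
    unless every score is zero.
    """
    scores = np.asarray(list(slice_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("no slice scores to render")
    if (scores < 0).any():
        raise ValueError("slice scores must be nonnegative")
    if score_max < 0:
        raise ValueError("score_max must be nonnegative")
    if score_max == 0:
        if scores.max() > 0:
            raise ValueError("score_max is zero but scores are not all zero")
        intensities = np.zeros_like(scores)
    else:
        intensities = np.clip(scores / score_max, 0.0, 1.0)
    return np.tile(intensities, (strip_height, 1))


def save_lateral_map(
    slice_scores: Sequence[float], score_max: float, path: str, dpi: int = 150
) -> str:
    strip = render_lateral_map(slice_scores, score_max)
    fig, ax = plt.subplots(figsize=(6, 1.2))
    ax.imshow(strip, cmap="gray", vmin=0.0, vmax=1.0, aspect="auto")
    ax.set_yticks([])
    ax.set_xlabel("slice index (proximal to distal)")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path


def latent_scatter(
    slices: pd.DataFrame,
    regions: Optional[RegionSet],
    path: str,
    dpi: int = 150,
) -> str:
    """Latent-plane scatter of encoded slices with region polygons."""
    fig, ax = plt.subplots(figsize=(5, 5))
    if regions is not None:
        for verts, color, label in (
            (regions.no_thrombus_polygon, COLOR_NO_THROMBUS, "no thrombus"),
            (regions.thrombosed_polygon, COLOR_THROMBOSED, "thrombosed"),
        ):
            closed = np.vstack([verts, verts[:1]])
            ax.fill(closed[:, 0], closed[:, 1], color=color, alpha=0.35, label=label)
    ax.plot(slices["latent_x"], slices["latent_y"], ".", color="red", ms=3,
            label="encoded slices")
    ax.set_xlabel("latent x")
    ax.set_ylabel("latent y")
    ax.legend(loc="best", fontsize=8)
    ax.set_title("Latent space with thrombus-state regions")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path


def paired_bars(records: pd.DataFrame, path: str, dpi: int = 150) -> str:
    """One pair of bars per patient: postop (blue) vs follow-up (orange)."""
    if records.empty:
        raise ValueError("empty cohort")
    n = len(records)
    xs = np.arange(n)
    fig, ax = plt.subplots(figsize=(max(6, 0.35 * n), 4))
    ax.bar(xs - 0.2, records["score_postop"], width=0.4, label="postoperative")
    ax.bar(xs + 0.2, records["score_followup"], width=0.4, label="follow-up")
    ax.set_xticks(xs)
    ax.set_xticklabels(records["patient_id"], rotation=90, fontsize=7)
    ax.set_ylabel("average thrombus score")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path


def timepoint_boxplot(records: pd.DataFrame, path: str, dpi: int = 150) -> str:
    if records.empty:
        raise ValueError("empty cohort")
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot(
        [records["score_postop"], records["score_followup"]],
        tick_labels=["postoperative", "follow-up"],
    )
    ax.set_ylabel("thrombus score")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path


def delta_histogram(
    records: pd.DataFrame, path: str, bins: int = 10, dpi: int = 150
) -> str:
    """Histogram of score differences with a Gaussian-kernel density curve.

    Bandwidth follows Scott's rule; the curve is omitted for degenerate
    (zero-variance) deltas.
    """
    if records.empty:
        raise ValueError("empty cohort")
    d = records["delta"].to_numpy()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(d, bins=bins, color=COLOR_NO_THROMBUS, edgecolor="k", density=True)
    if d.std() > 0 and d.size > 1:
        kde = sps.gaussian_kde(d, bw_method="scott")
        grid = np.linspace(d.min() - 0.2, d.max() + 0.2, 256)
        ax.plot(grid, kde(grid), color="red", lw=2, label="kernel density")
        ax.legend()
    ax.set_xlabel("thrombus score difference (follow-up − postop)")
    ax.set_ylabel("density")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path


def render_cohort_figures(
    records: pd.DataFrame,
    slices: pd.DataFrame,
    regions: Optional[RegionSet],
    out_dir: str,
    dpi: int = 150,
) -> dict[str, str]:
    """Write the four cohort figures; returns {figure name: path}."""
    if records.empty:
        raise ValueError("empty cohort")
    os.makedirs(out_dir, exist_ok=True)
    return {
        "latent_scatter": latent_scatter(
            slices, regions, os.path.join(out_dir, "latent_scatter.png"), dpi
        ),
        "paired_bars": paired_bars(
            records, os.path.join(out_dir, "paired_bars.png"), dpi
        ),
        "boxplot": timepoint_boxplot(
            records, os.path.join(out_dir, "timepoint_boxplot.png"), dpi
        ),
        "delta_histogram": delta_histogram(
            records, os.path.join(out_dir, "delta_histogram.png"), dpi=dpi
        ),
    }


def reconstruction_panel(
    model: TrainedModel,
    images: Sequence[np.ndarray],
    path: Optional[str] = None,
    dpi: int = 150,
) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """Original/reconstruction pairs with per-pair mean absolute error.

    Returns the list of (original, reconstruction, mae); if ``path`` is given
    also writes a side-by-side grid annotated with each MAE.
    """
    imgs = list(images)
    if not imgs:
        raise ValueError("no images to reconstruct")
    pairs = []
    for im in imgs:
        px = im.pixels if hasattr(im, "pixels") else np.asarray(im, float)
        rec = model.reconstruct(px)
        mae = float(np.mean(np.abs(px - rec)))
        pairs.append((px, rec, mae))
    if path is not None:
        n = len(pairs)
        fig, axes = plt.subplots(2, n, figsize=(1.6 * n, 3.4), squeeze=False)
        for j, (orig, rec, mae) in enumerate(pairs):
            axes[0][j].imshow(orig, cmap="gray", vmin=0, vmax=1)
            axes[0][j].set_title("input", fontsize=7)
            axes[1][j].imshow(rec, cmap="gray", vmin=0, vmax=1)
            axes[1][j].set_title(f"MAE {mae:.3f}", fontsize=7)
            for row in (0, 1):
                axes[row][j].set_xticks([])
                axes[row][j].set_yticks([])
        fig.tight_layout()
        fig.savefig(path, dpi=dpi)
        plt.close(fig)
    return pairs
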