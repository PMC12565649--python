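"""Shared fixtures: phantom cohorts and trained models at two scales.

``small_model`` is a minimally trained VAE for contract tests (shapes,
determinism); ``ref_model`` is trained long enough for the latent space to be
organized, and backs the separation / fidelity / monotonicity checks.
"""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from flvae import phantom as ph
from flvae import preprocess as pp
from flvae import vae
from flvae.pipeline import PipelineConfig, calibrate_regions, run_pipeline

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

SMALL_MIX = {"progressor": 2, "regressor": 2, "stable": 1}
REF_MIX = {"progressor": 8, "regressor": 7, "stable": 1}


def _preprocess_cohort(patients):
    series = []
    for p in patients:
        for raw, labels in ((p.postop, p.postop_labels), (p.followup, p.followup_labels)):
            s, _ = pp.preprocess_series(raw, label_stack=labels)
            series.append(s)
    return series


@pytest.fixture(scope="session")
def small_cohort():
    """5 phantom patients x 8 slices, with truth table and processed series."""
    patients, truth = ph.generate_cohort(SMALL_MIX, n_slices=8, rng_seed=7)
    return patients, truth, _preprocess_cohort(patients)


@pytest.fixture(scope="session")
def small_model(small_cohort):
    """A briefly trained VAE (3 epochs) on the small cohort."""
    _, _, series = small_cohort
    images = [sl for s in series for sl in s.slices]
    return vae.train(images, vae.VaeConfig(epochs=3, seed=3))


@pytest.fixture(scope="session")
def ref_model(small_cohort):
    """A well-trained VAE with calibrated regions (frozen seed).

    16 patients x 24 slices, 40 epochs: enough for clean class separation
    and sub-0.1 reconstruction error on this phantom family.
    """
    patients, truth = ph.generate_cohort(REF_MIX, n_slices=24, rng_seed=3)
    series = _preprocess_cohort(patients)
    images = [sl for s in series for sl in s.slices]
    model = vae.train(images, vae.VaeConfig(epochs=40, seed=3))
    regions = calibrate_regions(model, series, truth, rng_seed=3)
    return model, regions, series, truth


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """Full pipeline on the default 30-patient cohort at reduced epochs."""
    out = tmp_path_factory.mktemp("pipeline_default")
    cfg = PipelineConfig(
        out_dir=str(out),
        epochs=5,
        phantom_seed=2,
        train_seed=2,
        calibration_seed=2,
        make_figures=False,
    )
    return run_pipeline(cfg)
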