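"""Shared fixtures.

The end-to-end fixtures are session-scoped because they train the patch
CNN several times (once per fold per cohort restriction); every test that
inspects cross-validation behaviour reads from the same run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from survbira import (
    PipelineConfig,
    SurvpatchConfig,
    SyntheticCohortConfig,
    TilingConfig,
    generate_cohort,
    load_manifest,
    make_patient_folds,
    run_ablation,
    run_cross_validation,
)

#: Study conditions for the strong-signal end-to-end cohort: ~40 patients
#: with 1-3 slides each, small survival noise, a 40% admixture of
#: signal-free non-tumor slides (every patient keeps >= 1 primary slide),
#: and desk-scale image/patch sizes.
E2E_SEED = 11
E2E_COHORT = dict(
    n_patients=40,
    slides_per_patient=(1, 3),
    image_size=256,
    patch_size=64,
    noise_sd_days=30.0,
    fraction_primary=0.6,
    seed=E2E_SEED,
)
E2E_EPOCHS = 15
E2E_MAX_PATCHES = 8


def make_pipeline_config(tissue_keep=None, seed=E2E_SEED) -> PipelineConfig:
    return PipelineConfig(
        tiling=TilingConfig(patch_size=64),
        survpatch=SurvpatchConfig(epochs=E2E_EPOCHS, seed=seed),
        seed=seed,
        tissue_keep=tissue_keep,
        max_patches_per_slide=E2E_MAX_PATCHES,
    )


@pytest.fixture(scope="session")
def e2e_cohort(tmp_path_factory):
    """Synthetic cohort on disk plus its loaded records and fold split."""
    out = tmp_path_factory.mktemp("e2e_cohort")
    res = generate_cohort(SyntheticCohortConfig(**E2E_COHORT), out)
    patients, slides = load_manifest(res["manifest_path"])
    folds = make_patient_folds(patients, k=5, seed=E2E_SEED)
    return {
        "patients": patients,
        "slides": slides,
        "folds": folds,
        "truth": res["truth"],
        "manifest_path": res["manifest_path"],
    }


@pytest.fixture(scope="session")
def e2e_ablation(e2e_cohort):
    """Three-variant ablation CV on primary-tumor slides only.

    The ``full`` variant doubles as the headline cross-validation run.
    """
    config = make_pipeline_config(tissue_keep=frozenset({"primary_tumor"}))
    return run_ablation(
        e2e_cohort["patients"], e2e_cohort["slides"], e2e_cohort["folds"], config
    )


@pytest.fixture(scope="session")
def e2e_whole_type(e2e_cohort):
    """Full-cascade CV with all tissue types (the whole-type condition)."""
    config = make_pipeline_config(tissue_keep=None)
    return run_cross_validation(
        e2e_cohort["patients"], e2e_cohort["slides"], e2e_cohort["folds"], config
    )


@pytest.fixture(scope="session")
def constant_mean_baseline(e2e_ablation, e2e_cohort):
    """MAE of predicting every patient at the cohort mean survival."""
    table: pd.DataFrame = e2e_ablation["full"][2]
    truth = table["truth_days"].to_numpy(dtype=float)
    return float(np.mean(np.abs(truth - truth.mean())))
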