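"""Shared fixtures: tiny rendered fixtures plus the cached end-to-end runs."""

from __future__ import annotations

import numpy as np
import pytest

from keyfeat import prediction
from keyfeat.pipeline import (PipelineConfig, impact_recovery_spearman,
                              run_pipeline)
from keyfeat.synthdata import (SyntheticCohortSpec, default_texture_library,
                               render_texture_patch)

E2E_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def library():
    return default_texture_library()


@pytest.fixture(scope="session")
def two_class_patches(library):
    """28-px patches of two texture classes, 60 per class."""
    patches = np.stack([
        render_texture_patch(library, c, 28, s)
        for c in (0, 3) for s in range(60)
    ])
    labels = np.repeat([0, 1], 60)
    return patches, labels


@pytest.fixture(scope="session")
def small_cohort_spec():
    """A miniature cohort for structural (non-statistical) checks."""
    return SyntheticCohortSpec(n_patients=12, prevalence=1 / 3,
                               exclusion_counts={})


@pytest.fixture(scope="session")
def small_pipeline_result(small_cohort_spec):
    """One cheap end-to-end run used by structural pipeline tests."""
    return run_pipeline(small_cohort_spec, 11,
                        PipelineConfig(k_clusters=8, kmeans_restarts=3))


@pytest.fixture(scope="session")
def e2e_runs():
    """Full pipeline runs at the default study conditions, seeds 1-3.

    Computed once per session and shared by the recovery and permutation
    checks; each entry carries the run artifacts, the ground-truth recovery
    correlation and the cross-validated lasso AUC.
    """
    runs = {}
    for seed in E2E_SEEDS:
        spec = SyntheticCohortSpec(n_patients=200, exclusion_counts={})
        result = run_pipeline(spec, seed, PipelineConfig())
        ev = prediction.crossval_predict(
            result.features, result.labels.astype(int),
            prediction.ModelSpec(model="lasso", seed=seed),
            n_folds=10, seed=seed)
        runs[seed] = {
            "result": result,
            "spearman": impact_recovery_spearman(result),
            "lasso_auc": ev.auc,
        }
    return runs
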