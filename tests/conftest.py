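"""Shared fixtures: small synthetic cohorts and hand-built feature matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sakeityper import (
    CohortDesign,
    FeatureMatrix,
    NoiseParams,
    default_templates,
    generate_cohort,
    preprocess_cohort,
)


@pytest.fixture(scope="session")
def small_design() -> CohortDesign:
    """A scaled-down cohort (15/15/6 strains) with the default structure."""
    return CohortDesign(strains_per_class=(15, 15, 6), seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_design):
    """Spectra + manifest for the scaled-down cohort (144 spectra)."""
    return generate_cohort(small_design, default_templates(), NoiseParams(), seed=7)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    """Preprocessed feature matrix of the scaled-down cohort."""
    spectra, manifest = small_cohort
    labels = pd.Series(manifest["class_label"].to_numpy(), index=manifest["spectrum_id"])
    features, processed, peaklists = preprocess_cohort(
        [ls.spectrum for ls in spectra], labels=labels
    )
    return features, processed, peaklists, manifest


def make_feature_matrix(
    values: np.ndarray,
    detected: np.ndarray | None = None,
    labels: list[str] | None = None,
    columns: list[float] | None = None,
) -> FeatureMatrix:
    """Hand-build a FeatureMatrix from a dense array (helper, not a fixture)."""
    n, p = values.shape
    ids = [f"s{i}" for i in range(n)]
    cols = columns if columns is not None else [2000.0 + 100.0 * j for j in range(p)]
    det = detected if detected is not None else np.ones_like(values, dtype=bool)
    return FeatureMatrix(
        intensities=pd.DataFrame(values, index=ids, columns=cols),
        detected=pd.DataFrame(det, index=ids, columns=cols),
        labels=None if labels is None else pd.Series(labels, index=ids),
    )


@pytest.fixture(scope="session")
def separable_clouds():
    """Two well-separated Gaussian clouds in 6 dimensions, 60 samples/class."""
    rng = np.random.default_rng(42)
    a = rng.normal(0.0, 0.3, size=(60, 6))
    b = rng.normal(5.0, 0.3, size=(60, 6))
    values = np.vstack([a, b])
    labels = ["alpha"] * 60 + ["beta"] * 60
    return make_feature_matrix(values, labels=labels)
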