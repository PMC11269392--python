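"""Shared fixtures and independent oracles.

The trained classifier is session-scoped because training the masked net
on the standard synthetic cohort (8 classes x 20 samples, 5,000 CpGs)
takes tens of seconds; every test that needs a model shares it.
"""

from __future__ import annotations

import numpy as np
import pytest

from cnsmeth import classifier, datasets, features, synthetic


@pytest.fixture(scope="session")
def synthetic_config() -> synthetic.SyntheticConfig:
    return synthetic.SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def raw_atlas(synthetic_config) -> features.ReferenceAtlas:
    return synthetic.generate_reference_atlas(synthetic_config)


@pytest.fixture(scope="session")
def atlas(raw_atlas) -> features.ReferenceAtlas:
    return features.filter_zero_variance(raw_atlas)


@pytest.fixture(scope="session")
def model(atlas) -> classifier.MaskedNetModel:
    return classifier.train(atlas, seed=1)


@pytest.fixture(scope="session")
def ua_cohort():
    return datasets.load_ua_cohort()


@pytest.fixture(scope="session")
def ua_cases(ua_cohort):
    return datasets.scored_cases_from_cohort(ua_cohort, score_column="score_mc")


def nearest_centroid_fit(matrix: np.ndarray, labels: np.ndarray):
    """Per-class mean profiles — the analytic oracle for the
    disjoint-signature generative model."""
    classes = sorted(set(labels))
    centroids = np.stack([matrix[labels == c].mean(axis=0) for c in classes])
    return classes, centroids


def nearest_centroid_predict(classes, centroids, values: np.ndarray) -> str:
    """Classify one possibly-sparse binary vector by squared distance to
    each class centroid over the observed sites only."""
    obs = ~np.isnan(values)
    if not obs.any():
        return classes[0]
    d = ((centroids[:, obs] - values[obs][None, :]) ** 2).sum(axis=1)
    return classes[int(np.argmin(d))]


def sample_class_profile(
    config: synthetic.SyntheticConfig, class_idx: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw a fresh profile from the generative model of one class
    (signature block Bernoulli(p_high), background Bernoulli(p_low))."""
    profile = (rng.random(config.atlas_size) < config.p_low).astype(float)
    lo = class_idx * config.signature_size
    hi = lo + config.signature_size
    profile[lo:hi] = (rng.random(hi - lo) < config.p_high).astype(float)
    return profile


def fresh_sparse_vector(
    config: synthetic.SyntheticConfig,
    class_idx: int,
    n_observed: int,
    seed: int,
    raw_atlas: features.ReferenceAtlas,
    filtered_atlas: features.ReferenceAtlas,
) -> features.BinaryFeatureVector:
    """A new case from the generative model, sparsely observed and aligned
    to the (possibly column-filtered) atlas via genomic coordinates."""
    rng = np.random.default_rng(seed)
    profile = sample_class_profile(config, class_idx, rng)
    calls = synthetic.simulate_sparse_observation(
        profile, raw_atlas.cpg_index, n_observed, beta_noise_sd=0.0, seed=seed
    )
    states = features.binarize(calls)
    return features.align_to_atlas(states, filtered_atlas)
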