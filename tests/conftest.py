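import numpy as np
import pytest

import semdecode as sd


@pytest.fixture(scope="session")
def small_dataset() -> sd.Dataset:
    """Desk-miniature study: 2 subjects, 12x12 grid, 20 matched test pairs."""
    return sd.simulate_dataset(
        n_subjects=2,
        n_vertices=144,
        n_train_images=80,
        n_train_captions=80,
        n_test_pairs=20,
        latent_dim=8,
        feature_dims={"vision": 32, "language": 32, "multimodal": 32},
        region_size=16,
        noise_sd=1.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def noiseless_dataset() -> sd.Dataset:
    """Invariant-signal-only study with zero noise: accuracies must saturate."""
    return sd.simulate_dataset(
        n_subjects=1,
        n_vertices=64,
        n_train_images=40,
        n_train_captions=40,
        n_test_pairs=10,
        latent_dim=6,
        feature_dims={"vision": 16, "language": 16, "multimodal": 16},
        modality_specific_weight=0.0,
        region_size=12,
        noise_sd=0.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def grid5() -> sd.SurfaceGraph:
    return sd.generate_surface_graph(25, "grid")


def test_split_responses(responses: sd.BrainResponses) -> sd.BrainResponses:
    keep = np.concatenate(
        [responses.rows(split="test"), responses.rows(split="imagery")]
    )
    return sd.BrainResponses(
        responses.subject_id,
        responses.betas[keep],
        responses.trial_table.iloc[keep].reset_index(drop=True),
    )


@pytest.fixture(scope="session")
def fitted_trio(small_dataset):
    """Image-specific, caption-specific and agnostic decoders (multimodal
    provider) for the first subject, plus the test-split responses."""
    resp = small_dataset.responses["sub-01"]
    fm = small_dataset.features["multimodal"]
    trio = {
        "image": sd.fit_modality_specific(resp, fm, "image", alpha=10.0),
        "caption": sd.fit_modality_specific(resp, fm, "caption", alpha=10.0),
        "agnostic": sd.fit_modality_agnostic(resp, fm, alpha=10.0),
    }
    return trio, test_split_responses(resp)
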