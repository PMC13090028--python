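"""Synthetic multimodal fMRI datasets with planted ground truth.

The generator emulates the study design every downstream stage consumes:
subjects view images and read captions of the same stimuli (disjoint
training stimuli per modality, a shared test set presented once in each
modality), plus three mental-imagery conditions. Vertex responses are
linear-Gaussian:

* *invariant* vertices respond to the stimulus latent identically for
  image and caption trials — the modality-invariant signal the searchlight
  conjunction is designed to find;
* *image_only* vertices respond to vision-provider features on image
  trials and are pure noise on caption trials (``caption_only`` symmetric);
* *noise* vertices are Gaussian noise throughout;
* imagery trials drive the invariant pathway from the imagined stimulus
  latent with inflated noise (imagery is harder than perception).

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataIntegrityError
from .features import FeatureMatrix
from .surface import SurfaceGraph, generate_surface_graph

__all__ = [
    "StimulusSet",
    "GroundTruth",
    "BrainResponses",
    "Dataset",
    "generate_stimulus_set",
    "generate_feature_spaces",
    "make_region_labels",
    "make_ground_truth",
    "generate_brain_responses",
    "simulate_dataset",
]

REGION_LABELS = ("invariant", "image_only", "caption_only", "noise")


@dataclass
class StimulusSet:
    """Stimuli, their latent content vectors, and the trial design.

    ``trials`` has one row per trial with columns ``stimulus_id``,
    ``modality`` (image / caption / imagery) and ``split`` (train / test /
    imagery). Test stimuli appear exactly twice — once per perceptual
    modality — forming the matched pairs that cross-modal evaluation needs.
    """

    stimulus_ids: np.ndarray
    latents: np.ndarray
    trials: pd.DataFrame
    imagery_ids: np.ndarray

    def __post_init__(self) -> None:
        self.stimulus_ids = np.asarray(self.stimulus_ids)
        self.latents = np.asarray(self.latents, dtype=float)
        self.imagery_ids = np.asarray(self.imagery_ids)
        if self.latents.shape[0] != len(self.stimulus_ids):
            raise DataIntegrityError("one latent vector per stimulus required")
        test = self.trials[self.trials["split"] == "test"]
        by_stim = test.groupby("stimulus_id")["modality"].agg(sorted)
        for sid, mods in by_stim.items():
            if mods != ["caption", "image"]:
                raise DataIntegrityError(
                    f"test stimulus {sid} lacks a matched image/caption pair"
                )
        train = self.trials[self.trials["split"] == "train"]
        if train.duplicated(["stimulus_id", "modality"]).any():
            raise DataIntegrityError("duplicate training trials within a modality")
        percept = set(self.trials.loc[self.trials["split"] != "imagery", "stimulus_id"])
        if percept & set(int(i) for i in self.imagery_ids):
            raise DataIntegrityError("imagery stimuli overlap perceptual trials")

    @property
    def latent_dim(self) -> int:
        return self.latents.shape[1]

    @property
    def test_stimulus_ids(self) -> np.ndarray:
        """Test stimuli in a fixed canonical order (sorted ids)."""
        test = self.trials.loc[self.trials["split"] == "test", "stimulus_id"]
        return np.sort(test.unique())

    def latents_for(self, stimulus_ids) -> np.ndarray:
        index = {int(s): i for i, s in enumerate(self.stimulus_ids)}
        return self.latents[[index[int(s)] for s in stimulus_ids]]


def generate_stimulus_set(
    n_train_images: int = 400,
    n_train_captions: int = 400,
    n_test_pairs: int = 70,
    latent_dim: int = 16,
    seed: int | None = None,
    n_imagery: int = 3,
) -> StimulusSet:
    """Draw stimulus latents and lay out the trial design.

    Latents are i.i.d. standard normal. Training stimuli are disjoint
    between modalities; each of the ``n_test_pairs`` test stimuli yields one
    image trial and one caption trial; ``n_imagery`` stimuli are reserved
    for imagery and never shown perceptually.
    """
    if min(n_train_images, n_train_captions) < 0:
        raise ConfigurationError("train counts must be >= 0")
    if n_test_pairs < 2:
        raise ConfigurationError("n_test_pairs must be >= 2 (pairwise accuracy)")
    if latent_dim < 1:
        raise ConfigurationError("latent_dim must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_train_images + n_train_captions + n_test_pairs + n_imagery
    ids = np.arange(n)
    latents = rng.standard_normal((n, latent_dim))
    ti = ids[:n_train_images]
    tc = ids[n_train_images : n_train_images + n_train_captions]
    te = ids[n_train_images + n_train_captions : n - n_imagery]
    im = ids[n - n_imagery :]
    rows = (
        [(int(s), "image", "train") for s in ti]
        + [(int(s), "caption", "train") for s in tc]
        + [(int(s), "image", "test") for s in te]
        + [(int(s), "caption", "test") for s in te]
        + [(int(s), "imagery", "imagery") for s in im]
    )
    trials = pd.DataFrame(rows, columns=["stimulus_id", "modality", "split"])
    return StimulusSet(ids, latents, trials, im)


def generate_feature_spaces(
    stimuli: StimulusSet,
    dims: dict[str, int] | None = None,
    modality_specific_weight: float | dict[str, float] = 0.5,
    latent_weight: float = 1.0,
    multimodal_private_scale: float = 0.25,
    seed: int | None = None,
) -> dict[str, FeatureMatrix]:
    """Synthesize vision / language / multimodal embedding spaces.

    Each provider's features are a random linear map of the shared stimulus
    latents plus an independent modality-private Gaussian component scaled
    by ``modality_specific_weight`` (the multimodal provider's private part
    is further shrunk by ``multimodal_private_scale``). At weight 0 the
    unimodal spaces are deterministic functions of the same latents; at
    ``latent_weight=0`` and weight 1 they are independent.
    """
    dims = dims or {"vision": 64, "language": 64, "multimodal": 64}
    if any(d < 1 for d in dims.values()):
        raise ConfigurationError("feature dims must be >= 1")
    if isinstance(modality_specific_weight, dict):
        weights = dict(modality_specific_weight)
    else:
        weights = {name: float(modality_specific_weight) for name in dims}
    rng = np.random.default_rng(seed)
    z = stimuli.latents
    out: dict[str, FeatureMatrix] = {}
    for name in ("vision", "language", "multimodal"):
        if name not in dims:
            continue
        d = dims[name]
        loading = rng.standard_normal((stimuli.latent_dim, d)) / np.sqrt(
            stimuli.latent_dim
        )
        private = rng.standard_normal((len(stimuli.stimulus_ids), d))
        w = weights.get(name, 0.5)
        if name == "multimodal":
            w = w * multimodal_private_scale
        values = latent_weight * z @ loading + w * private
        out[name] = FeatureMatrix(
            provider_name=f"synthetic-{name}",
            modality_source=name,
            values=values,
            stimulus_ids=stimuli.stimulus_ids.copy(),
        )
    return out


@dataclass
class GroundTruth:
    """Planted spatial layout and response model for one subject.

    ``mixing_maps`` holds, per signal region, the linear map from its input
    space (latents for the invariant region, provider features for the
    modality-specific regions) to that region's vertices.
    """

    region_labels: np.ndarray
    latent_dim: int
    mixing_maps: dict[str, np.ndarray]
    noise_sd: float
    imagery_noise_factor: float = 2.0

    def __post_init__(self) -> None:
        self.region_labels = np.asarray(self.region_labels)
        bad = set(np.unique(self.region_labels)) - set(REGION_LABELS)
        if bad:
            raise DataIntegrityError(f"unknown region labels {sorted(bad)}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for region, m in self.mixing_maps.items():
            n_region = int(np.sum(self.region_labels == region))
            if m.shape[1] != n_region:
                raise DataIntegrityError(
                    f"mixing map for {region!r} has {m.shape[1]} columns, "
                    f"region has {n_region} vertices"
                )

    def indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.region_labels == label)


def make_region_labels(
    graph: SurfaceGraph,
    region_size: int | dict[str, int] = 60,
    seed: int | None = None,
) -> np.ndarray:
    """Plant three spatially contiguous regions on the graph.

    Centers are placed by greedy farthest-point sampling on vertex
    coordinates (seeded start) so the regions are well separated; each
    region is grown as a coordinate ball of ``region_size`` vertices
    (an int for all three regions, or a dict keyed by region label).
    """
    n = graph.n_vertices
    if isinstance(region_size, dict):
        sizes = {lab: int(region_size.get(lab, 0))
                 for lab in ("invariant", "image_only", "caption_only")}
    else:
        sizes = {lab: int(region_size)
                 for lab in ("invariant", "image_only", "caption_only")}
    if sum(sizes.values()) > n:
        raise ConfigurationError("regions would cover more than the whole graph")
    rng = np.random.default_rng(seed)
    coords = graph.coords
    centers = [int(rng.integers(n))]
    for _ in range(2):
        d = np.min(
            np.linalg.norm(coords[:, None, :] - coords[centers][None], axis=2), axis=1
        )
        centers.append(int(np.argmax(d)))
    labels = np.full(n, "noise", dtype=object)
    for center, label in zip(centers, ("invariant", "image_only", "caption_only")):
        dist = np.linalg.norm(coords - coords[center], axis=1)
        # coordinate ball around the center; ties broken by vertex id
        order = np.lexsort((np.arange(n), dist))
        chosen = [v for v in order if labels[v] == "noise"][: sizes[label]]
        labels[chosen] = label
    return labels.astype("U12")


def make_ground_truth(
    graph: SurfaceGraph,
    region_labels: np.ndarray | None = None,
    latent_dim: int = 16,
    feature_dims: dict[str, int] | None = None,
    region_size: int | dict[str, int] = 60,
    noise_sd: float = 1.0,
    imagery_noise_factor: float = 2.0,
    seed: int | None = None,
) -> GroundTruth:
    """Sample per-region mixing maps for one subject.

    Map entries are N(0, 1/in_dim) so each signal vertex has unit response
    variance; ``noise_sd`` then directly sets the signal-to-noise ratio.
    """
    feature_dims = feature_dims or {"vision": 64, "language": 64}
    rng = np.random.default_rng(seed)
    if region_labels is None:
        region_labels = make_region_labels(graph, region_size, seed=rng.integers(2**31))
    region_labels = np.asarray(region_labels)
    if region_labels.shape[0] != graph.n_vertices:
        raise DataIntegrityError("region labels must cover all graph vertices")

    def sample_map(in_dim: int, label: str) -> np.ndarray:
        n_region = int(np.sum(region_labels == label))
        return rng.standard_normal((in_dim, n_region)) / np.sqrt(in_dim)

    mixing = {
        "invariant": sample_map(latent_dim, "invariant"),
        "image_only": sample_map(feature_dims["vision"], "image_only"),
        "caption_only": sample_map(feature_dims["language"], "caption_only"),
    }
    return GroundTruth(region_labels, latent_dim, mixing, noise_sd, imagery_noise_factor)


@dataclass
class BrainResponses:
    """Per-trial beta matrix for one subject, rows aligned to ``trial_table``."""

    subject_id: str
    betas: np.ndarray
    trial_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.shape[0] != len(self.trial_table):
            raise DataIntegrityError("betas rows must match trial table length")
        if not np.all(np.isfinite(self.betas)):
            raise DataIntegrityError("betas contain non-finite values")

    @property
    def n_vertices(self) -> int:
        return self.betas.shape[1]

    def rows(self, modality: str | None = None, split: str | None = None) -> np.ndarray:
        mask = np.ones(len(self.trial_table), dtype=bool)
        if modality is not None:
            mask &= (self.trial_table["modality"] == modality).to_numpy()
        if split is not None:
            mask &= (self.trial_table["split"] == split).to_numpy()
        return np.flatnonzero(mask)


def generate_brain_responses(
    stimuli: StimulusSet,
    features: dict[str, FeatureMatrix],
    graph: SurfaceGraph,
    truth: GroundTruth,
    subject_id: str = "sub-01",
    seed: int | None = None,
    modality_noise_sd: dict[str, float] | None = None,
) -> BrainResponses:
    """Simulate the beta matrix for one subject under the planted model.

    ``modality_noise_sd`` optionally overrides ``truth.noise_sd`` per trial
    modality (image / caption), e.g. to make one modality's responses
    noisier; imagery trials always use ``noise_sd * imagery_noise_factor``.
    """
    if truth.region_labels.shape[0] != graph.n_vertices:
        raise DataIntegrityError("truth labels must cover all graph vertices")
    for name in ("vision", "language"):
        if name not in features:
            raise DataIntegrityError(f"features for provider {name!r} required")
    trials = stimuli.trials.reset_index(drop=True)
    known = set(int(s) for s in features["vision"].stimulus_ids)
    missing = set(int(s) for s in trials["stimulus_id"]) - known
    if missing:
        raise DataIntegrityError(f"no features for trial stimuli {sorted(missing)[:5]}")

    rng = np.random.default_rng(seed)
    n_trials, n_vertices = len(trials), graph.n_vertices
    modality = trials["modality"].to_numpy()
    sd = np.full(n_trials, truth.noise_sd)
    if modality_noise_sd:
        for mod, s in modality_noise_sd.items():
            sd[modality == mod] = s
    sd[modality == "imagery"] = truth.noise_sd * truth.imagery_noise_factor
    betas = rng.standard_normal((n_trials, n_vertices)) * sd[:, None]

    sids = trials["stimulus_id"].to_numpy()
    inv = truth.indices("invariant")
    if inv.size:
        # invariant pathway: identical drive for image, caption and imagery
        betas[:, inv] += stimuli.latents_for(sids) @ truth.mixing_maps["invariant"]
    img = truth.indices("image_only")
    img_rows = np.flatnonzero(modality == "image")
    if img.size and img_rows.size:
        betas[np.ix_(img_rows, img)] += (
            features["vision"].select(sids[img_rows]) @ truth.mixing_maps["image_only"]
        )
    cap = truth.indices("caption_only")
    cap_rows = np.flatnonzero(modality == "caption")
    if cap.size and cap_rows.size:
        betas[np.ix_(cap_rows, cap)] += (
            features["language"].select(sids[cap_rows])
            @ truth.mixing_maps["caption_only"]
        )
    return BrainResponses(subject_id, betas, trials.copy())


@dataclass
class Dataset:
    """A full synthetic study: graph, stimuli, features, truth, responses."""

    graph: SurfaceGraph
    stimuli: StimulusSet
    features: dict[str, FeatureMatrix]
    truths: dict[str, GroundTruth]
    responses: dict[str, BrainResponses]
    params: dict = field(default_factory=dict)

    @property
    def subjects(self) -> list[str]:
        return list(self.responses)


def simulate_dataset(
    n_subjects: int = 6,
    n_vertices: int = 900,
    topology: str = "grid",
    n_train_images: int = 400,
    n_train_captions: int = 400,
    n_test_pairs: int = 70,
    latent_dim: int = 16,
    feature_dims: dict[str, int] | None = None,
    modality_specific_weight: float | dict[str, float] = 0.5,
    region_size: int | dict[str, int] = 60,
    noise_sd: float = 1.0,
    imagery_noise_factor: float = 2.0,
    modality_noise_sd: dict[str, float] | None = None,
    seed: int = 0,
) -> Dataset:
    """Generate the default desk-scale study.

    Region labels are shared across subjects (group analyses assume spatial
    correspondence); mixing maps and noise are per subject. Every source of
    randomness descends deterministically from ``seed``.
    """
    feature_dims = feature_dims or {"vision": 64, "language": 64, "multimodal": 64}
    ss = np.random.SeedSequence(seed)
    s_graph, s_stim, s_feat, s_labels, *s_subj = ss.spawn(4 + n_subjects)

    def as_seed(s: np.random.SeedSequence) -> int:
        return int(s.generate_state(1)[0] % (2**31))

    graph = generate_surface_graph(n_vertices, topology, seed=as_seed(s_graph))
    stimuli = generate_stimulus_set(
        n_train_images, n_train_captions, n_test_pairs, latent_dim, seed=as_seed(s_stim)
    )
    features = generate_feature_spaces(
        stimuli,
        dims=feature_dims,
        modality_specific_weight=modality_specific_weight,
        seed=as_seed(s_feat),
    )
    labels = make_region_labels(graph, region_size, seed=as_seed(s_labels))
    truths: dict[str, GroundTruth] = {}
    responses: dict[str, BrainResponses] = {}
    for i, s in enumerate(s_subj):
        sub = f"sub-{i + 1:02d}"
        truth_seed, resp_seed = (as_seed(c) for c in s.spawn(2))
        truth = make_ground_truth(
            graph,
            region_labels=labels,
            latent_dim=latent_dim,
            feature_dims={k: v for k, v in feature_dims.items() if k != "multimodal"},
            noise_sd=noise_sd,
            imagery_noise_factor=imagery_noise_factor,
            seed=truth_seed,
        )
        truths[sub] = truth
        responses[sub] = generate_brain_responses(
            stimuli,
            features,
            graph,
            truth,
            subject_id=sub,
            seed=resp_seed,
            modality_noise_sd=modality_noise_sd,
        )
    params = dict(
        n_subjects=n_subjects,
        n_vertices=n_vertices,
        topology=topology,
        n_train_images=n_train_images,
        n_train_captions=n_train_captions,
        n_test_pairs=n_test_pairs,
        latent_dim=latent_dim,
        region_size=region_size,
        noise_sd=noise_sd,
        imagery_noise_factor=imagery_noise_factor,
        seed=seed,
    )
    return Dataset(graph, stimuli, features, truths, responses, params)
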