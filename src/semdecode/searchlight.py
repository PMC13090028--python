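"""Searchlight localization of modality-invariant cortex.

For every vertex, three ridge decoders (modality-agnostic, image-specific,
caption-specific) are fitted on the neighborhood's vertices and scored on
four conditions: agnostic decoding of images and of captions, and the two
cross-decoding directions. A region is modality-invariant only if all four
are above chance, so the four one-tailed t-maps (vs 0.5 across subjects)
are combined by their pointwise minimum, enhanced with graph TFCE
(exponents H=2, E=1), and tested against a bootstrap-permutation null:
each subject contributes shuffled-label chance maps, group-level max-TFCE
statistics are recomputed over unique subject combinations, and vertexwise
p-values compare observed TFCE to the null maxima (max-statistic FWER
correction).

The per-vertex ridge fits reuse one precomputed Gram matrix per decoder
and subject: a neighborhood's normal equations are a submatrix slice, so
the searchlight is exact yet far cheaper than refitting from raw trials.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .errors import ConfigurationError, DataIntegrityError
from .features import FeatureMatrix
from .surface import SurfaceGraph
from .synthetic import BrainResponses

__all__ = [
    "SearchlightConfig",
    "TFCEParams",
    "PermutationConfig",
    "StatMap",
    "AccuracyMaps",
    "build_neighborhoods",
    "run_searchlight",
    "per_subject_null",
    "one_sample_t_map",
    "conjunction_min_t",
    "tfce",
    "group_null",
    "compute_pvalues",
    "correlate_maps",
    "searchlight_analysis",
]

T_SENTINEL = 1e6  # cap for zero-variance t-values; keeps min/TFCE finite

PERCEPTION_CONDITIONS = (
    "agnostic_image",
    "agnostic_caption",
    "cross_image",
    "cross_caption",
)


@dataclass
class SearchlightConfig:
    """Searchlight decoding options.

    ``k_neighbors`` follows the field convention of a fixed-size
    neighborhood (750 closest vertices on a full-resolution surface; scale
    it with the graph). ``alpha`` is the shared ridge penalty used inside
    every neighborhood.
    """

    k_neighbors: int = 750
    provider: str = "multimodal"
    alpha: float = 10.0
    include_imagery: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ConfigurationError("k_neighbors must be >= 1")
        if self.alpha < 0:
            raise ConfigurationError("alpha must be >= 0")


@dataclass
class TFCEParams:
    """TFCE exponents and threshold step.

    ``h`` (height) and ``e`` (extent) default to the surface-based
    convention h=2, e=1. ``dh=None`` uses max(map)/100 (floored at 1e-6).
    """

    h: float = 2.0
    e: float = 1.0
    dh: float | None = None

    def __post_init__(self) -> None:
        if self.h <= 0 or self.e <= 0:
            raise ConfigurationError("TFCE exponents must be positive")
        if self.dh is not None and self.dh <= 0:
            raise ConfigurationError("dh must be positive")


@dataclass
class PermutationConfig:
    n_per_subject_nulls: int = 100
    n_group_permutations: int = 10_000
    unique: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_subject_nulls < 1 or self.n_group_permutations < 1:
            raise ConfigurationError("permutation counts must be >= 1")


@dataclass
class StatMap:
    """Per-vertex scalar field (accuracy, t, TFCE or p) on a surface."""

    values: np.ndarray
    kind: str
    graph: SurfaceGraph | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DataIntegrityError("StatMap values must be 1-D")
        if self.graph is not None and len(self.values) != self.graph.n_vertices:
            raise DataIntegrityError("StatMap length must match graph")
        if self.kind == "p" and (
            np.any(self.values < 0) or np.any(self.values > 1)
        ):
            raise DataIntegrityError("p-values must lie in [0, 1]")


@dataclass
class AccuracyMaps:
    """subjects x vertices x conditions accuracy array."""

    data: np.ndarray
    subjects: list[str]
    conditions: list[str]
    graph: SurfaceGraph | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[:1] != (len(self.subjects),) or self.data.shape[2] != len(
            self.conditions
        ):
            raise DataIntegrityError("AccuracyMaps shape mismatch")
        if np.any(self.data < 0) or np.any(self.data > 1):
            raise DataIntegrityError("accuracies must lie in [0, 1]")

    def condition(self, name: str) -> np.ndarray:
        return self.data[:, :, self.conditions.index(name)]


def build_neighborhoods(graph: SurfaceGraph, k: int) -> np.ndarray:
    """k-nearest-vertex searchlights by Euclidean coordinate distance.

    Each row lists the center first, then its k-1 nearest other vertices;
    distance ties break by vertex id. O(n^2) memory — intended for the
    desk-scale graphs this package simulates.
    """
    n = graph.n_vertices
    if k > n:
        raise ConfigurationError(f"k={k} exceeds n_vertices={n}")
    d = np.linalg.norm(graph.coords[:, None, :] - graph.coords[None], axis=2)
    ids = np.broadcast_to(np.arange(n), (n, n))
    order = np.lexsort((ids, d), axis=1)  # distance, then id
    out = np.empty((n, k), dtype=np.intp)
    for v in range(n):
        row = order[v]
        row = row[row != v]
        out[v, 0] = v
        out[v, 1:] = row[: k - 1]
    return out


def _standardized(x: np.ndarray, mean=None, sd=None):
    if mean is None:
        mean = x.mean(axis=0)
        s = x.std(axis=0, ddof=1)
        sd = np.where(s > 0, s, 1.0)
    return (x - mean) / sd, mean, sd


def _unit(x: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(x, axis=1, keepdims=True)
    return x / np.where(n > 0, n, 1.0)


def _chunk_accuracies(
    xq: np.ndarray,  # (Q, V) standardized query betas for this decoder
    w: np.ndarray,  # (Vc, k, D) neighborhood weights, chunk of vertices
    nb: np.ndarray,  # (Vc, k) neighborhood vertex indices
    ym: np.ndarray,  # (D,) target intercept
    cand_unit: np.ndarray,  # (C, D) unit-norm candidate features
    true_idx: np.ndarray,  # (Q,) true candidate column per query
    pairings: np.ndarray,  # (P, C) candidate-position permutations
) -> np.ndarray:
    """Pairwise accuracies, shape (P, Vc), for one condition and one chunk."""
    pred = np.einsum("qvk,vkd->vqd", xq[:, nb], w, optimize=True) + ym
    # per-vertex standardization of predictions over the evaluated set
    mean = pred.mean(axis=1, keepdims=True)
    sd = pred.std(axis=1, ddof=1, keepdims=True)
    pred = (pred - mean) / np.where(sd > 0, sd, 1.0)
    norms = np.linalg.norm(pred, axis=2, keepdims=True)
    pred /= np.where(norms > 0, norms, 1.0)
    sims = np.einsum("vqd,cd->vqc", pred, cand_unit, optimize=True)
    ranks = stats.rankdata(sims, method="average", axis=-1)
    scores = (ranks - 1.0) / (sims.shape[2] - 1)  # (Vc, Q, C)
    shuffled = pairings[:, true_idx]  # (P, Q)
    gathered = np.take_along_axis(
        scores[None], shuffled[:, None, :, None], axis=3
    )  # (P, Vc, Q, 1)
    return gathered[..., 0].mean(axis=2)


def _subject_searchlight(
    responses: BrainResponses,
    features: FeatureMatrix,
    neighborhoods: np.ndarray,
    alpha: float,
    pairings: np.ndarray,
    include_imagery: bool = False,
    chunk_size: int = 128,
) -> np.ndarray:
    """Accuracy maps for one subject under one or more label pairings.

    ``pairings`` has shape (n_pairings, n_test_stimuli); each row is a
    permutation of candidate positions applied to the true pairing (row 0
    is usually the identity). Returns (n_pairings, n_vertices,
    n_conditions); the imagery condition, if requested, is only scored for
    the identity pairing and repeated across pairings.

    Per-vertex ridge fits are exact but share one Gram matrix per decoder:
    a neighborhood's normal equations are a submatrix slice, solved in
    LAPACK batches across vertices.
    """
    if np.any(neighborhoods >= responses.n_vertices):
        raise DataIntegrityError("neighborhood references a missing vertex")
    tab = responses.trial_table
    sids = tab["stimulus_id"].to_numpy()
    rows_ti = responses.rows("image", "train")
    rows_tc = responses.rows("caption", "train")
    rows_ei = responses.rows("image", "test")
    rows_ec = responses.rows("caption", "test")
    if min(len(rows_ti), len(rows_tc)) == 0:
        raise DataIntegrityError("both modalities need training trials")

    cand_ids = np.sort(np.unique(sids[rows_ei]))
    cand = _unit(features.select(cand_ids))
    pos = {int(s): j for j, s in enumerate(cand_ids)}
    true_i = np.array([pos[int(s)] for s in sids[rows_ei]])
    true_c = np.array([pos[int(s)] for s in sids[rows_ec]])

    decoders = {
        "agnostic": np.concatenate([rows_ti, rows_tc]),
        "image": rows_ti,
        "caption": rows_tc,
    }
    conditions = [
        ("agnostic_image", "agnostic", rows_ei, true_i),
        ("agnostic_caption", "agnostic", rows_ec, true_c),
        ("cross_image", "caption", rows_ei, true_i),
        ("cross_caption", "image", rows_ec, true_c),
    ]

    prep = {}
    for name, rows in decoders.items():
        x, mean, sd = _standardized(responses.betas[rows])
        y = features.select(sids[rows])
        ym = y.mean(axis=0)
        prep[name] = dict(
            gram=x.T @ x, xty=x.T @ (y - ym), ym=ym, mean=mean, sd=sd
        )

    imagery_rows = responses.rows("imagery")
    if include_imagery:
        if imagery_rows.size < 2:
            raise DataIntegrityError("imagery searchlight needs >= 2 imagery trials")
        im_ids = np.sort(np.unique(sids[imagery_rows]))
        ext_ids = np.concatenate([im_ids, cand_ids])
        cand_ext = _unit(features.select(ext_ids))
        pos_ext = {int(s): j for j, s in enumerate(ext_ids)}
        true_im = np.array([pos_ext[int(s)] for s in sids[imagery_rows]])
        ident_ext = np.arange(len(ext_ids))[None, :]

    n_vertices = responses.n_vertices
    n_pair = len(pairings)
    n_cond = 4 + int(include_imagery)
    out = np.empty((n_pair, n_vertices, n_cond))
    k = neighborhoods.shape[1]
    eye = np.arange(k)
    for start in range(0, n_vertices, chunk_size):
        nb = neighborhoods[start : start + chunk_size]
        weights = {}
        for name, p in prep.items():
            g = p["gram"][nb[:, :, None], nb[:, None, :]].copy()  # (Vc, k, k)
            g[:, eye, eye] += alpha
            weights[name] = np.linalg.solve(g, p["xty"][nb])  # (Vc, k, D)
        for c, (_, dname, qrows, true_idx) in enumerate(conditions):
            p = prep[dname]
            xq = (responses.betas[qrows] - p["mean"]) / p["sd"]
            out[:, start : start + len(nb), c] = _chunk_accuracies(
                xq, weights[dname], nb, p["ym"], cand, true_idx, pairings
            )
        if include_imagery:
            p = prep["agnostic"]
            xq = (responses.betas[imagery_rows] - p["mean"]) / p["sd"]
            acc = _chunk_accuracies(
                xq, weights["agnostic"], nb, p["ym"], cand_ext, true_im, ident_ext
            )
            out[:, start : start + len(nb), 4] = acc[0]
    return out


def _identity_pairing(responses: BrainResponses) -> np.ndarray:
    rows_ei = responses.rows("image", "test")
    n = len(
        np.unique(responses.trial_table["stimulus_id"].to_numpy()[rows_ei])
    )
    return np.arange(n)[None, :]


def run_searchlight(
    responses_by_subject: dict[str, BrainResponses],
    features: FeatureMatrix,
    neighborhoods: np.ndarray,
    config: SearchlightConfig,
) -> AccuracyMaps:
    """Per-subject, per-vertex decoding accuracies for the four conditions
    (plus imagery if configured)."""
    subjects = list(responses_by_subject)
    maps = []
    for sub in subjects:
        resp = responses_by_subject[sub]
        acc = _subject_searchlight(
            resp,
            features,
            neighborhoods,
            config.alpha,
            _identity_pairing(resp),
            include_imagery=config.include_imagery,
        )
        maps.append(acc[0])
    conditions = list(PERCEPTION_CONDITIONS) + (
        ["imagery"] if config.include_imagery else []
    )
    return AccuracyMaps(np.stack(maps), subjects, conditions)


def per_subject_null(
    responses_by_subject: dict[str, BrainResponses],
    features: FeatureMatrix,
    neighborhoods: np.ndarray,
    n_shuffles: int,
    seed: int | None = None,
    config: SearchlightConfig | None = None,
) -> dict[str, np.ndarray]:
    """Shuffled-label chance maps per subject.

    Decoders are fitted once; each shuffle permutes the query-to-true-
    candidate pairing at evaluation time (one permutation per shuffle,
    shared across vertices and conditions so the null maps keep their
    spatial correlation). The identity permutation is excluded. Returns
    ``{subject: (n_shuffles, n_vertices, 4)}``.
    """
    if n_shuffles < 1:
        raise ConfigurationError("n_shuffles must be >= 1")
    config = config or SearchlightConfig()
    rng = np.random.default_rng(seed)
    out = {}
    for sub, resp in responses_by_subject.items():
        n = _identity_pairing(resp).shape[1]
        perms = np.empty((n_shuffles, n), dtype=np.intp)
        for i in range(n_shuffles):
            while True:
                perm = rng.permutation(n)
                if not np.array_equal(perm, np.arange(n)):
                    break
            perms[i] = perm
        acc = _subject_searchlight(
            resp, features, neighborhoods, config.alpha, perms, include_imagery=False
        )
        out[sub] = acc
    return out


def _t_values(acc: np.ndarray, null_value: float) -> np.ndarray:
    """One-sample t across the first axis with zero-variance capping."""
    n = acc.shape[0]
    mean = acc.mean(axis=0)
    sd = acc.std(axis=0, ddof=1)
    diff = mean - null_value
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / (sd / np.sqrt(n))
    t = np.where(sd == 0, np.sign(diff) * T_SENTINEL, t)
    return np.clip(t, -T_SENTINEL, T_SENTINEL)


def one_sample_t_map(
    accuracies: np.ndarray,
    null_value: float = 0.5,
    graph: SurfaceGraph | None = None,
) -> StatMap:
    """Vertexwise one-tailed one-sample t against chance.

    ``accuracies`` is (n_subjects, n_vertices); zero-variance vertices map
    to a signed sentinel of magnitude 1e6 instead of infinity.
    """
    acc = np.asarray(accuracies, dtype=float)
    if acc.ndim != 2 or acc.shape[0] < 2:
        raise DataIntegrityError("need >= 2 subjects for a t-map")
    return StatMap(_t_values(acc, null_value), "t", graph)


def conjunction_min_t(maps: list[StatMap]) -> StatMap:
    """Pointwise minimum of t-maps: significant only where all hold."""
    graphs = {id(m.graph) for m in maps if m.graph is not None}
    if len(graphs) > 1:
        raise DataIntegrityError("conjunction requires maps on the same graph")
    lengths = {len(m.values) for m in maps}
    if len(lengths) != 1:
        raise DataIntegrityError("conjunction requires equal-length maps")
    values = np.min(np.stack([m.values for m in maps]), axis=0)
    graph = next((m.graph for m in maps if m.graph is not None), None)
    return StatMap(values, "min_t", graph)


def _tfce_values(
    values: np.ndarray, edges: np.ndarray, n: int, params: TFCEParams
) -> np.ndarray:
    v = np.clip(np.asarray(values, dtype=float), 0.0, None)
    out = np.zeros(n)
    vmax = v.max() if v.size else 0.0
    if vmax <= 0:
        return out
    dh = params.dh if params.dh is not None else max(vmax / 100.0, 1e-6)
    if dh <= 0:
        raise ConfigurationError("dh must be positive")
    thresholds = np.arange(dh, vmax * (1 + 1e-12), dh)
    # restrict to the positive support once; everything else never clusters
    nodes = np.flatnonzero(v > 0)
    remap = np.full(n, -1, dtype=np.intp)
    remap[nodes] = np.arange(len(nodes))
    keep = (v[edges[:, 0]] > 0) & (v[edges[:, 1]] > 0)
    e0, e1 = remap[edges[keep, 0]], remap[edges[keep, 1]]
    vs = v[nodes]
    ns = len(nodes)
    acc = np.zeros(ns)
    for h in thresholds:
        active = vs >= h
        if not active.any():
            continue
        live = active[e0] & active[e1]
        adj = sparse.coo_matrix(
            (np.ones(int(live.sum())), (e0[live], e1[live])), shape=(ns, ns)
        )
        _, labels = connected_components(adj, directed=False)
        sizes = np.bincount(labels[active], minlength=labels.max() + 1)
        acc[active] += sizes[labels[active]] ** params.e * h**params.h * dh
    out[nodes] = acc
    return out


def tfce(
    stat_map: StatMap | np.ndarray,
    graph: SurfaceGraph | None = None,
    params: TFCEParams | None = None,
) -> StatMap:
    """Threshold-free cluster enhancement on the surface graph.

    TFCE(v) = sum over thresholds h (step dh, up to the map max) of
    extent(v, h)^E * h^H * dh, where extent is the size of v's connected
    component among vertices >= h. Negative values contribute nothing
    (one-tailed hypothesis; they are clamped to zero first).
    """
    params = params or TFCEParams()
    if isinstance(stat_map, StatMap):
        graph = graph or stat_map.graph
        values = stat_map.values
    else:
        values = np.asarray(stat_map, dtype=float)
    if graph is None:
        raise ConfigurationError("tfce needs a graph for connectivity")
    out = _tfce_values(values, graph.edges, graph.n_vertices, params)
    return StatMap(out, "tfce", graph)


def _unique_tuples(
    n_shuffles: int, n_subjects: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    bound = n_shuffles**n_subjects
    if n_perm > bound:
        raise ConfigurationError(
            f"cannot draw {n_perm} unique permutations from "
            f"{n_shuffles}^{n_subjects} = {bound} combinations"
        )
    if bound <= max(100_000, 4 * n_perm):
        allt = np.array(
            list(itertools.product(range(n_shuffles), repeat=n_subjects)),
            dtype=np.intp,
        )
        sel = rng.permutation(bound)[:n_perm]
        return allt[sel]
    seen: set[tuple[int, ...]] = set()
    out = np.empty((n_perm, n_subjects), dtype=np.intp)
    k = 0
    while k < n_perm:
        cand = tuple(int(x) for x in rng.integers(0, n_shuffles, size=n_subjects))
        if cand in seen:
            continue
        seen.add(cand)
        out[k] = cand
        k += 1
    return out


def group_null(
    banks: dict[str, np.ndarray],
    perm_config: PermutationConfig,
    graph: SurfaceGraph,
    tfce_params: TFCEParams | None = None,
    null_value: float = 0.5,
) -> np.ndarray:
    """Max-TFCE null distribution from per-subject chance banks.

    For each of ``n_group_permutations`` unique subject-shuffle
    combinations, one chance map is drawn per subject and the group
    statistic (four t-maps, min-t conjunction, TFCE) is recomputed; the
    spatial maximum is recorded. Returns the sorted-free maxima array.
    """
    tfce_params = tfce_params or TFCEParams()
    subjects = list(banks)
    shapes = {banks[s].shape for s in subjects}
    if len(shapes) != 1:
        raise DataIntegrityError("all null banks must share a shape")
    n_shuffles, n_vertices, n_cond = shapes.pop()
    rng = np.random.default_rng(perm_config.seed)
    tuples = _unique_tuples(
        n_shuffles, len(subjects), perm_config.n_group_permutations, rng
    )
    stack = np.stack([banks[s] for s in subjects])  # (S, shuffles, V, C)
    maxima = np.empty(len(tuples))
    edges, n = graph.edges, graph.n_vertices
    for i, tup in enumerate(tuples):
        acc = stack[np.arange(len(subjects)), tup]  # (S, V, C)
        t = _t_values(acc, null_value)  # (V, C)
        min_t = t.min(axis=1)
        maxima[i] = _tfce_values(min_t, edges, n, tfce_params).max()
    return maxima


def compute_pvalues(
    observed: StatMap, null_maxima: np.ndarray, method: str = "literal"
) -> StatMap:
    """Vertexwise p from the max-statistic null.

    ``literal`` is the plain proportion of null maxima exceeding the
    observed value (can be exactly 0); ``add_one`` is the Phipson–Smyth
    (b+1)/(m+1) variant.
    """
    null_maxima = np.asarray(null_maxima, dtype=float)
    if null_maxima.size == 0:
        raise ConfigurationError("null distribution is empty")
    exceed = (null_maxima[None, :] > observed.values[:, None]).sum(axis=1)
    if method == "literal":
        p = exceed / null_maxima.size
    elif method == "add_one":
        p = (exceed + 1) / (null_maxima.size + 1)
    else:
        raise ConfigurationError(f"unknown p-value method {method!r}")
    return StatMap(p, "p", observed.graph)


def correlate_maps(
    map_a: StatMap | np.ndarray,
    map_b: StatMap | np.ndarray,
    partition: np.ndarray | None = None,
):
    """Pearson correlation between two vertex maps.

    With ``partition`` (per-vertex block labels, e.g. hemispheres) returns
    ``{block: (r, p)}``; otherwise a single ``(r, p)``.
    """
    a = map_a.values if isinstance(map_a, StatMap) else np.asarray(map_a, float)
    b = map_b.values if isinstance(map_b, StatMap) else np.asarray(map_b, float)
    if a.shape != b.shape:
        raise DataIntegrityError("maps must have identical vertex sets")

    def one(x, y):
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ConfigurationError("correlation undefined for a constant map")
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)

    if partition is None:
        return one(a, b)
    partition = np.asarray(partition)
    return {
        lab: one(a[partition == lab], b[partition == lab])
        for lab in np.unique(partition)
    }


def searchlight_analysis(
    responses_by_subject: dict[str, BrainResponses],
    features: FeatureMatrix,
    graph: SurfaceGraph,
    config: SearchlightConfig | None = None,
    tfce_params: TFCEParams | None = None,
    perm_config: PermutationConfig | None = None,
) -> dict:
    """End-to-end conjunction analysis: searchlight, t-maps, min-t, TFCE,
    permutation null, corrected p-values (and imagery maps if configured)."""
    config = config or SearchlightConfig()
    tfce_params = tfce_params or TFCEParams()
    perm_config = perm_config or PermutationConfig()
    neighborhoods = build_neighborhoods(graph, config.k_neighbors)
    # one pass per subject: identity pairing (observed) + shuffled pairings
    # (per-subject null bank), sharing the per-vertex decoder fits
    rng = np.random.default_rng(perm_config.seed)
    subjects = list(responses_by_subject)
    obs_maps, banks = [], {}
    for sub in subjects:
        resp = responses_by_subject[sub]
        identity = _identity_pairing(resp)
        n = identity.shape[1]
        perms = np.empty((perm_config.n_per_subject_nulls, n), dtype=np.intp)
        for i in range(perm_config.n_per_subject_nulls):
            while True:
                perm = rng.permutation(n)
                if not np.array_equal(perm, identity[0]):
                    break
            perms[i] = perm
        all_pairings = np.vstack([identity, perms])
        acc_all = _subject_searchlight(
            resp,
            features,
            neighborhoods,
            config.alpha,
            all_pairings,
            include_imagery=config.include_imagery,
        )
        obs_maps.append(acc_all[0])
        banks[sub] = acc_all[1:, :, :4]
    conditions = list(PERCEPTION_CONDITIONS) + (
        ["imagery"] if config.include_imagery else []
    )
    acc = AccuracyMaps(np.stack(obs_maps), subjects, conditions, graph)
    t_maps = {
        cond: one_sample_t_map(acc.condition(cond), graph=graph)
        for cond in PERCEPTION_CONDITIONS
    }
    min_t = conjunction_min_t([t_maps[c] for c in PERCEPTION_CONDITIONS])
    observed = tfce(min_t, graph, tfce_params)
    maxima = group_null(banks, perm_config, graph, tfce_params)
    pvals = compute_pvalues(observed, maxima)
    result = dict(
        accuracy=acc,
        t_maps=t_maps,
        min_t=min_t,
        tfce=observed,
        null_maxima=maxima,
        p_values=pvals,
        neighborhoods=neighborhoods,
    )
    if config.include_imagery:
        t_im = one_sample_t_map(acc.condition("imagery"), graph=graph)
        tfce_im = tfce(StatMap(np.clip(t_im.values, 0, None), "t", graph), graph, tfce_params)
        result["imagery_t"] = t_im
        result["imagery_tfce"] = tfce_im
        result["imagery_conjunction_r"] = correlate_maps(observed, tfce_im)
    return result
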