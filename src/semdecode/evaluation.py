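"""Identification metrics and decoder comparisons.

The core metric is pairwise identification accuracy: predictions are
compared to every candidate's features by cosine similarity, and each
query scores the fraction of distractors whose similarity falls strictly
below the true candidate's (ties count one half). Chance is 0.5.

Within-modality, cross-modality and modality-agnostic configurations share
this metric; they differ only in which decoder produces the predictions
and which trials are queried. For cross-modal evaluation the true candidate
is the paired stimulus of the other modality. Predictions are column-
standardized over the evaluated stimulus set before similarity (imagery
predictions separately from perceptual ones).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
import statsmodels.formula.api as smf

from .errors import ConfigurationError, DataIntegrityError
from .features import FeatureMatrix, standardize_columns
from .synthetic import BrainResponses, StimulusSet

__all__ = [
    "SimilarityMatrix",
    "EvaluationResult",
    "cosine_similarity_matrix",
    "pairwise_accuracy",
    "evaluate_decoders",
    "rank_candidates",
    "evaluate_imagery",
    "bootstrap_ci",
    "compare_decoder_types",
    "results_to_frame",
]

METRICS = (
    "within_image",
    "within_caption",
    "cross_image",
    "cross_caption",
    "agnostic_image",
    "agnostic_caption",
    "imagery",
)


@dataclass
class SimilarityMatrix:
    """Cosine similarities between predicted and candidate features."""

    values: np.ndarray
    query_ids: np.ndarray
    candidate_ids: np.ndarray
    true_index: np.ndarray  # per query, column of its true candidate

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.true_index = np.asarray(self.true_index, dtype=np.intp)
        nq, nc = self.values.shape
        if self.true_index.shape != (nq,):
            raise DataIntegrityError("true_index must map every query")
        if np.any(self.true_index < 0) or np.any(self.true_index >= nc):
            raise DataIntegrityError("true_index out of candidate range")
        if not np.all(np.isfinite(self.values)):
            raise DataIntegrityError("similarities must be finite")


@dataclass
class EvaluationResult:
    metric: str
    accuracy: float
    n_queries: int
    subject_id: str | None = None
    provider_name: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise DataIntegrityError("accuracy must lie in [0, 1]")


def _unit_rows(x: np.ndarray, what: str, ids=None) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    norms = np.linalg.norm(x, axis=1)
    if np.any(norms == 0):
        bad = int(np.flatnonzero(norms == 0)[0])
        label = bad if ids is None else ids[bad]
        raise DataIntegrityError(f"zero-norm {what} row for id {label!r}")
    return x / norms[:, None]


def cosine_similarity_matrix(
    predictions,
    targets,
    query_ids=None,
    candidate_ids=None,
    true_index=None,
    truth_pairing: dict | None = None,
) -> SimilarityMatrix:
    """Cosine similarity of each prediction row against each target row.

    The true candidate per query comes either from ``true_index`` (column
    positions) or ``truth_pairing`` (query id -> candidate id), the latter
    expressing the cross-modal rule that the paired stimulus counts as
    correct.
    """
    predictions = np.asarray(predictions, dtype=float)
    targets = np.asarray(targets, dtype=float)
    nq, nc = predictions.shape[0], targets.shape[0]
    query_ids = np.arange(nq) if query_ids is None else np.asarray(query_ids)
    candidate_ids = np.arange(nc) if candidate_ids is None else np.asarray(candidate_ids)
    if true_index is None:
        if truth_pairing is None:
            raise ConfigurationError("need true_index or truth_pairing")
        col = {int(c): j for j, c in enumerate(candidate_ids)}
        true_index = np.array([col[int(truth_pairing[int(q)])] for q in query_ids])
    p = _unit_rows(predictions, "prediction", query_ids)
    t = _unit_rows(targets, "candidate", candidate_ids)
    values = np.clip(p @ t.T, -1.0, 1.0)
    return SimilarityMatrix(values, query_ids, candidate_ids, np.asarray(true_index))


def _row_scores(values: np.ndarray) -> np.ndarray:
    """Per (query, candidate): fraction of other candidates strictly below,
    ties counting 0.5 — i.e. (average rank - 1) / (n_candidates - 1)."""
    ranks = rankdata(values, method="average", axis=1)
    return (ranks - 1.0) / (values.shape[1] - 1)


def pairwise_accuracy(sim: SimilarityMatrix) -> float:
    """Mean over queries of the true candidate's win fraction; chance 0.5."""
    if sim.values.shape[1] < 2:
        raise ConfigurationError("pairwise accuracy needs >= 2 candidates")
    scores = _row_scores(sim.values)
    return float(scores[np.arange(len(sim.true_index)), sim.true_index].mean())


def _metric_accuracy(pred, candidates, true_index, ids=None, cand_ids=None) -> float:
    sim = cosine_similarity_matrix(
        standardize_columns(pred), candidates, ids, cand_ids, true_index=true_index
    )
    return pairwise_accuracy(sim)


def evaluate_decoders(
    test_responses: BrainResponses,
    decoders: dict,
    features: dict[str, FeatureMatrix] | FeatureMatrix,
) -> list[EvaluationResult]:
    """Score the six perception metrics on the matched test split.

    ``decoders`` maps roles ``image`` / ``caption`` / ``agnostic`` to fitted
    decoders. For every metric the candidate set is the test stimuli's
    features from the *evaluated decoder's* provider; image-decoding
    metrics query image trials, caption-decoding metrics caption trials.
    """
    for role in ("image", "caption", "agnostic"):
        if role not in decoders:
            raise ConfigurationError(f"missing decoder role {role!r}")
    if isinstance(features, FeatureMatrix):
        features = {features.provider_name: features}

    def candidates_for(decoder) -> FeatureMatrix:
        name = decoder.provider_name
        if name in features:
            return features[name]
        for fm in features.values():
            if fm.provider_name == name:
                return fm
        raise ConfigurationError(f"no feature matrix for provider {name!r}")

    tab = test_responses.trial_table
    out: list[EvaluationResult] = []
    metric_plan = [
        ("within_image", "image", "image"),
        ("within_caption", "caption", "caption"),
        ("cross_image", "caption", "image"),
        ("cross_caption", "image", "caption"),
        ("agnostic_image", "agnostic", "image"),
        ("agnostic_caption", "agnostic", "caption"),
    ]
    for metric, role, query_modality in metric_plan:
        decoder = decoders[role]
        rows = test_responses.rows(modality=query_modality, split="test")
        if rows.size < 2:
            raise DataIntegrityError(f"need >= 2 test {query_modality} trials")
        fm = candidates_for(decoder)
        sids = tab["stimulus_id"].to_numpy()[rows]
        cand_ids = np.sort(sids)
        cand = fm.select(cand_ids)
        pos = {int(s): j for j, s in enumerate(cand_ids)}
        true_index = np.array([pos[int(s)] for s in sids])
        pred = decoder.predict(test_responses.betas[rows])
        acc = _metric_accuracy(pred, cand, true_index, sids, cand_ids)
        out.append(
            EvaluationResult(
                metric, acc, len(rows), test_responses.subject_id, fm.provider_name
            )
        )
    return out


def rank_candidates(predictions, pool: FeatureMatrix, k: int):
    """Top-k candidate stimulus ids per query, by descending cosine.

    ``predictions`` may be a single vector or a matrix (e.g. subject-
    averaged predictions). Ties break deterministically by candidate id.
    """
    pred = np.atleast_2d(np.asarray(predictions, dtype=float))
    if k > len(pool.stimulus_ids):
        raise ConfigurationError("k exceeds candidate pool size")
    sims = _unit_rows(pred, "prediction") @ _unit_rows(pool.values, "candidate").T
    ids = np.asarray(pool.stimulus_ids)
    out = []
    for row in sims:
        order = np.lexsort((ids, -row))  # primary: similarity desc, then id asc
        out.append(ids[order[:k]])
    result = np.array(out)
    return result[0] if np.asarray(predictions).ndim == 1 else result


def evaluate_imagery(
    responses: BrainResponses,
    decoder,
    features: FeatureMatrix,
    stimuli: StimulusSet,
    mode: str = "three_only",
) -> EvaluationResult:
    """Apply a perception-trained decoder to the imagery trials.

    ``three_only`` ranks each imagery prediction against the three imagery
    stimuli; ``extended`` adds the full test set to the candidate pool.
    Imagery predictions are standardized separately (over their own rows),
    never pooled with perceptual predictions.
    """
    if mode not in ("three_only", "extended"):
        raise ConfigurationError("mode must be 'three_only' or 'extended'")
    if "imagery" in decoder.training_modalities_:
        raise ConfigurationError("decoder must be trained on perceptual trials only")
    rows = responses.rows(modality="imagery")
    if rows.size != len(stimuli.imagery_ids):
        raise DataIntegrityError("expected one trial per imagery condition")
    sids = responses.trial_table["stimulus_id"].to_numpy()[rows]
    cand_ids = np.sort(np.asarray(stimuli.imagery_ids))
    if mode == "extended":
        cand_ids = np.concatenate([cand_ids, stimuli.test_stimulus_ids])
    cand = features.select(cand_ids)
    pos = {int(s): j for j, s in enumerate(cand_ids)}
    true_index = np.array([pos[int(s)] for s in sids])
    pred = decoder.predict(responses.betas[rows])
    acc = _metric_accuracy(pred, cand, true_index, sids, cand_ids)
    return EvaluationResult(
        "imagery", acc, len(rows), responses.subject_id, decoder.provider_name
    )


def bootstrap_ci(
    values, n_boot: int = 10_000, level: float = 0.95, seed: int | None = None
) -> tuple[float, float]:
    """Percentile bootstrap interval for the mean of ``values``."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ConfigurationError("need >= 2 values to bootstrap")
    if n_boot < 100:
        raise ConfigurationError("n_boot must be >= 100 for a stable interval")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    means = x[idx].mean(axis=1)
    lo, hi = np.percentile(means, [50 * (1 - level), 100 - 50 * (1 - level)])
    return float(lo), float(hi)


def compare_decoder_types(table: pd.DataFrame):
    """Subject-grouped contrast between two decoder types.

    Fits ``accuracy ~ C(subject) + C(decoder_type)`` by least squares — the
    fixed-effects equivalent of a two-level repeated-measures comparison —
    and returns ``(coef, se, pvalue)`` for the decoder_type contrast
    (second level minus first, levels in sorted order).
    """
    required = {"subject", "decoder_type", "accuracy"}
    if not required <= set(table.columns):
        raise ConfigurationError(f"table must have columns {sorted(required)}")
    types = sorted(table["decoder_type"].unique())
    if len(types) != 2:
        raise ConfigurationError("exactly two decoder types required")
    per_subject = table.groupby("subject")["decoder_type"].nunique()
    if (per_subject < 2).any():
        bad = per_subject[per_subject < 2].index.tolist()
        raise DataIntegrityError(
            f"subjects observed under only one decoder type: {bad}"
        )
    formula = "accuracy ~ C(subject) + C(decoder_type)"
    if table["subject"].nunique() == 1:
        warnings.warn(
            "single subject: subject term absorbed into the intercept",
            UserWarning,
            stacklevel=2,
        )
        formula = "accuracy ~ C(decoder_type)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = smf.ols(formula, data=table).fit()
    name = f"C(decoder_type)[T.{types[1]}]"
    coef = float(fit.params[name])
    se = float(fit.bse[name])
    p = float(fit.pvalues[name])
    return coef, se, p


def results_to_frame(results: list[EvaluationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                subject=r.subject_id,
                provider=r.provider_name,
                metric=r.metric,
                accuracy=r.accuracy,
                n_queries=r.n_queries,
            )
            for r in results
        ]
    )
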