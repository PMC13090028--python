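"""Ridge decoders from vertex responses to stimulus embedding spaces.

The decoder is multi-output ridge regression with an unpenalized intercept
fitted by centering:

    min_W  ||Y - XW - b||^2 + alpha ||W||^2

Modality-specific decoders train on trials of one modality only;
modality-agnostic decoders train jointly on image and caption trials, each
row targeting its own stimulus's features. The regression target provider
may itself be of either modality or multimodal.

:class:`RidgeDecoder` follows scikit-learn estimator conventions
(``fit``/``predict``/``get_params``; fitted attributes end in ``_``) and
composes with sklearn model selection. ``fit_ridge`` is the bare closed
form used internally and by the searchlight's Gram-submatrix fast path.
"""

from __future__ import annotations

import warnings

import h5py
import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigurationError, DataIntegrityError, FormatError
from .features import FeatureMatrix, standardize_columns
from .synthetic import BrainResponses

__all__ = [
    "RidgeDecoder",
    "fit_ridge",
    "select_alpha",
    "fit_modality_specific",
    "fit_modality_agnostic",
    "predict",
    "save_decoder",
    "load_decoder",
]

DEFAULT_ALPHA_GRID = tuple(float(a) for a in np.logspace(-2, 6, 9))


def _solve_centered(xc: np.ndarray, yc: np.ndarray, alpha: float) -> np.ndarray:
    """Ridge weights on centered data; exact primal/dual closed form."""
    n, p = xc.shape
    if alpha < 0:
        raise ConfigurationError("alpha must be >= 0")
    if alpha == 0:
        w, _, rank, _ = np.linalg.lstsq(xc, yc, rcond=None)
        if rank < min(n - 1, p):  # centering itself removes one dimension
            warnings.warn(
                "alpha=0 with rank-deficient design: using pseudoinverse",
                RuntimeWarning,
                stacklevel=3,
            )
        return w
    if p <= n:
        g = xc.T @ xc
        g.flat[:: p + 1] += alpha
        return linalg.solve(g, xc.T @ yc, assume_a="pos")
    k = xc @ xc.T
    k.flat[:: n + 1] += alpha
    return xc.T @ linalg.solve(k, yc, assume_a="pos")


def fit_ridge(X, Y, alpha: float) -> "RidgeDecoder":
    """Fit the bare ridge map (no input standardization).

    Returns a fitted :class:`RidgeDecoder` whose ``weights_`` equal the
    normal-equations solution ``(Xc'Xc + alpha I)^-1 Xc'Yc`` on centered
    data, with ``intercept_ = mean(Y) - mean(X) @ W``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise DataIntegrityError("X and Y must have the same number of rows")
    if X.shape[0] < 2:
        raise DataIntegrityError("ridge fit needs >= 2 trials")
    est = RidgeDecoder(alpha=alpha, standardize=False)
    est._fit_arrays(X, Y)
    return est


class RidgeDecoder(BaseEstimator, RegressorMixin):
    """Multi-output ridge from vertex betas to an embedding space.

    Parameters
    ----------
    alpha : float or "cv"
        Ridge penalty. ``"cv"`` selects from ``alpha_grid`` by k-fold
        cross-validated pairwise identification accuracy on the training
        split (ties break to the smallest alpha).
    alpha_grid : sequence of float, optional
        Candidate penalties for ``alpha="cv"``; defaults to a logarithmic
        grid 1e-2 … 1e6.
    n_folds : int
        Folds for alpha selection.
    standardize : bool
        Column-standardize inputs using training statistics (ddof=1;
        constant columns pass through centered). The same transform is
        applied at prediction time.
    random_state : int, optional
        Seed for the cross-validation fold shuffle.
    provider_name : str, optional
        Provenance tag of the target feature space.

    Attributes
    ----------
    weights_ : (n_vertices, dim) ndarray
    intercept_ : (dim,) ndarray
    alpha_ : float — penalty actually used.
    training_modalities_ : frozenset of str
    x_mean_, x_sd_ : input standardization statistics (if enabled).
    vertex_subset_ : optional vertex ids this decoder was restricted to.
    """

    def __init__(
        self,
        alpha: float | str = 10.0,
        alpha_grid=None,
        n_folds: int = 5,
        standardize: bool = True,
        random_state: int | None = None,
        provider_name: str | None = None,
    ):
        self.alpha = alpha
        self.alpha_grid = alpha_grid
        self.n_folds = n_folds
        self.standardize = standardize
        self.random_state = random_state
        self.provider_name = provider_name

    # -- fitting ---------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.shape[0] != Y.shape[0]:
            raise DataIntegrityError("X and Y must have the same number of rows")
        if X.shape[0] < 2:
            raise DataIntegrityError("ridge fit needs >= 2 trials")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
            raise DataIntegrityError("non-finite values in training data")
        if self.standardize:
            self.x_mean_ = X.mean(axis=0)
            sd = X.std(axis=0, ddof=1)
            self.x_sd_ = np.where(sd > 0, sd, 1.0)
            X = (X - self.x_mean_) / self.x_sd_
        if self.alpha == "cv":
            grid = self.alpha_grid or DEFAULT_ALPHA_GRID
            self.alpha_ = select_alpha(
                X, Y, grid, n_folds=self.n_folds, seed=self.random_state
            )
        else:
            if not np.isscalar(self.alpha) or self.alpha < 0:
                raise ConfigurationError("alpha must be >= 0 or 'cv'")
            self.alpha_ = float(self.alpha)
        self._fit_arrays(X, Y, skip_standardize=True)
        return self

    def _fit_arrays(self, X, Y, skip_standardize: bool = False):
        if self.standardize and not skip_standardize:  # pragma: no cover
            raise RuntimeError("internal: standardize before _fit_arrays")
        if not hasattr(self, "alpha_"):
            self.alpha_ = float(self.alpha)
        xm, ym = X.mean(axis=0), Y.mean(axis=0)
        w = _solve_centered(X - xm, Y - ym, self.alpha_)
        self.weights_ = w
        self.intercept_ = ym - xm @ w
        self.n_features_in_ = X.shape[1]
        if not hasattr(self, "training_modalities_"):
            self.training_modalities_ = frozenset()
        if not hasattr(self, "vertex_subset_"):
            self.vertex_subset_ = None
        return self

    # -- prediction ------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.weights_.shape[0]:
            raise DataIntegrityError(
                f"X has {X.shape[-1] if X.ndim == 2 else '?'} columns, "
                f"decoder expects {self.weights_.shape[0]}"
            )
        if self.standardize:
            X = (X - self.x_mean_) / self.x_sd_
        return X @ self.weights_ + self.intercept_


def select_alpha(X, Y, alpha_grid, n_folds: int = 5, seed: int | None = None) -> float:
    """Pick the grid alpha maximizing mean held-out pairwise accuracy.

    Folds are a seeded shuffled k-fold over trials; held-out predictions are
    scored by pairwise identification against the held-out targets. Ties
    (within 1e-12) resolve to the smallest alpha.
    """
    from .evaluation import cosine_similarity_matrix, pairwise_accuracy

    grid = sorted(float(a) for a in alpha_grid)
    if not grid:
        raise ConfigurationError("alpha grid must be nonempty")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] < n_folds:
        raise ConfigurationError("fewer trials than folds")
    if n_folds < 2:
        raise ConfigurationError("n_folds must be >= 2")
    if len(grid) == 1:
        return grid[0]
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.zeros(len(grid))
    for tr, va in kf.split(X):
        for i, alpha in enumerate(grid):
            est = fit_ridge(X[tr], Y[tr], alpha)
            pred = est.predict(X[va])
            sim = cosine_similarity_matrix(
                standardize_columns(pred), Y[va], true_index=np.arange(len(va))
            )
            scores[i] += pairwise_accuracy(sim)
    best = np.max(scores)
    for alpha, s in zip(grid, scores):
        if s >= best - 1e-12:
            return alpha
    raise AssertionError("unreachable")


def _training_block(
    responses: BrainResponses, features: FeatureMatrix, modalities: tuple[str, ...]
):
    tab = responses.trial_table
    rows_list = []
    for mod in modalities:
        rows = responses.rows(modality=mod, split="train")
        if rows.size == 0:
            raise DataIntegrityError(f"no training trials for modality {mod!r}")
        sids = tab["stimulus_id"].to_numpy()[rows]
        if len(np.unique(sids)) != len(sids):
            raise DataIntegrityError(
                f"duplicate training trials within modality {mod!r}"
            )
        rows_list.append(rows)
    rows = np.concatenate(rows_list)
    X = responses.betas[rows]
    Y = features.select(tab["stimulus_id"].to_numpy()[rows])
    return X, Y


def fit_modality_specific(
    responses: BrainResponses,
    features: FeatureMatrix,
    modality: str,
    **estimator_kwargs,
) -> RidgeDecoder:
    """Train on trials of one modality; targets may be any provider."""
    if modality not in ("image", "caption"):
        raise ConfigurationError("modality must be 'image' or 'caption'")
    X, Y = _training_block(responses, features, (modality,))
    est = RidgeDecoder(provider_name=features.provider_name, **estimator_kwargs)
    est.fit(X, Y)
    est.training_modalities_ = frozenset({modality})
    return est


def fit_modality_agnostic(
    responses: BrainResponses, features: FeatureMatrix, **estimator_kwargs
) -> RidgeDecoder:
    """Train jointly on image and caption trials (one row per trial)."""
    X, Y = _training_block(responses, features, ("image", "caption"))
    est = RidgeDecoder(provider_name=features.provider_name, **estimator_kwargs)
    est.fit(X, Y)
    est.training_modalities_ = frozenset({"image", "caption"})
    return est


def predict(decoder: RidgeDecoder, X) -> np.ndarray:
    """Functional alias for ``decoder.predict(X)``."""
    return decoder.predict(X)


def save_decoder(decoder: RidgeDecoder, path, extra_attrs: dict | None = None) -> None:
    check_is_fitted(decoder, "weights_")
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=decoder.weights_)
        f.create_dataset("intercept", data=decoder.intercept_)
        if decoder.standardize:
            f.create_dataset("x_mean", data=decoder.x_mean_)
            f.create_dataset("x_sd", data=decoder.x_sd_)
        f.attrs["alpha"] = decoder.alpha_
        f.attrs["standardize"] = decoder.standardize
        f.attrs["provider_name"] = decoder.provider_name or ""
        f.attrs["training_modalities"] = ",".join(sorted(decoder.training_modalities_))
        for k, v in (extra_attrs or {}).items():
            f.attrs[k] = v


def load_decoder(path) -> RidgeDecoder:
    with h5py.File(path, "r") as f:
        for key in ("weights", "intercept"):
            if key not in f:
                raise FormatError(f"decoder file missing dataset {key!r}")
        est = RidgeDecoder(
            alpha=float(f.attrs["alpha"]),
            standardize=bool(f.attrs["standardize"]),
            provider_name=str(f.attrs["provider_name"]) or None,
        )
        est.alpha_ = float(f.attrs["alpha"])
        est.weights_ = f["weights"][()]
        est.intercept_ = f["intercept"][()]
        est.n_features_in_ = est.weights_.shape[0]
        if est.standardize:
            est.x_mean_ = f["x_mean"][()]
            est.x_sd_ = f["x_sd"][()]
        mods = str(f.attrs["training_modalities"])
        est.training_modalities_ = frozenset(m for m in mods.split(",") if m)
        est.vertex_subset_ = None
        return est
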