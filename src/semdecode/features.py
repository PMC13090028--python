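"""Per-stimulus embedding targets.

Decoders are trained to predict stimulus embeddings ("features") extracted
by a provider. Providers are tagged by modality source — ``vision`` (image
encoders), ``language`` (text encoders) or ``multimodal`` (joint encoders).
Only the synthetic provider ships; real network extraction sits behind the
same :class:`FeatureMatrix` surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .errors import DataIntegrityError, FormatError

__all__ = [
    "FeatureMatrix",
    "standardize_columns",
    "combine_multimodal",
    "save_features",
    "load_features",
]

MODALITY_SOURCES = ("vision", "language", "multimodal")


@dataclass
class FeatureMatrix:
    """Embedding targets: one row per stimulus, one column per feature dim."""

    provider_name: str
    modality_source: str
    values: np.ndarray
    stimulus_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.stimulus_ids = np.asarray(self.stimulus_ids)
        if self.modality_source not in MODALITY_SOURCES:
            raise DataIntegrityError(
                f"modality_source must be one of {MODALITY_SOURCES}"
            )
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise DataIntegrityError("values must be 2-D with dim >= 1")
        if self.stimulus_ids.shape != (self.values.shape[0],):
            raise DataIntegrityError("one stimulus id per row required")
        if len(np.unique(self.stimulus_ids)) != len(self.stimulus_ids):
            raise DataIntegrityError("stimulus ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise DataIntegrityError("feature values must be finite")

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def select(self, stimulus_ids) -> np.ndarray:
        """Rows for the requested stimuli, in the requested order."""
        index = {int(s): i for i, s in enumerate(self.stimulus_ids)}
        try:
            rows = [index[int(s)] for s in stimulus_ids]
        except KeyError as exc:  # pragma: no cover - message formatting
            raise DataIntegrityError(
                f"no features for stimulus {exc.args[0]} "
                f"(provider {self.provider_name!r})"
            ) from None
        return self.values[rows]


def standardize_columns(m, ddof: int = 1):
    """Center each column to mean 0 and scale to standard deviation 1.

    Uses the unbiased sample convention (``ddof=1``). Constant columns are
    mapped to all zeros instead of raising, so degenerate feature dimensions
    cannot poison downstream cosine evaluation. Accepts a plain array or a
    :class:`FeatureMatrix` (returned as a new ``FeatureMatrix``).
    """
    if isinstance(m, FeatureMatrix):
        return FeatureMatrix(
            m.provider_name,
            m.modality_source,
            standardize_columns(m.values, ddof=ddof),
            m.stimulus_ids.copy(),
        )
    x = np.asarray(m, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise DataIntegrityError("standardize_columns needs >= 2 rows")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=ddof)
    out = x - mean
    nonconst = sd > 0
    out[:, nonconst] /= sd[nonconst]
    out[:, ~nonconst] = 0.0
    return out


def combine_multimodal(
    vision: FeatureMatrix, language: FeatureMatrix, mode: str = "concat"
) -> FeatureMatrix:
    """Fuse unimodal feature spaces into a multimodal one.

    ``concat`` stacks the two spaces side by side; ``mean`` averages them
    after aligning rows by stimulus id (requires equal dims). Rows are
    aligned by stimulus id, so input row order is irrelevant.
    """
    ids_v = set(int(s) for s in vision.stimulus_ids)
    ids_l = set(int(s) for s in language.stimulus_ids)
    if ids_v != ids_l:
        raise DataIntegrityError("vision and language stimulus sets differ")
    lang_vals = language.select(vision.stimulus_ids)
    if mode == "concat":
        values = np.hstack([vision.values, lang_vals])
    elif mode == "mean":
        if vision.dim != language.dim:
            raise DataIntegrityError("mean fusion requires equal dims")
        values = 0.5 * (vision.values + lang_vals)
    else:
        raise DataIntegrityError(f"unknown fusion mode {mode!r}")
    return FeatureMatrix(
        provider_name=f"{vision.provider_name}+{language.provider_name}",
        modality_source="multimodal",
        values=values,
        stimulus_ids=vision.stimulus_ids.copy(),
    )


def save_features(m: FeatureMatrix, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=m.values)
        f.create_dataset("stimulus_ids", data=np.asarray(m.stimulus_ids, dtype=np.int64))
        f.attrs["provider_name"] = m.provider_name
        f.attrs["modality_source"] = m.modality_source
        f.attrs["dim"] = m.dim


def load_features(path) -> FeatureMatrix:
    with h5py.File(path, "r") as f:
        for key in ("provider_name", "modality_source", "dim"):
            if key not in f.attrs:
                raise FormatError(f"feature file missing attribute {key!r}")
        values = f["values"][()]
        if int(f.attrs["dim"]) != values.shape[1]:
            raise FormatError(
                f"dim attribute {int(f.attrs['dim'])} does not match "
                f"values shape {values.shape}"
            )
        return FeatureMatrix(
            provider_name=str(f.attrs["provider_name"]),
            modality_source=str(f.attrs["modality_source"]),
            values=values,
            stimulus_ids=f["stimulus_ids"][()],
        )
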