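"""Run configuration: YAML schema with strict validation.

Unknown keys are rejected with a close-match suggestion; the seed is
mandatory; every field has a desk-scale default so a minimal config is
just ``seed: 0``.
"""

from __future__ import annotations

import difflib
from pathlib import Path
from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import ConfigurationError

__all__ = ["RunConfig", "load_config", "dump_config", "parse_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulationSection(_Strict):
    n_subjects: int = 6
    n_vertices: int = 900
    topology: Literal["grid", "icosphere"] = "grid"
    n_train_images: int = 400
    n_train_captions: int = 400
    n_test_pairs: int = 70
    latent_dim: int = 16
    feature_dims: dict[str, int] = {"vision": 64, "language": 64, "multimodal": 64}
    modality_specific_weight: Union[float, dict[str, float]] = 0.5
    region_size: int = 60
    noise_sd: float = 1.0
    imagery_noise_factor: float = 2.0


class DecodingSection(_Strict):
    alpha: Union[float, Literal["cv"]] = 10.0
    alpha_grid: Optional[list[float]] = None
    n_folds: int = 5
    standardize: bool = True
    providers: list[str] = ["vision", "language", "multimodal"]


class EvaluationSection(_Strict):
    n_boot: int = 2000
    ci_level: float = 0.95
    imagery_modes: list[Literal["three_only", "extended"]] = [
        "three_only",
        "extended",
    ]


class SearchlightSection(_Strict):
    k_neighbors: int = 25
    provider: str = "multimodal"
    alpha: float = 10.0
    include_imagery: bool = True
    tfce_h: float = 2.0
    tfce_e: float = 1.0
    tfce_dh: Optional[float] = None


class PermutationSection(_Strict):
    n_per_subject_nulls: int = 30
    n_group_permutations: int = 500
    unique: bool = True


class RunConfig(_Strict):
    seed: int
    out_dir: Optional[str] = None
    simulation: SimulationSection = SimulationSection()
    decoding: DecodingSection = DecodingSection()
    evaluation: EvaluationSection = EvaluationSection()
    searchlight: SearchlightSection = SearchlightSection()
    permutation: PermutationSection = PermutationSection()


_SECTION_FIELDS = {
    "": list(RunConfig.model_fields),
    "simulation": list(SimulationSection.model_fields),
    "decoding": list(DecodingSection.model_fields),
    "evaluation": list(EvaluationSection.model_fields),
    "searchlight": list(SearchlightSection.model_fields),
    "permutation": list(PermutationSection.model_fields),
}


def _explain(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = [str(x) for x in err["loc"]]
        if err["type"] == "extra_forbidden":
            key = loc[-1]
            section = loc[-2] if len(loc) > 1 else ""
            candidates = _SECTION_FIELDS.get(section, [])
            close = difflib.get_close_matches(key, candidates, n=1)
            hint = f" (did you mean {close[0]!r}?)" if close else ""
            lines.append(f"unknown key {'.'.join(loc)!r}{hint}")
        elif err["type"] == "missing":
            lines.append(f"missing required key {'.'.join(loc)!r}")
        else:
            lines.append(f"invalid value at {'.'.join(loc)!r}: {err['msg']}")
    return "; ".join(lines)


def parse_config(data: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(data or {})
    except ValidationError as exc:
        raise ConfigurationError(_explain(exc)) from None


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file {path} does not exist")
    data = yaml.safe_load(path.read_text())
    if data is not None and not isinstance(data, dict):
        raise ConfigurationError("config must be a YAML mapping")
    return parse_config(data)


def dump_config(config: RunConfig) -> str:
    return yaml.safe_dump(config.model_dump(), sort_keys=True)
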