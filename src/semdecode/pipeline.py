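"""End-to-end orchestration: simulate -> decode -> evaluate -> searchlight
-> report.

Stages communicate through files in the output directory, so each stage
can be re-run on its own; a single root seed spawns per-stage child seeds
deterministically, and every artifact carries the run's config hash.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import decoders as dec
from . import evaluation as ev
from .config import RunConfig, dump_config
from .errors import StageError
from .io import (
    check_hash,
    config_hash,
    load_dataset,
    save_dataset,
    write_graph_csv,
    write_provenance,
    write_statmap_csv,
)
from .searchlight import (
    PERCEPTION_CONDITIONS,
    PermutationConfig,
    SearchlightConfig,
    TFCEParams,
    searchlight_analysis,
)
from .synthetic import Dataset, simulate_dataset

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("simulate", "decode", "evaluate", "searchlight", "report")
log = logging.getLogger("semdecode")


def _stage_seed(root_seed: int, stage: str) -> int:
    idx = STAGES.index(stage)
    child = np.random.SeedSequence(root_seed).spawn(len(STAGES))[idx]
    return int(child.generate_state(1)[0] % (2**31))


def _decoder_path(out: Path, subject: str, provider: str, role: str) -> Path:
    return out / "decoders" / f"{subject}_{provider}_{role}.h5"


def _stage_simulate(cfg: RunConfig, out: Path, run_hash: str) -> Dataset:
    ds = simulate_dataset(
        **cfg.simulation.model_dump(), seed=_stage_seed(cfg.seed, "simulate")
    )
    save_dataset(ds, out / "dataset.h5", run_hash)
    write_graph_csv(ds.graph, out)
    ds.stimuli.trials.to_csv(out / "trials.csv", index=False)
    pd.DataFrame(
        {
            "vertex": np.arange(ds.graph.n_vertices),
            "region": next(iter(ds.truths.values())).region_labels,
        }
    ).to_csv(out / "region_labels.csv", index=False)
    return ds


def _load_ds(out: Path, run_hash: str) -> Dataset:
    ds = load_dataset(out / "dataset.h5")
    check_hash(ds.params.get("config_hash", ""), run_hash, "dataset.h5")
    return ds


def _stage_decode(cfg: RunConfig, out: Path, run_hash: str, ds: Dataset) -> dict:
    (out / "decoders").mkdir(exist_ok=True)
    seed = _stage_seed(cfg.seed, "decode")
    d = cfg.decoding
    kwargs = dict(
        alpha=d.alpha,
        alpha_grid=d.alpha_grid,
        n_folds=d.n_folds,
        standardize=d.standardize,
        random_state=seed,
    )
    fitted: dict = {}
    for sub, resp in ds.responses.items():
        fitted[sub] = {}
        for provider in d.providers:
            fm = ds.features[provider]
            trio = {
                "image": dec.fit_modality_specific(resp, fm, "image", **kwargs),
                "caption": dec.fit_modality_specific(resp, fm, "caption", **kwargs),
                "agnostic": dec.fit_modality_agnostic(resp, fm, **kwargs),
            }
            fitted[sub][provider] = trio
            for role, est in trio.items():
                dec.save_decoder(
                    est,
                    _decoder_path(out, sub, provider, role),
                    extra_attrs={"config_hash": run_hash, "subject": sub},
                )
    return fitted


def _load_decoders(cfg: RunConfig, out: Path, ds: Dataset) -> dict:
    fitted: dict = {}
    for sub in ds.responses:
        fitted[sub] = {}
        for provider in cfg.decoding.providers:
            trio = {}
            for role in ("image", "caption", "agnostic"):
                path = _decoder_path(out, sub, provider, role)
                if not path.exists():
                    raise StageError(
                        f"decoder file {path} missing; run the decode stage first"
                    )
                trio[role] = dec.load_decoder(path)
            fitted[sub][provider] = trio
    return fitted


def _stage_evaluate(
    cfg: RunConfig, out: Path, run_hash: str, ds: Dataset, fitted: dict
) -> pd.DataFrame:
    seed = _stage_seed(cfg.seed, "evaluate")
    rows = []
    for sub, resp in ds.responses.items():
        test_rows = resp.rows(split="test")
        imagery_rows = resp.rows(split="imagery")
        keep = np.concatenate([test_rows, imagery_rows])
        test_resp = type(resp)(
            sub, resp.betas[keep], resp.trial_table.iloc[keep].reset_index(drop=True)
        )
        for provider, trio in fitted[sub].items():
            results = ev.evaluate_decoders(test_resp, trio, ds.features[provider])
            for mode in cfg.evaluation.imagery_modes:
                res = ev.evaluate_imagery(
                    test_resp, trio["agnostic"], ds.features[provider], ds.stimuli, mode
                )
                res.metric = f"imagery_{mode}"
                results.append(res)
            for r in results:
                rows.append(
                    dict(
                        subject=sub,
                        provider=provider,
                        metric=r.metric,
                        accuracy=r.accuracy,
                        n_queries=r.n_queries,
                    )
                )
    frame = pd.DataFrame(rows)
    cis = []
    for (provider, metric), grp in frame.groupby(["provider", "metric"]):
        if len(grp) >= 2:
            lo, hi = ev.bootstrap_ci(
                grp["accuracy"].to_numpy(),
                n_boot=cfg.evaluation.n_boot,
                level=cfg.evaluation.ci_level,
                seed=seed,
            )
        else:
            lo = hi = float(grp["accuracy"].iloc[0])
        cis.append(dict(provider=provider, metric=metric, ci_low=lo, ci_high=hi))
    frame = frame.merge(pd.DataFrame(cis), on=["provider", "metric"])
    frame.to_csv(out / "results.csv", index=False)
    return frame


def _stage_searchlight(cfg: RunConfig, out: Path, run_hash: str, ds: Dataset) -> dict:
    seed = _stage_seed(cfg.seed, "searchlight")
    s = cfg.searchlight
    sl_cfg = SearchlightConfig(
        k_neighbors=s.k_neighbors,
        provider=s.provider,
        alpha=s.alpha,
        include_imagery=s.include_imagery,
        seed=seed,
    )
    tfce_params = TFCEParams(h=s.tfce_h, e=s.tfce_e, dh=s.tfce_dh)
    perm = PermutationConfig(
        n_per_subject_nulls=cfg.permutation.n_per_subject_nulls,
        n_group_permutations=cfg.permutation.n_group_permutations,
        unique=cfg.permutation.unique,
        seed=seed,
    )
    result = searchlight_analysis(
        ds.responses, ds.features[s.provider], ds.graph, sl_cfg, tfce_params, perm
    )
    maps = {
        f"mean_acc_{c}": result["accuracy"].condition(c).mean(axis=0)
        for c in result["accuracy"].conditions
    }
    for c in PERCEPTION_CONDITIONS:
        maps[f"t_{c}"] = result["t_maps"][c].values
    maps["min_t"] = result["min_t"].values
    maps["tfce"] = result["tfce"].values
    maps["p"] = result["p_values"].values
    if "imagery_tfce" in result:
        maps["imagery_t"] = result["imagery_t"].values
        maps["imagery_tfce"] = result["imagery_tfce"].values
    write_statmap_csv(maps, out / "searchlight_maps.csv")
    pd.DataFrame({"max_tfce": result["null_maxima"]}).to_csv(
        out / "null_maxima.csv", index=False
    )
    return result


def _stage_report(cfg: RunConfig, out: Path, run_hash: str) -> dict:
    results_path = out / "results.csv"
    maps_path = out / "searchlight_maps.csv"
    if not results_path.exists() or not maps_path.exists():
        raise StageError("report needs results.csv and searchlight_maps.csv")
    frame = pd.read_csv(results_path)
    maps = pd.read_csv(maps_path)
    nulls = pd.read_csv(out / "null_maxima.csv")["max_tfce"].to_numpy()
    summary = {
        "mean_accuracy": {
            metric: float(grp["accuracy"].mean())
            for metric, grp in frame.groupby("metric")
        },
        "n_vertices_p_lt_05": int((maps["p"] < 0.05).sum()),
        "max_tfce_observed": float(maps["tfce"].max()),
        "null_max_tfce_q95": float(np.quantile(nulls, 0.95)),
    }
    if "imagery_tfce" in maps:
        a, b = maps["tfce"].to_numpy(), maps["imagery_tfce"].to_numpy()
        if np.ptp(a) > 0 and np.ptp(b) > 0:
            summary["imagery_conjunction_r"] = float(np.corrcoef(a, b)[0, 1])
    (out / "report.json").write_text(json.dumps(summary, indent=2))
    return summary


def run_pipeline(
    config: RunConfig, out_dir=None, stages: tuple[str, ...] | None = None
) -> Path:
    """Run the requested stages (default: all) into the output directory."""
    stages = tuple(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise StageError(f"unknown stages {sorted(unknown)}")
    out = Path(out_dir or config.out_dir or "semdecode_out")
    out.mkdir(parents=True, exist_ok=True)
    run_hash = config_hash(dump_config(config))
    (out / "config_echo.yaml").write_text(dump_config(config))

    ds = fitted = None
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        log.info("stage %s starting (seed %d)", stage, _stage_seed(config.seed, stage))
        if stage == "simulate":
            ds = _stage_simulate(config, out, run_hash)
        elif stage == "decode":
            ds = ds or _load_ds(out, run_hash)
            fitted = _stage_decode(config, out, run_hash, ds)
        elif stage == "evaluate":
            ds = ds or _load_ds(out, run_hash)
            fitted = fitted or _load_decoders(config, out, ds)
            _stage_evaluate(config, out, run_hash, ds, fitted)
        elif stage == "searchlight":
            ds = ds or _load_ds(out, run_hash)
            _stage_searchlight(config, out, run_hash, ds)
        elif stage == "report":
            _stage_report(config, out, run_hash)
        write_provenance(
            out,
            stage,
            run_hash,
            config.seed,
            extra={"wall_time_s": round(time.perf_counter() - t0, 3)},
        )
    return out
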