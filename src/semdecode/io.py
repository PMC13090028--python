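"""On-disk formats: HDF5 datasets, CSV tables, GIFTI maps, provenance.

Every artifact written by the pipeline carries the run's config hash so
that stages refuse to mix files from different runs. CSV dialect is fixed
(UTF-8, comma, header row, '.' decimal) to avoid locale drift.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError, StageError
from .features import FeatureMatrix
from .surface import SurfaceGraph
from .synthetic import BrainResponses, Dataset, GroundTruth, StimulusSet

__all__ = [
    "config_hash",
    "save_dataset",
    "load_dataset",
    "write_graph_csv",
    "write_statmap_csv",
    "save_gifti_map",
    "write_provenance",
    "check_hash",
]


def config_hash(config_text: str) -> str:
    return hashlib.sha256(config_text.encode("utf-8")).hexdigest()[:16]


def _write_str_array(group, name, values) -> None:
    group.create_dataset(name, data=np.asarray(values, dtype="S32"))


def _read_str_array(group, name) -> np.ndarray:
    return np.array([s.decode() for s in group[name][()]])


def save_dataset(ds: Dataset, path, run_hash: str = "") -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["config_hash"] = run_hash
        f.attrs["params"] = json.dumps(ds.params)
        g = f.create_group("graph")
        g.create_dataset("coords", data=ds.graph.coords)
        g.create_dataset("edges", data=ds.graph.edges)
        s = f.create_group("stimuli")
        s.create_dataset("stimulus_ids", data=np.asarray(ds.stimuli.stimulus_ids))
        s.create_dataset("latents", data=ds.stimuli.latents)
        s.create_dataset("imagery_ids", data=np.asarray(ds.stimuli.imagery_ids))
        s.create_dataset(
            "trial_stimulus_id", data=ds.stimuli.trials["stimulus_id"].to_numpy()
        )
        _write_str_array(s, "trial_modality", ds.stimuli.trials["modality"])
        _write_str_array(s, "trial_split", ds.stimuli.trials["split"])
        feats = f.create_group("features")
        for name, fm in ds.features.items():
            fg = feats.create_group(name)
            fg.create_dataset("values", data=fm.values)
            fg.create_dataset("stimulus_ids", data=np.asarray(fm.stimulus_ids))
            fg.attrs["provider_name"] = fm.provider_name
            fg.attrs["modality_source"] = fm.modality_source
        tr = f.create_group("truth")
        any_truth = next(iter(ds.truths.values()))
        _write_str_array(tr, "region_labels", any_truth.region_labels)
        tr.attrs["latent_dim"] = any_truth.latent_dim
        tr.attrs["noise_sd"] = any_truth.noise_sd
        tr.attrs["imagery_noise_factor"] = any_truth.imagery_noise_factor
        for sub, truth in ds.truths.items():
            sg = tr.create_group(sub)
            for region, m in truth.mixing_maps.items():
                sg.create_dataset(region, data=m)
        resp = f.create_group("responses")
        for sub, r in ds.responses.items():
            rg = resp.create_group(sub)
            rg.create_dataset("betas", data=r.betas)
            rg.create_dataset(
                "trial_stimulus_id", data=r.trial_table["stimulus_id"].to_numpy()
            )
            _write_str_array(rg, "trial_modality", r.trial_table["modality"])
            _write_str_array(rg, "trial_split", r.trial_table["split"])


def _trials_frame(group, prefix="trial_") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "stimulus_id": group[f"{prefix}stimulus_id"][()],
            "modality": _read_str_array(group, f"{prefix}modality"),
            "split": _read_str_array(group, f"{prefix}split"),
        }
    )


def load_dataset(path) -> Dataset:
    path = Path(path)
    if not path.exists():
        raise StageError(f"dataset file {path} does not exist; run simulate first")
    with h5py.File(path, "r") as f:
        for key in ("graph", "stimuli", "features", "truth", "responses"):
            if key not in f:
                raise FormatError(f"dataset file missing group {key!r}")
        graph = SurfaceGraph(f["graph/coords"][()], f["graph/edges"][()])
        s = f["stimuli"]
        stimuli = StimulusSet(
            s["stimulus_ids"][()],
            s["latents"][()],
            _trials_frame(s),
            s["imagery_ids"][()],
        )
        features = {}
        for name, fg in f["features"].items():
            features[name] = FeatureMatrix(
                str(fg.attrs["provider_name"]),
                str(fg.attrs["modality_source"]),
                fg["values"][()],
                fg["stimulus_ids"][()],
            )
        tr = f["truth"]
        labels = _read_str_array(tr, "region_labels")
        truths, responses = {}, {}
        for sub in f["responses"]:
            truths[sub] = GroundTruth(
                labels,
                int(tr.attrs["latent_dim"]),
                {region: tr[sub][region][()] for region in tr[sub]},
                float(tr.attrs["noise_sd"]),
                float(tr.attrs["imagery_noise_factor"]),
            )
            rg = f["responses"][sub]
            responses[sub] = BrainResponses(sub, rg["betas"][()], _trials_frame(rg))
        params = json.loads(f.attrs.get("params", "{}"))
        ds = Dataset(graph, stimuli, features, truths, responses, params)
        ds.params["config_hash"] = str(f.attrs.get("config_hash", ""))
        return ds


def write_graph_csv(graph: SurfaceGraph, out_dir) -> None:
    out_dir = Path(out_dir)
    cols = ["x", "y", "z"][: graph.coords.shape[1]]
    pd.DataFrame(graph.coords, columns=cols).assign(
        vertex_id=graph.vertex_ids
    ).to_csv(out_dir / "graph_coords.csv", index=False)
    pd.DataFrame(graph.edges, columns=["v0", "v1"]).to_csv(
        out_dir / "graph_edges.csv", index=False
    )


def write_statmap_csv(maps: dict[str, np.ndarray], path) -> None:
    frame = pd.DataFrame({"vertex": np.arange(len(next(iter(maps.values()))))})
    for name, values in maps.items():
        frame[name] = np.asarray(values)
    frame.to_csv(path, index=False)


def save_gifti_map(values: np.ndarray, path) -> None:
    """Export a per-vertex scalar map as a GIFTI functional file."""
    import nibabel as nib

    da = nib.gifti.GiftiDataArray(
        np.asarray(values, dtype=np.float32), intent="NIFTI_INTENT_NONE"
    )
    nib.save(nib.gifti.GiftiImage(darrays=[da]), str(path))


def write_provenance(out_dir, stage: str, run_hash: str, seed: int, extra=None) -> None:
    out_dir = Path(out_dir)
    record = dict(stage=stage, config_hash=run_hash, seed=seed, **(extra or {}))
    path = out_dir / "provenance.json"
    existing = json.loads(path.read_text()) if path.exists() else {}
    if existing and existing.get("config_hash", run_hash) != run_hash:
        raise StageError(
            "output directory contains artifacts from a different config hash"
        )
    existing.setdefault("config_hash", run_hash)
    existing.setdefault("stages", {})
    existing["stages"][stage] = record
    path.write_text(json.dumps(existing, indent=2))


def check_hash(stored: str, current: str, what: str) -> None:
    if stored and current and stored != current:
        raise StageError(
            f"{what} was produced under config hash {stored}, "
            f"current config hash is {current}; refusing to mix runs"
        )
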