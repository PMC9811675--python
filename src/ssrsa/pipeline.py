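"""End-to-end pipeline orchestration with manifests and provenance.

Stages: simulate -> model-rdms -> map (searchlight + latency matching) ->
infer (TFCE + sign-flip correction) -> cluster-eval.  Each stage writes its
artifacts under the run directory and appends an entry (outputs, content
hashes, seed, timing) to ``manifest.json``; a failing stage halts the run
with the stage named, retaining completed outputs.  Re-running the same
config reproduces identical content hashes for deterministic artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .clustering import default_label_schemes, evaluate_all_schemes
from .latency import (
    DEFAULT_LATENCIES_MS,
    RhoMap,
    all_subject_rho_maps,
    group_mean_rho,
)
from .model_rdms import build_model_stream, timelines_to_hdf5
from .searchlight import SearchlightConfig
from .synthetic import (
    SynthConfig,
    make_conditions,
    make_layer_activations,
    make_mesh,
    make_segments,
    make_source_epochs,
)
from .tfce import group_inference

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration for a full synthetic-data pipeline run.

    Defaults mirror the analysis constants: 20 mm searchlight radius, 25 ms
    window, 10 ms step, latencies 0-250 ms in 10 ms increments, TFCE
    delta_h 0.1, corrected alpha 0.01, and 1000/5000 permutations for
    inference/clustering; every constant is overridable.  ``target_layer``
    names the layer whose model stream is planted into the synthetic
    epochs; ``map_layers`` lists the layers mapped against the brain data.
    """

    synth: SynthConfig = field(default_factory=SynthConfig)
    searchlight: SearchlightConfig = field(default_factory=SearchlightConfig)
    latencies_ms: tuple = tuple(int(k) for k in DEFAULT_LATENCIES_MS)
    n_perm_inference: int = 1000
    n_perm_clustering: int = 5000
    alpha: float = 0.01
    delta_h: float = 0.1
    inference_seed: int = 0
    target_layer: str = "L7"
    map_layers: tuple = ("L7",)
    subject_average_rdms: bool = False

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = json.load(f)
        synth = SynthConfig(**raw.pop("synth", {}))
        sl = raw.pop("searchlight", {})
        if "epoch_ms" in sl:
            sl["epoch_ms"] = tuple(sl["epoch_ms"])
        searchlight = SearchlightConfig(**sl)
        for key in ("latencies_ms", "map_layers"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(synth=synth, searchlight=searchlight, **raw)

    def to_json(self, path) -> None:
        raw = asdict(self)
        raw["synth"]["layer_dims"] = dict(self.synth.layer_dims)
        with open(path, "w") as f:
            json.dump(raw, f, indent=2, default=lambda o: list(o))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.entries: dict = {"stages": {}}

    def record(self, stage: str, out_dir: Path, outputs: list, seed, elapsed: float):
        self.entries["stages"][stage] = {
            "outputs": {
                str(p.relative_to(out_dir)): _sha256(p) for p in outputs
            },
            "seed": seed,
            "elapsed_s": round(elapsed, 3),
        }
        with open(self.path, "w") as f:
            json.dump(self.entries, f, indent=2)


def _write_rho_maps(path: Path, layer: str, maps: list) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["layer"] = layer
        for m in maps:
            g = f.create_group(f"subjects/{m.subject}")
            g.create_dataset("values", data=m.values, track_times=False)
            g.create_dataset("vertex_ids", data=m.vertex_ids, track_times=False)
            g.create_dataset("latencies_ms", data=m.latencies_ms, track_times=False)


def read_rho_maps(path) -> list:
    maps = []
    with h5py.File(path, "r") as f:
        layer = f.attrs["layer"]
        for subject, g in f["subjects"].items():
            maps.append(
                RhoMap(
                    layer=str(layer),
                    subject=subject,
                    vertex_ids=g["vertex_ids"][()],
                    latencies_ms=g["latencies_ms"][()],
                    values=g["values"][()],
                )
            )
    return sorted(maps, key=lambda m: m.subject)


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Run every stage under ``out_dir``; returns the run directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out_dir / "manifest.json")
    config.to_json(out_dir / "config.json")
    state: dict = {}

    stages = [
        ("simulate", _stage_simulate),
        ("model-rdms", _stage_model_rdms),
        ("map", _stage_map),
        ("infer", _stage_infer),
        ("cluster-eval", _stage_cluster_eval),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            outputs, seed = fn(config, out_dir, state)
        except Exception as e:
            raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e
        manifest.record(name, out_dir, outputs, seed, time.perf_counter() - t0)
    return out_dir


def _stage_simulate(config: RunConfig, out_dir: Path, state: dict):
    synth = config.synth
    mesh = make_mesh(
        synth.n_vertices_per_hemisphere, synth.mesh_radius_mm, synth.seed
    )
    conditions = make_conditions(synth)
    segments = make_segments(synth, conditions)
    activations = make_layer_activations(synth, segments, conditions=conditions)
    target_stream = build_model_stream(activations[config.target_layer])
    epochs = make_source_epochs(synth, mesh, target_stream)
    mesh_dir = out_dir / "mesh"
    mesh.to_tsv(mesh_dir)
    segments.to_tsv(out_dir / "segments.tsv")
    timelines_to_hdf5(out_dir / "activations.h5", activations)
    epochs.to_hdf5(out_dir / "epochs.h5")
    state.update(
        mesh=mesh, segments=segments, activations=activations, epochs=epochs
    )
    outputs = [
        mesh_dir / "vertices.tsv",
        mesh_dir / "edges.tsv",
        out_dir / "segments.tsv",
        out_dir / "activations.h5",
        out_dir / "epochs.h5",
    ]
    return outputs, synth.seed


def _stage_model_rdms(config: RunConfig, out_dir: Path, state: dict):
    streams = {
        layer: build_model_stream(tl) for layer, tl in state["activations"].items()
    }
    path = out_dir / "model_rdms.h5"
    with h5py.File(path, "w") as f:
        for layer, stream in streams.items():
            stream.to_hdf5(f.create_group(f"layers/{layer}"))
    state["streams"] = streams
    return [path], config.synth.seed


def _stage_map(config: RunConfig, out_dir: Path, state: dict):
    lats = np.asarray(config.latencies_ms, dtype=float)
    outputs = []
    state["rho_maps"] = {}
    for layer in config.map_layers:
        maps = all_subject_rho_maps(
            state["streams"][layer],
            state["epochs"],
            state["mesh"],
            config.searchlight,
            latencies_ms=lats,
            layer=layer,
        )
        path = out_dir / f"rho_maps_{layer}.h5"
        _write_rho_maps(path, layer, maps)
        state["rho_maps"][layer] = maps
        outputs.append(path)
        mean_rho = group_mean_rho(maps)
        vi, ki = np.unravel_index(np.argmax(mean_rho), mean_rho.shape)
        summary = pd.DataFrame(
            {
                "layer": [layer],
                "peak_vertex": [int(state["mesh"].ids[vi])],
                "peak_latency_ms": [float(lats[ki])],
                "peak_mean_rho": [float(mean_rho[vi, ki])],
            }
        )
        spath = out_dir / f"rho_summary_{layer}.tsv"
        summary.to_csv(spath, sep="\t", index=False)
        outputs.append(spath)
    return outputs, config.synth.seed


def _stage_infer(config: RunConfig, out_dir: Path, state: dict):
    outputs = []
    state["inference"] = {}
    for layer, maps in state["rho_maps"].items():
        result = group_inference(
            maps,
            state["mesh"],
            n_perm=config.n_perm_inference,
            alpha=config.alpha,
            seed=config.inference_seed,
            delta_h=config.delta_h,
        )
        state["inference"][layer] = result
        rows = []
        for cl in result.report.clusters:
            rows.append(
                {
                    "layer": layer,
                    "hemisphere": cl.hemisphere,
                    "extent": cl.extent,
                    "peak_tfce": cl.peak_value,
                    "peak_latency_ms": cl.peak_latency_ms,
                    "vertices": ";".join(
                        str(v) for v in sorted({c[0] for c in cl.cells})
                    ),
                }
            )
        path = out_dir / f"clusters_{layer}.tsv"
        pd.DataFrame(
            rows,
            columns=[
                "layer",
                "hemisphere",
                "extent",
                "peak_tfce",
                "peak_latency_ms",
                "vertices",
            ],
        ).to_csv(path, sep="\t", index=False)
        outputs.append(path)
        with h5py.File(out_dir / f"inference_{layer}.h5", "w") as f:
            f.attrs["alpha"] = config.alpha
            f.attrs["n_perm"] = config.n_perm_inference
            f.attrs["seed"] = config.inference_seed
            f.attrs["max_summed_extent"] = result.report.max_summed_extent
            f.create_dataset(
                "tmap", data=result.tmap.values, track_times=False
            )
            for hemi in result.pmaps:
                g = f.create_group(hemi)
                g.create_dataset(
                    "tfce", data=result.tfce_maps[hemi].values, track_times=False
                )
                g.create_dataset("p_corrected", data=result.pmaps[hemi], track_times=False)
                g.create_dataset(
                    "null_max", data=result.nulls[hemi].values, track_times=False
                )
        outputs.append(out_dir / f"inference_{layer}.h5")
    return outputs, config.inference_seed


def _stage_cluster_eval(config: RunConfig, out_dir: Path, state: dict):
    table = evaluate_all_schemes(
        state["activations"],
        state["segments"],
        default_label_schemes(),
        n_perm=config.n_perm_clustering,
        seed=config.synth.seed,
    )
    path = out_dir / "clustering_eval.tsv"
    table.to_csv(path, sep="\t", index=False)
    return [path], config.synth.seed
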