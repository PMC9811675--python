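"""Synthetic inputs with known planted structure.

Generates everything the pipeline consumes — cortical mesh, phonetic
segmentations, layer-activation timelines, and multi-subject source-space
epochs — so every downstream stage is testable without any recorded data.

Planted structure
-----------------
*Activations*: frames within a phonetic segment are drawn around a
label-specific centroid; between-centroid distance scales with
``cluster_separation`` so the Davies-Bouldin evaluation has a controllable
effect to find.

*Source epochs*: a chosen set of effect vertices carries, at a chosen
processing latency, condition response patterns whose pairwise correlation
distances realise a target model RDM stream.  For each model frame the
pattern matrix is constructed exactly: a symmetric square root of the target
correlation matrix is mapped through an orthonormal, zero-mean feature basis,
so pattern rows have exactly the target correlations.  Pattern samples are
laid out in 5 ms blocks with a period-5 column schedule, so every 25 ms
searchlight window (10 ms step) sees a full column permutation of one
pattern matrix: when the target stream is locally constant the window RDM is
exact; when it varies, adjacent frames blend at window edges.  The planted
signal is mixed as ``effect_size * pattern + (1 - effect_size) * noise`` at
effect vertices; everywhere else is pure Gaussian noise with ``noise_sd``.
Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from ._rng import substream
from .clustering import LabelScheme, PHONE_INVENTORY, SegmentTable, default_label_schemes
from .core import ConditionSet, RDMStream
from .mesh import CorticalMesh
from .model_rdms import FeatureTimeline, reserved_frame_count
from .searchlight import SourceEpochs

__all__ = [
    "SynthConfig",
    "make_mesh",
    "default_effect_vertices",
    "make_conditions",
    "make_segments",
    "make_layer_activations",
    "make_source_epochs",
]

_DEFAULT_LAYER_DIMS = {
    "FBK": 40,
    "L2": 100,
    "L3": 100,
    "L4": 100,
    "L5": 100,
    "L6": 100,
    "L7": 26,
    "TRI": 50,
}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic dataset.

    Defaults are the desk-scale design: 40 spoken-word conditions with a
    285 ms shortest duration, 6 subjects, two 160-vertex hemispheres of
    50 mm radius, a compact 6-vertex planted effect at 70 ms latency with
    effect size 0.8 against unit noise, and eight layers mirroring the
    input / five-wide / bottleneck / output structure of the reference
    network.
    """

    n_conditions: int = 40
    condition_durations_ms: tuple | None = None
    n_subjects: int = 6
    n_vertices_per_hemisphere: int = 160
    mesh_radius_mm: float = 50.0
    effect_vertices: tuple | None = None
    planted_latency_ms: int = 70
    effect_size: float = 0.8
    noise_sd: float = 1.0
    layer_dims: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_LAYER_DIMS)
    )
    cluster_separation: float = 2.0
    seed: int = 0
    epoch_end_ms: int = 540
    step_ms: int = 10

    def __post_init__(self) -> None:
        if self.n_conditions < 3:
            raise ValueError("need at least 3 conditions")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.planted_latency_ms < 0 or self.planted_latency_ms % self.step_ms:
            raise ValueError(
                "planted latency must be a non-negative multiple of the step"
            )
        if not 0 <= self.effect_size <= 1:
            raise ValueError("effect_size must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.cluster_separation < 0:
            raise ValueError("cluster_separation must be non-negative")
        if any(d < 1 for d in self.layer_dims.values()):
            raise ValueError("all layer dims must be >= 1")
        if self.condition_durations_ms is not None:
            durations = tuple(float(d) for d in self.condition_durations_ms)
            if len(durations) != self.n_conditions:
                raise ValueError("one duration per condition required")
            if any(d <= 0 for d in durations):
                raise ValueError("durations must be positive")
            object.__setattr__(self, "condition_durations_ms", durations)
        if self.effect_vertices is not None:
            object.__setattr__(
                self, "effect_vertices", tuple(int(v) for v in self.effect_vertices)
            )


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + np.sqrt(5.0)) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def make_mesh(
    n_vertices_per_hemisphere: int, radius_mm: float, seed: int
) -> CorticalMesh:
    """Two disjoint sphere-like triangulated hemispheres.

    Vertices are Fibonacci-sphere points (given a seeded random rotation)
    scaled to ``radius_mm``; triangulation is the convex hull (the spherical
    Delaunay triangulation), so every vertex has degree >= 3 and each
    hemisphere is connected.  Hemispheres are offset along x by +/- 2 radii,
    so no edge can cross the midline.
    """
    n = int(n_vertices_per_hemisphere)
    if n < 4:
        raise ValueError("need at least 4 vertices per hemisphere to triangulate")
    rng = substream(seed, "mesh")
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    pts = _fibonacci_sphere(n) @ q.T * float(radius_mm)
    hull = ConvexHull(pts)
    tri = hull.simplices
    edges = np.unique(
        np.sort(
            np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [0, 2]]]), axis=1
        ),
        axis=0,
    )
    offset = np.array([2.0 * radius_mm, 0.0, 0.0])
    coords = np.vstack([pts - offset, pts + offset])
    ids = np.arange(2 * n)
    hemis = np.array(["L"] * n + ["R"] * n)
    all_edges = np.vstack([edges, edges + n])
    return CorticalMesh(ids=ids, hemispheres=hemis, coords=coords, edges=all_edges)


def default_effect_vertices(
    mesh: CorticalMesh, k: int = 6, hemisphere: str = "L"
) -> tuple:
    """A compact planted-effect site: a seed vertex and its k-1 nearest
    neighbours within one hemisphere."""
    rows = np.flatnonzero(mesh.hemispheres == hemisphere)
    seed_row = rows[0]
    dist = np.linalg.norm(mesh.coords[rows] - mesh.coords[seed_row], axis=1)
    nearest = rows[np.argsort(dist)[:k]]
    return tuple(int(v) for v in np.sort(mesh.ids[nearest]))


def make_conditions(config: SynthConfig) -> ConditionSet:
    """Condition set with seeded word-like durations.

    Durations are multiples of 10 ms in [285, 505); the first condition is
    pinned to 285 ms so the shortest-stimulus frame rule reserves 27 frames.
    """
    if config.condition_durations_ms is not None:
        durations = config.condition_durations_ms
    else:
        rng = substream(config.seed, "durations")
        durations = 285.0 + 10.0 * rng.integers(0, 23, size=config.n_conditions)
        durations[0] = 285.0
        durations = tuple(durations)
    width = max(3, len(str(config.n_conditions - 1)))
    ids = tuple(f"w{i:0{width}d}" for i in range(config.n_conditions))
    return ConditionSet(ids, durations)


def make_segments(
    config: SynthConfig,
    conditions: ConditionSet | None = None,
    phones: Sequence[str] = PHONE_INVENTORY,
    min_len_ms: float = 40.0,
    max_len_ms: float = 90.0,
) -> SegmentTable:
    """Random phonetic segmentation covering each condition's duration.

    Contiguous, non-overlapping segments with lengths in
    [min_len_ms, min_len_ms + max_len_ms), each long enough to contain at
    least one 25 ms frame midpoint.
    """
    if conditions is None:
        conditions = make_conditions(config)
    rng = substream(config.seed, "segments")
    phones = list(phones)
    rows = []
    for cid, dur in zip(conditions.ids, conditions.durations_ms):
        t = 0.0
        bounds = []
        while dur - t >= min_len_ms + max_len_ms:
            length = float(rng.uniform(min_len_ms, max_len_ms))
            bounds.append((t, t + length))
            t += length
        bounds.append((t, dur))
        for start, end in bounds:
            rows.append(
                {
                    "condition": cid,
                    "start_ms": start,
                    "end_ms": end,
                    "phone": phones[rng.integers(len(phones))],
                }
            )
    return SegmentTable(pd.DataFrame(rows))


def make_layer_activations(
    config: SynthConfig,
    segments: SegmentTable,
    scheme: LabelScheme | None = None,
    conditions: ConditionSet | None = None,
) -> dict:
    """Per-layer activation timelines with label-driven cluster structure.

    For each layer, one centroid is drawn per scheme label with magnitude
    proportional to ``cluster_separation``; each 10 ms frame's vector is its
    segment's label centroid plus isotropic noise of sd ``noise_sd``.  The
    frame count per condition follows the duration rule
    (floor((D - 25)/10) + 1).  Raises, naming the phone, when the scheme has
    no label for a phone in the segmentation.
    """
    if conditions is None:
        conditions = make_conditions(config)
    if scheme is None:
        scheme = default_label_schemes()["phone"]
    seg_phones = segments.phones()
    missing = [p for p in seg_phones if not scheme.applicable(p)]
    if missing:
        raise ValueError(
            f"scheme '{scheme.name}' has no label for phone '{missing[0]}'"
        )
    labels = sorted({scheme.label(p) for p in seg_phones})
    label_idx = {lab: i for i, lab in enumerate(labels)}
    out = {}
    for layer, dim in config.layer_dims.items():
        rng = substream(config.seed, "activations", layer)
        centroids = config.cluster_separation * rng.normal(
            size=(len(labels), int(dim))
        )
        frames = []
        for cid, dur in zip(conditions.ids, conditions.durations_ms):
            nf = reserved_frame_count(dur)
            mids = 10.0 * np.arange(nf) + 12.5
            seg = segments.for_condition(cid)
            starts = seg["start_ms"].to_numpy(dtype=float)
            pos = np.searchsorted(starts, mids, side="right") - 1
            pos = np.clip(pos, 0, len(seg) - 1)
            seg_labels = np.array(
                [label_idx[scheme.label(p)] for p in seg["phone"]]
            )
            X = centroids[seg_labels[pos]] + rng.normal(
                scale=config.noise_sd, size=(nf, int(dim))
            )
            frames.append(X)
        out[layer] = FeatureTimeline(
            conditions=conditions, layer_name=layer, frames=tuple(frames)
        )
    return out


def _exact_correlation_patterns(
    corr: np.ndarray, basis: np.ndarray
) -> np.ndarray:
    """Rows with exactly the given correlation matrix over the basis features.

    ``basis`` is (M, n) with orthonormal columns each orthogonal to the
    all-ones vector; the returned (n, M) matrix has zero-mean rows whose
    pairwise Pearson correlations equal ``corr`` (eigenvalues clipped at 0),
    scaled to unit per-feature variance.
    """
    c = np.asarray(corr, dtype=float)
    w, u = np.linalg.eigh((c + c.T) / 2.0)
    root = u * np.sqrt(np.clip(w, 0.0, None))
    m = basis.shape[0]
    return (root @ basis.T) * np.sqrt(m)


def make_source_epochs(
    config: SynthConfig,
    mesh: CorticalMesh,
    target_rdm_stream: RDMStream,
) -> SourceEpochs:
    """Multi-subject 1 ms source epochs with the target RDM stream planted.

    At the effect vertices, windows starting ``planted_latency_ms`` after
    model time tau realise (up to the effect_size/noise mixture and edge
    blending between adjacent frames) the target RDM at tau; all other
    vertices are pure Gaussian noise.  The planted pattern is shared across
    subjects; noise is independent per subject.
    """
    lat = int(config.planted_latency_ms)
    if lat % config.step_ms:
        raise ValueError("planted latency must be a multiple of the window step")
    times = target_rdm_stream.times_ms
    if times[0] != 0 or (len(times) > 1 and target_rdm_stream.step_ms != config.step_ms):
        raise ValueError("target stream must start at 0 on the window step grid")
    window_ms = 25
    n_times = int(config.epoch_end_ms)
    if lat + times[-1] + window_ms > n_times:
        raise ValueError(
            "planted latency plus the last target time exceeds the epoch"
        )
    conditions = target_rdm_stream.conditions
    n = conditions.n
    effect = config.effect_vertices
    if effect is None:
        effect = default_effect_vertices(mesh)
    effect = tuple(sorted(int(v) for v in effect))
    if not set(effect) <= set(int(v) for v in mesh.ids):
        raise ValueError("effect vertices must be mesh vertex ids")
    n_eff = len(effect)
    m = n_eff * window_ms
    if m < n + 1:
        raise ValueError(
            f"{n_eff} effect vertices give {m} pattern features; need at least "
            f"{n + 1} for {n} conditions (add effect vertices)"
        )
    # orthonormal zero-mean feature basis shared by all frames
    basis_rng = substream(config.seed, "epochs-basis")
    g = basis_rng.normal(size=(m, n))
    g -= g.mean(axis=0)
    basis, _ = np.linalg.qr(g)
    n_frames = target_rdm_stream.n_times
    patterns = np.empty((n_frames, n, m))
    for tau in range(n_frames):
        corr = 1.0 - target_rdm_stream.values[tau]
        patterns[tau] = _exact_correlation_patterns(corr, basis)
    noise_rng = substream(config.seed, "epochs-noise")
    # single-precision epochs: halves memory traffic downstream; the
    # searchlight statistics are insensitive at this precision
    data = noise_rng.standard_normal(
        size=(config.n_subjects, n, mesh.n_vertices, n_times), dtype=np.float32
    )
    data *= np.float32(config.noise_sd)
    effect_rows = np.array([mesh.index_of(v) for v in effect])
    # 5 ms blocks with a period-5 column schedule: every 25 ms window (10 ms
    # step) collects a full column permutation of one pattern matrix
    n_blocks = 2 * (n_frames - 1) + 5
    es = config.effect_size
    for b in range(n_blocks):
        t0 = lat + 5 * b
        if t0 >= n_times:
            break
        width = min(5, n_times - t0)
        tau = min(max((b - 1) // 2, 0), n_frames - 1)
        for j, row in enumerate(effect_rows):
            col0 = j * window_ms + (b % 5) * 5
            sig = patterns[tau][:, col0 : col0 + width]  # (n_conditions, width)
            data[:, :, row, t0 : t0 + width] = (
                es * sig[None, :, :]
                + (1.0 - es) * data[:, :, row, t0 : t0 + width]
            )
    subjects = tuple(f"s{i:02d}" for i in range(config.n_subjects))
    return SourceEpochs(
        subjects=subjects,
        conditions=conditions,
        vertex_ids=mesh.ids.copy(),
        data=data,
        meta={
            "planted_latency_ms": lat,
            "effect_vertices": list(effect),
            "effect_size": float(es),
            "noise_sd": float(config.noise_sd),
            "seed": int(config.seed),
        },
    )
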