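"""Spatiotemporal searchlight: per-vertex, per-window brain RDM streams.

Source-space recordings give, per subject, a 1 ms-resolution time series at
every cortical vertex and for every stimulus condition.  The searchlight
slides a spatial patch (all vertices within ``radius_mm`` of a centre, within
the centre's hemisphere) and a temporal window (``window_ms`` wide, stepped
by ``step_ms``) over these data.  For each (centre, window) the response
vector of a condition is the concatenation, patch-vertex-major, of the 1 ms
samples in the half-open window [t, t + window); the condition-by-condition
correlation-distance matrix of those vectors is one brain RDM frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .core import ConditionSet, RDMStream, batched_upper_corr_distance, correlation_distance_rdm
from .mesh import CorticalMesh

__all__ = [
    "SearchlightConfig",
    "SourceEpochs",
    "patch_vertices",
    "window_starts",
    "brain_rdm_stream",
]


@dataclass(frozen=True)
class SearchlightConfig:
    """Searchlight geometry: 20 mm patch, 25 ms window, 10 ms step over a
    [0, 540] ms epoch by default."""

    radius_mm: float = 20.0
    window_ms: int = 25
    step_ms: int = 10
    epoch_ms: tuple = (0, 540)

    def __post_init__(self) -> None:
        if self.radius_mm < 0:
            raise ValueError("radius_mm must be non-negative")
        if self.window_ms <= 0 or self.step_ms <= 0:
            raise ValueError("window_ms and step_ms must be positive")
        if self.epoch_ms[1] - self.epoch_ms[0] < self.window_ms:
            raise ValueError("epoch must be at least one window long")


@dataclass(frozen=True)
class SourceEpochs:
    """Per-subject source-space epochs.

    ``data`` has axis order (subject, condition, vertex, time_ms) with 1 ms
    resolution; sample t covers [t, t+1) ms from epoch onset.  ``meta`` may
    carry provenance (e.g. planted-effect parameters from the synthetic
    generator).
    """

    subjects: tuple
    conditions: ConditionSet
    vertex_ids: np.ndarray
    data: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        subjects = tuple(str(s) for s in self.subjects)
        vids = np.asarray(self.vertex_ids, dtype=int)
        d = np.asarray(self.data)
        if d.dtype != np.float32:  # keep single precision when provided
            d = d.astype(np.float64)
        if d.ndim != 4:
            raise ValueError("data must be (subject, condition, vertex, time)")
        s, c, v, _ = d.shape
        if s != len(subjects) or c != self.conditions.n or v != len(vids):
            raise ValueError("data shape inconsistent with labels")
        if not np.all(np.isfinite(d)):
            raise ValueError("epochs must be finite (no missing cells)")
        object.__setattr__(self, "subjects", subjects)
        object.__setattr__(self, "vertex_ids", vids)
        object.__setattr__(self, "data", d)

    @property
    def n_times(self) -> int:
        return self.data.shape[3]

    def subject_index(self, subject: str) -> int:
        try:
            return self.subjects.index(str(subject))
        except ValueError:
            raise ValueError(f"unknown subject {subject!r}") from None

    def vertex_rows(self, vertex_ids) -> np.ndarray:
        lookup = {int(v): i for i, v in enumerate(self.vertex_ids)}
        try:
            return np.array([lookup[int(v)] for v in vertex_ids], dtype=int)
        except KeyError as e:
            raise ValueError(f"vertex id {e.args[0]} not present in epochs") from None

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("epochs", data=self.data, track_times=False)
            ds.attrs["axis_order"] = "subject,condition,vertex,time_ms"
            f.create_dataset(
                "subjects", data=np.array(self.subjects, dtype="S"), track_times=False
            )
            f.create_dataset(
                "condition_ids",
                data=np.array(self.conditions.ids, dtype="S"),
                track_times=False,
            )
            f.create_dataset(
                "condition_durations_ms",
                data=np.array(self.conditions.durations_ms),
                track_times=False,
            )
            f.create_dataset("vertex_ids", data=self.vertex_ids, track_times=False)
            meta = f.create_group("meta")
            for k, v in self.meta.items():
                meta.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path) -> "SourceEpochs":
        with h5py.File(path, "r") as f:
            subjects = tuple(s.decode() for s in f["subjects"][()])
            ids = tuple(s.decode() for s in f["condition_ids"][()])
            durations = tuple(f["condition_durations_ms"][()])
            meta = dict(f["meta"].attrs) if "meta" in f else {}
            meta = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in meta.items()
            }
            return cls(
                subjects=subjects,
                conditions=ConditionSet(ids, durations),
                vertex_ids=f["vertex_ids"][()],
                data=f["epochs"][()],
                meta=meta,
            )


def patch_vertices(
    mesh: CorticalMesh, center: int, radius_mm: float
) -> np.ndarray:
    """Vertex ids within ``radius_mm`` (Euclidean, inclusive) of ``center``,
    restricted to the centre's hemisphere; always contains the centre.

    Euclidean 3-D distance is used rather than geodesic distance along the
    mesh: the common searchlight convention, and well-defined on any vertex
    cloud.
    """
    ci = mesh.index_of(center)
    same_hemi = mesh.hemispheres == mesh.hemispheres[ci]
    dist = np.linalg.norm(mesh.coords - mesh.coords[ci], axis=1)
    members = mesh.ids[same_hemi & (dist <= radius_mm)]
    return np.sort(members)


def window_starts(
    epoch_ms: tuple = (0, 540), window_ms: int = 25, step_ms: int = 10
) -> np.ndarray:
    """Ordered window start times t = e0, e0+step, ... with t+window <= e1."""
    e0, e1 = epoch_ms
    if e1 - e0 < window_ms:
        raise ValueError("epoch shorter than one window")
    return np.arange(e0, e1 - window_ms + 1, step_ms)


def _window_response_tensor(
    sub_data: np.ndarray, starts: np.ndarray, window_ms: int
) -> np.ndarray:
    """(n_windows, n_conditions, patch*window) response tensor from a
    (condition, patch_vertex, time) array; concatenation is vertex-major."""
    c, p, _ = sub_data.shape
    views = np.lib.stride_tricks.sliding_window_view(sub_data, window_ms, axis=2)
    sel = views[:, :, starts, :]  # (C, P, W, window)
    return sel.transpose(2, 0, 1, 3).reshape(len(starts), c, p * window_ms)


def brain_rdm_stream(
    epochs: SourceEpochs,
    mesh: CorticalMesh,
    config: SearchlightConfig,
    center: int,
    subject: str,
) -> RDMStream:
    """Brain RDM stream for one searchlight centre and one subject.

    For each window start t, the per-condition response vector concatenates
    source values over (patch vertex x ms sample in [t, t+window)); the RDM
    is the correlation-distance matrix of those vectors.  Stream times are
    the window starts.
    """
    si = epochs.subject_index(subject)
    patch = patch_vertices(mesh, center, config.radius_mm)
    rows = epochs.vertex_rows(patch)
    starts = window_starts(config.epoch_ms, config.window_ms, config.step_ms)
    if starts[-1] + config.window_ms > epochs.n_times:
        raise ValueError("epoch windows extend beyond the recorded samples")
    sub = epochs.data[si][:, rows, :]
    responses = _window_response_tensor(sub, starts, config.window_ms)
    n = epochs.conditions.n
    values = np.empty((len(starts), n, n))
    for wi, t in enumerate(starts):
        X = responses[wi]
        sd = X.std(axis=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(
                f"zero-variance response (subject={subject!r}, vertex={center}, "
                f"window={int(t)} ms, condition='{epochs.conditions.ids[bad[0]]}')"
            )
        values[wi] = correlation_distance_rdm(X, epochs.conditions).values
    return RDMStream(epochs.conditions, np.asarray(starts, dtype=float), values)


def _searchlight_upper_vectors(
    epochs: SourceEpochs,
    mesh: CorticalMesh,
    config: SearchlightConfig,
    center: int,
    subject_index: int,
) -> np.ndarray:
    """Fast path: (n_windows, n_pairs) upper-triangle RDM vectors for one
    centre/subject, identical values to :func:`brain_rdm_stream`."""
    patch = patch_vertices(mesh, center, config.radius_mm)
    rows = epochs.vertex_rows(patch)
    starts = window_starts(config.epoch_ms, config.window_ms, config.step_ms)
    sub = epochs.data[subject_index][:, rows, :]
    responses = _window_response_tensor(sub, starts, config.window_ms)
    return batched_upper_corr_distance(responses)
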