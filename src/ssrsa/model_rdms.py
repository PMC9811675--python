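"""Dynamic model RDM streams from layer-activation timelines.

A speech recogniser's acoustic front end produces one feature vector per
25 ms analysis frame, shifted in 10 ms steps; each network layer then yields
one activation vector per frame and per stimulus.  This module implements the
frame bookkeeping needed to turn those per-frame activations into a dynamic
series of model RDMs:

* delta (first-derivative) augmentation of base features (40 -> 80 dims),
* context stacking of nine consecutive frames (80 -> 720 dims) with boundary
  frames duplicated at the edges of a recording,
* the frame-reservation rule restricting analysis to frames every stimulus
  has: frame index t is kept when ``shift*t + frame <= shortest duration``
  (285 ms -> 27 frames),
* per-frame RDM construction across conditions.

The effective receptive field of a stacked-with-deltas input frame is
125 ms: nine stacked frames span 105 ms and the central-difference
derivative adds one 10 ms frame of support on each side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import h5py
import numpy as np

from .core import ConditionSet, RDMStream, correlation_distance_rdm

__all__ = [
    "FeatureTimeline",
    "append_deltas",
    "stack_context",
    "reserved_frame_count",
    "build_model_stream",
    "fbk_stream_select",
    "receptive_field_ms",
    "timelines_to_hdf5",
    "timelines_from_hdf5",
]


@dataclass(frozen=True)
class FeatureTimeline:
    """Per-condition, per-frame activation vectors for one named layer.

    ``frames[i]`` is an (n_frames_i, dim) array for condition i.  The frame
    grid is the acoustic one: frame t covers [shift*t, shift*t + frame) ms.
    ``base_dim``, ``has_deltas`` and ``context_frames`` record how the
    vectors were assembled, so the bare features can be recovered later
    (see :func:`fbk_stream_select`).
    """

    conditions: ConditionSet
    layer_name: str
    frames: tuple
    frame_ms: float = 25.0
    shift_ms: float = 10.0
    base_dim: int | None = None
    has_deltas: bool = False
    context_frames: int = 0

    def __post_init__(self) -> None:
        frames = tuple(np.asarray(f, dtype=float) for f in self.frames)
        if len(frames) != self.conditions.n:
            raise ValueError("one frame array per condition required")
        dims = {f.shape[1] for f in frames if f.ndim == 2}
        if any(f.ndim != 2 for f in frames) or len(dims) != 1:
            raise ValueError("all frame arrays must be 2-D with equal dimension")
        if any(f.shape[0] < 1 for f in frames):
            raise ValueError("every condition needs at least one frame")
        object.__setattr__(self, "frames", frames)
        if self.base_dim is None:
            object.__setattr__(self, "base_dim", frames[0].shape[1])

    @property
    def dim(self) -> int:
        return self.frames[0].shape[1]

    @property
    def frame_counts(self) -> np.ndarray:
        return np.array([f.shape[0] for f in self.frames])

    def frame_midpoints_ms(self, condition_index: int) -> np.ndarray:
        t = np.arange(self.frames[condition_index].shape[0])
        return self.shift_ms * t + self.frame_ms / 2.0


def append_deltas(timeline: FeatureTimeline) -> FeatureTimeline:
    """Extend each frame vector with its first-order time derivative.

    The derivative is the central difference ``(o[t+1] - o[t-1]) / 2`` with
    boundary neighbours duplicated, so a constant timeline has all-zero
    deltas.  Output dimension is double the input (e.g. 40 -> 80).
    """
    if timeline.has_deltas or timeline.context_frames:
        raise ValueError("deltas must be appended to a bare feature timeline")
    new_frames = []
    for cid, X in zip(timeline.conditions.ids, timeline.frames):
        if X.shape[0] < 2:
            raise ValueError(
                f"condition '{cid}' has a single frame: derivative undefined"
            )
        padded = np.vstack([X[:1], X, X[-1:]])
        delta = (padded[2:] - padded[:-2]) / 2.0
        new_frames.append(np.hstack([X, delta]))
    return replace(timeline, frames=tuple(new_frames), has_deltas=True)


def stack_context(timeline: FeatureTimeline, context: int = 4) -> FeatureTimeline:
    """Concatenate each frame with its ``context`` neighbours on either side.

    Frame t's stacked vector is the concatenation of frames t-c ... t+c with
    out-of-range indices clamped to the nearest valid frame (boundary-frame
    duplication).  Output dimension is ``(2*context + 1) * dim`` (80 -> 720
    for the standard nine-frame stack).
    """
    if context < 0:
        raise ValueError("context must be non-negative")
    if timeline.context_frames:
        raise ValueError("timeline is already context-stacked")
    new_frames = []
    for X in timeline.frames:
        n = X.shape[0]
        idx = np.clip(
            np.arange(n)[:, None] + np.arange(-context, context + 1)[None, :],
            0,
            n - 1,
        )
        new_frames.append(X[idx].reshape(n, -1))
    return replace(timeline, frames=tuple(new_frames), context_frames=context)


def fbk_stream_select(timeline: FeatureTimeline) -> FeatureTimeline:
    """Recover the bare base features (no deltas, no context stacking).

    For input-layer RDMs only the base filterbank values of the central
    frame are used; this undoes :func:`stack_context` and
    :func:`append_deltas` using the metadata they record.  A bare timeline
    is returned unchanged.
    """
    if not timeline.has_deltas and not timeline.context_frames:
        return timeline
    c = timeline.context_frames
    per_frame = timeline.dim // (2 * c + 1)
    start = c * per_frame
    base = timeline.base_dim
    new_frames = tuple(
        X[:, start : start + base] for X in timeline.frames
    )
    return replace(
        timeline, frames=new_frames, has_deltas=False, context_frames=0
    )


def reserved_frame_count(
    shortest_duration_ms: float, frame_ms: float = 25.0, shift_ms: float = 10.0
) -> int:
    """Number of frame indices shared by all stimuli.

    Counts 0-based indices t with ``shift*t + frame <= shortest_duration``:
    ``floor((D - frame)/shift) + 1``.  A 285 ms shortest word with 25 ms
    frames shifted by 10 ms reserves 27 frames.
    """
    if shortest_duration_ms < frame_ms:
        raise ValueError("shortest duration is shorter than one frame")
    return int(math.floor((shortest_duration_ms - frame_ms) / shift_ms + 1e-9)) + 1


def receptive_field_ms(
    frame_ms: float = 25.0,
    shift_ms: float = 10.0,
    context: int = 4,
    delta_support: int = 1,
) -> float:
    """Temporal extent of audio influencing one stacked-with-deltas frame.

    Nine stacked 25 ms frames at 10 ms shift span 105 ms; the central
    difference adds ``delta_support`` frames each side: 125 ms by default.
    """
    return frame_ms + shift_ms * 2 * (context + delta_support)


def build_model_stream(
    timeline: FeatureTimeline, n_frames: int | None = None
) -> RDMStream:
    """One RDM per reserved frame index, from all conditions' frame-t vectors.

    The RDM at index t is the correlation-distance matrix of the
    (n_conditions x dim) matrix of frame-t activations; stream times are
    ``shift_ms * t``.
    """
    if n_frames is None:
        n_frames = reserved_frame_count(
            min(timeline.conditions.durations_ms),
            timeline.frame_ms,
            timeline.shift_ms,
        )
    for cid, X in zip(timeline.conditions.ids, timeline.frames):
        if X.shape[0] < n_frames:
            raise ValueError(
                f"condition '{cid}' has {X.shape[0]} frames, "
                f"fewer than the {n_frames} reserved"
            )
    values = np.empty((n_frames, timeline.conditions.n, timeline.conditions.n))
    for t in range(n_frames):
        responses = np.stack([X[t] for X in timeline.frames])
        values[t] = correlation_distance_rdm(responses, timeline.conditions).values
    times = timeline.shift_ms * np.arange(n_frames)
    return RDMStream(timeline.conditions, times, values)


def timelines_to_hdf5(path, timelines: Mapping[str, FeatureTimeline]) -> None:
    """Write layer timelines to HDF5; per condition dataset axis order is
    (frame, node)."""
    with h5py.File(path, "w") as f:
        for name, tl in timelines.items():
            g = f.create_group(f"layers/{name}")
            g.attrs["frame_ms"] = tl.frame_ms
            g.attrs["shift_ms"] = tl.shift_ms
            g.attrs["base_dim"] = tl.base_dim
            g.attrs["has_deltas"] = tl.has_deltas
            g.attrs["context_frames"] = tl.context_frames
            for cid, X in zip(tl.conditions.ids, tl.frames):
                g.create_dataset(f"conditions/{cid}", data=X, track_times=False)
            g.create_dataset(
                "condition_ids",
                data=np.array(tl.conditions.ids, dtype="S"),
                track_times=False,
            )
            g.create_dataset(
                "condition_durations_ms",
                data=np.array(tl.conditions.durations_ms),
                track_times=False,
            )


def timelines_from_hdf5(path) -> dict:
    out: dict[str, FeatureTimeline] = {}
    with h5py.File(path, "r") as f:
        for name, g in f["layers"].items():
            ids = tuple(s.decode() for s in g["condition_ids"][()])
            durations = tuple(g["condition_durations_ms"][()])
            conditions = ConditionSet(ids, durations)
            frames = tuple(g[f"conditions/{cid}"][()] for cid in ids)
            out[name] = FeatureTimeline(
                conditions=conditions,
                layer_name=name,
                frames=frames,
                frame_ms=float(g.attrs["frame_ms"]),
                shift_ms=float(g.attrs["shift_ms"]),
                base_dim=int(g.attrs["base_dim"]),
                has_deltas=bool(g.attrs["has_deltas"]),
                context_frames=int(g.attrs["context_frames"]),
            )
    return out
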