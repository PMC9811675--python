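"""Latency-offset matching of model RDM streams to brain RDM streams.

Cortical responses lag the stimulus: the representation recorded at epoch
time tau + k was elicited by stimulus content at time tau, for some
processing latency k.  For a hypothesised latency k, the model RDM at each
stimulus time tau is compared (Spearman rank correlation) with the brain RDM
at epoch time tau + k, and the correlations are averaged over all alignable
window pairs — pairs where both streams have a frame; no padding is used at
stream ends.  Sweeping k over a grid (0-250 ms in 10 ms steps by default)
and all searchlight centres yields a per-subject rho-map over
(vertex, latency); subjects are combined by a one-sample t-test per cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import RDMStream, spearman_rdm
from .mesh import CorticalMesh
from .searchlight import SearchlightConfig, SourceEpochs, _searchlight_upper_vectors

__all__ = [
    "RhoMap",
    "TMap",
    "DEFAULT_LATENCIES_MS",
    "ZERO_VARIANCE_SENTINEL_T",
    "latency_rho",
    "rho_map",
    "subject_rho_map",
    "group_tmap",
    "group_mean_rho",
]

DEFAULT_LATENCIES_MS = np.arange(0, 251, 10)

# One-sample t is undefined when all subjects report the identical rho.  A
# bounded sentinel (sign of the mean) keeps downstream cluster enhancement
# defined; the cell is flagged in TMap.zero_variance.  Never reached with
# continuous noisy data.
ZERO_VARIANCE_SENTINEL_T = 100.0


@dataclass(frozen=True)
class RhoMap:
    """Per-subject map of mean Spearman rho over (vertex, latency)."""

    layer: str
    subject: str
    vertex_ids: np.ndarray
    latencies_ms: np.ndarray
    values: np.ndarray  # (n_vertices, n_latencies)

    def __post_init__(self) -> None:
        vids = np.asarray(self.vertex_ids, dtype=int)
        lats = np.asarray(self.latencies_ms, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(vids), len(lats)):
            raise ValueError("values must be (n_vertices, n_latencies)")
        if np.any(np.abs(v) > 1 + 1e-9):
            raise ValueError("rho values must lie in [-1, 1]")
        if len(lats) > 1 and not np.allclose(np.diff(lats), lats[1] - lats[0]):
            raise ValueError("latency grid must be uniform")
        object.__setattr__(self, "vertex_ids", vids)
        object.__setattr__(self, "latencies_ms", lats)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class TMap:
    """Group t-statistics over (vertex, latency) for one layer."""

    layer: str
    vertex_ids: np.ndarray
    latencies_ms: np.ndarray
    values: np.ndarray
    n_subjects: int
    zero_variance: np.ndarray = None  # cells where the sentinel was used

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("t-map must be finite after degenerate handling")
        zv = self.zero_variance
        if zv is None:
            zv = np.zeros_like(v, dtype=bool)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "zero_variance", np.asarray(zv, dtype=bool))
        object.__setattr__(self, "vertex_ids", np.asarray(self.vertex_ids, dtype=int))
        object.__setattr__(
            self, "latencies_ms", np.asarray(self.latencies_ms, dtype=float)
        )


def _aligned_indices(
    model: RDMStream, brain: RDMStream, latency_ms: float
) -> tuple[np.ndarray, np.ndarray]:
    """Indices (tau_i, w_i) with brain time == model time + latency."""
    step = brain.step_ms if brain.n_times > 1 else model.step_ms
    if np.isfinite(step):
        off = (latency_ms + model.times_ms[0] - brain.times_ms[0]) / step
        if abs(off - round(off)) > 1e-9:
            raise ValueError(
                f"latency {latency_ms} ms is not on the shared {step} ms grid"
            )
    target = model.times_ms + latency_ms
    bi = np.searchsorted(brain.times_ms, target)
    ok = (bi < brain.n_times) & np.isclose(
        brain.times_ms[np.clip(bi, 0, brain.n_times - 1)], target
    )
    return np.flatnonzero(ok), bi[ok]


def latency_rho(model: RDMStream, brain: RDMStream, latency_ms: float) -> float:
    """Mean Spearman rho between model[tau] and brain[tau + latency] over all
    alignable pairs; raises when no pair aligns."""
    mi, bi = _aligned_indices(model, brain, latency_ms)
    if len(mi) == 0:
        raise ValueError(f"no alignable window pairs at latency {latency_ms} ms")
    rhos = [
        spearman_rdm(model.frame(int(m)), brain.frame(int(b)))
        for m, b in zip(mi, bi)
    ]
    return float(np.mean(rhos))


def rho_map(
    model: RDMStream,
    brain_streams: Mapping[int, RDMStream],
    latencies_ms: Sequence[float] = DEFAULT_LATENCIES_MS,
    layer: str = "",
    subject: str = "",
) -> RhoMap:
    """One rho per (vertex, latency) from per-vertex brain RDM streams."""
    vids = np.array(sorted(brain_streams.keys()), dtype=int)
    lats = np.asarray(latencies_ms, dtype=float)
    values = np.empty((len(vids), len(lats)))
    for vi, v in enumerate(vids):
        for ki, k in enumerate(lats):
            values[vi, ki] = latency_rho(model, brain_streams[v], k)
    return RhoMap(layer, subject, vids, lats, values)


def _rank_zscore(vectors: np.ndarray) -> np.ndarray:
    """Average-rank transform each row, then z-score; Pearson of two such
    rows equals Spearman rho of the originals."""
    ranks = stats.rankdata(vectors, axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("constant RDM vector: Spearman undefined")
    return ranks / norms


def subject_rho_map(
    model: RDMStream,
    epochs: SourceEpochs,
    mesh: CorticalMesh,
    config: SearchlightConfig,
    subject: str,
    latencies_ms: Sequence[float] = DEFAULT_LATENCIES_MS,
    layer: str = "",
) -> RhoMap:
    """Full-mesh rho-map for one subject, computed directly from epochs.

    Numerically identical to running :func:`ssrsa.searchlight.brain_rdm_stream`
    at every centre and calling :func:`rho_map`, but evaluated with batched
    rank correlations.
    """
    lats = np.asarray(latencies_ms, dtype=float)
    step = float(config.step_ms)
    offs = lats / step
    if np.any(np.abs(offs - np.round(offs)) > 1e-9):
        raise ValueError("latencies must be multiples of the window step")
    offs = np.round(offs).astype(int)
    si = epochs.subject_index(subject)
    mz = _rank_zscore(model.upper_vectors())
    n_model = mz.shape[0]
    if model.n_times > 1 and abs(model.step_ms - step) > 1e-9:
        raise ValueError("model stream step must equal the searchlight step")
    values = np.empty((mesh.n_vertices, len(lats)))
    for vi, v in enumerate(mesh.ids):
        bu = _searchlight_upper_vectors(epochs, mesh, config, int(v), si)
        bz = _rank_zscore(bu)
        corr = mz @ bz.T  # (n_model, n_windows)
        n_windows = bz.shape[0]
        for ki, off in enumerate(offs):
            taus = np.arange(n_model)
            valid = taus + off < n_windows
            if not np.any(valid):
                raise ValueError(
                    f"no alignable window pairs at latency {lats[ki]} ms"
                )
            values[vi, ki] = corr[taus[valid], taus[valid] + off].mean()
    values = np.clip(values, -1.0, 1.0)
    return RhoMap(layer, str(subject), mesh.ids.copy(), lats, values)


def _rank_zscore_batch(vectors: np.ndarray) -> np.ndarray:
    """Batched :func:`_rank_zscore`.

    When a row has no tied values its average ranks are a permutation of
    1..D, whose mean and norm are constants, so one argsort suffices; rows
    with ties fall back to the average-rank path.
    """
    a = np.asarray(vectors)
    n_rows, d = a.shape
    order = np.argsort(a, axis=1)
    sorted_a = np.take_along_axis(a, order, axis=1)
    tied_rows = np.any(sorted_a[:, 1:] == sorted_a[:, :-1], axis=1)
    ranks = np.empty(a.shape, dtype=np.float64)
    np.put_along_axis(
        ranks, order, np.broadcast_to(np.arange(1.0, d + 1.0), (n_rows, d)), axis=1
    )
    if np.any(tied_rows):
        ranks[tied_rows] = stats.rankdata(a[tied_rows], axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", ranks, ranks))[:, None]
    if np.any(norms == 0):
        raise ValueError("constant RDM vector: Spearman undefined")
    return ranks / norms


def all_subject_rho_maps(
    model: RDMStream,
    epochs: SourceEpochs,
    mesh: CorticalMesh,
    config: SearchlightConfig,
    latencies_ms: Sequence[float] = DEFAULT_LATENCIES_MS,
    layer: str = "",
) -> list:
    """Rho-maps for every subject, sharing searchlight work across patches.

    Neighbouring searchlight patches overlap heavily, so the per-window
    condition cross-products and sums are precomputed once per vertex and
    summed over each patch; the patch correlation matrix then follows from
    those sufficient statistics.  Agrees with :func:`subject_rho_map` (which
    recomputes each patch from scratch) to floating-point accuracy.
    """
    from .searchlight import patch_vertices, window_starts

    lats = np.asarray(latencies_ms, dtype=float)
    step = float(config.step_ms)
    offs = lats / step
    if np.any(np.abs(offs - np.round(offs)) > 1e-9):
        raise ValueError("latencies must be multiples of the window step")
    offs = np.round(offs).astype(int)
    if model.n_times > 1 and abs(model.step_ms - step) > 1e-9:
        raise ValueError("model stream step must equal the searchlight step")
    mz = _rank_zscore(model.upper_vectors())
    n_model = mz.shape[0]
    starts = window_starts(config.epoch_ms, config.window_ms, config.step_ms)
    w = int(config.window_ms)
    n_windows = len(starts)
    if np.any(np.asarray(offs) + 1 > n_windows):
        raise ValueError("latency grid extends beyond the epoch windows")
    patch_rows = [
        epochs.vertex_rows(patch_vertices(mesh, int(v), config.radius_mm))
        for v in mesh.ids
    ]
    iu = np.triu_indices(epochs.conditions.n, k=1)
    taus = np.arange(n_model)
    nv = mesh.n_vertices
    n_pairs = len(iu[0])
    maps = []
    for si, subject in enumerate(epochs.subjects):
        data = epochs.data[si]  # (C, V, T)
        dtype = data.dtype if data.dtype == np.float32 else np.float64
        views = np.lib.stride_tricks.sliding_window_view(data, w, axis=2)
        A = np.ascontiguousarray(
            views[:, :, starts, :].transpose(1, 2, 0, 3), dtype=dtype
        )  # (V, W, C, w)
        G = A @ A.transpose(0, 1, 3, 2)  # per-vertex window cross-products
        S = A.sum(axis=3)  # (V, W, C)
        uppers = np.empty((nv, n_windows, n_pairs), dtype=dtype)
        for vi in range(nv):
            rows = patch_rows[vi]
            gp = G[rows].sum(axis=0)  # (W, C, C)
            sp = S[rows].sum(axis=0)  # (W, C)
            f = len(rows) * w
            cov = gp - sp[:, :, None] * sp[:, None, :] / f
            var = np.einsum("wcc->wc", cov)
            denom = np.sqrt(var[:, :, None] * var[:, None, :])
            if np.any(denom == 0):
                raise ValueError(
                    f"zero-variance response (subject={subject!r}, "
                    f"vertex={int(mesh.ids[vi])})"
                )
            uppers[vi] = np.clip(1.0 - cov / denom, 0.0, 2.0)[:, iu[0], iu[1]]
        del A, G, S, views
        bz = _rank_zscore_batch(uppers.reshape(nv * n_windows, n_pairs))
        corr = (bz @ mz.T).reshape(nv, n_windows, n_model)
        values = np.empty((nv, len(lats)))
        for ki, off in enumerate(offs):
            valid = taus + off < n_windows
            values[:, ki] = corr[:, taus[valid] + off, taus[valid]].mean(axis=1)
        maps.append(
            RhoMap(
                layer,
                str(subject),
                mesh.ids.copy(),
                lats,
                np.clip(values, -1.0, 1.0),
            )
        )
    return maps


def _one_sample_t(
    total: np.ndarray, total_sq: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """t = mean / (sd / sqrt(n)) with an n-1 denominator, from per-cell sums
    and sums of squares; returns (t, zero_variance_mask)."""
    mean = total / n
    var = (total_sq - n * mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    sd = np.sqrt(var)
    zero = sd == 0
    t = np.zeros_like(mean)
    nz = ~zero
    t[nz] = mean[nz] / (sd[nz] / np.sqrt(n))
    t[zero] = np.sign(mean[zero]) * ZERO_VARIANCE_SENTINEL_T
    return t, zero


def group_tmap(rho_maps: Sequence[RhoMap], layer: str | None = None) -> TMap:
    """One-sample t of rho across subjects at each (vertex, latency).

    Cells where every subject reports the same rho get the signed sentinel
    ``ZERO_VARIANCE_SENTINEL_T`` and are flagged in ``zero_variance``.
    """
    if len(rho_maps) < 2:
        raise ValueError("group t-map needs at least 2 subjects")
    first = rho_maps[0]
    for m in rho_maps[1:]:
        if not (
            np.array_equal(m.vertex_ids, first.vertex_ids)
            and np.array_equal(m.latencies_ms, first.latencies_ms)
        ):
            raise ValueError("rho-maps must share one (vertex, latency) grid")
    stack = np.stack([m.values for m in rho_maps])
    t, zero = _one_sample_t(stack.sum(axis=0), (stack**2).sum(axis=0), len(rho_maps))
    return TMap(
        layer=layer if layer is not None else first.layer,
        vertex_ids=first.vertex_ids.copy(),
        latencies_ms=first.latencies_ms.copy(),
        values=t,
        n_subjects=len(rho_maps),
        zero_variance=zero,
    )


def group_mean_rho(rho_maps: Sequence[RhoMap]) -> np.ndarray:
    """Cross-subject mean rho per (vertex, latency)."""
    if not rho_maps:
        raise ValueError("empty rho-map list")
    return np.mean([m.values for m in rho_maps], axis=0)
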