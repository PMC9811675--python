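"""Threshold-free cluster enhancement and map-maximum sign-flip inference.

A spatiotemporal t-map lives on a grid of (vertex, latency) cells.  Cells are
connected when they share a mesh edge at the same latency, or the same vertex
at adjacent latencies (no diagonal links).  TFCE replaces each positive
t-value by a weighted sum of the clustered support beneath it,

    TFCE(t_cell) = sum over thresholds h = i*dh <= t_cell of h^2 * e(h),

where e(h) is the extent (cell count) of the connected component containing
the cell among cells with value >= h.  The sum is evaluated literally on the
h = i*dh grid with dh = 0.1; the omitted Riemann factor dh is a uniform
monotone scale that cannot change maxima or permutation p-values.  Negative
t-values receive an enhancement of 0 (the hypothesis is one-sided: positive
model-brain correlation).

Family-wise-corrected p-values come from a map-maximum sign-flip
randomization: under the null, each subject's rho-map is symmetric about
zero, so flipping the sign of whole subject maps (one flip per subject per
permutation, shared across all cells and both hemispheres) simulates null
t-maps.  The maximum TFCE value per hemisphere from each permutation forms a
per-hemisphere null distribution; a cell's corrected p is
(1 + #{null maxima > observed}) / n_permutations, clamped to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numba import njit
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .latency import RhoMap, TMap, _one_sample_t, group_tmap
from .mesh import CorticalMesh

__all__ = [
    "SpatioTemporalGraph",
    "TfceMap",
    "NullDistribution",
    "ClusterInfo",
    "ClusterReport",
    "build_st_graph",
    "cluster_extent",
    "tfce_transform",
    "isocontour_check",
    "signflip_null",
    "corrected_pmap",
    "threshold_and_report",
    "group_inference",
    "InferenceResult",
]


@dataclass(frozen=True)
class SpatioTemporalGraph:
    """Connectivity over (vertex, latency) cells for one vertex subset.

    Cell (vi, ki) maps to flat node index ``vi * n_latencies + ki``.  Edges:
    mesh adjacency at equal latency plus same-vertex links between
    consecutive latencies.
    """

    vertex_ids: np.ndarray
    n_latencies: int
    adjacency: sparse.csr_matrix

    @property
    def n_cells(self) -> int:
        return len(self.vertex_ids) * self.n_latencies

    def flat_index(self, vertex_row: int, latency_index: int) -> int:
        return vertex_row * self.n_latencies + latency_index


def build_st_graph(
    mesh: CorticalMesh, n_latencies: int, hemisphere: str | None = None
) -> SpatioTemporalGraph:
    """Build the spatiotemporal grid graph, optionally for one hemisphere."""
    if hemisphere is None:
        keep = np.arange(mesh.n_vertices)
    else:
        keep = np.flatnonzero(mesh.hemispheres == hemisphere)
    vids = mesh.ids[keep]
    nv, nl = len(keep), int(n_latencies)
    spatial = mesh.adjacency_matrix()[keep][:, keep]
    time_adj = sparse.diags([1, 1], [-1, 1], shape=(nl, nl), dtype=bool)
    eye_l = sparse.identity(nl, dtype=bool)
    eye_v = sparse.identity(nv, dtype=bool)
    adj = sparse.kron(spatial, eye_l) + sparse.kron(eye_v, time_adj)
    return SpatioTemporalGraph(vids, nl, adj.tocsr())


@dataclass(frozen=True)
class TfceMap:
    """Enhanced values over (vertex, latency); zero where t < smallest
    positive threshold."""

    values: np.ndarray
    delta_h: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0):
            raise ValueError("TFCE values must be non-negative")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class NullDistribution:
    """Map-maximum null values for one hemisphere, one per permutation."""

    hemisphere: str
    values: np.ndarray
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if len(v) != self.n_permutations:
            raise ValueError("need one map maximum per permutation")
        object.__setattr__(self, "values", v)

    def sorted(self) -> np.ndarray:
        return np.sort(self.values)


def _component_sizes(
    adjacency: sparse.csr_matrix, active: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Component label per active cell and size per label, for the subgraph
    of ``active`` (boolean mask) cells."""
    idx = np.flatnonzero(active)
    sub = adjacency[idx][:, idx]
    _, labels = connected_components(sub, directed=False)
    sizes = np.bincount(labels)
    return labels, sizes


def cluster_extent(
    values: np.ndarray,
    threshold: float,
    graph: SpatioTemporalGraph,
    cell: tuple,
) -> int:
    """Extent (cell count) of the connected component of ``cell`` among cells
    with value >= threshold; 0 if the cell itself is below threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    flat = np.asarray(values, dtype=float).ravel()
    ci = graph.flat_index(*cell)
    if flat[ci] < threshold:
        return 0
    active = flat >= threshold
    labels, sizes = _component_sizes(graph.adjacency, active)
    pos = np.searchsorted(np.flatnonzero(active), ci)
    return int(sizes[labels[pos]])


@njit(cache=True)
def _tfce_kernel(t, indptr, indices, delta_h, i_max):  # pragma: no cover
    """Union-find evaluation of the thresholded-extent sum.

    Thresholds h = i*delta_h are visited in descending order; cells activate
    as h drops below their value and merge with active neighbours, so the
    component of every active cell at each threshold is its union-find root.
    Per-cell terms accumulate in descending-threshold order.
    """
    n = t.size
    out = np.zeros(n, dtype=np.float64)
    order = np.argsort(t)[::-1]
    parent = np.full(n, -1, dtype=np.int64)
    size = np.ones(n, dtype=np.int64)
    ptr = 0
    for i in range(i_max, 0, -1):
        h = i * delta_h
        while ptr < n and t[order[ptr]] >= h:
            c = order[ptr]
            parent[c] = c
            for k in range(indptr[c], indptr[c + 1]):
                nb = indices[k]
                if parent[nb] >= 0:
                    ra = c
                    while parent[ra] != ra:
                        ra = parent[ra]
                    rb = nb
                    while parent[rb] != rb:
                        rb = parent[rb]
                    if ra != rb:
                        if size[ra] < size[rb]:
                            ra, rb = rb, ra
                        parent[rb] = ra
                        size[ra] += size[rb]
            ptr += 1
        hh = h * h
        for j in range(ptr):
            c = order[j]
            r = c
            while parent[r] != r:
                r = parent[r]
            while parent[c] != r:  # path compression
                nxt = parent[c]
                parent[c] = r
                c = nxt
            out[order[j]] += hh * size[r]
    return out


def tfce_transform(
    values: np.ndarray, graph: SpatioTemporalGraph, delta_h: float = 0.1
) -> TfceMap:
    """Apply the h^2-weighted cluster enhancement on the i*delta_h grid.

    The value at each cell is ``sum_{i>=1, i*dh <= t} (i*dh)^2 * e(i*dh)``
    (the i = 0 term vanishes), with per-cell terms accumulated from the
    highest threshold downwards.
    """
    if delta_h <= 0:
        raise ValueError("delta_h must be positive")
    arr = np.asarray(values, dtype=np.float64)
    t = np.maximum(arr.ravel(), 0.0)
    tmax = t.max() if t.size else 0.0
    i_max = int(tmax / delta_h) + 1
    while i_max > 0 and i_max * delta_h > tmax:
        i_max -= 1
    if i_max == 0:
        return TfceMap(np.zeros_like(arr), delta_h)
    adj = graph.adjacency
    out = _tfce_kernel(
        t,
        adj.indptr.astype(np.int64),
        adj.indices.astype(np.int64),
        float(delta_h),
        i_max,
    )
    return TfceMap(out.reshape(arr.shape), delta_h)


def isocontour_check(
    values: np.ndarray, enhanced: np.ndarray, graph: SpatioTemporalGraph
) -> bool:
    """Verify the enhancement preserved the map's local ordering.

    True iff (a) no adjacent pair of cells is strictly reordered — there is
    no edge (u, v) with t_u < t_v but enhanced_u > enhanced_v — and (b) every
    weak local maximum of the positive part of the original map is a weak
    local maximum of the enhanced map.  Both hold for a genuine TFCE
    transform, which is monotone along edges; locations of local maxima, and
    hence isocontour shapes, are therefore unchanged.
    """
    t = np.asarray(values, dtype=float).ravel()
    e = np.asarray(enhanced, dtype=float).ravel()
    if t.shape != e.shape:
        raise ValueError("maps must share one grid")
    coo = graph.adjacency.tocoo()
    rows, cols = coo.row, coo.col
    if np.any((t[rows] - t[cols]) * (e[rows] - e[cols]) < 0):
        return False
    neigh_max_t = np.full(t.shape, -np.inf)
    neigh_max_e = np.full(t.shape, -np.inf)
    np.maximum.at(neigh_max_t, rows, t[cols])
    np.maximum.at(neigh_max_e, rows, e[cols])
    local_max = (t > 0) & (t >= neigh_max_t)
    return bool(np.all(e[local_max] >= neigh_max_e[local_max]))


def _hemisphere_stacks(
    rho_maps: Sequence[RhoMap], mesh: CorticalMesh
) -> dict:
    """Split per-subject rho-maps by hemisphere -> (S, Vh, L) stacks."""
    stack = np.stack([m.values for m in rho_maps])
    out = {}
    for hemi in ("L", "R"):
        keep = np.flatnonzero(mesh.hemispheres == hemi)
        if keep.size:
            out[hemi] = stack[:, keep, :]
    return out


def signflip_null(
    rho_maps: Sequence[RhoMap],
    mesh: CorticalMesh,
    n_perm: int = 1000,
    seed: int = 0,
    delta_h: float = 0.1,
    rng: np.random.Generator | None = None,
) -> dict:
    """Per-hemisphere map-maximum null distributions under sign flipping.

    Each permutation draws one independent +/-1 per subject (shared across
    all cells and hemispheres, preserving within-subject spatial covariance),
    recomputes the group t-map, enhances it, and records each hemisphere's
    map maximum.  Deterministic given ``seed``.
    """
    if len(rho_maps) < 2:
        raise ValueError("sign-flip null needs at least 2 subjects")
    n_subjects = len(rho_maps)
    n_lat = len(rho_maps[0].latencies_ms)
    if rng is None:
        rng = np.random.default_rng(seed)
    flips = rng.choice(np.array([-1.0, 1.0]), size=(n_perm, n_subjects))
    stacks = _hemisphere_stacks(rho_maps, mesh)
    graphs = {h: build_st_graph(mesh, n_lat, h) for h in stacks}
    maxima = {h: np.empty(n_perm) for h in stacks}
    for hemi, stack in stacks.items():
        flat = stack.reshape(n_subjects, -1)
        total_sq = (flat**2).sum(axis=0)  # invariant under sign flips
        graph = graphs[hemi]
        shape = stack.shape[1:]
        for p in range(n_perm):
            total = flips[p] @ flat
            t, _ = _one_sample_t(total, total_sq, n_subjects)
            enhanced = tfce_transform(t.reshape(shape), graph, delta_h)
            maxima[hemi][p] = enhanced.values.max()
    return {
        hemi: NullDistribution(hemi, maxima[hemi], n_perm, seed) for hemi in stacks
    }


def corrected_pmap(
    observed_tfce: TfceMap | np.ndarray, null: NullDistribution
) -> np.ndarray:
    """Corrected p per cell: (1 + #{null maxima > observed}) / n_perm,
    clamped to <= 1 (strictly-greater counting)."""
    obs = observed_tfce.values if isinstance(observed_tfce, TfceMap) else observed_tfce
    obs = np.asarray(obs, dtype=float)
    if null.n_permutations == 0:
        raise ValueError("empty null distribution")
    srt = null.sorted()
    greater = null.n_permutations - np.searchsorted(srt, obs, side="right")
    p = (1.0 + greater) / null.n_permutations
    return np.minimum(p, 1.0)


@dataclass(frozen=True)
class ClusterInfo:
    hemisphere: str
    cells: tuple  # ((vertex_id, latency_ms), ...)
    extent: int
    peak_value: float
    peak_latency_ms: float


@dataclass(frozen=True)
class ClusterReport:
    """Suprathreshold connected components and the summed-extent summary.

    ``max_summed_extent`` is the maximum over latencies of the total
    suprathreshold extent at that latency, summing spatially discontinuous
    clusters.
    """

    alpha: float
    clusters: tuple
    extent_by_latency: np.ndarray
    max_summed_extent: int

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def threshold_and_report(
    pmaps: Mapping[str, np.ndarray],
    tfce_maps: Mapping[str, TfceMap],
    graphs: Mapping[str, SpatioTemporalGraph],
    latencies_ms: np.ndarray,
    alpha: float = 0.01,
) -> ClusterReport:
    """Group cells at corrected p < alpha into connected components.

    Inputs are keyed by hemisphere; extents are counted per component, and
    the per-latency totals (summing clusters and hemispheres) give the
    maximum summed extent.
    """
    latencies_ms = np.asarray(latencies_ms, dtype=float)
    clusters = []
    extent_by_latency = np.zeros(len(latencies_ms), dtype=int)
    for hemi, pmap in pmaps.items():
        graph = graphs[hemi]
        tf = tfce_maps[hemi].values
        mask = np.asarray(pmap) < alpha
        flat_mask = mask.ravel()
        if not flat_mask.any():
            continue
        labels, sizes = _component_sizes(graph.adjacency, flat_mask)
        idx = np.flatnonzero(flat_mask)
        nl = graph.n_latencies
        for lab in range(len(sizes)):
            members = idx[labels == lab]
            v_rows = members // nl
            k_idx = members % nl
            vals = tf.ravel()[members]
            peak = int(np.argmax(vals))
            clusters.append(
                ClusterInfo(
                    hemisphere=hemi,
                    cells=tuple(
                        (int(graph.vertex_ids[vr]), float(latencies_ms[ki]))
                        for vr, ki in zip(v_rows, k_idx)
                    ),
                    extent=int(sizes[lab]),
                    peak_value=float(vals[peak]),
                    peak_latency_ms=float(latencies_ms[k_idx[peak]]),
                )
            )
        extent_by_latency += np.bincount(
            idx % nl, minlength=len(latencies_ms)
        )
    return ClusterReport(
        alpha=alpha,
        clusters=tuple(clusters),
        extent_by_latency=extent_by_latency,
        max_summed_extent=int(extent_by_latency.max()) if len(latencies_ms) else 0,
    )


@dataclass(frozen=True)
class InferenceResult:
    """Everything produced by one group inference for one layer."""

    tmap: TMap
    tfce_maps: dict  # hemisphere -> TfceMap
    nulls: dict  # hemisphere -> NullDistribution
    pmaps: dict  # hemisphere -> (Vh, L) corrected p array
    report: ClusterReport
    graphs: dict

    def min_p(self) -> float:
        return float(min(p.min() for p in self.pmaps.values()))


def group_inference(
    rho_maps: Sequence[RhoMap],
    mesh: CorticalMesh,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    delta_h: float = 0.1,
) -> InferenceResult:
    """Observed t-map, TFCE, per-hemisphere nulls, corrected p and clusters.

    Each hemisphere's observed TFCE map is compared against its own
    map-maximum null distribution.
    """
    tmap = group_tmap(rho_maps)
    n_lat = len(tmap.latencies_ms)
    stacks = _hemisphere_stacks(rho_maps, mesh)
    graphs = {h: build_st_graph(mesh, n_lat, h) for h in stacks}
    tfce_maps = {}
    for hemi, graph in graphs.items():
        keep = np.flatnonzero(mesh.hemispheres == hemi)
        tfce_maps[hemi] = tfce_transform(tmap.values[keep], graph, delta_h)
    nulls = signflip_null(rho_maps, mesh, n_perm=n_perm, seed=seed, delta_h=delta_h)
    pmaps = {h: corrected_pmap(tfce_maps[h], nulls[h]) for h in graphs}
    report = threshold_and_report(pmaps, tfce_maps, graphs, tmap.latencies_ms, alpha)
    return InferenceResult(tmap, tfce_maps, nulls, pmaps, report, graphs)
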