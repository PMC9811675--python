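"""Cortical mesh container: vertex coordinates, hemisphere tags, adjacency.

The mesh is the spatial domain of the searchlight (patch membership by
Euclidean distance in mm) and of the spatiotemporal connectivity used by
cluster enhancement.  Hemispheres are disjoint components: no adjacency edge
crosses the midline, and per-hemisphere analyses (null distributions, cluster
reports) partition the vertex set by the hemisphere tag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = ["CorticalMesh"]


@dataclass(frozen=True)
class CorticalMesh:
    """Vertices with mm coordinates, "L"/"R" hemisphere tags and undirected
    adjacency edges."""

    ids: np.ndarray  # (N,) int vertex ids
    hemispheres: np.ndarray  # (N,) "L" or "R"
    coords: np.ndarray  # (N, 3) mm
    edges: np.ndarray  # (E, 2) int vertex-id pairs, undirected

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=int)
        hemis = np.asarray(self.hemispheres, dtype="U1")
        coords = np.asarray(self.coords, dtype=float)
        edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        n = len(ids)
        if len(np.unique(ids)) != n:
            raise ValueError("vertex ids must be unique")
        if hemis.shape != (n,) or not np.all(np.isin(hemis, ["L", "R"])):
            raise ValueError("hemisphere tags must be 'L' or 'R' per vertex")
        if coords.shape != (n, 3) or not np.all(np.isfinite(coords)):
            raise ValueError("coords must be finite (N, 3)")
        if np.any(edges[:, 0] == edges[:, 1]):
            raise ValueError("self-edges are not allowed")
        index = {int(v): i for i, v in enumerate(ids)}
        if not np.all(np.isin(edges, ids)):
            raise ValueError("edge endpoints must be mesh vertex ids")
        rows = np.array([index[int(a)] for a in edges[:, 0]], dtype=int)
        cols = np.array([index[int(b)] for b in edges[:, 1]], dtype=int)
        if np.any(hemis[rows] != hemis[cols]):
            raise ValueError("adjacency must not cross hemispheres")
        # canonical undirected edge list: sorted pairs, unique
        canon = np.sort(np.stack([edges[:, 0], edges[:, 1]], axis=1), axis=1)
        canon = np.unique(canon, axis=0)
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "hemispheres", hemis)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "edges", canon)
        object.__setattr__(self, "_index", index)

    @property
    def n_vertices(self) -> int:
        return len(self.ids)

    def index_of(self, vertex_id: int) -> int:
        try:
            return self._index[int(vertex_id)]
        except KeyError:
            raise ValueError(f"unknown vertex id {vertex_id!r}") from None

    def hemisphere_ids(self, hemisphere: str) -> np.ndarray:
        return self.ids[self.hemispheres == hemisphere]

    def adjacency_matrix(self) -> sparse.csr_matrix:
        """Symmetric boolean CSR adjacency over vertex row indices."""
        rows = np.array([self._index[int(a)] for a in self.edges[:, 0]])
        cols = np.array([self._index[int(b)] for b in self.edges[:, 1]])
        n = self.n_vertices
        data = np.ones(len(rows), dtype=bool)
        a = sparse.coo_matrix((data, (rows, cols)), shape=(n, n))
        return (a + a.T).tocsr()

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency_matrix().sum(axis=1)).ravel()

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, directory) -> None:
        """Write vertices.tsv (id, hemisphere, x_mm, y_mm, z_mm) and
        edges.tsv (id_a, id_b)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "id": self.ids,
                "hemisphere": self.hemispheres,
                "x_mm": self.coords[:, 0],
                "y_mm": self.coords[:, 1],
                "z_mm": self.coords[:, 2],
            }
        ).to_csv(directory / "vertices.tsv", sep="\t", index=False)
        pd.DataFrame({"id_a": self.edges[:, 0], "id_b": self.edges[:, 1]}).to_csv(
            directory / "edges.tsv", sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, directory) -> "CorticalMesh":
        directory = Path(directory)
        v = pd.read_csv(directory / "vertices.tsv", sep="\t")
        e = pd.read_csv(directory / "edges.tsv", sep="\t")
        return cls(
            ids=v["id"].to_numpy(),
            hemispheres=v["hemisphere"].to_numpy(),
            coords=v[["x_mm", "y_mm", "z_mm"]].to_numpy(),
            edges=e[["id_a", "id_b"]].to_numpy(),
        )
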