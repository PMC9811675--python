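"""Core representational-dissimilarity objects and comparisons.

A representational dissimilarity matrix (RDM) summarises how differently a
system (a network layer, or a patch of cortex) responds to a set of stimulus
conditions: entry (i, j) is the Pearson correlation distance ``1 - r`` between
the response vectors to conditions i and j.  RDMs abstract away from the
response format, so an RDM from a 26-node network layer can be compared
directly with an RDM from a 150-dimensional cortical response pattern; the
comparison used throughout this package is Spearman's rank correlation of the
two upper triangles.

An :class:`RDMStream` is a time-indexed series of RDMs over one shared
condition set, used both for model timelines (one RDM per activation frame)
and for data timelines (one RDM per sliding searchlight window).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConditionSet",
    "RDM",
    "RDMStream",
    "correlation_distance_rdm",
    "vectorize_upper",
    "rdm_from_upper",
    "spearman_rdm",
    "average_rdms",
    "corr_distance_matrix",
    "batched_upper_corr_distance",
]

_ATOL = 1e-8


@dataclass(frozen=True)
class ConditionSet:
    """Ordered experimental conditions with their stimulus durations (ms)."""

    ids: tuple
    durations_ms: tuple

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.ids)
        durations = tuple(float(d) for d in self.durations_ms)
        if len(ids) != len(durations):
            raise ValueError("ids and durations_ms must have equal length")
        if len(set(ids)) != len(ids):
            raise ValueError("condition ids must be unique")
        if any(d <= 0 for d in durations):
            raise ValueError("all condition durations must be positive")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "durations_ms", durations)

    @property
    def n(self) -> int:
        return len(self.ids)

    @classmethod
    def default(cls, n: int, duration_ms: float = 1000.0) -> "ConditionSet":
        width = max(3, len(str(n - 1)))
        return cls(
            ids=tuple(f"c{i:0{width}d}" for i in range(n)),
            durations_ms=(duration_ms,) * n,
        )


def _validate_rdm_values(values: np.ndarray, n: int) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.shape != (n, n):
        raise ValueError(f"RDM values must be {n}x{n}, got {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("RDM entries must be finite")
    if not np.allclose(v, v.T, atol=_ATOL):
        raise ValueError("RDM must be symmetric")
    if np.any(np.abs(np.diag(v)) > _ATOL):
        raise ValueError("RDM diagonal must be zero")
    if v.min() < -_ATOL or v.max() > 2 + _ATOL:
        raise ValueError("RDM entries must lie in [0, 2]")
    # canonicalise: exact symmetry, exact zero diagonal, exact range
    v = np.clip((v + v.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(v, 0.0)
    return v


@dataclass(frozen=True)
class RDM:
    """Square symmetric matrix of correlation distances (1 - r) in [0, 2]."""

    conditions: ConditionSet
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", _validate_rdm_values(self.values, self.conditions.n)
        )

    @property
    def n(self) -> int:
        return self.conditions.n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.conditions.ids, columns=self.conditions.ids
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, durations_ms=None) -> "RDM":
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = tuple(df.index)
        if durations_ms is None:
            durations_ms = (1000.0,) * len(ids)
        return cls(ConditionSet(ids, durations_ms), df.to_numpy())

    def to_hdf5(self, group: h5py.Group) -> None:
        group.create_dataset("values", data=self.values, track_times=False)
        group.create_dataset(
            "condition_ids",
            data=np.array(self.conditions.ids, dtype="S"),
            track_times=False,
        )
        group.create_dataset(
            "condition_durations_ms",
            data=np.array(self.conditions.durations_ms),
            track_times=False,
        )

    @classmethod
    def from_hdf5(cls, group: h5py.Group) -> "RDM":
        ids = tuple(s.decode() for s in group["condition_ids"][()])
        durations = tuple(group["condition_durations_ms"][()])
        return cls(ConditionSet(ids, durations), group["values"][()])


@dataclass(frozen=True)
class RDMStream:
    """Uniformly time-indexed series of RDMs over one condition set.

    ``values`` has shape ``(n_times, n_conditions, n_conditions)``.
    """

    conditions: ConditionSet
    times_ms: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ms, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or len(t) == 0:
            raise ValueError("times_ms must be a non-empty 1-D array")
        if len(t) > 1:
            steps = np.diff(t)
            if np.any(steps <= 0):
                raise ValueError("times_ms must be strictly increasing")
            if not np.allclose(steps, steps[0]):
                raise ValueError("times_ms must have a uniform step")
        n = self.conditions.n
        if v.shape != (len(t), n, n):
            raise ValueError(
                f"values must have shape ({len(t)}, {n}, {n}), got {v.shape}"
            )
        object.__setattr__(self, "times_ms", t)
        object.__setattr__(self, "values", v)

    @property
    def n_times(self) -> int:
        return len(self.times_ms)

    @property
    def step_ms(self) -> float:
        if len(self.times_ms) < 2:
            return float("nan")
        return float(self.times_ms[1] - self.times_ms[0])

    def frame(self, index: int) -> RDM:
        return RDM(self.conditions, self.values[index])

    def upper_vectors(self) -> np.ndarray:
        """All frames vectorised, shape (n_times, n*(n-1)/2)."""
        iu = np.triu_indices(self.conditions.n, k=1)
        return self.values[:, iu[0], iu[1]]

    def to_hdf5(self, group: h5py.Group) -> None:
        group.create_dataset("values", data=self.values, track_times=False)
        group.create_dataset("times_ms", data=self.times_ms, track_times=False)
        group.create_dataset(
            "condition_ids",
            data=np.array(self.conditions.ids, dtype="S"),
            track_times=False,
        )
        group.create_dataset(
            "condition_durations_ms",
            data=np.array(self.conditions.durations_ms),
            track_times=False,
        )

    @classmethod
    def from_hdf5(cls, group: h5py.Group) -> "RDMStream":
        ids = tuple(s.decode() for s in group["condition_ids"][()])
        durations = tuple(group["condition_durations_ms"][()])
        return cls(
            ConditionSet(ids, durations),
            group["times_ms"][()],
            group["values"][()],
        )


def corr_distance_matrix(responses: np.ndarray) -> np.ndarray:
    """Pearson correlation distance (1 - r) between rows; raw array form."""
    X = np.asarray(responses, dtype=float)
    d = 1.0 - np.corrcoef(X)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return d


def correlation_distance_rdm(
    responses: np.ndarray, conditions: ConditionSet | None = None
) -> RDM:
    """Build an RDM of correlation distances 1 - r between condition rows.

    Parameters
    ----------
    responses:
        (n_conditions, n_features) response matrix, one row per condition.
    conditions:
        Optional condition set; a placeholder set is created when omitted.

    Raises
    ------
    ValueError
        If fewer than 2 conditions/features, non-finite entries, or a
        zero-variance row (correlation distance undefined); the error names
        the offending condition.
    """
    X = np.asarray(responses, dtype=float)
    if X.ndim != 2:
        raise ValueError("responses must be a 2-D (condition x feature) matrix")
    n, f = X.shape
    if n < 2 or f < 2:
        raise ValueError("need at least 2 conditions and 2 features")
    if not np.all(np.isfinite(X)):
        raise ValueError("responses contain non-finite values")
    if conditions is None:
        conditions = ConditionSet.default(n)
    elif conditions.n != n:
        raise ValueError("conditions do not match response matrix")
    sd = X.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            "zero-variance response for condition "
            f"'{conditions.ids[bad[0]]}': correlation distance undefined"
        )
    return RDM(conditions, corr_distance_matrix(X))


def vectorize_upper(rdm: RDM) -> np.ndarray:
    """Row-major upper-triangle vector (d12, d13, ..., d23, ...).

    Length n(n-1)/2; the fixed order makes stored vectors portable and is the
    inverse of :func:`rdm_from_upper`.
    """
    iu = np.triu_indices(rdm.n, k=1)
    return rdm.values[iu]


def rdm_from_upper(vector: np.ndarray, conditions: ConditionSet) -> RDM:
    """Rebuild a full RDM from its row-major upper-triangle vector."""
    v = np.asarray(vector, dtype=float)
    n = conditions.n
    expected = n * (n - 1) // 2
    if v.shape != (expected,):
        raise ValueError(f"expected vector of length {expected}, got {v.shape}")
    mat = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mat[iu] = v
    mat = mat + mat.T
    return RDM(conditions, mat)


def spearman_rdm(a: RDM, b: RDM) -> float:
    """Spearman's rank correlation between two RDMs' upper triangles.

    Ties receive average (mid) ranks.  Raises if the two RDMs do not share a
    condition set or if either vectorised RDM is constant (rho undefined).
    """
    if a.conditions != b.conditions:
        raise ValueError("RDMs must share one condition set")
    va = vectorize_upper(a)
    vb = vectorize_upper(b)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("constant RDM: Spearman correlation undefined")
    return float(stats.spearmanr(va, vb).statistic)


def average_rdms(rdms: Sequence[RDM] | Iterable[RDM]) -> RDM:
    """Entrywise mean of RDMs sharing a condition set (e.g. across subjects)."""
    rdms = list(rdms)
    if not rdms:
        raise ValueError("cannot average an empty list of RDMs")
    conditions = rdms[0].conditions
    for r in rdms[1:]:
        if r.conditions != conditions:
            raise ValueError("all RDMs must share one condition set")
    return RDM(conditions, np.mean([r.values for r in rdms], axis=0))


def batched_upper_corr_distance(responses: np.ndarray) -> np.ndarray:
    """Upper-triangle correlation-distance vectors for a batch of matrices.

    Parameters
    ----------
    responses:
        (batch, n_conditions, n_features) array.

    Returns
    -------
    (batch, n_conditions*(n_conditions-1)/2) array of 1 - r values in the
    row-major upper-triangle order of :func:`vectorize_upper`.

    Notes
    -----
    Fast path used by the searchlight; rows are assumed to have non-zero
    variance (guaranteed for continuous noisy data; the validating object API
    :func:`correlation_distance_rdm` raises on degenerate rows).
    """
    X = np.asarray(responses, dtype=float)
    if X.ndim != 3:
        raise ValueError("expected a (batch, condition, feature) array")
    Xc = X - X.mean(axis=2, keepdims=True)
    norms = np.linalg.norm(Xc, axis=2)
    if np.any(norms == 0):
        raise ValueError("zero-variance response row in batch")
    Xn = Xc / norms[:, :, None]
    r = Xn @ Xn.transpose(0, 2, 1)
    d = np.clip(1.0 - r, 0.0, 2.0)
    iu = np.triu_indices(X.shape[1], k=1)
    return d[:, iu[0], iu[1]]
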