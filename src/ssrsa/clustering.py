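"""Clustering evaluation of layer representational spaces.

How well do phonetic and articulatory-feature labels explain a layer's
activation geometry?  Frame activations are first averaged over each
contiguous phonetic segment of each stimulus (adjacent frames overlap in
time, so per-frame vectors are highly correlated; repeated phones within a
word yield separate averaged vectors).  Each averaged vector is then labelled
under one of five schemes — phone identity, place and manner of articulation
(obstruents only), and vowel frontness and closeness (syllabic vowels only) —
and cluster quality is scored with the Davies-Bouldin index: for each
cluster, the worst-case ratio of summed within-cluster scatter to
between-centroid distance, averaged over clusters.  Lower is better; 0 is
attained only when labels are shared only between identical points.
Significance comes from a permutation null in which labels are shuffled over
the averaged vectors.

A Sammon non-linear MDS embedding is provided for visualising the
representational space in two dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .model_rdms import FeatureTimeline

__all__ = [
    "SegmentTable",
    "LabelScheme",
    "SegmentVectors",
    "EmbeddingResult",
    "PHONE_TABLE",
    "PHONE_INVENTORY",
    "default_label_schemes",
    "segment_average",
    "davies_bouldin",
    "db_permutation_p",
    "evaluate_all_schemes",
    "sammon_embed",
]


@dataclass(frozen=True)
class SegmentTable:
    """Phonetic segmentation: rows of (condition, start_ms, end_ms, phone).

    Within a condition, segments must be ordered and non-overlapping with
    end > start.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"condition", "start_ms", "end_ms", "phone"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"segment table needs columns {sorted(required)}")
        df = self.table.reset_index(drop=True).copy()
        df["condition"] = df["condition"].astype(str)
        df["phone"] = df["phone"].astype(str)
        for cond, grp in df.groupby("condition", sort=False):
            starts = grp["start_ms"].to_numpy(dtype=float)
            ends = grp["end_ms"].to_numpy(dtype=float)
            if np.any(ends <= starts):
                raise ValueError(f"condition '{cond}': segment end must exceed start")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"condition '{cond}': segments overlap or unordered")
        object.__setattr__(self, "table", df)

    def phones(self) -> np.ndarray:
        return np.unique(self.table["phone"])

    def for_condition(self, condition: str) -> pd.DataFrame:
        return self.table[self.table["condition"] == str(condition)]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SegmentTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class LabelScheme:
    """A named phone -> label map with an applicability domain.

    Phones absent from ``mapping`` are inapplicable under the scheme and
    their segment vectors are excluded before indexing.
    """

    name: str
    mapping: Mapping[str, str]

    def applicable(self, phone: str) -> bool:
        return str(phone) in self.mapping

    def label(self, phone: str) -> str:
        try:
            return self.mapping[str(phone)]
        except KeyError:
            raise ValueError(
                f"scheme '{self.name}' has no label for phone '{phone}'"
            ) from None

    @classmethod
    def phone_scheme(cls, phones: Sequence[str]) -> "LabelScheme":
        return cls("phone", {str(p): str(p) for p in phones})


# Synthetic stand-in phone/feature table used by the synthetic-data generator
# and the default label schemes.  Columns: place and manner for obstruents,
# frontness and closeness for syllabic vowels; sonorant consonants carry
# neither feature set.  Every phone has exactly one label per applicable
# scheme.
PHONE_TABLE = pd.DataFrame(
    [
        # phone, place, manner, frontness, closeness
        ("p", "bilabial", "plosive", None, None),
        ("b", "bilabial", "plosive", None, None),
        ("t", "alveolar", "plosive", None, None),
        ("d", "alveolar", "plosive", None, None),
        ("k", "velar", "plosive", None, None),
        ("g", "velar", "plosive", None, None),
        ("f", "labiodental", "fricative", None, None),
        ("v", "labiodental", "fricative", None, None),
        ("th", "dental", "fricative", None, None),
        ("dh", "dental", "fricative", None, None),
        ("s", "alveolar", "fricative", None, None),
        ("z", "alveolar", "fricative", None, None),
        ("sh", "postalveolar", "fricative", None, None),
        ("ch", "postalveolar", "affricate", None, None),
        ("jh", "postalveolar", "affricate", None, None),
        ("m", None, None, None, None),
        ("n", None, None, None, None),
        ("ng", None, None, None, None),
        ("l", None, None, None, None),
        ("r", None, None, None, None),
        ("w", None, None, None, None),
        ("y", None, None, None, None),
        ("iy", None, None, "front", "close"),
        ("ih", None, None, "front", "close"),
        ("eh", None, None, "front", "mid"),
        ("ae", None, None, "front", "open"),
        ("ax", None, None, "central", "mid"),
        ("aa", None, None, "back", "open"),
        ("ao", None, None, "back", "mid"),
        ("ow", None, None, "back", "mid"),
        ("uh", None, None, "back", "close"),
        ("uw", None, None, "back", "close"),
    ],
    columns=["phone", "place", "manner", "frontness", "closeness"],
)

PHONE_INVENTORY = tuple(PHONE_TABLE["phone"])


def default_label_schemes() -> dict:
    """The five labeling schemes: phone, place, manner, frontness, closeness."""
    schemes = {"phone": LabelScheme.phone_scheme(PHONE_INVENTORY)}
    for feature in ("place", "manner", "frontness", "closeness"):
        sub = PHONE_TABLE[PHONE_TABLE[feature].notna()]
        schemes[feature] = LabelScheme(
            feature, dict(zip(sub["phone"], sub[feature]))
        )
    return schemes


@dataclass(frozen=True)
class SegmentVectors:
    """Mean activation vector per (condition, segment), with phone labels."""

    layer_name: str
    table: pd.DataFrame  # condition, start_ms, end_ms, phone
    vectors: np.ndarray  # (n_segments, dim)

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 2 or v.shape[0] != len(self.table):
            raise ValueError("one vector per segment row required")
        object.__setattr__(self, "vectors", v)


def segment_average(
    timeline: FeatureTimeline, segments: SegmentTable
) -> SegmentVectors:
    """Average frame vectors over each contiguous phonetic segment.

    A frame belongs to a segment when its window midpoint
    ``shift*t + frame/2`` falls in [start_ms, end_ms).  Repeated phones in
    one word yield separate averaged vectors.  A segment containing no frame
    midpoint is an error naming the segment.
    """
    cond_index = {cid: i for i, cid in enumerate(timeline.conditions.ids)}
    rows = []
    vectors = []
    for _, seg in segments.table.iterrows():
        cond = seg["condition"]
        if cond not in cond_index:
            raise ValueError(f"segment condition '{cond}' not in timeline")
        ci = cond_index[cond]
        mids = timeline.frame_midpoints_ms(ci)
        sel = (mids >= seg["start_ms"]) & (mids < seg["end_ms"])
        if not np.any(sel):
            raise ValueError(
                f"segment (condition='{cond}', "
                f"[{seg['start_ms']}, {seg['end_ms']}) ms, phone='{seg['phone']}') "
                "contains no frame midpoint"
            )
        rows.append(seg)
        vectors.append(timeline.frames[ci][sel].mean(axis=0))
    return SegmentVectors(
        layer_name=timeline.layer_name,
        table=pd.DataFrame(rows).reset_index(drop=True),
        vectors=np.vstack(vectors),
    )


def _db_index(points: np.ndarray, codes: np.ndarray, n_labels: int) -> float:
    """Davies-Bouldin from integer-coded labels; assumes >= 2 labels."""
    counts = np.bincount(codes, minlength=n_labels)
    centroids = np.zeros((n_labels, points.shape[1]))
    np.add.at(centroids, codes, points)
    centroids /= counts[:, None]
    scatter = np.zeros(n_labels)
    dists = np.linalg.norm(points - centroids[codes], axis=1)
    np.add.at(scatter, codes, dists)
    scatter /= counts
    diff = centroids[:, None, :] - centroids[None, :, :]
    cd = np.linalg.norm(diff, axis=2)
    off = ~np.eye(n_labels, dtype=bool)
    if np.any(cd[off] == 0):
        raise ValueError("coincident cluster centroids: index undefined")
    with np.errstate(divide="ignore"):
        ratio = (scatter[:, None] + scatter[None, :]) / np.where(off, cd, np.inf)
    return float(np.max(ratio, axis=1).mean())


def davies_bouldin(points: np.ndarray, labels: Sequence) -> float:
    """Davies-Bouldin index: mean over clusters of the worst-case
    (s_i + s_j) / d(c_i, c_j) ratio with any other cluster.

    s is the mean Euclidean distance of members to their centroid and d the
    Euclidean distance between centroids; lower is better, 0 minimal.
    Raises with a single label or coincident centroids.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise ValueError("points must be 2-D")
    labels = np.asarray(labels)
    if len(labels) != X.shape[0]:
        raise ValueError("one label per point required")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("Davies-Bouldin needs at least 2 distinct labels")
    return _db_index(X, codes, len(uniq))


def db_permutation_p(
    points: np.ndarray,
    labels: Sequence,
    n_perm: int = 5000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Observed Davies-Bouldin index and its label-permutation p-value.

    The null shuffles the label multiset over points; lower indices are more
    extreme (better clustering), so p = (1 + #{null strictly below
    observed}) / n_perm, clamped to <= 1.  With 5000 permutations and an
    observed index below every null the p-value is exactly 0.0002.

    A shuffled labeling that makes two cluster centroids coincide (possible
    with duplicated points) is an infinitely bad clustering; its null index
    is treated as +inf rather than an error.
    """
    X = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("Davies-Bouldin needs at least 2 distinct labels")
    observed = _db_index(X, codes, len(uniq))
    if rng is None:
        rng = np.random.default_rng(seed)
    lower = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        try:
            null = _db_index(X, perm, len(uniq))
        except ValueError:
            continue  # coincident centroids: null index is +inf, never lower
        if null < observed:
            lower += 1
    p = (1.0 + lower) / n_perm
    return observed, min(p, 1.0)


def evaluate_all_schemes(
    timelines: Mapping[str, FeatureTimeline],
    segments: SegmentTable,
    schemes: Mapping[str, LabelScheme] | None = None,
    n_perm: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Davies-Bouldin index and permutation p per (layer, scheme).

    Segment vectors are restricted to each scheme's applicable phones before
    indexing; a scheme left with fewer than 2 distinct labels is flagged
    (NaN index/p) rather than scored.
    """
    if schemes is None:
        schemes = default_label_schemes()
    rows = []
    for layer, timeline in timelines.items():
        sv = segment_average(timeline, segments)
        phones = sv.table["phone"].to_numpy()
        for name, scheme in schemes.items():
            mask = np.array([scheme.applicable(p) for p in phones])
            labels = [scheme.label(p) for p in phones[mask]]
            if len(set(labels)) < 2:
                rows.append(
                    {
                        "layer": layer,
                        "scheme": name,
                        "n_points": int(mask.sum()),
                        "n_labels": len(set(labels)),
                        "db_index": np.nan,
                        "p_value": np.nan,
                        "note": "fewer than 2 labels after applicability filter",
                    }
                )
                continue
            obs, p = db_permutation_p(
                sv.vectors[mask],
                labels,
                n_perm=n_perm,
                rng=substream(seed, "db-perm", layer, name),
            )
            rows.append(
                {
                    "layer": layer,
                    "scheme": name,
                    "n_points": int(mask.sum()),
                    "n_labels": len(set(labels)),
                    "db_index": obs,
                    "p_value": p,
                    "note": "",
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EmbeddingResult:
    """2-D (by default) coordinates and the final Sammon stress."""

    coords: np.ndarray
    stress: float
    n_iterations: int
    converged: bool

    def __post_init__(self) -> None:
        if self.stress < 0:
            raise ValueError("stress must be non-negative")


def _sammon_stress(delta: np.ndarray, d: np.ndarray, c: float, iu) -> float:
    num = (delta[iu] - d[iu]) ** 2 / delta[iu]
    return float(num.sum() / c)


def sammon_embed(
    distances: np.ndarray,
    dims: int = 2,
    max_iter: int = 500,
    seed: int = 0,
    tol: float = 1e-10,
) -> EmbeddingResult:
    """Sammon non-linear MDS: minimise the inverse-distance-weighted stress

        E = (sum delta)^-1 * sum_{i<j} (delta_ij - d_ij)^2 / delta_ij

    by gradient descent with step halving on any stress increase, from a
    seeded random initialisation.  Stress is non-increasing across accepted
    iterations.  Zero off-diagonal distances are an error (the weight 1/delta
    is undefined).
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("distances must be square symmetric")
    iu = np.triu_indices(n, k=1)
    if np.any(D[iu] <= 0):
        raise ValueError("off-diagonal distances must be strictly positive")
    c = float(D[iu].sum())
    rng = np.random.default_rng(seed)
    scale = D[iu].mean()
    Y = rng.normal(scale=scale, size=(n, dims))

    def pairwise(Y):
        diff = Y[:, None, :] - Y[None, :, :]
        return np.linalg.norm(diff, axis=2), diff

    d, diff = pairwise(Y)
    stress = _sammon_stress(D, d, c, iu)
    lr = 0.3
    n_iter = 0
    converged = False
    eps = 1e-12
    for n_iter in range(1, max_iter + 1):
        d_safe = np.maximum(d, eps)
        w = (D - d) / (np.maximum(D, eps) * d_safe)
        np.fill_diagonal(w, 0.0)
        grad = (-2.0 / c) * np.einsum("ij,ijk->ik", w, diff)
        accepted = False
        step = lr
        for _ in range(40):
            cand = Y - step * grad
            d_c, diff_c = pairwise(cand)
            s_c = _sammon_stress(D, d_c, c, iu)
            if s_c <= stress:
                accepted = True
                break
            step /= 2.0
        if not accepted or stress - s_c < tol:
            converged = True
            if accepted:
                Y, d, diff, stress = cand, d_c, diff_c, s_c
            break
        Y, d, diff, stress = cand, d_c, diff_c, s_c
        lr = min(step * 1.2, 1.0)
    return EmbeddingResult(
        coords=Y, stress=stress, n_iterations=n_iter, converged=converged
    )
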