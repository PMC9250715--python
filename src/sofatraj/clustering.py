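"""Subphenotype discovery: hierarchical clustering on DTW distances.

Agglomerative clustering runs directly on the precomputed dissimilarity
matrix (average linkage by default — Ward would assume squared Euclidean
geometry, which DTW distances do not have). The number of clusters is
chosen by an ensemble of three distance-compatible indices (mean
silhouette, Dunn index, C-index) voting over a candidate range, majority
wins and ties go to the smallest k. At k = 4 the clusters are mapped onto
the four trajectory archetypes (RW/DW/RI/DI) from the early and late slopes
of their mean curves.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _hierarchy
from sklearn.metrics import silhouette_score

from .dtw import validate_distance_matrix

LINKAGES = ("average", "complete", "single")
ARCHETYPE_LABELS = ("RW", "DW", "RI", "DI")


@dataclasses.dataclass
class ClusterAssignment:
    patient_ids: list
    clusters: np.ndarray  # int ids 1..k
    k: int

    def __post_init__(self) -> None:
        uniq = np.unique(self.clusters)
        if len(uniq) != self.k or uniq.min() != 1 or uniq.max() != self.k:
            raise ValueError("clusters must use every id in 1..k")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cluster": self.clusters},
            index=pd.Index(self.patient_ids, name="patient_id"),
        )


def hac_linkage(d, linkage: str = "average") -> np.ndarray:
    """Agglomerative linkage matrix from a precomputed dissimilarity matrix.

    Lance-Williams agglomeration with deterministic tie-breaking: among
    equally close active pairs the lexicographically smallest (i, j) index
    pair merges first. Returns an (n-1, 4) matrix in the usual format
    (left node, right node, merge height, cluster size), leaves 0..n-1 and
    the cluster created at step s numbered n + s.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    D = validate_distance_matrix(d).copy()
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least two observations")
    np.fill_diagonal(D, np.inf)  # inactive cells (diagonal, merged rows) sit at inf
    labels = np.arange(n)
    sizes = np.ones(n)
    Z = np.empty((n - 1, 4))
    for step in range(n - 1):
        # row-major argmin over the symmetric matrix: first occurrence is the
        # lexicographically smallest (i, j) with i < j among tied pairs
        flat = int(np.argmin(D))
        i, j = divmod(flat, n)
        height = D[i, j]
        si, sj = sizes[i], sizes[j]
        if linkage == "average":
            new = (si * D[i] + sj * D[j]) / (si + sj)
        elif linkage == "complete":
            new = np.maximum(D[i], D[j])
        else:
            new = np.minimum(D[i], D[j])
        D[i] = new
        D[:, i] = new
        D[i, i] = np.inf
        D[j, :] = np.inf
        D[:, j] = np.inf
        Z[step] = (labels[i], labels[j], height, si + sj)
        labels[i] = n + step
        sizes[i] = si + sj
    return Z


def cut_tree(Z: np.ndarray, k: int, patient_ids: Sequence | None = None) -> ClusterAssignment:
    """Cut the dendrogram into k clusters by undoing the k-1 highest merges.

    Cluster ids 1..k are assigned by descending cluster size, ties broken
    by the smallest member index.
    """
    n = Z.shape[0] + 1
    if not (2 <= k <= n):
        raise ValueError(f"k must lie in [2, {n}]")
    raw = _hierarchy.cut_tree(Z, n_clusters=k).ravel()
    if patient_ids is None:
        patient_ids = list(range(n))
    clusters = relabel_by_size(raw)
    return ClusterAssignment(patient_ids=list(patient_ids), clusters=clusters, k=k)


def relabel_by_size(raw: np.ndarray) -> np.ndarray:
    """Map arbitrary labels to 1..k by descending size then smallest member."""
    raw = np.asarray(raw)
    uniq = np.unique(raw)
    order = sorted(
        uniq,
        key=lambda c: (-int((raw == c).sum()), int(np.flatnonzero(raw == c)[0])),
    )
    mapping = {c: r + 1 for r, c in enumerate(order)}
    return np.array([mapping[c] for c in raw], dtype=int)


# ---------------------------------------------------------------------------
# cluster-count indices
# ---------------------------------------------------------------------------


def dunn_index(D: np.ndarray, labels: np.ndarray) -> float:
    """min inter-cluster distance / max intra-cluster diameter."""
    uniq = np.unique(labels)
    diameters = []
    for c in uniq:
        members = labels == c
        sub = D[np.ix_(members, members)]
        diameters.append(sub.max(initial=0.0))
    max_diam = max(diameters)
    min_sep = np.inf
    for a in range(len(uniq)):
        for b in range(a + 1, len(uniq)):
            sub = D[np.ix_(labels == uniq[a], labels == uniq[b])]
            min_sep = min(min_sep, sub.min())
    if max_diam == 0.0:
        return np.inf
    return float(min_sep / max_diam)


def c_index(D: np.ndarray, labels: np.ndarray) -> float:
    """(S_w - S_min) / (S_max - S_min) over within-cluster pairs; lower is better."""
    n = D.shape[0]
    iu = np.triu_indices(n, 1)
    all_d = np.sort(D[iu])
    within_mask = labels[iu[0]] == labels[iu[1]]
    n_within = int(within_mask.sum())
    if n_within == 0:
        return 0.0
    s_w = D[iu][within_mask].sum()
    s_min = all_d[:n_within].sum()
    s_max = all_d[-n_within:].sum()
    if s_max == s_min:
        return 0.0
    return float((s_w - s_min) / (s_max - s_min))


@dataclasses.dataclass
class IndexReport:
    table: pd.DataFrame  # index k; columns silhouette, dunn, c_index
    votes: dict  # index name -> k it voted for
    chosen_k: int


def select_k(
    d,
    tree: np.ndarray | None = None,
    k_range: Sequence[int] = range(2, 9),
    linkage: str = "average",
) -> IndexReport:
    """Pick the cluster count by majority vote of silhouette, Dunn, C-index.

    Silhouette and Dunn vote for their maximising k, the C-index for its
    minimising k; the chosen k is the modal vote, ties resolved in favour
    of the smallest k.
    """
    D = validate_distance_matrix(d)
    if D.max(initial=0.0) == 0.0:
        raise ValueError("degenerate all-zero distance matrix")
    n = D.shape[0]
    k_range = [k for k in k_range]
    if any(k < 2 or k > n - 1 for k in k_range):
        raise ValueError("k_range must lie within [2, n-1]")
    if tree is None:
        tree = hac_linkage(d, linkage=linkage)
    rows = {}
    for k in k_range:
        labels = cut_tree(tree, k).clusters
        rows[k] = {
            "silhouette": float(silhouette_score(D, labels, metric="precomputed")),
            "dunn": dunn_index(D, labels),
            "c_index": c_index(D, labels),
        }
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    votes = {
        "silhouette": int(table["silhouette"].idxmax()),
        "dunn": int(table["dunn"].idxmax()),
        "c_index": int(table["c_index"].idxmin()),
    }
    counts: dict[int, int] = {}
    for k in votes.values():
        counts[k] = counts.get(k, 0) + 1
    best = max(counts.values())
    chosen = min(k for k, c in counts.items() if c == best)
    return IndexReport(table=table, votes=votes, chosen_k=int(chosen))


# ---------------------------------------------------------------------------
# archetype labelling
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ArchetypeLabeling:
    labels: Mapping[int, str]  # cluster id -> archetype; empty when skipped
    mean_curves: Mapping[int, np.ndarray]
    deltas: Mapping[int, tuple[float, float]]  # (early, late) per cluster
    status: str = "ok"


def _delta_signs(early: float, late: float, eps: float) -> tuple[int, int]:
    se = 1 if early > eps else (-1 if early < -eps else 0)
    sl = 1 if late > eps else (-1 if late < -eps else 0)
    if se == 0:  # fall back to the raw sign for a flat first two days
        se = 1 if early >= 0 else -1
    return se, sl


def label_archetypes(
    assign: ClusterAssignment, trajectories, eps: float = 0.1
) -> ArchetypeLabeling:
    """Name four clusters RW/DW/RI/DI from their mean-curve slopes.

    Per cluster, with mean curve m over the 12 windows, the early change is
    m(window 8) - m(window 1) (the first 48 h) and the late change is
    m(window 12) - m(window 8) (the last 24 h). Sign pattern with a noise
    tolerance ``eps``: rising/rising -> RW, falling/falling -> RI,
    falling/rising -> DW, rising/falling -> DI. If two clusters collide on
    a label, the one with the larger absolute net change keeps the Rapid
    label of its worsening/improving family and the other takes the
    Delayed one.
    """
    if assign.k != 4:
        warnings.warn(f"archetype labelling requires k=4 (got k={assign.k}); skipped")
        return ArchetypeLabeling(labels={}, mean_curves={}, deltas={}, status="skipped")
    values = (
        trajectories.to_numpy(dtype=float)
        if isinstance(trajectories, pd.DataFrame)
        else np.asarray(trajectories, dtype=float)
    )
    curves: dict[int, np.ndarray] = {}
    deltas: dict[int, tuple[float, float]] = {}
    provisional: dict[int, str] = {}
    for c in range(1, 5):
        m = values[assign.clusters == c].mean(axis=0)
        curves[c] = m
        early = float(m[7] - m[0])
        late = float(m[11] - m[7])
        deltas[c] = (early, late)
        se, sl = _delta_signs(early, late, eps)
        if se > 0:
            provisional[c] = "RW" if sl >= 0 else "DI"
        else:
            provisional[c] = "RI" if sl <= 0 else "DW"

    labels = dict(provisional)
    for fam_rapid, fam_delayed in [("RW", "DW"), ("RI", "DI")]:
        for dup in (fam_rapid, fam_delayed):
            holders = [c for c, lab in labels.items() if lab == dup]
            if len(holders) == 2:
                net = {c: abs(curves[c][11] - curves[c][0]) for c in holders}
                big, small = sorted(holders, key=lambda c: -net[c])
                labels[big] = fam_rapid
                labels[small] = fam_delayed
    if len(set(labels.values())) != 4:
        # degenerate shapes: fall back to best bipolar match on slope signs
        from scipy.optimize import linear_sum_assignment

        proto = {"RW": (1, 1), "DW": (-1, 1), "RI": (-1, -1), "DI": (1, -1)}
        names = list(ARCHETYPE_LABELS)
        cost = np.zeros((4, 4))
        for ci, c in enumerate(range(1, 5)):
            e, l = deltas[c]
            norm = max(abs(e), abs(l), eps)
            for ni, name in enumerate(names):
                pe, pl = proto[name]
                cost[ci, ni] = -(pe * e + pl * l) / norm
        rows_idx, cols_idx = linear_sum_assignment(cost)
        labels = {r + 1: names[c] for r, c in zip(rows_idx, cols_idx)}
    assert len(set(labels.values())) == 4
    return ArchetypeLabeling(labels=labels, mean_curves=curves, deltas=deltas)


def archetype_series(assign: ClusterAssignment, labeling: ArchetypeLabeling) -> pd.Series:
    """Per-patient archetype labels (falls back to cluster ids when skipped)."""
    if labeling.status != "ok":
        return pd.Series(
            [f"C{c}" for c in assign.clusters],
            index=pd.Index(assign.patient_ids, name="patient_id"),
            name="label",
        )
    return pd.Series(
        [labeling.labels[c] for c in assign.clusters],
        index=pd.Index(assign.patient_ids, name="patient_id"),
        name="label",
    )
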