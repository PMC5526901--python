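"""Grid-based density clustering with centroid cross-sample assignment.

Events are binned on a regular grid over the selected marker channels
(each channel min-max scaled to [0, 1]); hyper-bins holding at least a
minimum number of events are "dense".  Each dense bin points to its
best (highest-occupancy) Chebyshev-adjacent dense bin; following these
uphill pointers to their fixed points partitions the dense region into
one group per local density mode, so adjacent populations that meet at a
density saddle stay separate while contiguous bins of one mode merge.
The modes seed the clusters.  Every event — dense-region or not — is
then assigned to the nearest cluster centroid
(Euclidean distance in the scaled space), centroids are re-estimated once
from that assignment, and a final nearest-centroid pass fixes the model,
so re-assigning the training events reproduces the stored counts exactly.

A model fitted on one sample (or on a subsampled multi-sample consensus,
see :func:`build_template`) can be reused as a reference: its
normalization scale is frozen, so assigning another sample's events to
its centroids is well defined.  This is a functional stand-in for
centroid-based cross-comparison in grid-density tools; it does not
reproduce any particular tool's internal heuristics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import pairwise_distances_argmin

from .io import EventTable

#: Roles eligible for clustering by default (markers, not scatter/viability).
DEFAULT_CLUSTER_ROLES = ("CD3", "dump", "CD8", "multimer-PE", "multimer-APC")


@dataclass
class ClusterModel:
    """Fitted cluster template.

    centroids are on the analysis scale (same units as the input table);
    `scale` records the per-channel (min, max) used for [0, 1]
    normalization so that cross-sample assignment reuses the same metric.
    """

    centroids: np.ndarray  # (k, d), analysis scale
    counts: np.ndarray  # (k,), events per cluster at fit time
    channel_roles: tuple[str, ...]
    scale: np.ndarray  # (d, 2): per-channel (min, max)
    bins: int
    min_density: int

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.scale = np.asarray(self.scale, dtype=float)
        if self.centroids.ndim != 2 or self.centroids.shape[0] < 1:
            raise ValueError("model must hold at least one cluster")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    def scaled_centroids(self) -> np.ndarray:
        lo, hi = self.scale[:, 0], self.scale[:, 1]
        span = np.where(hi > lo, hi - lo, 1.0)
        return (self.centroids - lo) / span

    def scale_values(self, values: np.ndarray) -> np.ndarray:
        lo, hi = self.scale[:, 0], self.scale[:, 1]
        span = np.where(hi > lo, hi - lo, 1.0)
        return (values - lo) / span

    # -- serialization -------------------------------------------------
    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "centroids": self.centroids.tolist(),
            "counts": self.counts.tolist(),
            "channel_roles": list(self.channel_roles),
            "scale": self.scale.tolist(),
            "bins": self.bins,
            "min_density": self.min_density,
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            centroids=np.array(payload["centroids"]),
            counts=np.array(payload["counts"]),
            channel_roles=tuple(payload["channel_roles"]),
            scale=np.array(payload["scale"]),
            bins=int(payload["bins"]),
            min_density=int(payload["min_density"]),
        )


def default_min_density(n_events: int) -> int:
    """Dense-bin threshold: enough to suppress stray background bins while
    keeping ~100-event rare populations resolvable at around 10^6 events."""
    return max(5, n_events // 100_000)


def _extract(table: EventTable, roles: Sequence[str]) -> np.ndarray:
    cols = [table.role_index(r) for r in roles]
    return table.values[:, cols]


def _nearest(scaled: np.ndarray, centroids_scaled: np.ndarray) -> np.ndarray:
    """Nearest-centroid assignment; ties resolve to the lowest index."""
    return pairwise_distances_argmin(scaled, centroids_scaled)


def _mode_seek(occupancy: np.ndarray, dense: np.ndarray) -> np.ndarray:
    """Partition dense hyper-bins into density modes by uphill pointers.

    Every dense bin points at its Chebyshev neighbor with the highest
    occupancy (ties broken toward the lower flat index, and a bin with no
    strictly better neighbor is its own mode).  Following the pointers to
    their fixed points labels each dense bin with a mode id 1..k; sparse
    bins get 0.  A neighbor is "better" than the bin itself when its
    (count, -flat index) key is lexicographically larger, which makes the
    partition deterministic under count ties.
    """
    d = occupancy.ndim
    shape = occupancy.shape
    coords = np.argwhere(dense)
    flats = np.ravel_multi_index(coords.T, shape)
    count_of = {int(f): int(occupancy[tuple(c)]) for f, c in zip(flats, coords)}
    offsets = np.array(
        [o for o in np.ndindex(*(3,) * d) if any(v != 1 for v in o)]
    ) - 1
    parent: dict[int, int] = {}
    for f, coord in zip(flats, coords):
        f = int(f)
        best_key = (count_of[f], -f)
        best_f = f
        for off in offsets:
            nb = coord + off
            if np.any(nb < 0) or np.any(nb >= shape):
                continue
            nf = int(np.ravel_multi_index(nb, shape))
            nc = count_of.get(nf)
            if nc is None:
                continue
            if (nc, -nf) > best_key:
                best_key = (nc, -nf)
                best_f = nf
        parent[f] = best_f

    def find(f: int) -> int:
        root = f
        while parent[root] != root:
            root = parent[root]
        while parent[f] != root:  # path compression
            parent[f], f = root, parent[f]
        return root

    mode_ids: dict[int, int] = {}
    labels = np.zeros(shape, dtype=np.int64)
    for f, coord in zip(flats, coords):
        root = find(int(f))
        if root not in mode_ids:
            mode_ids[root] = len(mode_ids) + 1
        labels[tuple(coord)] = mode_ids[root]
    return labels


def grid_density_cluster(
    table: EventTable,
    roles: Sequence[str],
    bins: int = 16,
    min_density: int | None = None,
    max_clusters: int = 100,
) -> tuple[ClusterModel, np.ndarray]:
    """Cluster `table` on the given channel roles; returns (model, assignment).

    See the module docstring for the algorithm.  When every hyper-bin is
    sparse the whole table collapses into a single cluster (with a
    warning via the fallback path).
    """
    if len(roles) < 2:
        raise ValueError("grid_density_cluster needs at least 2 channel roles")
    if table.n_events == 0:
        raise ValueError("grid_density_cluster: empty table")
    X = _extract(table, roles)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    scale = np.column_stack([lo, hi])
    span = np.where(hi > lo, hi - lo, 1.0)
    scaled = (X - lo) / span

    n = X.shape[0]
    if min_density is None:
        min_density = default_min_density(n)

    idx = np.clip((scaled * bins).astype(np.int64), 0, bins - 1)
    d = X.shape[1]
    occupancy = np.zeros((bins,) * d, dtype=np.int64)
    np.add.at(occupancy, tuple(idx.T), 1)

    dense = occupancy >= min_density
    if not dense.any():
        centroid = scaled.mean(axis=0, keepdims=True)
        model = ClusterModel(
            centroids=centroid * span + lo,
            counts=np.array([n]),
            channel_roles=tuple(roles),
            scale=scale,
            bins=bins,
            min_density=min_density,
        )
        return model, np.zeros(n, dtype=np.int64)

    components = _mode_seek(occupancy, dense)
    event_comp = components[tuple(idx.T)]  # 0 = sparse bin
    n_comp = int(components.max())

    # seed centroids: mean scaled position of events in each dense mode
    seeds = []
    comp_sizes = []
    for c in range(1, n_comp + 1):
        members = event_comp == c
        seeds.append(scaled[members].mean(axis=0))
        comp_sizes.append(int(members.sum()))
    seeds_arr = np.asarray(seeds)
    if n_comp > max_clusters:
        keep = np.argsort(comp_sizes)[::-1][:max_clusters]
        keep.sort()
        seeds_arr = seeds_arr[keep]

    assignment = _nearest(scaled, seeds_arr)
    # one centroid update from the full assignment, then a final pass so the
    # stored counts are reproducible by plain nearest-centroid assignment
    k = seeds_arr.shape[0]
    refined = np.empty_like(seeds_arr)
    for j in range(k):
        members = assignment == j
        refined[j] = scaled[members].mean(axis=0) if members.any() else seeds_arr[j]
    final = _nearest(scaled, refined)
    counts = np.bincount(final, minlength=k)

    model = ClusterModel(
        centroids=refined * span + lo,
        counts=counts,
        channel_roles=tuple(roles),
        scale=scale,
        bins=bins,
        min_density=min_density,
    )
    return model, final


def build_template(
    consensus: EventTable,
    roles: Sequence[str],
    bins: int = 16,
    min_density: int | None = None,
    max_clusters: int = 100,
) -> ClusterModel:
    """Fit a reference template on a (typically multi-sample consensus)
    table; the stored normalization scale makes it reusable across
    samples."""
    model, _ = grid_density_cluster(consensus, roles, bins=bins,
                                    min_density=min_density,
                                    max_clusters=max_clusters)
    return model


def assign_to_centroids(
    table: EventTable, model: ClusterModel
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each event to the nearest template centroid (Euclidean in the
    template's frozen scaled space); ties go to the lowest cluster index.

    Returns (per-event assignment, per-cluster counts).
    """
    for role in model.channel_roles:
        if not table.has_role(role):
            raise ValueError(f"assign_to_centroids: table lacks role {role!r}")
    X = _extract(table, model.channel_roles)
    assignment = _nearest(model.scale_values(X), model.scaled_centroids())
    counts = np.bincount(assignment, minlength=model.n_clusters)
    return assignment, counts


class GridDensityCluster(ClusterMixin, BaseEstimator):
    """Grid-density clustering as a scikit-learn-style estimator.

    Parameters
    ----------
    roles : sequence of str or None
        Channel roles to cluster on; None selects every marker role
        present in the table (CD3, dump, CD8, multimer channels).
    bins : int
        Grid resolution per channel.
    min_density : int or None
        Events per hyper-bin required for a bin to count as dense; None
        uses ``max(5, n // 100_000)``.
    max_clusters : int
        Cap on the number of clusters (largest components kept).

    Attributes
    ----------
    model_ : ClusterModel
    labels_ : per-event cluster assignment of the fit table
    cluster_centers_ : centroids on the analysis scale
    """

    def __init__(self, roles: Sequence[str] | None = None, bins: int = 16,
                 min_density: int | None = None, max_clusters: int = 100):
        self.roles = roles
        self.bins = bins
        self.min_density = min_density
        self.max_clusters = max_clusters

    def _resolve_roles(self, table: EventTable) -> list[str]:
        if self.roles is not None:
            return list(self.roles)
        roles = [r for r in DEFAULT_CLUSTER_ROLES if table.has_role(r)]
        if len(roles) < 2:
            raise ValueError("table has fewer than 2 default marker roles")
        return roles

    def fit(self, X: EventTable, y=None) -> "GridDensityCluster":
        roles = self._resolve_roles(X)
        self.model_, self.labels_ = grid_density_cluster(
            X, roles, bins=self.bins, min_density=self.min_density,
            max_clusters=self.max_clusters,
        )
        self.cluster_centers_ = self.model_.centroids
        return self

    def predict(self, X: EventTable) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("GridDensityCluster is not fitted")
        assignment, _ = assign_to_centroids(X, self.model_)
        return assignment
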