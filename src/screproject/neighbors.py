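"""Subcluster re-projection: KNN graphs, distance rescaling, weighted merge,
and embedding from the merged graph.

The algorithm integrates subcluster structure back into the total-cell map:

1. exact K-nearest-neighbor graphs are built for the parent object and for
   every subcluster object, each on its own low-dimensional reduction;
2. each subcluster graph's distances are rescaled so its mean neighbor
   distance matches the parent's mean neighbor distance *within that
   subcluster's cells*, putting both graphs on one scale;
3. per subclustered cell, up to ``K1 = round(w·K)`` of its nearest parent
   neighbors lying in a *different* parent-level cluster are retained
   (preserving global structure), the remainder of the row is filled with its
   nearest subcluster neighbors, and the merged row is re-sorted by distance
   and truncated to K.  Cells in no subcluster keep their parent rows
   verbatim;
4. a 2-D UMAP layout is computed from the merged graph used as a precomputed
   neighbor structure.

``w`` ∈ [0, 1] trades global connectivity (w = 1, the default) against
subcluster separability (w = 0 uses only subcluster neighbors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import floor
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.utils import check_random_state
from umap.umap_ import find_ab_params, fuzzy_simplicial_set, simplicial_set_embedding

from .errors import (
    DegenerateScaleError,
    MissingReductionError,
    ParameterError,
    PiWarning,
    StructureError,
)
from .pi import PiObject, SubclusterLink

PARENT_TAG = "parent"


@dataclass
class NeighborGraph:
    """Per-cell ranked K-nearest-neighbor lists with distances.

    ``indices``/``distances`` are (n_cells, K) arrays; rows are sorted
    ascending by distance.  Short rows (possible only in merged graphs) are
    padded with index −1 and distance +inf.  ``scale_factor`` records the
    multiplier applied by :func:`rescale_child_distances`, if any.
    """

    cell_ids: np.ndarray
    K: int
    indices: np.ndarray
    distances: np.ndarray
    scale_factor: Optional[float] = None

    def __post_init__(self):
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.distances = np.asarray(self.distances, dtype=np.float64)
        n = len(self.cell_ids)
        if self.indices.shape != (n, self.K) or self.distances.shape != (n, self.K):
            raise StructureError(
                f"neighbor arrays must be ({n}, {self.K}); got "
                f"{self.indices.shape} and {self.distances.shape}"
            )

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def row_lengths(self) -> np.ndarray:
        return (self.indices >= 0).sum(axis=1)

    def validate(self) -> None:
        n = self.n_cells
        valid = self.indices >= 0
        if (self.indices[valid] >= n).any():
            raise StructureError("neighbor indices out of range")
        rows = np.arange(n)[:, None]
        if (self.indices == rows).any():
            raise StructureError("self-edges are not allowed")
        d = self.distances.copy()
        if (d[valid] < 0).any() or not np.isfinite(d[valid]).all():
            raise StructureError("distances must be finite and nonnegative")
        if (np.diff(d, axis=1) < 0).any():
            raise StructureError("per-cell distances must be ascending")


@dataclass
class MergedGraph(NeighborGraph):
    """A neighbor graph over the parent's cells with per-edge provenance.

    ``provenance[i, j]`` is ``"parent"`` or ``"child:<name>"`` for real
    edges and ``""`` for padding.
    """

    provenance: np.ndarray = None

    def __post_init__(self):
        super().__post_init__()
        if self.provenance is None:
            self.provenance = np.where(self.indices >= 0, PARENT_TAG, "").astype(object)
        self.provenance = np.asarray(self.provenance, dtype=object)
        if self.provenance.shape != self.indices.shape:
            raise StructureError("provenance shape must match indices")


@dataclass
class ReprojectionConfig:
    """Parameters of the re-projection.

    K is the neighbor count used for every graph; w caps the fraction of
    parent-derived cross-cluster edges retained per subclustered cell;
    ``reduction`` names the coordinates used for KNN (default: first
    available reduction of each object); ``seed`` controls only the layout;
    ``embed_params`` is passed through to the UMAP layout stage
    (min_dist, spread, n_epochs, negative_sample_rate, init).
    """

    K: int = 20
    w: float = 1.0
    scaling: str = "mean-distance"
    seed: int = 0
    reduction: Optional[str] = None
    embed_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.w <= 1.0):
            raise ParameterError(f"w must be in [0, 1]; got {self.w}")
        if self.K < 1:
            raise ParameterError(f"K must be >= 1; got {self.K}")
        if self.scaling != "mean-distance":
            raise ParameterError(f"unknown scaling {self.scaling!r}")

    @property
    def K1(self) -> int:
        """Cap on retained parent cross-cluster edges: round(w·K), half away
        from zero."""
        return int(floor(self.w * self.K + 0.5))


def _pick_reduction(pi: PiObject, name: Optional[str]) -> str:
    keys = list(pi.reductions.keys())
    if name is not None:
        if name not in keys:
            raise MissingReductionError(
                f"reduction {name!r} not found in {pi.name or 'object'}; have {keys}"
            )
        return name
    if not keys:
        raise MissingReductionError(f"{pi.name or 'object'} has no reductions")
    return keys[0]


def build_knn(
    pi: PiObject, reduction: Optional[str] = None, K: int = 20, metric: str = "euclidean"
) -> NeighborGraph:
    """Exact K-nearest-neighbor graph on a named reduction.

    Self is excluded; ties are broken by cell order; distances ascend within
    each row.  Exact brute-force search keeps the graph deterministic.
    """
    if metric != "euclidean":
        raise ParameterError(f"unsupported metric {metric!r}")
    name = _pick_reduction(pi, reduction)
    X = np.asarray(pi.reductions[name], dtype=np.float64)
    n = X.shape[0]
    if K >= n:
        raise ParameterError(f"K={K} must be smaller than the number of cells ({n})")
    indices = np.empty((n, K), dtype=np.int64)
    distances = np.empty((n, K), dtype=np.float64)
    chunk = max(1, int(2e7) // max(n, 1))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        D = cdist(X[start:stop], X, metric="euclidean")
        D[np.arange(start, stop) - start, np.arange(start, stop)] = np.inf
        # ascending distance, ties broken by neighbor position
        order = np.lexsort((np.broadcast_to(np.arange(n), D.shape), D), axis=1)[:, :K]
        indices[start:stop] = order
        distances[start:stop] = np.take_along_axis(D, order, axis=1)
    return NeighborGraph(cell_ids=pi.cell_ids.copy(), K=K, indices=indices, distances=distances)


def rescale_child_distances(
    parent_graph: NeighborGraph, child_graph: NeighborGraph, link: SubclusterLink
) -> NeighborGraph:
    """Rescale a subcluster graph's distances to the parent's scale.

    All child distances are multiplied by ``s = A_p / A_c`` where ``A_c`` is
    the mean neighbor distance in the child graph and ``A_p`` the mean parent
    neighbor distance over edges whose both endpoints lie in the subcluster's
    cell set.  If no parent edge is internal to the set, edges with at least
    one endpoint in the set are used instead; if none exist, ``s = 1`` with a
    warning.  Neighbor ranks are unchanged.
    """
    valid_c = child_graph.indices >= 0
    A_c = float(child_graph.distances[valid_c].mean()) if valid_c.any() else 0.0
    if A_c == 0.0:
        raise DegenerateScaleError(
            f"all child distances are zero in subcluster {link.name!r}; "
            "cannot rescale coincident cells"
        )
    member = np.isin(parent_graph.cell_ids, np.asarray(link.cell_ids, dtype=object))
    src_in = member[:, None] & (parent_graph.indices >= 0)
    both_in = src_in & member[np.clip(parent_graph.indices, 0, None)]
    if both_in.any():
        A_p = float(parent_graph.distances[both_in].mean())
    elif src_in.any() or (member[np.clip(parent_graph.indices, 0, None)] & (parent_graph.indices >= 0)).any():
        one_in = (src_in | (member[np.clip(parent_graph.indices, 0, None)] & (parent_graph.indices >= 0)))
        A_p = float(parent_graph.distances[one_in].mean())
        warnings.warn(
            f"no parent edges internal to subcluster {link.name!r}; using edges "
            "with one endpoint inside",
            PiWarning,
        )
    else:
        warnings.warn(
            f"no parent edges touch subcluster {link.name!r}; leaving distances unscaled",
            PiWarning,
        )
        A_p = A_c
    s = A_p / A_c
    return NeighborGraph(
        cell_ids=child_graph.cell_ids.copy(),
        K=child_graph.K,
        indices=child_graph.indices.copy(),
        distances=child_graph.distances * s,
        scale_factor=s,
    )


def merge_neighbors(
    parent_graph: NeighborGraph,
    scaled_children: Mapping[str, tuple],
    config: ReprojectionConfig,
    parent_labels,
) -> MergedGraph:
    """Merge parent and rescaled subcluster neighbor lists under the w rule.

    ``scaled_children`` maps child name → (rescaled NeighborGraph, link or
    cell-id list).  ``parent_labels`` gives the parent-level cluster label per
    parent cell (aligned with ``parent_graph.cell_ids``).

    For each cell in a subcluster: up to ``K1 = round(w·K)`` of its nearest
    parent neighbors from a *different* parent-level cluster are retained (in
    rank order); the remaining slots are filled with its nearest subcluster
    neighbors; a neighbor present in both lists keeps the smaller distance
    (and that copy's provenance); the row is sorted ascending by distance
    — ties broken by parent-provenance first, then neighbor order — and
    truncated to K.  Cells in no subcluster keep their parent rows verbatim.
    """
    K = parent_graph.K
    n = parent_graph.n_cells
    labels = np.asarray(pd.Series(parent_labels).astype(str).to_numpy(), dtype=object)
    if len(labels) != n:
        raise StructureError("parent_labels must align with the parent graph")
    pos_of = {cid: i for i, cid in enumerate(parent_graph.cell_ids)}

    # resolve membership; check disjointness
    assigned = np.full(n, -1, dtype=np.int64)
    child_items = []
    for ci, (name, (graph, link_or_ids)) in enumerate(scaled_children.items()):
        ids = link_or_ids.cell_ids if isinstance(link_or_ids, SubclusterLink) else link_or_ids
        ppos = np.array([pos_of[str(c)] for c in ids], dtype=np.int64)
        gpos = {str(c): j for j, c in enumerate(graph.cell_ids)}
        if (assigned[ppos] >= 0).any():
            raise ParameterError("subcluster cell sets must be mutually disjoint")
        assigned[ppos] = ci
        # map child-graph row index -> parent position
        child_to_parent = np.array([pos_of[str(c)] for c in graph.cell_ids], dtype=np.int64)
        child_items.append((name, graph, gpos, child_to_parent))

    K1 = config.K1
    out_idx = np.full((n, K), -1, dtype=np.int64)
    out_dist = np.full((n, K), np.inf, dtype=np.float64)
    out_prov = np.full((n, K), "", dtype=object)
    short_rows = []

    for c in range(n):
        ci = assigned[c]
        if ci < 0:
            out_idx[c] = parent_graph.indices[c]
            out_dist[c] = parent_graph.distances[c]
            out_prov[c] = np.where(parent_graph.indices[c] >= 0, PARENT_TAG, "")
            continue
        name, graph, gpos, child_to_parent = child_items[ci]
        # step 1: cross-cluster parent edges, rank order, capped at K1
        picks: dict[int, tuple[float, str]] = {}
        for j, d in zip(parent_graph.indices[c], parent_graph.distances[c]):
            if j < 0 or len(picks) >= K1:
                break
            if labels[j] != labels[c]:
                picks[int(j)] = (float(d), PARENT_TAG)
        r = len(picks)
        # step 2: fill K - r slots from the subcluster graph
        g = gpos[str(parent_graph.cell_ids[c])]
        taken = 0
        tag = f"child:{name}"
        for j, d in zip(graph.indices[g], graph.distances[g]):
            if j < 0:
                break
            p = int(child_to_parent[j])
            if p in picks:
                # duplicate edge: keep the smaller distance and its provenance
                if d < picks[p][0]:
                    picks[p] = (float(d), tag)
                continue
            if taken >= K - r:
                continue
            picks[p] = (float(d), tag)
            taken += 1
        # step 3: sort by (distance, parent first, neighbor order), truncate
        entries = sorted(
            ((d, 0 if prov == PARENT_TAG else 1, p, prov) for p, (d, prov) in picks.items())
        )[:K]
        if len(entries) < K:
            short_rows.append(parent_graph.cell_ids[c])
        for slot, (d, _, p, prov) in enumerate(entries):
            out_idx[c, slot] = p
            out_dist[c, slot] = d
            out_prov[c, slot] = prov

    if short_rows:
        warnings.warn(
            f"{len(short_rows)} merged rows have fewer than K={K} neighbors "
            f"(e.g. {list(short_rows[:3])})",
            PiWarning,
        )
    return MergedGraph(
        cell_ids=parent_graph.cell_ids.copy(),
        K=K,
        indices=out_idx,
        distances=out_dist,
        provenance=out_prov,
    )


def embed_merged(merged: NeighborGraph, config: ReprojectionConfig) -> np.ndarray:
    """2-D layout from a (merged) neighbor graph used as precomputed KNN.

    The directed neighbor lists are handed to the standard fuzzy-union
    simplicial-set construction and layout; neighbors are never recomputed
    from coordinates.  Deterministic given ``config.seed``.
    """
    n = merged.n_cells
    lengths = merged.row_lengths()
    if (lengths == 0).any():
        bad = list(merged.cell_ids[lengths == 0][:5])
        raise StructureError(f"cells with empty neighbor lists cannot be embedded: {bad}")
    K = merged.K
    knn_i = np.hstack([np.arange(n, dtype=np.int64)[:, None], merged.indices]).astype(np.int32)
    knn_d = np.hstack([np.zeros((n, 1)), merged.distances]).astype(np.float32)
    knn_d[~np.isfinite(knn_d)] = np.inf

    params = dict(config.embed_params)
    min_dist = params.pop("min_dist", 0.1)
    spread = params.pop("spread", 1.0)
    n_epochs = params.pop("n_epochs", 200)
    negative_sample_rate = params.pop("negative_sample_rate", 5)
    init = params.pop("init", "spectral")
    if params:
        raise ParameterError(f"unknown embed_params: {sorted(params)}")

    a, b = find_ab_params(spread, min_dist)
    dummy = np.zeros((n, 1), dtype=np.float32)
    graph, _, _ = fuzzy_simplicial_set(
        X=dummy,
        n_neighbors=K + 1,
        random_state=check_random_state(config.seed),
        metric="precomputed",
        knn_indices=knn_i,
        knn_dists=knn_d,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="umap")
        warnings.filterwarnings("ignore", module="scipy")
        emb, _ = simplicial_set_embedding(
            dummy,
            graph,
            2,
            1.0,
            a,
            b,
            1.0,
            negative_sample_rate,
            n_epochs,
            init,
            check_random_state(config.seed),
            "euclidean",
            {},
            False,
            {},
            False,
            parallel=False,
            verbose=False,
        )
    emb = np.asarray(emb, dtype=np.float64)
    if not np.isfinite(emb).all():
        raise StructureError("embedding produced non-finite coordinates")
    return emb


def _graph_for(pi: PiObject, config: ReprojectionConfig) -> NeighborGraph:
    """The object's neighbor graph for merging: its own re-projected graph if
    it has children (computed recursively), else a fresh exact KNN graph."""
    if pi.children:
        reproject(pi, children=list(pi.children), config=config, embed=False)
        return pi.neighbor_graphs["reprojected"]
    return build_knn(pi, reduction=_child_reduction(pi, config), K=config.K)


def _child_reduction(pi: PiObject, config: ReprojectionConfig) -> str:
    if config.reduction is not None and config.reduction in pi.reductions:
        return config.reduction
    return _pick_reduction(pi, None)


def reproject(
    root: PiObject,
    children: Optional[Iterable[str]] = None,
    config: Optional[ReprojectionConfig] = None,
    embed: bool = True,
) -> PiObject:
    """Run the full re-projection pipeline on ``root``.

    Builds the parent KNN graph, recursively obtains each named child's graph
    (a child with its own children is re-projected first and contributes its
    merged graph), rescales child distances, merges under the w rule, and
    stores the result under ``neighbor_graphs["reprojected"]`` and — when
    ``embed`` is true — the 2-D layout under ``reductions["reprojected.umap"]``.
    Returns ``root``.
    """
    config = config or ReprojectionConfig()
    names = list(children) if children is not None else list(root.children)
    unknown = [nm for nm in names if nm not in root.children]
    if unknown:
        raise MissingReductionError(f"children not attached to root: {unknown}")

    def staged(stage, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as e:
            raise type(e)(f"[{stage}] {e}") from e

    parent_graph = staged(
        "build_knn", build_knn, root, reduction=config.reduction, K=config.K
    )
    scaled: dict[str, tuple] = {}
    for nm in names:
        link = root.children[nm]
        child_graph = staged(f"child_graph:{nm}", _graph_for, link.child, config)
        scaled[nm] = (
            staged(f"rescale:{nm}", rescale_child_distances, parent_graph, child_graph, link),
            link,
        )
    if scaled:
        merged = staged(
            "merge_neighbors",
            merge_neighbors,
            parent_graph,
            scaled,
            config,
            root.cells["cluster"],
        )
    else:
        merged = MergedGraph(
            cell_ids=parent_graph.cell_ids.copy(),
            K=parent_graph.K,
            indices=parent_graph.indices.copy(),
            distances=parent_graph.distances.copy(),
        )
    root.neighbor_graphs["reprojected"] = merged
    if embed:
        root.adata.obsm["reprojected.umap"] = staged("embed_merged", embed_merged, merged, config)
    return root
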