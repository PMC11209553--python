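"""Independent brute-force reference implementations used as oracles.

Everything here is written straight from the definitions, favouring clarity
over speed, and deliberately shares no code with the package's production
paths: exhaustive pairwise distances for KNN and silhouette, plain-Python
bookkeeping for the neighbor-list merge.
"""

from __future__ import annotations

import numpy as np

from screproject.neighbors import MergedGraph, NeighborGraph, ReprojectionConfig


def brute_knn(X: np.ndarray, K: int):
    """All-pairs exact KNN: returns (indices, distances), self excluded,
    ties broken by neighbor position."""
    X = np.asarray(X, dtype=np.float64)
    n = len(X)
    idx_out, d_out = [], []
    for i in range(n):
        cand = []
        for j in range(n):
            if j == i:
                continue
            d = float(np.sqrt(((X[i] - X[j]) ** 2).sum()))
            cand.append((d, j))
        cand.sort()
        idx_out.append([j for _, j in cand[:K]])
        d_out.append([d for d, _ in cand[:K]])
    return np.array(idx_out), np.array(d_out)


def brute_scale_factor(parent_graph, child_graph, member_ids) -> float:
    """Mean parent distance over edges internal to the member set divided by
    the mean child distance."""
    member = set(member_ids)
    child_d = [
        d
        for row_i, row_d in zip(child_graph.indices, child_graph.distances)
        for j, d in zip(row_i, row_d)
        if j >= 0
    ]
    a_c = sum(child_d) / len(child_d)
    internal = []
    touching = []
    for i in range(parent_graph.n_cells):
        for j, d in zip(parent_graph.indices[i], parent_graph.distances[i]):
            if j < 0:
                continue
            src_in = parent_graph.cell_ids[i] in member
            dst_in = parent_graph.cell_ids[j] in member
            if src_in and dst_in:
                internal.append(d)
            if src_in or dst_in:
                touching.append(d)
    if internal:
        a_p = sum(internal) / len(internal)
    elif touching:
        a_p = sum(touching) / len(touching)
    else:
        a_p = a_c
    return a_p / a_c


def brute_merge(parent_graph, scaled_children, config, parent_labels) -> MergedGraph:
    """Straight-line transcription of the merge rule.

    For a cell in subcluster S: keep its nearest parent neighbors from a
    different parent-level cluster (rank order, at most K1 = round(w*K)),
    fill the remaining slots from S's scaled graph, keep the smaller copy of
    any duplicate edge, sort by (distance, parent-first, neighbor order) and
    truncate to K.  Other cells keep their parent rows.
    """
    K = parent_graph.K
    w = config.w
    K1 = int(np.floor(w * K + 0.5))
    labels = [str(x) for x in parent_labels]
    id2pos = {c: i for i, c in enumerate(parent_graph.cell_ids)}

    membership = {}
    for name, (graph, link) in scaled_children.items():
        ids = link.cell_ids if hasattr(link, "cell_ids") else link
        for c in ids:
            assert str(c) not in membership, "children must be disjoint"
            membership[str(c)] = name

    n = parent_graph.n_cells
    out_i = np.full((n, K), -1, dtype=np.int64)
    out_d = np.full((n, K), np.inf)
    out_p = np.full((n, K), "", dtype=object)

    for i in range(n):
        cid = str(parent_graph.cell_ids[i])
        if cid not in membership:
            for s in range(K):
                j = parent_graph.indices[i, s]
                if j >= 0:
                    out_i[i, s] = j
                    out_d[i, s] = parent_graph.distances[i, s]
                    out_p[i, s] = "parent"
            continue
        name = membership[cid]
        graph, _link = scaled_children[name]
        # step 1: cross-cluster parent edges in rank order, capped at K1
        step1 = []
        for j, d in zip(parent_graph.indices[i], parent_graph.distances[i]):
            if j < 0 or len(step1) >= K1:
                break
            if labels[j] != labels[i]:
                step1.append([int(j), float(d), "parent"])
        r = len(step1)
        chosen = {e[0]: e for e in step1}
        # step 2: K - r nearest subcluster neighbors, duplicates keep the min
        row = [str(c) for c in graph.cell_ids].index(cid)
        quota = K - r
        for j, d in zip(graph.indices[row], graph.distances[row]):
            if j < 0:
                break
            p = id2pos[str(graph.cell_ids[j])]
            if p in chosen:
                if d < chosen[p][1]:
                    chosen[p][1] = float(d)
                    chosen[p][2] = f"child:{name}"
                continue
            if quota <= 0:
                continue
            chosen[p] = [p, float(d), f"child:{name}"]
            quota -= 1
        ordered = sorted(
            chosen.values(), key=lambda e: (e[1], 0 if e[2] == "parent" else 1, e[0])
        )[:K]
        for s, (p, d, tag) in enumerate(ordered):
            out_i[i, s] = p
            out_d[i, s] = d
            out_p[i, s] = tag
    return MergedGraph(
        cell_ids=parent_graph.cell_ids.copy(),
        K=K,
        indices=out_i,
        distances=out_d,
        provenance=out_p,
    )


def brute_silhouette(X: np.ndarray, labels) -> np.ndarray:
    """Exhaustive silhouette widths; singleton clusters get 0."""
    X = np.asarray(X, dtype=np.float64)
    labels = [str(x) for x in labels]
    n = len(X)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = np.sqrt(((X[i] - X[j]) ** 2).sum())
    widths = np.zeros(n)
    uniq = sorted(set(labels))
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            widths[i] = 0.0
            continue
        a = D[i, same].mean()
        b = min(
            D[i, [j for j in range(n) if labels[j] == k]].mean()
            for k in uniq
            if k != labels[i]
        )
        widths[i] = (b - a) / max(a, b)
    return widths


def random_merge_instance(seed: int, n_max: int = 100):
    """A randomized merge problem: parent graph over clustered 2-D points,
    one or two disjoint child subsets with their own graphs on fresh
    coordinates.  Returns (parent_graph, scaled_children, labels)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(30, n_max + 1))
    n_clusters = int(rng.integers(2, 5))
    centers = rng.normal(scale=4.0, size=(n_clusters, 2))
    labels = rng.integers(0, n_clusters, size=n)
    X = centers[labels] + rng.normal(scale=1.5, size=(n, 2))
    K = int(rng.integers(3, 9))
    cell_ids = np.array([f"c{i}" for i in range(n)], dtype=object)
    idx, dist = brute_knn(X, K)
    parent = NeighborGraph(cell_ids=cell_ids, K=K, indices=idx, distances=dist)

    n_children = int(rng.integers(1, 3))
    child_clusters = rng.permutation(n_clusters)[:n_children]
    scaled = {}
    for ci, kc in enumerate(child_clusters):
        members = np.flatnonzero(labels == kc)
        if len(members) <= K:
            continue
        Y = rng.normal(scale=2.0, size=(len(members), 3))
        cidx, cdist = brute_knn(Y, K)
        graph = NeighborGraph(
            cell_ids=cell_ids[members].copy(), K=K, indices=cidx, distances=cdist
        )
        scaled[f"sub{ci}"] = (graph, list(cell_ids[members]))
    return parent, scaled, [str(x) for x in labels]
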