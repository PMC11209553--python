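"""Directory serialization of PiObject trees.

One directory per object, all plain text, so a nested subclustering is a
directory tree that can be diffed and inspected:

    <dir>/
      matrix.mtx          genes × cells sparse counts (MatrixMarket)
      features.tsv        gene ids
      barcodes.tsv        cell ids, canonical order
      cells.tsv           cell metadata (cell_id, sample_id, group, cluster, ...)
      reductions/<name>.csv       cell_id + coordinate columns
      graphs/<name>.tsv           cell_id_from, cell_id_to, distance[, provenance]
      slots/exp_freq.tsv, markers.tsv, ds.tsv, cell_prop/<key>.tsv
      children/<name>/    nested PiObject directories
      manifest.json       names, K per graph, child list
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .errors import StructureError
from .neighbors import MergedGraph, NeighborGraph
from .pi import PiObject, attach_subcluster, create_pi
from .quantify import ProportionTable

__all__ = ["write_pi", "read_pi", "write_graph", "read_graph", "write_embedding"]


def write_graph(graph: NeighborGraph, path) -> None:
    """Sparse triplet TSV; rows in canonical cell order, neighbors in rank
    order, so the graph round-trips exactly."""
    rows = []
    has_prov = isinstance(graph, MergedGraph)
    for i in range(graph.n_cells):
        for slot in range(graph.K):
            j = graph.indices[i, slot]
            if j < 0:
                continue
            row = {
                "cell_id_from": graph.cell_ids[i],
                "cell_id_to": graph.cell_ids[j],
                "distance": repr(float(graph.distances[i, slot])),
            }
            if has_prov:
                row["provenance"] = graph.provenance[i, slot]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_graph(path, cell_ids, K: int) -> NeighborGraph:
    df = pd.read_csv(
        path, sep="\t", dtype={"cell_id_from": str, "cell_id_to": str},
        float_precision="round_trip",
    )
    cell_ids = np.asarray(cell_ids, dtype=object)
    pos = {c: i for i, c in enumerate(cell_ids)}
    n = len(cell_ids)
    indices = np.full((n, K), -1, dtype=np.int64)
    distances = np.full((n, K), np.inf)
    has_prov = "provenance" in df.columns
    prov = np.full((n, K), "", dtype=object)
    slot = {c: 0 for c in cell_ids}
    for row in df.itertuples(index=False):
        i = pos[row.cell_id_from]
        s = slot[row.cell_id_from]
        indices[i, s] = pos[row.cell_id_to]
        distances[i, s] = float(row.distance)
        if has_prov:
            prov[i, s] = row.provenance
        slot[row.cell_id_from] = s + 1
    if has_prov:
        return MergedGraph(cell_ids=cell_ids, K=K, indices=indices, distances=distances, provenance=prov)
    return NeighborGraph(cell_ids=cell_ids, K=K, indices=indices, distances=distances)


def write_embedding(coords, cell_ids, path) -> None:
    """2-D embedding as CSV (cell_id, x, y)."""
    coords = np.asarray(coords)
    pd.DataFrame({"cell_id": cell_ids, "x": coords[:, 0], "y": coords[:, 1]}).to_csv(
        path, index=False
    )


def write_pi(pi: PiObject, path) -> None:
    """Write a PiObject (and, recursively, its children) to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = sp.csc_matrix(pi.adata.X.T)  # genes × cells
    if np.all(X.data == np.round(X.data)):
        X = X.astype(np.int64)
    mmwrite(path / "matrix.mtx", X)
    pd.Series(pi.genes).to_csv(path / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(pi.cell_ids).to_csv(path / "barcodes.tsv", sep="\t", index=False, header=False)
    pi.cells.to_csv(path / "cells.tsv", sep="\t", index=False)

    (path / "reductions").mkdir(exist_ok=True)
    for name, mat in pi.reductions.items():
        mat = np.asarray(mat)
        df = pd.DataFrame(mat, columns=[f"dim{i}" for i in range(mat.shape[1])])
        df.insert(0, "cell_id", pi.cell_ids)
        df.to_csv(path / "reductions" / f"{name}.csv", index=False, float_format="%.17g")

    (path / "graphs").mkdir(exist_ok=True)
    graph_meta = {}
    for name, graph in pi.neighbor_graphs.items():
        write_graph(graph, path / "graphs" / f"{name}.tsv")
        graph_meta[name] = {"K": int(graph.K), "merged": isinstance(graph, MergedGraph)}

    slots_dir = path / "slots"
    slots_dir.mkdir(exist_ok=True)
    for key in ("exp_freq", "markers", "ds"):
        val = pi.slots.get(key)
        if val is not None and len(val):
            val.to_csv(slots_dir / f"{key}.tsv", sep="\t", index=(key == "exp_freq"))
    props = pi.slots.get("cell_prop") or {}
    if props:
        (slots_dir / "cell_prop").mkdir(exist_ok=True)
        for key, tab in props.items():
            safe = key.replace("/", "_").replace(":", "__")
            tab.to_tsv(slots_dir / "cell_prop" / f"{safe}.tsv")

    children = {}
    for name, link in pi.children.items():
        write_pi(link.child, path / "children" / name)
        children[name] = {"path": f"children/{name}", "n_cells": len(link.cell_ids)}

    manifest = {
        "name": pi.name,
        "n_cells": int(pi.n_cells),
        "n_genes": int(pi.adata.n_vars),
        "reductions": list(pi.reductions.keys()),
        "graphs": graph_meta,
        "slots": {
            "exp_freq": pi.slots.get("exp_freq") is not None,
            "markers": pi.slots.get("markers") is not None,
            "ds": pi.slots.get("ds") is not None,
            "cell_prop": sorted(props),
        },
        "children": children,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_pi(path) -> PiObject:
    """Read a PiObject directory tree written by :func:`write_pi`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    X = sp.csr_matrix(mmread(path / "matrix.mtx"))  # genes × cells
    genes = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(path / "cells.tsv", sep="\t", dtype=str)
    if list(cells["cell_id"]) != list(barcodes):
        raise StructureError(f"{path}: cells.tsv order disagrees with barcodes.tsv")

    reductions = {}
    for name in manifest["reductions"]:
        df = pd.read_csv(
            path / "reductions" / f"{name}.csv", dtype={"cell_id": str},
            float_precision="round_trip",
        )
        if list(df["cell_id"]) != list(barcodes):
            raise StructureError(f"{path}: reduction {name!r} cell order mismatch")
        reductions[name] = df.drop(columns="cell_id").to_numpy(dtype=np.float64)

    pi = create_pi(X, cells, reductions=reductions, genes=genes, name=manifest.get("name"))

    for name, meta in manifest.get("graphs", {}).items():
        pi.neighbor_graphs[name] = read_graph(
            path / "graphs" / f"{name}.tsv", pi.cell_ids, K=meta["K"]
        )

    slots_dir = path / "slots"
    if (slots_dir / "exp_freq.tsv").exists():
        pi.slots["exp_freq"] = pd.read_csv(slots_dir / "exp_freq.tsv", sep="\t", index_col=0)
    for key in ("markers", "ds"):
        f = slots_dir / f"{key}.tsv"
        if f.exists():
            pi.slots[key] = pd.read_csv(f, sep="\t", dtype={"cluster": str, "gene": str})
    prop_dir = slots_dir / "cell_prop"
    if prop_dir.is_dir():
        for f in sorted(prop_dir.glob("*.tsv")):
            key = f.stem.replace("__", ":")
            pi.slots["cell_prop"][key] = ProportionTable.from_tsv(f)

    for name, meta in manifest.get("children", {}).items():
        child = read_pi(path / meta["path"])
        attach_subcluster(pi, name, list(child.cell_ids), child)
    return pi
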