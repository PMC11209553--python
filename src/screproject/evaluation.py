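"""Embedding quality via per-cluster average silhouette width.

The silhouette width of cell i is s(i) = (b(i) − a(i)) / max(a(i), b(i)),
where a(i) is the mean Euclidean distance to the other cells of its own
cluster and b(i) the smallest mean distance to any other cluster; s(i) lies
in [−1, 1] (higher = better separated).  Widths are computed exactly on all
cells of the 2-D embedding; cells in singleton clusters receive width 0 (a
documented convention, with a warning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples

from .errors import ParameterError, PiWarning, StructureError
from .pi import PiObject

__all__ = ["SilhouetteReport", "silhouette", "compare_embeddings"]


@dataclass
class SilhouetteReport:
    """Per-cluster average silhouette widths on a named embedding."""

    embedding: str
    label_level: str
    per_cluster: pd.DataFrame = field(repr=False)
    overall: float = 0.0
    widths: pd.Series = field(default=None, repr=False)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# embedding={self.embedding} labels={self.label_level} overall={self.overall:.6g}\n")
            self.per_cluster.to_csv(fh, sep="\t", index=False)


def silhouette(coords, labels, embedding: str = "embedding", label_level: str = "labels") -> SilhouetteReport:
    """Exact silhouette widths of a labelling on 2-D (or d-D) coordinates.

    Requires at least two distinct labels.  Cells in singleton clusters get
    width 0 with a warning.
    """
    coords = np.asarray(coords, dtype=np.float64)
    labels = pd.Series(labels).astype(str).reset_index(drop=True)
    if coords.shape[0] != len(labels):
        raise StructureError(
            f"{coords.shape[0]} coordinate rows for {len(labels)} labels"
        )
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ParameterError("silhouette requires at least 2 distinct labels")
    singletons = counts.index[counts == 1]
    if len(singletons) > 0:
        warnings.warn(
            f"singleton clusters get silhouette width 0: {list(singletons)}", PiWarning
        )
    widths = np.zeros(len(labels))
    multi = ~labels.isin(singletons).to_numpy()
    if counts[counts > 1].size >= 2:
        widths[multi] = silhouette_samples(coords[multi], labels[multi].to_numpy())
    per = (
        pd.DataFrame({"cluster": labels, "width": widths})
        .groupby("cluster", sort=True, observed=True)
        .agg(n_cells=("width", "size"), mean_width=("width", "mean"))
        .reset_index()
    )
    return SilhouetteReport(
        embedding=embedding,
        label_level=label_level,
        per_cluster=per,
        overall=float(widths.mean()),
        widths=pd.Series(widths, name="width"),
    )


def compare_embeddings(
    pi: PiObject, before: str, after: str, labels, label_level: str = "labels",
    restrict_to=None,
) -> pd.DataFrame:
    """Per-cluster silhouette deltas between two reductions of one object.

    ``labels`` is a per-cell label vector aligned with the object's cells (or
    a Series keyed by cell id).  ``restrict_to`` optionally limits the
    comparison to a boolean mask or list of cell ids (e.g. only subclustered
    cells, or only cells left untouched).  Returns a frame with per-cluster
    mean widths before and after, the delta (after − before) and an
    ``improved`` flag; the overall row is labelled ``__overall__``.
    """
    for name in (before, after):
        if name not in pi.reductions:
            raise StructureError(f"reduction {name!r} not found")
    lab = pd.Series(labels)
    if not lab.index.equals(pd.RangeIndex(len(lab))):
        lab = lab.reindex(pi.adata.obs_names)
        if lab.isna().any():
            raise StructureError("labels do not cover all cells of the object")
    lab = lab.astype(str).to_numpy()
    mask = np.ones(pi.n_cells, dtype=bool)
    if restrict_to is not None:
        restrict_to = np.asarray(restrict_to)
        if restrict_to.dtype == bool:
            mask = restrict_to
        else:
            mask = np.isin(pi.cell_ids, restrict_to)
    ra = silhouette(np.asarray(pi.reductions[before])[mask], lab[mask], before, label_level)
    rb = silhouette(np.asarray(pi.reductions[after])[mask], lab[mask], after, label_level)
    merged = ra.per_cluster.merge(rb.per_cluster, on="cluster", suffixes=("_before", "_after"))
    merged["delta"] = merged["mean_width_after"] - merged["mean_width_before"]
    merged["improved"] = merged["delta"] > 0
    overall = pd.DataFrame(
        [
            {
                "cluster": "__overall__",
                "n_cells_before": int(mask.sum()),
                "mean_width_before": ra.overall,
                "n_cells_after": int(mask.sum()),
                "mean_width_after": rb.overall,
                "delta": rb.overall - ra.overall,
                "improved": rb.overall > ra.overall,
            }
        ]
    )
    return pd.concat([merged, overall], ignore_index=True)
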