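"""Hierarchical post-integration ("Pi") data model.

A :class:`PiObject` couples one clustering level of a single-cell dataset —
expression matrix, per-cell metadata, low-dimensional reductions, neighbor
graphs and analysis slots — with links to a parent object (the population it
was subset from) and named child objects (subclusterings of some of its
cells).  A two-level analysis such as PBMC → T cells → CD4 memory cells is
therefore a tree of PiObjects, and :func:`resolve_labels` flattens that tree
into one per-cell labelling at any requested depth.

The expression matrix is stored internally as an :class:`anndata.AnnData`
(cells × genes, sparse); the public accessors present the genes × cells
orientation used by the file formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .errors import (
    DuplicateNameError,
    LabelAmbiguityError,
    MembershipError,
    MetadataError,
    StructureError,
)

REQUIRED_CELL_COLUMNS = ("cell_id", "sample_id", "group", "cluster")


def _as_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a cell-metadata table.

    The returned frame is indexed by ``cell_id`` and keeps the required
    columns first, preserving input row order.
    """
    cells = cells.copy()
    if "cell_id" not in cells.columns:
        cells.insert(0, "cell_id", cells.index.astype(str))
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise MetadataError(f"cell table is missing required columns: {missing}")
    for col in REQUIRED_CELL_COLUMNS:
        if cells[col].isna().any():
            bad = cells.loc[cells[col].isna(), "cell_id"].tolist()[:5]
            raise MetadataError(f"column {col!r} has missing values (e.g. cells {bad})")
        cells[col] = cells[col].astype(str)
    if cells["cell_id"].duplicated().any():
        dup = cells.loc[cells["cell_id"].duplicated(), "cell_id"].tolist()[:5]
        raise MetadataError(f"duplicate cell_id values: {dup}")
    cells.index = pd.Index(cells["cell_id"], name="cell_id")
    return cells


@dataclass
class SubclusterLink:
    """Mapping of a child object's cells into its parent.

    ``label_map`` carries the child's cluster label for every linked cell,
    keyed by parent cell id.
    """

    name: str
    cell_ids: list
    child: "PiObject"
    label_map: pd.Series = field(repr=False)


class PiObject:
    """One clustering level of a single-cell dataset plus its analysis state.

    Parameters
    ----------
    adata
        Cells × genes AnnData; ``obs`` must contain the required metadata
        columns (``cell_id``, ``sample_id``, ``group``, ``cluster``).
    name
        Optional human-readable name (used in manifests and error messages).
    """

    def __init__(self, adata: AnnData, name: Optional[str] = None):
        self.adata = adata
        self.name = name
        self.neighbor_graphs: dict = {}
        #: analysis slots: exp_freq, markers, ds, cell_prop
        self.slots: dict = {"exp_freq": None, "markers": None, "ds": None, "cell_prop": {}}
        self.parent: Optional[PiObject] = None
        self.children: dict[str, SubclusterLink] = {}
        self._validate()

    # -- basic accessors ---------------------------------------------------
    @property
    def cells(self) -> pd.DataFrame:
        """Cell metadata table, indexed by cell_id, in canonical cell order."""
        return self.adata.obs

    @property
    def cell_ids(self) -> np.ndarray:
        return self.adata.obs["cell_id"].to_numpy()

    @property
    def n_cells(self) -> int:
        return self.adata.n_obs

    @property
    def genes(self) -> pd.Index:
        return self.adata.var_names

    @property
    def expression(self) -> sp.csc_matrix:
        """Genes × cells sparse expression matrix."""
        return sp.csc_matrix(self.adata.X.T)

    @property
    def reductions(self) -> Mapping[str, np.ndarray]:
        return self.adata.obsm

    def _validate(self) -> None:
        obs = self.adata.obs
        missing = [c for c in REQUIRED_CELL_COLUMNS if c not in obs.columns]
        if missing:
            raise MetadataError(f"cell table is missing required columns: {missing}")
        for key in self.adata.obsm:
            mat = np.asarray(self.adata.obsm[key])
            if mat.shape[0] != self.adata.n_obs:
                raise StructureError(
                    f"reduction {key!r} has {mat.shape[0]} rows for {self.adata.n_obs} cells"
                )

    # -- hierarchy ---------------------------------------------------------
    def positions_of(self, cell_ids: Iterable[str]) -> np.ndarray:
        """Row positions of the given cell ids (canonical order of this object)."""
        lookup = pd.Series(np.arange(self.n_cells), index=self.adata.obs_names)
        ids = pd.Index(cell_ids)
        unknown = ids.difference(lookup.index)
        if len(unknown) > 0:
            raise MembershipError(
                f"cell ids not present in {self.name or 'object'}: {list(unknown[:5])}"
            )
        return lookup.loc[ids].to_numpy()

    def subcluster_cell_ids(self) -> set:
        """Ids of cells covered by at least one child."""
        out: set = set()
        for link in self.children.values():
            out.update(link.cell_ids)
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PiObject({self.name or 'unnamed'}: {self.n_cells} cells × "
            f"{self.adata.n_vars} genes, {len(self.children)} children)"
        )


def create_pi(
    expression,
    cells: pd.DataFrame,
    reductions: Optional[Mapping[str, np.ndarray]] = None,
    genes: Optional[Iterable[str]] = None,
    name: Optional[str] = None,
) -> PiObject:
    """Build a PiObject from a genes × cells matrix and a cell table.

    Parameters
    ----------
    expression
        Genes × cells matrix (dense, sparse, or DataFrame with gene index).
    cells
        Cell metadata with columns ``cell_id``, ``sample_id``, ``group``,
        ``cluster``; row order defines the object's canonical cell order.
    reductions
        Named per-cell coordinate matrices (cells × d), e.g. ``{"pca": ...}``.
    genes
        Gene identifiers (required unless ``expression`` is a DataFrame).
    """
    if isinstance(expression, pd.DataFrame):
        genes = expression.index.astype(str)
        expression = expression.to_numpy()
    X = sp.csr_matrix(expression)
    cells = _as_cell_table(cells)
    if X.shape[1] != len(cells):
        raise StructureError(
            f"expression has {X.shape[1]} cell columns but the cell table has "
            f"{len(cells)} rows"
        )
    if genes is None:
        genes = [f"g{i}" for i in range(X.shape[0])]
    genes = pd.Index([str(g) for g in genes], name="gene")
    if len(genes) != X.shape[0]:
        raise StructureError(
            f"expression has {X.shape[0]} gene rows but {len(genes)} gene ids given"
        )
    if (X.data < 0).any():
        raise StructureError("expression must be nonnegative")
    adata = AnnData(X=X.T.tocsr(), obs=cells, var=pd.DataFrame(index=genes))
    if reductions:
        for key, mat in reductions.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape[0] != adata.n_obs:
                raise StructureError(
                    f"reduction {key!r} has {mat.shape[0]} rows for {adata.n_obs} cells"
                )
            adata.obsm[key] = mat
    return PiObject(adata, name=name)


def attach_subcluster(
    parent: PiObject, name: str, cell_ids: Iterable[str], child: PiObject
) -> PiObject:
    """Attach ``child`` (a subclustering of ``cell_ids``) to ``parent``.

    The child's cells must be exactly ``cell_ids`` (any order).  The link
    records the child's cluster label per parent cell id; the child's own
    analysis slots are left untouched.  Returns ``parent`` for chaining.
    """
    if name in parent.children:
        raise DuplicateNameError(f"parent already has a child named {name!r}")
    cell_ids = [str(c) for c in cell_ids]
    if len(set(cell_ids)) != len(cell_ids):
        raise MembershipError("duplicate cell ids in subcluster membership list")
    parent.positions_of(cell_ids)  # raises MembershipError on unknown ids
    if set(child.cell_ids) != set(cell_ids):
        extra = sorted(set(child.cell_ids) - set(cell_ids))[:5]
        missing = sorted(set(cell_ids) - set(child.cell_ids))[:5]
        raise MembershipError(
            f"child cells do not match the membership list (extra={extra}, missing={missing})"
        )
    label_map = child.cells["cluster"].copy()
    label_map = label_map.loc[cell_ids]
    link = SubclusterLink(name=name, cell_ids=list(cell_ids), child=child, label_map=label_map)
    parent.children[name] = link
    child.parent = parent
    return parent


def _check_overlaps(root: PiObject, priority: Optional[list]) -> list:
    """Order child links, erroring on overlapping cell sets unless a priority
    order is supplied (earlier names win)."""
    links = list(root.children.values())
    seen: dict = {}
    overlap = set()
    for link in links:
        for cid in link.cell_ids:
            if cid in seen and seen[cid] != link.name:
                overlap.add(cid)
            seen.setdefault(cid, link.name)
    if overlap and priority is None:
        raise LabelAmbiguityError(
            f"{len(overlap)} cells are claimed by multiple children with no "
            f"priority order (e.g. {sorted(overlap)[:5]})",
            cell_ids=sorted(overlap),
        )
    if priority is not None:
        order = {n: i for i, n in enumerate(priority)}
        links.sort(key=lambda l: order.get(l.name, len(order)))
    return links


def resolve_labels(
    root: PiObject, level: "int | str" = "leaf", priority: Optional[list] = None
) -> pd.Series:
    """Flatten the subcluster hierarchy into one per-cell label vector.

    Each cell receives the deepest available label at or above ``level``
    (``level=0`` is the root's own clustering, ``"leaf"`` descends fully).
    Cells never subclustered keep their root cluster label.  Output order is
    the root's canonical cell order.

    Overlapping children raise :class:`LabelAmbiguityError` unless
    ``priority`` (a list of child names, earlier wins) is given.
    """
    if level == "leaf":
        depth = None
    else:
        depth = int(level)
        if depth < 0:
            raise ValueError("level must be 'leaf' or a nonnegative integer")
    labels = root.cells["cluster"].astype(str).copy()
    if depth == 0 or not root.children:
        labels.name = "label"
        return labels
    next_level = "leaf" if depth is None else depth - 1
    # later links are applied first so that earlier (higher-priority) ones win
    for link in reversed(_check_overlaps(root, priority)):
        child_labels = resolve_labels(link.child, next_level, priority=priority)
        # child cell ids are parent cell ids; align to the link's cells
        labels.loc[link.cell_ids] = child_labels.loc[link.cell_ids].to_numpy()
    labels.name = "label"
    return labels
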