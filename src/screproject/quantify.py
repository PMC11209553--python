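"""Quantification of Pi objects: expression frequency, cluster markers,
pseudobulk differential state, and conditional cell-proportion analysis.

Proportions are *conditional*: every proportion is a count ratio against a
caller-chosen reference population (the object itself, any ancestor, or a
labelled subset of an ancestor).  Changing the reference changes the
biological question — e.g. regulatory-T subsets as a fraction of total Tregs,
of total T cells, or of all PBMCs answer three different questions, and a
compartment-wide shift (such as lymphopenia) can make a subset look stable
within its compartment yet significantly changed against the total.

Testing conventions (transparent defaults, pluggable where noted): cluster
markers and unpooled proportion comparisons use the two-sided Wilcoxon
rank-sum test; differential state uses a two-sided Welch t-test on
log2(CPM + 1) pseudobulk profiles.  p-values are Benjamini–Hochberg adjusted
across genes within a cluster (markers, differential state) or across
clusters within one table (proportions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ContainmentError, ParameterError, PiWarning
from .pi import PiObject, resolve_labels

__all__ = [
    "ProportionTable",
    "PseudobulkMatrix",
    "expression_frequency",
    "find_markers",
    "pseudobulk",
    "differential_state",
    "differential_state_all",
    "cell_proportions",
    "test_proportions",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass
class ProportionTable:
    """Per-sample (unpooled) or per-group (pooled) cluster proportions
    relative to a reference population."""

    mode: str
    reference: str
    data: pd.DataFrame = field(repr=False)
    test: Optional[pd.DataFrame] = field(default=None, repr=False)
    params: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        header = "# " + " ".join(
            f"{k}={v}" for k, v in {"mode": self.mode, "reference": self.reference, **self.params}.items()
        )
        with open(path, "w") as fh:
            fh.write(header + "\n")
            self.data.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ProportionTable":
        with open(path) as fh:
            header = fh.readline().strip().lstrip("# ")
            data = pd.read_csv(fh, sep="\t", float_precision="round_trip")
        params = dict(kv.split("=", 1) for kv in header.split())
        mode = params.pop("mode")
        reference = params.pop("reference")
        for col in ("cluster", "group", "sample_id"):
            if col in data.columns:
                data[col] = data[col].astype(str)
        return cls(mode=mode, reference=reference, data=data, params=params)


@dataclass
class PseudobulkMatrix:
    """Genes × (sample, cluster) summed raw counts with column annotations."""

    matrix: pd.DataFrame = field(repr=False)
    annotation: pd.DataFrame = field(repr=False)

    @property
    def total(self) -> float:
        return float(self.matrix.to_numpy().sum())


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------
def _labels_for(pi: PiObject, level) -> pd.Series:
    """Per-cell labels at a level spec: ``"cluster"``/0 = the object's own
    clustering, an integer depth or ``"leaf"`` descends the hierarchy."""
    if level in ("cluster", 0, None):
        return pi.cells["cluster"].astype(str)
    return resolve_labels(pi, level)


def _bh(p: np.ndarray) -> np.ndarray:
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _dense(pi: PiObject) -> np.ndarray:
    X = pi.adata.X
    return np.asarray(X.todense() if sp.issparse(X) else X, dtype=np.float64)


# ---------------------------------------------------------------------------
# expression frequency and markers
# ---------------------------------------------------------------------------
def expression_frequency(pi: PiObject, level="cluster") -> pd.DataFrame:
    """Fraction of cells per cluster with expression strictly above zero.

    Returns a genes × clusters frame with entries in [0, 1]; the result is
    also stored in ``pi.slots["exp_freq"]``.
    """
    labels = _labels_for(pi, level)
    X = sp.csr_matrix(pi.adata.X)
    nz = X.copy()
    nz.data = (nz.data > 0).astype(np.float64)
    out = {}
    for k in sorted(labels.unique()):
        rows = np.flatnonzero((labels == k).to_numpy())
        if len(rows) == 0:  # pragma: no cover - labels come from cells
            warnings.warn(f"cluster {k!r} has no cells; excluded", PiWarning)
            continue
        out[k] = np.asarray(nz[rows].mean(axis=0)).ravel()
    freq = pd.DataFrame(out, index=pi.genes)
    freq.columns.name = "cluster"
    pi.slots["exp_freq"] = freq
    return freq


def find_markers(pi: PiObject, level="cluster") -> pd.DataFrame:
    """One-vs-rest cluster markers by Wilcoxon rank-sum.

    Per gene and cluster: log2 fold change of means (cluster vs rest), raw
    and BH-adjusted p (adjusted across genes within the cluster).  Rows are
    ranked per cluster by adjusted p, then by descending effect.  Clusters
    with fewer than 3 cells are skipped with a warning.  The tidy table is
    stored in ``pi.slots["markers"]``.
    """
    labels = _labels_for(pi, level)
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ParameterError("marker detection requires at least 2 clusters")
    X = _dense(pi)
    eps = 1e-9
    tables = []
    for k in uniq:
        mask = (labels == k).to_numpy()
        if mask.sum() < 3:
            warnings.warn(f"cluster {k!r} has fewer than 3 cells; skipped", PiWarning)
            continue
        a, b = X[mask], X[~mask]
        with np.errstate(invalid="ignore"):
            res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided")
        p = np.nan_to_num(res.pvalue, nan=1.0)
        lfc = np.log2((a.mean(axis=0) + eps) / (b.mean(axis=0) + eps))
        tab = pd.DataFrame(
            {
                "cluster": k,
                "gene": pi.genes,
                "log2fc": lfc,
                "statistic": res.statistic,
                "p": p,
                "p_adj": _bh(p),
            }
        )
        tab = tab.sort_values(["p_adj", "log2fc"], ascending=[True, False], kind="mergesort")
        tab["rank"] = np.arange(1, len(tab) + 1)
        tables.append(tab)
    markers = pd.concat(tables, ignore_index=True)
    pi.slots["markers"] = markers
    return markers


# ---------------------------------------------------------------------------
# pseudobulk differential state
# ---------------------------------------------------------------------------
def pseudobulk(pi: PiObject, level="cluster") -> PseudobulkMatrix:
    """Sum raw counts per gene within each (sample, cluster) cell set."""
    X = sp.csr_matrix(pi.adata.X)
    if np.any(X.data != np.round(X.data)):
        warnings.warn(
            "expression matrix contains non-integer values; pseudobulk expects "
            "raw counts — proceeding with sums",
            PiWarning,
        )
    labels = _labels_for(pi, level)
    cells = pi.cells
    key = cells["sample_id"].astype(str) + ":" + labels
    cols, ann = {}, []
    for col_key, idx in cells.groupby(key.to_numpy(), sort=True).groups.items():
        rows = pi.positions_of(idx)
        cols[col_key] = np.asarray(X[rows].sum(axis=0)).ravel()
        sample = cells.loc[idx[0], "sample_id"]
        ann.append(
            {
                "column": col_key,
                "sample_id": sample,
                "cluster": labels.loc[idx[0]],
                "group": cells.loc[idx[0], "group"],
                "n_cells": len(rows),
            }
        )
    matrix = pd.DataFrame(cols, index=pi.genes)
    annotation = pd.DataFrame(ann).set_index("column").loc[matrix.columns]
    return PseudobulkMatrix(matrix=matrix, annotation=annotation)


def _log_cpm(cols: pd.DataFrame) -> pd.DataFrame:
    depth = cols.sum(axis=0)
    return np.log2(cols.div(depth, axis=1) * 1e6 + 1.0)


def differential_state(
    pb: PseudobulkMatrix, cluster: str, groups: Sequence[str]
) -> pd.DataFrame:
    """Two-group differential state for one cluster on pseudobulk profiles.

    Columns of the cluster are depth-normalised to counts-per-million,
    log2-transformed with pseudocount 1, and compared per gene with a
    two-sided Welch t-test between the sample groups; BH adjustment across
    genes.  ``log2fc`` is mean(groups[0]) − mean(groups[1]).  Requires at
    least 2 samples per group (sample-level replication).
    """
    g1, g2 = groups
    ann = pb.annotation
    in_cluster = ann["cluster"].astype(str) == str(cluster)
    cols1 = ann.index[in_cluster & (ann["group"].astype(str) == str(g1))]
    cols2 = ann.index[in_cluster & (ann["group"].astype(str) == str(g2))]
    if len(cols1) < 2 or len(cols2) < 2:
        raise ParameterError(
            f"differential state in cluster {cluster!r} needs >= 2 samples per "
            f"group; got {len(cols1)} ({g1}) and {len(cols2)} ({g2}). Pseudobulk "
            "testing requires sample-level replication."
        )
    logc = _log_cpm(pb.matrix[list(cols1) + list(cols2)])
    a = logc[cols1].to_numpy()
    b = logc[cols2].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.nan_to_num(p, nan=1.0)
    t = np.nan_to_num(t, nan=0.0)
    out = pd.DataFrame(
        {
            "cluster": str(cluster),
            "gene": pb.matrix.index,
            "log2fc": a.mean(axis=1) - b.mean(axis=1),
            "t": t,
            "p": p,
            "p_adj": _bh(p),
        }
    )
    return out.sort_values(["p_adj", "p"], kind="mergesort").reset_index(drop=True)


def differential_state_all(
    pi: PiObject, groups: Sequence[str], level="cluster"
) -> pd.DataFrame:
    """Run :func:`differential_state` for every eligible cluster and store the
    combined tidy table in ``pi.slots["ds"]``."""
    pb = pseudobulk(pi, level)
    tables = []
    for k in sorted(pb.annotation["cluster"].unique()):
        try:
            tables.append(differential_state(pb, k, groups))
        except ParameterError as e:
            warnings.warn(str(e), PiWarning)
    ds = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    pi.slots["ds"] = ds
    return ds


# ---------------------------------------------------------------------------
# conditional cell proportions
# ---------------------------------------------------------------------------
def cell_proportions(
    obj: PiObject,
    reference: Optional[PiObject] = None,
    reference_labels: Optional[Sequence[str]] = None,
    level="cluster",
    mode: str = "unpooled",
) -> ProportionTable:
    """Cluster proportions of ``obj`` conditioned on a reference population.

    ``reference`` is the denominator population: ``None`` uses ``obj`` itself;
    otherwise any object whose cells are a superset of ``obj``'s (typically an
    ancestor such as the total T cells or the root PBMC object), optionally
    restricted to ``reference_labels`` of its clustering.  ``mode="pooled"``
    aggregates counts per group; ``"unpooled"`` computes per-sample
    proportions suited to between-group testing.  The table is stored under
    ``obj.slots["cell_prop"]`` keyed by reference and mode.
    """
    if mode not in ("pooled", "unpooled"):
        raise ParameterError(f"mode must be 'pooled' or 'unpooled'; got {mode!r}")
    ref = reference if reference is not None else obj
    ref_cells = ref.cells
    if reference_labels is not None:
        keep = ref_cells["cluster"].astype(str).isin([str(x) for x in reference_labels])
        ref_cells = ref_cells.loc[keep]
    ref_ids = set(ref_cells["cell_id"])
    target_ids = set(obj.cell_ids)
    if not target_ids <= ref_ids:
        raise ContainmentError(
            f"reference {ref.name or 'population'} does not contain the target "
            f"cells ({len(target_ids - ref_ids)} outside)"
        )
    labels = _labels_for(obj, level)
    target = obj.cells[["cell_id", "sample_id", "group"]].copy()
    target["cluster"] = labels.to_numpy()
    clusters = sorted(target["cluster"].unique())

    ref_name = ref.name or ("self" if reference is None else "reference")
    if reference_labels is not None:
        ref_name += "[" + ",".join(map(str, reference_labels)) + "]"
    params = {"test": "wilcoxon-rank-sum", "adjust": "BH"}

    if mode == "pooled":
        ref_n = ref_cells.groupby("group", observed=True)["cell_id"].count()
        rows = []
        for g, n_ref in ref_n.items():
            sub = target[target["group"] == g]
            counts = sub.groupby("cluster", observed=True)["cell_id"].count()
            for k in clusters:
                c = int(counts.get(k, 0))
                rows.append(
                    {
                        "cluster": k,
                        "group": g,
                        "count": c,
                        "n_reference": int(n_ref),
                        "proportion": c / n_ref,
                    }
                )
        data = pd.DataFrame(rows)
    else:
        ref_n = ref_cells.groupby("sample_id", observed=True)["cell_id"].count()
        sample_group = ref_cells.drop_duplicates("sample_id").set_index("sample_id")["group"]
        empty = [s for s in sample_group.index if ref_n.get(s, 0) == 0]
        if empty:  # pragma: no cover - counts come from the same table
            warnings.warn(f"samples with zero reference cells dropped: {empty}", PiWarning)
        rows = []
        for s, n_ref in ref_n.items():
            sub = target[target["sample_id"] == s]
            counts = sub.groupby("cluster", observed=True)["cell_id"].count()
            for k in clusters:
                c = int(counts.get(k, 0))
                rows.append(
                    {
                        "cluster": k,
                        "sample_id": s,
                        "group": sample_group[s],
                        "count": c,
                        "n_reference": int(n_ref),
                        "proportion": c / n_ref,
                    }
                )
        data = pd.DataFrame(rows)

    tab = ProportionTable(mode=mode, reference=ref_name, data=data, params=params)
    obj.slots.setdefault("cell_prop", {})[f"{ref_name}:{mode}"] = tab
    return tab


def test_proportions(tab: ProportionTable, groups: Sequence[str]) -> ProportionTable:
    """Two-group comparison of unpooled per-sample proportions.

    Per cluster, a two-sided Wilcoxon rank-sum test on per-sample proportions
    between the two groups; BH adjustment across clusters.  Results are
    attached to ``tab.test`` and returned with the table.
    """
    if tab.mode != "unpooled":
        raise ParameterError(
            "proportion testing requires an unpooled table (per-sample replication)"
        )
    g1, g2 = str(groups[0]), str(groups[1])
    rows = []
    for k, sub in tab.data.groupby("cluster", sort=True, observed=True):
        a = sub.loc[sub["group"].astype(str) == g1, "proportion"].to_numpy()
        b = sub.loc[sub["group"].astype(str) == g2, "proportion"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ParameterError(
                f"cluster {k!r} needs >= 2 samples per group; got {len(a)} and {len(b)}"
            )
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"cluster": k, "statistic": float(stat), "p": float(p)})
    test = pd.DataFrame(rows)
    test["p_adj"] = _bh(test["p"].to_numpy())
    tab.test = test
    tab.params.update({"groups": f"{g1}-vs-{g2}"})
    return tab
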