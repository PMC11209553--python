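"""Synthetic desk-scale fixtures with known ground truth.

The generator emulates the data a multi-level subcluster analysis consumes:

* hierarchical cluster structure — well-separated main clusters, one of which
  contains tight/overlapping subpopulations (including a rare one) that a
  total-cell 2-D embedding does not resolve;
* a multi-sample, two-group design with group-dependent composition;
* sparse over-dispersed counts (gamma–Poisson) with planted marker genes and
  an optional planted group effect for differential-state testing.

Latent cell coordinates are Gaussian blobs in a ``latent_dim``-dimensional
space: main-cluster centres sit far apart, subpopulation centres are offset
by ``sub_separation`` inside their main blob.  The parent object's "pca"
reduction is the latent space plus noise; its "umap" reduction is a 2-D view
that fully separates main clusters but shows subpopulations only through a
weak fixed projection of their offsets — so sublabels overlap there unless
``sub_separation`` is made very large.  Each child object carries a fresh
PCA of its own cells' latent coordinates (times ``child_scale``), emulating
an independently produced subcluster reduction on its own distance scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .errors import PlanError
from .pi import PiObject, attach_subcluster, create_pi
from .quantify import ProportionTable

__all__ = [
    "FixturePlan",
    "generate",
    "default_plan",
    "two_level_plan",
    "ds_plan",
    "lymphopenia_fixture",
    "simulate_unpooled_proportions",
]


@dataclass
class FixturePlan:
    """Ground-truth plan for one synthetic hierarchy.

    ``main_composition``/``sub_composition`` give per-group expected
    proportion vectors (mains; subpopulations within the split main).  The
    last subpopulation is the rare one.
    """

    n_cells: int = 1200
    n_genes: int = 200
    n_main: int = 3
    split_main: int = 0
    main_composition: dict = field(
        default_factory=lambda: {"A": (0.40, 0.35, 0.25), "B": (0.30, 0.40, 0.30)}
    )
    sub_composition: dict = field(
        default_factory=lambda: {"A": (0.50, 0.47, 0.03), "B": (0.38, 0.56, 0.06)}
    )
    n_samples_per_group: int = 8
    latent_dim: int = 10
    main_separation: float = 30.0
    sub_separation: float = 4.0
    n_markers_per_cluster: int = 5
    marker_fold: float = 8.0
    library_size: float = 2000.0
    dispersion: float = 0.5
    child_scale: float = 1.0
    embedding_noise: float = 1.0
    reduction_noise: float = 0.05
    two_level: bool = False
    subsub_separation: float = 3.0
    ds_effect: Optional[dict] = None  # {"gene": int, "cluster": str, "group": str, "fold": float}
    seed: int = 0

    def __post_init__(self):
        for comp in (self.main_composition, self.sub_composition):
            for g, v in comp.items():
                if abs(sum(v) - 1.0) > 1e-9:
                    raise PlanError(f"composition for group {g!r} must sum to 1; got {sum(v)}")
        if self.main_separation <= 0 or self.sub_separation <= 0:
            raise PlanError("separations must be positive")
        if not (0 < min(min(v) for v in self.sub_composition.values()) <= 0.5):
            raise PlanError("subpopulation fractions must lie in (0, 0.5]")
        # expected size of the rarest subpopulation across both groups
        rare = np.mean(
            [
                min(self.sub_composition[g]) * self.main_composition[g][self.split_main]
                for g in self.sub_composition
            ]
        )
        if rare * self.n_cells < 5:
            raise PlanError(
                f"rarest subpopulation expects {rare * self.n_cells:.1f} cells (< 5); "
                "increase n_cells or the rare fraction"
            )


def default_plan(seed: int = 0, **overrides) -> FixturePlan:
    """The standard fixture: 3 main clusters, one split into two overlapping
    subpopulations plus a rare (3%) one, 8 + 8 samples."""
    return replace(FixturePlan(seed=seed), **overrides)


def two_level_plan(seed: int = 0, **overrides) -> FixturePlan:
    """Default plan with a second subclustering level under the first
    subpopulation."""
    return replace(FixturePlan(seed=seed, two_level=True), **overrides)


def ds_plan(seed: int = 0, fold: float = 4.0, **overrides) -> FixturePlan:
    """Default plan with a planted differential-state effect: gene 0 is
    ``fold``-times higher in group B cells of the split main cluster
    (6 vs 6 samples)."""
    return replace(
        FixturePlan(
            seed=seed,
            n_samples_per_group=6,
            ds_effect={"gene": 0, "cluster": "M0", "group": "B", "fold": fold},
        ),
        **overrides,
    )


def _leaf_names(plan: FixturePlan) -> tuple[list, dict]:
    """Leaf cluster names and {group: leaf probability vector}."""
    mains = [f"M{i}" for i in range(plan.n_main)]
    subs = [f"M{plan.split_main}.S{j}" for j in range(len(next(iter(plan.sub_composition.values()))))]
    leaves = []
    for i, m in enumerate(mains):
        leaves.extend(subs if i == plan.split_main else [m])
    probs = {}
    for g in plan.main_composition:
        p = []
        for i in range(plan.n_main):
            pm = plan.main_composition[g][i]
            if i == plan.split_main:
                p.extend(pm * np.asarray(plan.sub_composition[g]))
            else:
                p.append(pm)
        probs[g] = np.asarray(p)
    return leaves, probs


def generate(plan: Optional[FixturePlan] = None) -> tuple[PiObject, dict]:
    """Generate a PiObject hierarchy plus ground-truth tables.

    Returns ``(root, truth)`` where ``truth`` contains the per-cell truth
    table (``cells``: cell_id, sample_id, group, main, sub, leaf), the
    planned per-group leaf composition (``planned_composition``), the planted
    marker map (``markers``), the child's coordinate scale
    (``child_scale``) and the plan itself.
    """
    plan = plan or FixturePlan()
    rng = np.random.default_rng(plan.seed)
    leaves, probs = _leaf_names(plan)
    mains = [f"M{i}" for i in range(plan.n_main)]
    groups = sorted(plan.main_composition)

    # --- per-sample cell assignment -------------------------------------
    samples = [(f"{g}{j}", g) for g in groups for j in range(plan.n_samples_per_group)]
    base = plan.n_cells // len(samples)
    sizes = [base + (1 if i < plan.n_cells % len(samples) else 0) for i in range(len(samples))]
    rows = []
    for (sid, g), n_s in zip(samples, sizes):
        counts = rng.multinomial(n_s, probs[g])
        for leaf, c in zip(leaves, counts):
            rows.extend({"sample_id": sid, "group": g, "leaf": leaf} for _ in range(c))
    cells = pd.DataFrame(rows)
    # shuffle so cluster order is not confounded with cell order
    cells = cells.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    cells.insert(0, "cell_id", [f"c{i:05d}" for i in range(len(cells))])
    cells["main"] = cells["leaf"].str.split(".").str[0]
    cells["sub"] = np.where(
        cells["main"] == f"M{plan.split_main}", cells["leaf"], cells["main"]
    )

    # --- second-level split of the first subpopulation ------------------
    subsub_parent = f"M{plan.split_main}.S0"
    if plan.two_level:
        in_ss = cells["leaf"] == subsub_parent
        halves = rng.random(int(in_ss.sum())) < 0.5
        new = np.where(halves, f"{subsub_parent}.a", f"{subsub_parent}.b")
        cells.loc[in_ss, "leaf"] = new
    cells["leaf"] = cells["leaf"].astype(str)

    # --- latent coordinates ---------------------------------------------
    d = plan.latent_dim
    centers = {m: np.zeros(d) for m in mains}
    for i, m in enumerate(mains):
        centers[m][i % d] = plan.main_separation * (1 + i // d)
    leaf_set = sorted(cells["leaf"].unique())
    leaf_centers = {}
    for leaf in leaf_set:
        parts = leaf.split(".")
        c = centers[parts[0]].copy()
        if len(parts) >= 2:
            u = rng.normal(size=d)
            c = c + plan.sub_separation * u / np.linalg.norm(u)
        if len(parts) == 3:
            u = rng.normal(size=d)
            c = c + plan.subsub_separation * u / np.linalg.norm(u)
        leaf_centers[leaf] = c
    latent = np.stack([leaf_centers[l] for l in cells["leaf"]]) + rng.normal(size=(len(cells), d))

    # --- parent reductions ----------------------------------------------
    pca = latent + rng.normal(scale=plan.reduction_noise, size=latent.shape)
    # 2-D view: mains on a circle; sub offsets visible only through a weak
    # fixed projection — emulates a total-cell embedding that under-resolves
    # subpopulations
    angle = {m: 2 * np.pi * i / plan.n_main for i, m in enumerate(mains)}
    circ = np.stack(
        [[15 * np.cos(angle[m]), 15 * np.sin(angle[m])] for m in cells["main"]]
    )
    P, _ = np.linalg.qr(rng.normal(size=(d, 2)))
    resid = latent - np.stack([centers[m] for m in cells["main"]])
    umap0 = circ + resid @ P + rng.normal(scale=plan.embedding_noise, size=(len(cells), 2))

    # --- counts: gamma-Poisson with planted markers ----------------------
    clusters_with_markers = mains.copy()
    clusters_with_markers += [l for l in leaf_set if l.count(".") >= 1]
    n_marker_genes = plan.n_markers_per_cluster * len(clusters_with_markers)
    if n_marker_genes > plan.n_genes:
        raise PlanError("not enough genes for the requested markers")
    gene_ids = [f"g{i:04d}" for i in range(plan.n_genes)]
    base_mu = rng.lognormal(mean=0.0, sigma=1.0, size=plan.n_genes)
    marker_rows = []
    marker_of = {}
    gpool = rng.permutation(plan.n_genes)[:n_marker_genes]
    for ci, k in enumerate(clusters_with_markers):
        gs = gpool[ci * plan.n_markers_per_cluster : (ci + 1) * plan.n_markers_per_cluster]
        marker_of[k] = gs
        marker_rows.extend({"cluster": k, "gene": gene_ids[g]} for g in gs)

    mu = np.tile(base_mu, (len(cells), 1))
    for k, gs in marker_of.items():
        if "." in k:
            in_k = cells["leaf"].str.startswith(k).to_numpy()
        else:
            in_k = (cells["main"] == k).to_numpy()
        mu[np.ix_(in_k, gs)] *= plan.marker_fold
    if plan.ds_effect is not None:
        eff = plan.ds_effect
        in_eff = (
            (cells["main" if "." not in eff["cluster"] else "leaf"] == eff["cluster"])
            & (cells["group"] == eff["group"])
        ).to_numpy()
        mu[in_eff, int(eff["gene"])] *= float(eff["fold"])
    mu = mu / mu.sum(axis=1, keepdims=True) * plan.library_size
    shape = 1.0 / plan.dispersion
    lam = rng.gamma(shape, mu * plan.dispersion)
    counts = rng.poisson(lam).astype(np.int64)

    # --- assemble objects -------------------------------------------------
    meta = cells[["cell_id", "sample_id", "group"]].copy()
    meta["cluster"] = cells["main"]
    root = create_pi(
        sp.csr_matrix(counts.T),
        meta,
        reductions={"pca": pca, "umap": umap0},
        genes=gene_ids,
        name="root",
    )

    split_mask = (cells["main"] == f"M{plan.split_main}").to_numpy()
    child_meta = cells.loc[split_mask, ["cell_id", "sample_id", "group"]].copy()
    child_meta["cluster"] = cells.loc[split_mask, "sub"]
    child_latent = latent[split_mask]
    child_pca = PCA(n_components=min(d, split_mask.sum() - 1), random_state=0).fit_transform(
        child_latent
    )
    child_pca = child_pca * plan.child_scale + rng.normal(
        scale=plan.reduction_noise, size=child_pca.shape
    )
    child = create_pi(
        sp.csr_matrix(counts[split_mask].T),
        child_meta,
        reductions={"pca": child_pca},
        genes=gene_ids,
        name=f"M{plan.split_main}.sub",
    )
    attach_subcluster(root, "sub0", list(child_meta["cell_id"]), child)

    if plan.two_level:
        gmask = cells["leaf"].str.startswith(subsub_parent + ".").to_numpy()
        g_meta = cells.loc[gmask, ["cell_id", "sample_id", "group"]].copy()
        g_meta["cluster"] = cells.loc[gmask, "leaf"]
        g_latent = latent[gmask]
        g_pca = PCA(n_components=min(d, gmask.sum() - 1), random_state=0).fit_transform(g_latent)
        g_pca = g_pca + rng.normal(scale=plan.reduction_noise, size=g_pca.shape)
        grand = create_pi(
            sp.csr_matrix(counts[gmask].T),
            g_meta,
            reductions={"pca": g_pca},
            genes=gene_ids,
            name=subsub_parent,
        )
        attach_subcluster(child, "subsub0", list(g_meta["cell_id"]), grand)

    planned = {
        g: pd.Series(probs[g], index=leaves)
        for g in groups
    }
    truth = {
        "cells": cells,
        "planned_composition": planned,
        "planned_main_composition": {
            g: pd.Series(plan.main_composition[g], index=mains) for g in groups
        },
        "markers": pd.DataFrame(marker_rows),
        "child_scale": plan.child_scale,
        "plan": plan,
    }
    return root, truth


# ---------------------------------------------------------------------------
# light-weight simulators for proportion testing
# ---------------------------------------------------------------------------
def simulate_unpooled_proportions(
    seed: int,
    means: dict,
    sd: float = 0.03,
    n_per_group: int = 8,
) -> ProportionTable:
    """Directly simulate an unpooled proportion table.

    ``means`` maps cluster → (mean_A, mean_B); per-sample proportions are
    Gaussian around the group mean (clipped to [0, 1]).  Counts are filled as
    rounded proportions of a nominal 1000-cell reference.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g_i, g in enumerate(("A", "B")):
        for j in range(n_per_group):
            sid = f"{g}{j}"
            for k, (ma, mb) in means.items():
                p = float(np.clip(rng.normal((ma, mb)[g_i], sd), 0.0, 1.0))
                rows.append(
                    {
                        "cluster": k,
                        "sample_id": sid,
                        "group": g,
                        "count": int(round(1000 * p)),
                        "proportion": p,
                    }
                )
    return ProportionTable(
        mode="unpooled",
        reference="simulated",
        data=pd.DataFrame(rows),
        params={"test": "wilcoxon-rank-sum", "adjust": "BH"},
    )


def lymphopenia_fixture(
    seed: int,
    n_per_group: int = 8,
    cells_per_sample: int = 400,
    t_fraction: Optional[dict] = None,
    within_t: tuple = (0.4, 0.6),
    t_fraction_sd: float = 0.03,
) -> tuple[PiObject, PiObject]:
    """A compartment-shrinkage fixture: the T compartment shrinks in group B
    while its internal composition stays constant.

    Mirrors the lymphopenia situation: subset frequencies are stable *within*
    the compartment but drop against the total population.  Returns
    ``(root, t_child)``; the child is attached to the root under ``"T"``.
    """
    t_fraction = t_fraction or {"A": 0.45, "B": 0.18}
    rng = np.random.default_rng(seed)
    rows = []
    for g in ("A", "B"):
        for j in range(n_per_group):
            sid = f"{g}{j}"
            ft = float(np.clip(rng.normal(t_fraction[g], t_fraction_sd), 0.02, 0.95))
            n_t = rng.binomial(cells_per_sample, ft)
            n_naive = rng.binomial(n_t, within_t[0])
            kinds = (
                ["T.naive"] * n_naive
                + ["T.memory"] * (n_t - n_naive)
                + ["other"] * (cells_per_sample - n_t)
            )
            rows.extend({"sample_id": sid, "group": g, "leaf": k} for k in kinds)
    cells = pd.DataFrame(rows)
    cells.insert(0, "cell_id", [f"c{i:05d}" for i in range(len(cells))])
    meta = cells[["cell_id", "sample_id", "group"]].copy()
    meta["cluster"] = np.where(cells["leaf"] == "other", "other", "T")
    n = len(cells)
    expr = sp.random(5, n, density=0.3, random_state=rng.integers(2**31), data_rvs=lambda k: rng.poisson(1.0, k) + 1)
    root = create_pi(expr.tocsr(), meta, name="root")
    t_mask = (meta["cluster"] == "T").to_numpy()
    t_meta = cells.loc[t_mask, ["cell_id", "sample_id", "group"]].copy()
    t_meta["cluster"] = cells.loc[t_mask, "leaf"]
    t_child = create_pi(sp.csr_matrix(expr.tocsc()[:, t_mask]), t_meta, name="T")
    attach_subcluster(root, "T", list(t_meta["cell_id"]), t_child)
    return root, t_child
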