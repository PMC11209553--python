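import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import screproject as srp


@pytest.fixture
def tiny_pi():
    """5 genes × 8 cells, 2 clusters, one 2-D reduction."""
    rng = np.random.default_rng(0)
    expr = rng.poisson(2.0, size=(5, 8))
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(8)],
            "sample_id": ["s1"] * 4 + ["s2"] * 4,
            "group": ["A"] * 4 + ["B"] * 4,
            "cluster": ["k0", "k0", "k0", "k0", "k1", "k1", "k1", "k1"],
        }
    )
    red = {"pca": rng.normal(size=(8, 2))}
    return srp.create_pi(expr, cells, reductions=red, genes=[f"g{i}" for i in range(5)])


def make_pi(coords, clusters, samples=None, groups=None, genes=3, prefix="c", name=None,
            extra_reductions=None, expression=None, seed=0):
    """Small helper: a PiObject from coordinates and labels.

    ``expression`` (genes × cells) overrides the default random counts.
    """
    rng = np.random.default_rng(seed)
    n = len(clusters)
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    cells = pd.DataFrame(
        {
            "cell_id": [f"{prefix}{i}" for i in range(n)],
            "sample_id": samples if samples is not None else ["s1"] * n,
            "group": groups if groups is not None else ["A"] * n,
            "cluster": clusters,
        }
    )
    reductions = {"pca": coords}
    if extra_reductions:
        reductions.update(extra_reductions)
    if expression is None:
        expression = rng.poisson(1.0, size=(genes, n))
    return srp.create_pi(expression, cells, reductions=reductions, name=name)


@pytest.fixture
def toy12():
    """12-cell two-main-cluster toy; main cluster X is subclustered into a/b.

    Parent coordinates put X near the origin and Y at x≈10 so the two mains
    have both within- and cross-cluster neighbors at small K; the child
    carries its own 1-D reduction separating a from b.
    """
    x_coords = np.array(
        [[0.0, 0.0], [1.0, 0.1], [0.5, 1.0], [4.0, 0.0], [4.5, 0.8], [5.0, 0.2]]
    )
    y_coords = np.array(
        [[10.0, 0.0], [10.5, 0.5], [11.0, 0.1], [11.5, 0.9], [12.0, 0.3], [12.5, 0.6]]
    )
    coords = np.vstack([x_coords, y_coords])
    parent = make_pi(coords, ["X"] * 6 + ["Y"] * 6, prefix="c", name="root")
    child_ids = [f"c{i}" for i in range(6)]
    child_coords = np.array([[0.0], [0.2], [0.4], [8.0], [8.2], [8.4]])
    child = make_pi(child_coords, ["a", "a", "a", "b", "b", "b"], prefix="c", name="X.sub")
    srp.attach_subcluster(parent, "Xsub", child_ids, child)
    return parent, child


@pytest.fixture(scope="session")
def fixture600():
    """Default synthetic hierarchy at 600 cells (session-scoped; read-only)."""
    return srp.generate(srp.default_plan(seed=1, n_cells=600))
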