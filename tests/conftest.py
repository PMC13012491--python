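import numpy as np
import pandas as pd
import pytest

from soilcd.io import CountTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    counts = np.array(
        [
            [10, 0, 3],
            [1, 1, 2],
            [5, 9, 0],
        ]
    )
    return CountTable(
        ["A", "B", "C"],
        ["d__Bacteria;p__P1", "d__Bacteria;p__P1", "d__Bacteria;p__P2"],
        ["s1", "s2", "s3"],
        counts,
    )


def make_two_group_table(
    rng,
    n_taxa=100,
    n_per_group=20,
    planted=None,
    depth=(5000, 20000),
    overdispersion=0.5,
):
    """Two-group multinomial count table with optional planted log-fold changes.

    ``planted`` maps taxon index -> lfc added in group 'b'. Returns
    (CountTable, metadata frame with a 'grp' column).
    """
    planted = planted or {}
    base = rng.normal(0.0, 1.0, n_taxa)
    effect = np.zeros(n_taxa)
    for i, lfc in planted.items():
        effect[i] = lfc
    cols, groups = [], []
    for j in range(2 * n_per_group):
        g = "a" if j < n_per_group else "b"
        la = base + (effect if g == "b" else 0.0) + rng.normal(0, overdispersion, n_taxa)
        p = np.exp(la - la.max())
        p /= p.sum()
        cols.append(rng.multinomial(int(rng.integers(depth[0], depth[1])), p))
        groups.append(g)
    table = CountTable(
        [f"T{i:03d}" for i in range(n_taxa)],
        [""] * n_taxa,
        [f"S{j:02d}" for j in range(2 * n_per_group)],
        np.array(cols).T,
    )
    meta = pd.DataFrame(
        {
            "sample_id": table.samples,
            "farm": "f1",
            "plot": "p1",
            "cd_soil": 0.0,
            "treatment": "control",
            "grp": groups,
        }
    )
    return table, meta
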