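"""Diversity and ordination statistics for ASV count tables.

Alpha diversity per sample (observed richness, bias-corrected Chao1,
Shannon entropy in nats), group comparisons by Kruskal–Wallis with Dunn's
post hoc z-tests, Benjamini–Hochberg correction and a compact-letter
display, Bray–Curtis dissimilarities, PERMANOVA by label permutation
(optionally restricted within strata for nested designs), and principal
coordinates with an optional constrained (CAP / distance-based RDA) step.

Chao1 uses the bias-corrected estimator

    chao1 = S_obs + F1 * (F1 - 1) / (2 * (F2 + 1))

(F1 singletons, F2 doubletons), which stays defined when no doubleton is
observed. Bray–Curtis is computed on relative abundances by default because
library sizes in this design span an order of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy.stats import kruskal, norm, rankdata

from .diffabund import bh_adjust
from .io import CountTable

__all__ = [
    "AlphaDiversity",
    "KruskalDunnResult",
    "PermanovaResult",
    "OrdinationResult",
    "alpha_diversity",
    "alpha_diversity_table",
    "kruskal_dunn",
    "bray_curtis",
    "permanova",
    "pcoa",
    "cap_ordination",
    "rarefy_counts",
]


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlphaDiversity:
    sample_id: str
    observed_richness: int
    chao1: float
    shannon: float


def alpha_diversity(counts: np.ndarray, sample_id: str = "") -> AlphaDiversity:
    """Observed richness, bias-corrected Chao1 and Shannon (nats) for one sample."""
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    positive = counts[counts > 0]
    if positive.size == 0:
        raise ValueError(f"sample {sample_id!r} has no positive counts")
    s_obs = int(positive.size)
    f1 = int((positive == 1).sum())
    f2 = int((positive == 2).sum())
    chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    p = positive / positive.sum()
    shannon = float(-(p * np.log(p)).sum())
    return AlphaDiversity(sample_id, s_obs, chao1, shannon)


def alpha_diversity_table(table: CountTable) -> pd.DataFrame:
    rows = [
        alpha_diversity(table.counts[:, j], table.samples[j])
        for j in range(table.n_samples)
    ]
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rows],
            "observed_richness": [r.observed_richness for r in rows],
            "chao1": [r.chao1 for r in rows],
            "shannon": [r.shannon for r in rows],
        }
    )


def rarefy_counts(table: CountTable, seed: int = 0, depth: int | None = None) -> CountTable:
    """Subsample every library without replacement to a common depth."""
    rng = np.random.default_rng(seed)
    sums = table.counts.sum(axis=0)
    target = int(sums.min()) if depth is None else int(depth)
    if (sums < target).any():
        raise ValueError("rarefaction depth exceeds a library size")
    out = np.zeros_like(table.counts)
    for j in range(table.n_samples):
        col = table.counts[:, j]
        pool = np.repeat(np.arange(table.n_taxa), col)
        take = rng.choice(pool, size=target, replace=False)
        out[:, j] = np.bincount(take, minlength=table.n_taxa)
    return CountTable(list(table.taxon_ids), list(table.lineage), list(table.samples), out)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn + compact letters
# ---------------------------------------------------------------------------


@dataclass
class KruskalDunnResult:
    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame      # columns group_a, group_b, z, p, q
    letters: dict[str, str]     # group -> compact letter string


def _dunn_pairwise(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's z statistics on pooled ranks with tie correction."""
    n = len(values)
    ranks = rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n - 1))) if n > 1 else 0.0
    var_unit = n * (n + 1) / 12.0 - tie_term
    levels = list(pd.unique(groups))
    mean_rank = {g: ranks[groups == g].mean() for g in levels}
    size = {g: int((groups == g).sum()) for g in levels}
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            se = np.sqrt(var_unit * (1.0 / size[a] + 1.0 / size[b]))
            z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
            p = 2.0 * norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "z": z, "p": p})
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df


def _compact_letters(levels: Sequence[str], pairwise: pd.DataFrame, alpha: float) -> dict[str, str]:
    """Compact-letter display: groups share a letter iff not significantly different.

    Letters label the maximal cliques of the "indistinct" graph (edge when
    adjusted p > alpha), ordered by each clique's first member.
    """
    g = nx.Graph()
    g.add_nodes_from(levels)
    for _, row in pairwise.iterrows():
        if row["q"] > alpha:
            g.add_edge(row["group_a"], row["group_b"])
    order = {lvl: i for i, lvl in enumerate(levels)}
    cliques = sorted(nx.find_cliques(g), key=lambda c: min(order[m] for m in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {lvl: [] for lvl in levels}
    for k, clique in enumerate(cliques):
        for member in clique:
            letters[member].append(alphabet[k % len(alphabet)])
    return {lvl: "".join(sorted(set(ls))) for lvl, ls in letters.items()}


def kruskal_dunn(
    values: Sequence[float], groups: Sequence[str], alpha: float = 0.05
) -> KruskalDunnResult:
    """Kruskal-Wallis H test with Dunn's post hoc comparisons and BH letters.

    Groups sharing a letter are not significantly different at ``alpha``
    after Benjamini-Hochberg adjustment over all pairs.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray([str(g) for g in groups])
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    for g in levels:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    samples = [values[groups == g] for g in levels]
    try:
        h, p = kruskal(*samples)
    except ValueError:  # scipy rejects all-identical data; nothing to detect
        h, p = 0.0, 1.0
    pairwise = _dunn_pairwise(values, groups)
    if p > alpha:
        # post hocs are gated on the omnibus test: without a significant
        # Kruskal-Wallis H, no pair is declared different
        letters = {lvl: "a" for lvl in levels}
    else:
        letters = _compact_letters(levels, pairwise, alpha)
    return KruskalDunnResult(float(h), float(p), pairwise, letters)


# ---------------------------------------------------------------------------
# Bray-Curtis + PERMANOVA
# ---------------------------------------------------------------------------


def bray_curtis(table: CountTable, normalize: bool = True) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between samples.

    d(a, b) = sum|a_i - b_i| / sum(a_i + b_i), computed on per-sample
    proportions by default (raw counts with ``normalize=False``).
    """
    table.check_no_empty_samples()
    x = table.relative_abundance().T if normalize else table.counts.T.astype(float)
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=table.samples, columns=table.samples)


@dataclass
class PermanovaResult:
    factor: str
    pseudo_f: float
    p_value: float
    r_squared: float
    n_permutations: int
    permuted_labels: np.ndarray | None = None  # retained for audit when requested


def _permute_within_strata(
    rng: np.random.Generator, n: int, n_perm: int, strata: np.ndarray | None
) -> np.ndarray:
    """(n_perm, n) index matrix; permutations never cross stratum blocks."""
    perms = np.empty((n_perm, n), dtype=int)
    base = np.arange(n)
    if strata is None:
        for i in range(n_perm):
            perms[i] = rng.permutation(n)
        return perms
    blocks = [np.nonzero(strata == s)[0] for s in pd.unique(strata)]
    for i in range(n_perm):
        row = base.copy()
        for idx in blocks:
            row[idx] = idx[rng.permutation(len(idx))]
        perms[i] = row
    return perms


def permanova(
    distance: pd.DataFrame,
    factor: Sequence[str],
    n_permutations: int = 999,
    seed: int = 0,
    strata: Sequence[str] | None = None,
    factor_name: str = "factor",
    keep_permutations: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    Pseudo-F from the among/within decomposition of squared distances
    (equivalent to the Gower-centred form); the p-value is
    ``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)``. With ``strata``,
    labels are only exchanged within blocks (e.g. plots within farms).
    """
    d2 = np.asarray(distance, dtype=float) ** 2
    n = d2.shape[0]
    labels = np.asarray([str(x) for x in factor])
    if len(labels) != n:
        raise ValueError("factor length must match the distance matrix")
    levels = pd.unique(labels)
    if len(levels) < 2:
        raise ValueError("factor must have at least 2 levels")
    for g in levels:
        if (labels == g).sum() < 2:
            raise ValueError(f"level {g!r} has fewer than 2 samples")
    k = len(levels)
    sst = d2.sum() / (2.0 * n)

    masks = np.stack([(labels == g) for g in levels]).astype(float)  # (k, n)
    sizes = masks.sum(axis=1)

    def ssw_for(perm_masks: np.ndarray) -> np.ndarray:
        # perm_masks: (k, P, n) -> SSW per permutation
        ssw = np.zeros(perm_masks.shape[1])
        for g in range(k):
            m = perm_masks[g]                       # (P, n)
            ssw += np.einsum("pi,ij,pj->p", m, d2, m) / (2.0 * sizes[g])
        return ssw

    obs_ssw = ssw_for(masks[:, None, :])[0]
    f_obs = ((sst - obs_ssw) / (k - 1)) / (obs_ssw / (n - k))

    rng = np.random.default_rng(seed)
    strata_arr = np.asarray([str(s) for s in strata]) if strata is not None else None
    perms = _permute_within_strata(rng, n, n_permutations, strata_arr)
    # permute labels, equivalently permute the masks' columns
    perm_masks = masks[:, perms]                    # (k, P, n)
    ssw_perm = ssw_for(perm_masks)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = ((sst - ssw_perm) / (k - 1)) / (ssw_perm / (n - k))
    p = (1.0 + np.sum(f_perm >= f_obs - 1e-12)) / (1.0 + n_permutations)
    r2 = (sst - obs_ssw) / sst if sst > 0 else 0.0
    return PermanovaResult(
        factor=factor_name,
        pseudo_f=float(f_obs),
        p_value=float(p),
        r_squared=float(r2),
        n_permutations=int(n_permutations),
        permuted_labels=perms if keep_permutations else None,
    )


# ---------------------------------------------------------------------------
# PCoA + CAP
# ---------------------------------------------------------------------------


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    scores: np.ndarray            # (n_samples, n_axes)
    eigenvalues: np.ndarray       # non-increasing
    proportion_explained: np.ndarray
    constrained: bool
    n_negative_eigenvalues: int = 0
    negative_eigenvalue_magnitude: float = 0.0


def pcoa(distance: pd.DataFrame, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinates by Gower double-centring.

    Negative eigenvalues (non-Euclidean distances) are dropped; their count
    and total magnitude are reported on the result rather than corrected.
    """
    d = np.asarray(distance, dtype=float)
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    vals, vecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    neg = vals < -1e-9 * max(abs(vals[0]), 1.0)
    pos = vals > 1e-9 * max(abs(vals[0]), 1.0)
    keep = np.nonzero(pos)[0]
    if n_axes is not None:
        keep = keep[:n_axes]
    scores = vecs[:, keep] * np.sqrt(vals[keep])
    total = vals[pos].sum()
    return OrdinationResult(
        sample_ids=list(distance.index),
        scores=scores,
        eigenvalues=vals[keep],
        proportion_explained=vals[keep] / total,
        constrained=False,
        n_negative_eigenvalues=int(neg.sum()),
        negative_eigenvalue_magnitude=float(-vals[neg].sum()),
    )


def cap_ordination(
    distance: pd.DataFrame, constraints: pd.DataFrame | None = None
) -> OrdinationResult:
    """Constrained analysis of principal coordinates (distance-based RDA).

    PCoA axes are regressed on the constraint design matrix (an intercept is
    always included); the constrained axes are the principal components of
    the fitted values. With no constraints the plain PCoA is returned.
    Rank-deficient constraint matrices reduce the constrained axis count.
    """
    base = pcoa(distance)
    if constraints is None or constraints.shape[1] == 0:
        return base
    if len(constraints) != len(base.sample_ids):
        raise ValueError("constraint rows must align with samples")
    x = np.column_stack([np.ones(len(constraints)), np.asarray(constraints, dtype=float)])
    rank = np.linalg.matrix_rank(x)
    n_constrained = min(rank - 1, base.scores.shape[1])
    y = base.scores
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    fitted -= fitted.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(fitted, full_matrices=False)
    eig = (s**2)[:n_constrained]
    scores = (u * s)[:, :n_constrained]
    total = base.eigenvalues.sum() / base.proportion_explained.sum()
    return OrdinationResult(
        sample_ids=list(base.sample_ids),
        scores=scores,
        eigenvalues=eig,
        proportion_explained=eig / total,
        constrained=True,
        n_negative_eigenvalues=base.n_negative_eigenvalues,
        negative_eigenvalue_magnitude=base.negative_eigenvalue_magnitude,
    )
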