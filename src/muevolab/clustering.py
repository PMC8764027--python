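"""Density-profile clustering and the Monte-Carlo composition test.

Each lineage's OD600 trajectory across transfers forms one row of a
profile matrix (dead lineages contribute zero density after extinction).
Profiles are clustered with a Gaussian mixture (diagonal covariances,
model order selected by BIC) and summarised as a Ward hierarchy exported
in Newick form.

Whether a cluster is dominated by one experimental group is tested by a
Monte-Carlo label permutation: the observed statistic is the maximum, over
clusters of at least ``min_cluster_size`` members, of

    T = (number of focal-group members in the cluster) x (focal fraction)

i.e. count^2 / cluster size, and group labels are permuted uniformly
across lineages to build the null. The add-one estimator
``p = (1 + #{T* >= T_obs}) / (1 + N)`` never returns zero, so the smallest
attainable p with N permutations is 1/(N+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from skbio.tree import TreeNode
from sklearn.mixture import GaussianMixture

from .config import child_rng, child_seed


def build_profiles(table: pd.DataFrame, impute_value: float = 0.0,
                   n_transfers: int | None = None
                   ) -> tuple[pd.DataFrame, pd.Series]:
    """Pivot a transfers table into a lineage x transfer profile matrix.

    Transfers after a lineage's death carry no OD record and are imputed
    with ``impute_value`` (default 0: a dead culture has no density), so
    extinct lineages remain comparable with survivors. A gap *before* a
    lineage's last recorded transfer is a schema error.

    Returns (matrix, groups) where ``groups`` maps each row to its culture
    type.
    """
    if n_transfers is None:
        n_transfers = int(table["transfer"].max())
    wide = table.pivot_table(index="lineage_id", columns="transfer",
                             values="od600", aggfunc="first")
    wide = wide.reindex(columns=range(n_transfers + 1))
    arr = wide.to_numpy(dtype=float)
    for i, lid in enumerate(wide.index):
        obs = ~np.isnan(arr[i])
        if not obs.any():
            raise ValueError(f"lineage {lid!r} has no OD records")
        last = int(np.flatnonzero(obs)[-1])
        if np.isnan(arr[i, :last + 1]).any():
            raise ValueError(
                f"lineage {lid!r} is missing a transfer before its last record")
        arr[i, last + 1:] = impute_value
    matrix = pd.DataFrame(arr, index=wide.index,
                          columns=range(n_transfers + 1))
    groups = (table.drop_duplicates("lineage_id")
              .set_index("lineage_id")["culture_type"]
              .reindex(matrix.index))
    groups.name = "group"
    return matrix, groups


@dataclass
class ClusterResult:
    labels: np.ndarray
    n_components: int
    bic_by_k: dict[int, float] = field(default_factory=dict)
    note: str = ""


def fit_gmm(profiles: pd.DataFrame | np.ndarray,
            k_range=range(1, 7), seed: int = 0, *,
            n_restarts: int = 10) -> ClusterResult:
    """Gaussian-mixture clustering with BIC model selection.

    Diagonal covariances with a 1e-6 variance floor; for each candidate K
    the best of ``n_restarts`` EM starts is kept and the K minimising BIC
    wins. Degenerate input (all rows identical) returns K = 1 with a note.
    """
    x = np.asarray(profiles, dtype=float)
    if x.ndim != 2 or len(x) < 2:
        raise ValueError("profile matrix must be 2-D with at least 2 rows")
    if np.allclose(x, x[0]):
        return ClusterResult(labels=np.zeros(len(x), dtype=int),
                             n_components=1, note="degenerate: identical rows")
    ks = [k for k in k_range if k * 3 <= len(x)]
    if not ks:
        ks = [1]
    best = None
    bics: dict[int, float] = {}
    for k in ks:
        gm = GaussianMixture(n_components=k, covariance_type="diag",
                             reg_covar=1e-6, n_init=n_restarts,
                             random_state=child_seed(seed, "fit_gmm", k))
        gm.fit(x)
        bics[k] = float(gm.bic(x))
        if best is None or bics[k] < bics[best[0]]:
            best = (k, gm)
    k, gm = best
    return ClusterResult(labels=gm.predict(x).astype(int),
                         n_components=k, bic_by_k=bics)


def cluster_tree(profiles: pd.DataFrame, groups: pd.Series | None = None
                 ) -> TreeNode:
    """Ward-linkage hierarchy over profile rows, as a rooted scikit-bio tree.

    Leaves are named ``lineage_id|group`` (or just the lineage id) and
    branch lengths derive from the merge heights. Serialise with
    ``str(tree)`` or ``tree.write(path)`` for Newick output.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to build a tree")
    z = linkage(profiles.to_numpy(dtype=float), method="ward")
    if groups is not None:
        ids = [f"{lid}|{groups.loc[lid]}" for lid in profiles.index]
    else:
        ids = [str(lid) for lid in profiles.index]
    return TreeNode.from_linkage_matrix(z, ids)


@dataclass(frozen=True)
class CompositionTest:
    statistic: float
    p: float
    n_permutations: int
    focal: str
    best_cluster: int
    focal_in_best: int
    best_cluster_size: int


def composition_test(labels: np.ndarray, groups, focal: str,
                     n_permutations: int = 10**6, seed: int = 0, *,
                     min_cluster_size: int = 5,
                     chunk: int = 20000) -> CompositionTest:
    """Monte-Carlo permutation test for focal-group enrichment in clusters.

    Invariant to cluster relabelling and to lineage order; with a single
    all-encompassing cluster every permutation ties the observed statistic
    and p = 1.
    """
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    if labels.shape != groups.shape:
        raise ValueError("labels and groups must be aligned")
    focal_vec = (groups == focal).astype(np.float64)
    if focal_vec.sum() == 0:
        raise ValueError(f"focal group {focal!r} absent from groups")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")

    uniq, inv = np.unique(labels, return_inverse=True)
    k = len(uniq)
    sizes = np.bincount(inv, minlength=k).astype(np.float64)
    eligible = sizes >= min_cluster_size
    indicator = np.zeros((len(labels), k))
    indicator[np.arange(len(labels)), inv] = 1.0

    def stat(counts: np.ndarray) -> np.ndarray:
        # counts: (..., k) focal members per cluster
        t = np.where(eligible, counts**2 / np.maximum(sizes, 1.0), -np.inf)
        return t.max(axis=-1)

    t_obs = float(stat(focal_vec @ indicator))
    rng = child_rng(seed, "composition_test", focal)
    n_ge = 0
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        perms = np.tile(focal_vec, (m, 1))
        perms = rng.permuted(perms, axis=1)
        t_null = stat(perms @ indicator)
        n_ge += int(np.count_nonzero(t_null >= t_obs))
        done += m
    p = (1 + n_ge) / (1 + n_permutations)
    counts_obs = focal_vec @ indicator
    with np.errstate(divide="ignore", invalid="ignore"):
        t_per_cluster = np.where(eligible, counts_obs**2 / np.maximum(sizes, 1.0),
                                 -np.inf)
    best = int(np.argmax(t_per_cluster))
    return CompositionTest(statistic=t_obs, p=float(p),
                           n_permutations=int(n_permutations), focal=focal,
                           best_cluster=int(uniq[best]),
                           focal_in_best=int(counts_obs[best]),
                           best_cluster_size=int(sizes[best]))
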