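"""Gene-cluster agglomeration with a standardized chi-square stopping rule.

Selected genes are first segmented into ``k_init`` k-means clusters of their
standardized profiles.  The two clusters closest in the principal-component
plane of the current centroid matrix are then merged, repeatedly, and at
each level the partition is cross-tabulated against a reference partition;
the level maximizing |standardized chi-square| is kept, where

    std_chi2 = (chi2 - df) / sqrt(2 * df)

makes Pearson chi-square values comparable across table sizes.  Two
reference modes are provided: ``hierarchical`` cross-tabulates against a
Ward-linkage clustering of the same profiles cut at the current k
(concordance of the two clustering routes), ``direction`` against the
per-gene up/down fold-change direction (association of cluster membership
with response direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import chi2_contingency
from sklearn.cluster import KMeans

from .diffexpr import log2_fold_changes
from .matrix import ExpressionMatrix

__all__ = [
    "AggregationState",
    "MergeRecord",
    "initial_kmeans",
    "centroid_pc_distance",
    "chi2_criterion",
    "aggregate",
]

CENTROID_TOL = 1e-9


@dataclass(frozen=True)
class MergeRecord:
    step: int
    pair: tuple[int, int]
    chi2: float
    std_chi2: float
    k: int  # number of clusters after this merge


@dataclass
class AggregationState:
    """Evolving gene-cluster partition with merge trace."""

    assignment: pd.Series  # gene id -> cluster index, contiguous 0..k-1
    centroids: np.ndarray  # k x n_samples mean standardized profiles
    profiles: pd.DataFrame  # standardized genes x samples (frozen input)
    k_init: int
    trace: list[MergeRecord] = field(default_factory=list)
    k_star: int | None = None
    initial_assignment: pd.Series | None = None
    _snapshots: dict[int, pd.Series] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return int(self.assignment.max()) + 1

    def check(self) -> None:
        labels = np.sort(self.assignment.unique())
        if not np.array_equal(labels, np.arange(len(labels))):
            raise AssertionError("cluster indices not contiguous")
        for c in range(self.k):
            members = self.profiles.loc[self.assignment[self.assignment == c].index]
            if not np.allclose(
                self.centroids[c], members.to_numpy().mean(axis=0), atol=CENTROID_TOL
            ):
                raise AssertionError(f"centroid {c} is not the mean member profile")

    def members(self, cluster: int) -> list[str]:
        return list(self.assignment.index[self.assignment == cluster])

    def replay(self) -> pd.Series:
        """Re-run the recorded merges from the initial assignment."""
        if self.initial_assignment is None:
            raise ValueError("no initial assignment recorded")
        assign = self.initial_assignment.to_numpy().copy()
        for rec in self.trace:
            i, j = rec.pair
            assign[assign == j] = i
            assign[assign > j] -= 1
            if rec.k == self.k_star:
                break
        return pd.Series(assign, index=self.initial_assignment.index)


def _centroids_of(profiles: pd.DataFrame, assignment: np.ndarray, k: int) -> np.ndarray:
    x = profiles.to_numpy()
    return np.vstack([x[assignment == c].mean(axis=0) for c in range(k)])


def initial_kmeans(
    matrix: ExpressionMatrix,
    k_init: int = 40,
    seed: int = 0,
    restarts: int = 10,
) -> AggregationState:
    """Best-of-``restarts`` k-means on standardized gene profiles.

    Empty clusters (possible when k approaches the gene count) are dropped
    and indices re-compacted.
    """
    if matrix.n_genes < k_init:
        raise ValueError(
            f"{matrix.n_genes} genes < k_init = {k_init}; choose a smaller k_init"
        )
    profiles = matrix.standardized()
    km = KMeans(n_clusters=k_init, n_init=restarts, random_state=seed)
    labels = km.fit_predict(profiles.to_numpy())
    # re-compact in case of empty clusters
    present = np.unique(labels)
    remap = {old: new for new, old in enumerate(present)}
    labels = np.array([remap[l] for l in labels])
    k = len(present)
    assignment = pd.Series(labels, index=profiles.index)
    state = AggregationState(
        assignment=assignment,
        centroids=_centroids_of(profiles, labels, k),
        profiles=profiles,
        k_init=k,
        initial_assignment=assignment.copy(),
    )
    return state


def centroid_pc_distance(state: AggregationState) -> np.ndarray:
    """Pairwise Euclidean distances between centroids projected onto the
    first min(2, k-1) principal components of the centroid matrix."""
    k = state.k
    if k < 2:
        raise ValueError("at least 2 clusters are required")
    c = state.centroids - state.centroids.mean(axis=0, keepdims=True)
    n_comp = min(2, k - 1)
    # principal axes of the (column-centered) centroid matrix via SVD
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    proj = c @ vt[:n_comp].T
    diff = proj[:, None, :] - proj[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def chi2_criterion(
    state_or_assignment: AggregationState | pd.Series,
    reference: Mapping[str, object] | pd.Series,
) -> tuple[float, float]:
    """Pearson chi-square of cluster labels vs a reference partition.

    Empty rows/columns are removed before computing; df = (r-1)(c-1);
    std_chi2 = (chi2 - df)/sqrt(2 df); a degenerate table (df = 0) yields
    (0, 0).
    """
    if isinstance(state_or_assignment, AggregationState):
        assignment = state_or_assignment.assignment
    else:
        assignment = state_or_assignment
    ref = pd.Series(reference)
    if set(ref.index) != set(assignment.index):
        raise ValueError("reference partition covers a different gene set")
    ref = ref.loc[assignment.index]
    table = pd.crosstab(assignment, ref)
    table = table.loc[(table.sum(axis=1) > 0), (table.sum(axis=0) > 0)]
    r, c = table.shape
    df = (r - 1) * (c - 1)
    if df == 0:
        return 0.0, 0.0
    chi2 = float(chi2_contingency(table.to_numpy(), correction=False).statistic)
    std = (chi2 - df) / np.sqrt(2.0 * df)
    return chi2, float(std)


def _closest_pair(dist: np.ndarray, tol: float = 1e-12) -> tuple[int, int]:
    """Lexicographically smallest pair attaining the minimum distance."""
    k = dist.shape[0]
    best, best_d = None, np.inf
    for i in range(k):
        for j in range(i + 1, k):
            if dist[i, j] < best_d - tol:
                best, best_d = (i, j), dist[i, j]
    assert best is not None
    return best


def direction_reference(
    matrix: ExpressionMatrix, genes: Sequence[str], group_contrast: tuple[str, str]
) -> pd.Series:
    """Per-gene up/down labels for the given contrast, as a reference partition."""
    sub = matrix.subset_genes(genes)
    fc = log2_fold_changes(sub, *group_contrast)
    return pd.Series(np.where(fc > 0, "up", "down"), index=sub.gene_ids)


def aggregate(
    state: AggregationState,
    reference_mode: str = "hierarchical",
    matrix: ExpressionMatrix | None = None,
    group_contrast: tuple[str, str] | None = None,
) -> AggregationState:
    """Greedy closest-pair agglomeration down to 2 clusters, keeping the
    level that maximizes |std_chi2| against the reference partition.

    Ties in pair distance go to the lexicographically smallest pair; ties
    in |std_chi2| go to the largest k.  A state with fewer than 3 clusters
    is returned unchanged with ``k_star`` set to its current k.
    """
    if state.k < 3:
        state.k_star = state.k
        return state
    if reference_mode not in ("hierarchical", "direction"):
        raise ValueError(f"unknown reference_mode {reference_mode!r}")

    genes = list(state.assignment.index)
    if reference_mode == "hierarchical":
        z = linkage(state.profiles.to_numpy(), method="ward")

        def reference_at(k: int) -> pd.Series:
            return pd.Series(fcluster(z, t=k, criterion="maxclust"), index=genes)

    else:
        if matrix is None or group_contrast is None:
            raise ValueError("direction mode needs matrix and group_contrast")
        fixed_ref = direction_reference(matrix, genes, group_contrast)

        def reference_at(k: int) -> pd.Series:  # noqa: ARG001 - fixed reference
            return fixed_ref

    assign = state.assignment.to_numpy().copy()
    k = state.k
    trace: list[MergeRecord] = []
    snapshots: dict[int, np.ndarray] = {}
    centroids = state.centroids.copy()
    step = 0
    work = AggregationState(
        assignment=pd.Series(assign, index=genes),
        centroids=centroids,
        profiles=state.profiles,
        k_init=state.k_init,
    )
    while k > 2:
        dist = centroid_pc_distance(work)
        i, j = _closest_pair(dist)
        assign[assign == j] = i
        assign[assign > j] -= 1
        k -= 1
        step += 1
        work.assignment = pd.Series(assign, index=genes)
        work.centroids = _centroids_of(state.profiles, assign, k)
        chi2, std = chi2_criterion(work.assignment, reference_at(k))
        trace.append(MergeRecord(step, (i, j), chi2, std, k))
        snapshots[k] = assign.copy()

    best = max(trace, key=lambda r: (abs(r.std_chi2), r.k))
    k_star = best.k
    final_assign = snapshots[k_star]
    return AggregationState(
        assignment=pd.Series(final_assign, index=genes),
        centroids=_centroids_of(state.profiles, final_assign, k_star),
        profiles=state.profiles,
        k_init=state.k_init,
        trace=trace,
        k_star=k_star,
        initial_assignment=state.initial_assignment,
        _snapshots={kk: pd.Series(a, index=genes) for kk, a in snapshots.items()},
    )


def trace_table(state: AggregationState) -> pd.DataFrame:
    """Merge trace as a TSV-ready table."""
    return pd.DataFrame(
        [
            {
                "step": r.step,
                "pair": f"{r.pair[0]}+{r.pair[1]}",
                "chi2": r.chi2,
                "std_chi2": r.std_chi2,
                "k": r.k,
            }
            for r in state.trace
        ]
    )


def plot_cluster_heatmap(state: AggregationState, path) -> None:
    """Diagnostic heatmap of standardized profiles ordered by cluster."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    order = state.assignment.sort_values(kind="stable").index
    data = state.profiles.loc[order]
    fig, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-2, vmax=2)
    ax.set_xticks(range(data.shape[1]))
    ax.set_xticklabels(data.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel(f"{data.shape[0]} genes in {state.k} aggregated clusters")
    fig.colorbar(im, ax=ax, label="standardized log2 expression")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
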