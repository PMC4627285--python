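"""Agglomerative gene clustering with the uncentered-correlation metric.

Average-linkage (UPGMA-style) hierarchical clustering on distance
``1 - uncentered correlation``, the Cluster 3.0 convention for microarray
gene trees. The agglomeration is implemented directly (Lance–Williams
distance updates) so that tie-breaking and leaf ordering are fully
deterministic:

* among equal-distance cluster pairs, the pair whose (smallest leaf index,
  other smallest leaf index) tuple is lexicographically least merges first;
* in the output tree the child with the smaller minimum leaf index is the
  left child, and the leaf order is the left-to-right traversal.

Merges are recorded with their distance; the similarity written to GTR
files is ``1 - distance``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SampleDesign


def uncentered_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine-like similarity sum(x*y) / sqrt(sum(x^2) * sum(y^2)).

    Computed without mean subtraction, so two rows with proportional
    (not merely correlated) profiles score 1. A zero-norm vector has no
    direction: the similarity is defined as 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("inputs must be equal-length 1-D vectors of length >= 1")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    nx = float(np.dot(x, x))
    ny = float(np.dot(y, y))
    if nx == 0.0 or ny == 0.0:
        warnings.warn("zero-norm vector in uncentered correlation; similarity set to 0")
        return 0.0
    sim = float(np.dot(x, y)) / np.sqrt(nx * ny)
    return float(np.clip(sim, -1.0, 1.0))


def pairwise_distances(values: np.ndarray) -> np.ndarray:
    """Full n x n matrix of 1 - uncentered correlation between rows.

    This is the single distance computation shared by the fast agglomerator
    and any reference re-implementation, so exact float ties (e.g. duplicate
    rows at distance 0) are identical for both.
    """
    values = np.asarray(values, dtype=float)
    norms = np.sqrt((values**2).sum(axis=1))
    zero = norms == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-norm row(s); similarities involving them set to 0"
        )
    safe = norms.copy()
    safe[zero] = 1.0
    unit = values / safe[:, None]
    sim = unit @ unit.T
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    np.clip(sim, -1.0, 1.0, out=sim)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    return dist


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: ``node`` joins ``left`` and ``right``.

    Child indices < n_leaves are leaves; internal nodes are numbered
    n_leaves, n_leaves + 1, ... in merge order. ``node`` for merge t is
    ``n_leaves + t``.
    """

    node: int
    left: int
    right: int
    distance: float


@dataclass
class ClusterTree:
    """Merge history of an agglomerative clustering over named leaves."""

    n_leaves: int
    leaf_names: list[str]
    merges: list[Merge]
    _leaf_order: list[int] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.leaf_names) != self.n_leaves:
            raise ValueError("leaf_names length must equal n_leaves")
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a tree over n leaves has exactly n-1 merges")

    @property
    def leaf_order(self) -> list[int]:
        """Left-to-right leaf indices from tree traversal."""
        if self._leaf_order is None:
            children: dict[int, tuple[int, int]] = {
                m.node: (m.left, m.right) for m in self.merges
            }
            order: list[int] = []
            root = self.n_leaves + len(self.merges) - 1 if self.merges else 0
            stack = [root]
            while stack:
                node = stack.pop()
                if node < self.n_leaves:
                    order.append(node)
                else:
                    left, right = children[node]
                    stack.append(right)
                    stack.append(left)
            self._leaf_order = order
        return self._leaf_order

    @property
    def leaf_order_names(self) -> list[str]:
        return [self.leaf_names[i] for i in self.leaf_order]

    @property
    def heights(self) -> list[float]:
        return [m.distance for m in self.merges]


def average_linkage(
    matrix: ExpressionMatrix | np.ndarray,
    leaf_names: list[str] | None = None,
    distances: np.ndarray | None = None,
) -> ClusterTree:
    """Average-linkage agglomeration over gene rows.

    At each step the pair of clusters with minimal average pairwise
    distance merges; the new cluster's distances follow the Lance–Williams
    update ``d(ij, k) = (n_i d(i,k) + n_j d(j,k)) / (n_i + n_j)``, which is
    exact for average linkage. Ties break to the lexicographically smallest
    (min leaf index, min leaf index) pair. A precomputed ``distances``
    matrix overrides the uncentered-correlation default.
    """
    if isinstance(matrix, ExpressionMatrix):
        values = matrix.values.to_numpy(dtype=float)
        names = matrix.gene_ids
    else:
        values = np.asarray(matrix, dtype=float)
        names = leaf_names if leaf_names is not None else [str(i) for i in range(len(values))]
    n = values.shape[0]
    if n < 2:
        raise ValueError("clustering needs at least 2 rows")
    if len(names) != n:
        raise ValueError("leaf_names length mismatch")

    D = pairwise_distances(values) if distances is None else np.array(distances, dtype=float)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")

    INF = np.inf
    D = D.copy()
    np.fill_diagonal(D, INF)
    sizes = np.ones(n, dtype=float)
    min_leaf = np.arange(n)          # smallest original leaf index per slot
    node_of = np.arange(n)           # tree node id currently held by each slot

    merges: list[Merge] = []
    for t in range(n - 1):
        dmin = D.min()
        cand = np.argwhere(D == dmin)
        best = None
        best_key = None
        for i, j in cand:
            if i >= j:
                continue
            a, b = sorted((int(min_leaf[i]), int(min_leaf[j])))
            key = (a, b)
            if best_key is None or key < best_key:
                best_key = key
                best = (int(i), int(j))
        i, j = best  # type: ignore[misc]
        # left child = smaller min leaf index
        if min_leaf[i] <= min_leaf[j]:
            left, right = node_of[i], node_of[j]
        else:
            left, right = node_of[j], node_of[i]
        new_node = n + t
        merges.append(Merge(new_node, int(left), int(right), float(dmin)))

        # Lance-Williams average-linkage update into slot i; retire slot j
        ni, nj = sizes[i], sizes[j]
        new_row = (ni * D[i, :] + nj * D[j, :]) / (ni + nj)
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = INF
        D[j, :] = INF
        D[:, j] = INF
        sizes[i] = ni + nj
        min_leaf[i] = min(min_leaf[i], min_leaf[j])
        node_of[i] = new_node

    return ClusterTree(n, list(names), merges)


@dataclass
class ClusterAssignment:
    """Gene -> cluster index mapping with optional descriptive labels."""

    assignment: pd.Series  # index: gene IDs, values: int cluster index
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.assignment = self.assignment.astype(int)

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(set(int(c) for c in self.assignment))

    def genes_in_cluster(self, cluster: int) -> list[str]:
        return [str(g) for g in self.assignment.index[self.assignment == cluster]]

    def label_of(self, cluster: int) -> str:
        return self.labels.get(cluster, "unclassified")

    def genes_with_label(self, label: str) -> list[str]:
        out: list[str] = []
        for c in self.cluster_ids:
            if self.label_of(c) == label:
                out.extend(self.genes_in_cluster(c))
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cluster": self.assignment,
                "label": [self.label_of(int(c)) for c in self.assignment],
            }
        )
        df.index.name = "gene_id"
        return df


def cut_tree(
    tree: ClusterTree, k: int | None = None, h: float | None = None
) -> ClusterAssignment:
    """Cut the dendrogram into flat clusters.

    Exactly one of ``k`` (cluster count; undoes the last k-1 merges) or
    ``h`` (height threshold; applies every merge with distance <= h) is
    given. Cluster indices are assigned 0, 1, ... by each cluster's
    smallest leaf index.
    """
    if (k is None) == (h is None):
        raise ValueError("give exactly one of k or h")
    n = tree.n_leaves
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}], got {k}")
        applied = tree.merges[: n - k]
    else:
        # heights are non-decreasing, so merges at or below h form a prefix
        applied = []
        for m in tree.merges:
            if m.distance <= h:
                applied.append(m)
            else:
                break

    parent = list(range(n + len(tree.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m in applied:
        for child in (m.left, m.right):
            parent[find(child)] = m.node

    roots: dict[int, list[int]] = {}
    for leaf in range(n):
        roots.setdefault(find(leaf), []).append(leaf)
    clusters = sorted(roots.values(), key=lambda leaves: min(leaves))
    mapping: dict[str, int] = {}
    for idx, leaves in enumerate(clusters):
        for leaf in leaves:
            mapping[tree.leaf_names[leaf]] = idx
    series = pd.Series({name: mapping[name] for name in tree.leaf_names})
    series.index.name = "gene_id"
    return ClusterAssignment(series)


def label_clusters(
    assignment: ClusterAssignment,
    matrix: ExpressionMatrix,
    design: SampleDesign,
    margin: float = 0.5,
) -> ClusterAssignment:
    """Attach condition-contrast labels to flat clusters.

    For each cluster's mean profile in the p53-proficient (vector) genotype
    without inhibitor, two single-factor contrasts are computed on the
    (centered) log2 scale:

    * drug:   mean(Nutlin, no ligand) - mean(DMSO, no ligand)
    * ligand: mean(DMSO, flagellin)  - mean(DMSO, no ligand)

    The cluster is labeled ``drug-induced`` / ``drug-repressed`` /
    ``ligand-induced`` by the largest-magnitude contrast exceeding
    ``margin`` (drug wins exact ties), else ``unclassified``.
    """
    cells = {
        "ref": design.samples_for("vector", "DMSO", "none", "none"),
        "drug": design.samples_for("vector", "Nutlin", "none", "none"),
        "ligand": design.samples_for("vector", "DMSO", "flagellin", "none"),
    }
    for name, samples in cells.items():
        samples_present = [s for s in samples if s in matrix.values.columns]
        if not samples_present:
            raise ValueError(f"design/matrix lack samples for the {name} condition")
        cells[name] = samples_present

    labels: dict[int, str] = {}
    for cluster in assignment.cluster_ids:
        genes = [g for g in assignment.genes_in_cluster(cluster) if g in matrix.values.index]
        if not genes:
            labels[cluster] = "unclassified"
            continue
        sub = matrix.values.loc[genes]
        ref = sub[cells["ref"]].to_numpy().mean()
        drug_contrast = sub[cells["drug"]].to_numpy().mean() - ref
        ligand_contrast = sub[cells["ligand"]].to_numpy().mean() - ref
        label = "unclassified"
        best = margin
        if abs(drug_contrast) > best:
            best = abs(drug_contrast)
            label = "drug-induced" if drug_contrast > 0 else "drug-repressed"
        if ligand_contrast > best:
            label = "ligand-induced"
        labels[cluster] = label
    return ClusterAssignment(assignment.assignment.copy(), labels)
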