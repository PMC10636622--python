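"""Range standardization and Ward minimum-variance clustering of plants.

Features (per-capita loads) are min-max rescaled to [0, 1] per analyte, then
plants are agglomerated by Ward's criterion: each step merges the pair of
clusters whose union least increases the total within-cluster error sum of
squares (ESS, summed over all variables).  The increase is maintained with
the Lance-Williams recurrence

    d(k, i+j) = ((n_i + n_k) d(k,i) + (n_j + n_k) d(k,j) - n_k d(i,j))
                / (n_i + n_j + n_k)

seeded with d(i, j) = ||x_i - x_j||^2 / 2 for singletons, which is exactly
the ANOVA between-cluster sum-of-squares distance.  Each merge is annotated
with its semipartial R^2 = delta-ESS / total SS about the grand centroid;
over a full agglomeration these sum to 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, DomainError


@dataclass
class StandardizedMatrix:
    """Plants x analytes matrix of range-standardized values in [0, 1]."""

    frame: pd.DataFrame = field(repr=False)
    mins: pd.Series = field(repr=False)
    maxs: pd.Series = field(repr=False)


def range_standardize(values: pd.DataFrame) -> StandardizedMatrix:
    """Min-max rescale each column to [0, 1]: v' = (v - min) / (max - min).

    A constant column makes the scale undefined and raises, naming the
    analyte.
    """
    if len(values) < 2:
        raise DomainError("range standardization needs at least 2 plants")
    mins = values.min(axis=0)
    maxs = values.max(axis=0)
    span = maxs - mins
    constant = span[span == 0].index.tolist()
    if constant:
        raise DegenerateDataError(
            f"constant column(s) cannot be range standardized: {constant}"
        )
    return StandardizedMatrix((values - mins) / span, mins, maxs)


@dataclass
class DendrogramNode:
    """Binary merge node (or leaf when ``plant_id`` is set)."""

    members: tuple[str, ...]
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None
    merge_cost: float = 0.0  # delta-ESS of this merge (0 for leaves)
    semipartial_r2: float = 0.0
    plant_id: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"leaf": self.plant_id}
        return {
            "members": list(self.members),
            "merge_cost": self.merge_cost,
            "semipartial_r2": self.semipartial_r2,
            "children": [c.to_dict() for c in self.children],
        }

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights (delta-ESS)."""

        def rec(node: DendrogramNode, parent_height: float) -> str:
            length = parent_height - node.merge_cost
            if node.is_leaf:
                return f"{node.plant_id}:{parent_height:.6g}"
            inner = ",".join(rec(c, node.merge_cost) for c in node.children)
            return f"({inner}):{length:.6g}"

        if self.is_leaf:
            return f"{self.plant_id};"
        inner = ",".join(rec(c, self.merge_cost) for c in self.children)
        return f"({inner});"


@dataclass(frozen=True)
class Merge:
    members_a: tuple[str, ...]
    members_b: tuple[str, ...]
    cost: float  # delta-ESS
    semipartial_r2: float


def ward_cluster(
    matrix: StandardizedMatrix | pd.DataFrame,
) -> tuple[DendrogramNode, list[Merge]]:
    """Agglomerate plants by Ward's minimum-variance criterion.

    Ties on the minimal merge cost break by the lexicographically smallest
    pair of smallest member ids, making the tree deterministic.  Returns the
    root node and the merges in agglomeration order.
    """
    frame = matrix.frame if isinstance(matrix, StandardizedMatrix) else matrix
    x = frame.to_numpy(dtype=float)
    ids = [str(i) for i in frame.index]
    n = len(ids)
    if n < 2:
        raise DomainError("clustering needs at least 2 plants")
    total_ss = float(((x - x.mean(axis=0)) ** 2).sum())
    if total_ss <= 0:
        raise DegenerateDataError("all plants identical: total SS is zero")

    nodes: dict[int, DendrogramNode] = {
        i: DendrogramNode(members=(ids[i],), plant_id=ids[i]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    # pairwise delta-ESS for singletons
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = 0.5 * float(((x[i] - x[j]) ** 2).sum())

    def d(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    merges: list[Merge] = []
    next_id = n
    while len(active) > 1:
        best_key = None
        best_pair = None
        for i in sorted(active):
            for j in sorted(active):
                if i >= j:
                    continue
                mi = min(nodes[i].members)
                mj = min(nodes[j].members)
                key = (d(i, j), tuple(sorted((mi, mj))))
                if best_key is None or key < best_key:
                    best_key = key
                    best_pair = (i, j)
        i, j = best_pair
        cost = d(i, j)
        spr2 = cost / total_ss
        merged = DendrogramNode(
            members=tuple(sorted(nodes[i].members + nodes[j].members)),
            children=(nodes[i], nodes[j]),
            merge_cost=cost,
            semipartial_r2=spr2,
        )
        merges.append(Merge(nodes[i].members, nodes[j].members, cost, spr2))
        # Lance-Williams update of delta-ESS distances to the new cluster
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dist[(min(k, next_id), max(k, next_id))] = (
                (ni + nk) * d(k, i) + (nj + nk) * d(k, j) - nk * cost
            ) / (ni + nj + nk)
        nodes[next_id] = merged
        sizes[next_id] = ni + nj
        active.discard(i)
        active.discard(j)
        active.add(next_id)
        next_id += 1
    return nodes[next_id - 1], merges


def cut_tree(
    root: DendrogramNode, k: int, merges: list[Merge] | None = None
) -> pd.Series:
    """Cluster labels after removing the k-1 costliest (last) merges.

    Labels are integers 0..k-1 assigned in order of each cluster's smallest
    member id.
    """
    leaves = root.members
    n = len(leaves)
    if not 1 <= k <= n:
        raise DomainError(f"k must be in [1, {n}], got {k}")
    # collect clusters: descend from the root, splitting the k-1 highest merges
    clusters: list[DendrogramNode] = [root]
    while len(clusters) < k:
        # split the internal node with the largest merge cost
        internal = [c for c in clusters if not c.is_leaf]
        node = max(internal, key=lambda nd: nd.merge_cost)
        clusters.remove(node)
        clusters.extend(node.children)
    clusters.sort(key=lambda nd: min(nd.members))
    mapping: dict[str, int] = {}
    for label, node in enumerate(clusters):
        for pid in node.members:
            mapping[pid] = label
    return pd.Series([mapping[pid] for pid in sorted(leaves)],
                     index=sorted(leaves), name="cluster")


# ---------------------------------------------------------------------------
# Model / Results surface

class WardClustering:
    """Ward minimum-variance clustering model over a plants x features table.

    ``standardize=True`` (default) applies range standardization first, as the
    surveillance analysis prescribes.
    """

    def __init__(self, data: pd.DataFrame, standardize: bool = True) -> None:
        self.data = data
        self.standardize = standardize

    def fit(self) -> "WardResults":
        std = range_standardize(self.data) if self.standardize else StandardizedMatrix(
            self.data, self.data.min(axis=0), self.data.max(axis=0)
        )
        root, merges = ward_cluster(std)
        return WardResults(self, std, root, merges)


@dataclass
class WardResults:
    model: WardClustering
    standardized: StandardizedMatrix
    root: DendrogramNode
    merges: list[Merge]

    @property
    def semipartial_r2(self) -> list[float]:
        return [m.semipartial_r2 for m in self.merges]

    def cut(self, k: int) -> pd.Series:
        return cut_tree(self.root, k, self.merges)

    def to_newick(self, path: str | Path | None = None) -> str:
        nwk = self.root.to_newick()
        if path is not None:
            Path(path).write_text(nwk + "\n")
        return nwk

    def to_dict(self) -> dict:
        return {
            "features": list(self.standardized.frame.columns),
            "range_min": self.standardized.mins.to_dict(),
            "range_max": self.standardized.maxs.to_dict(),
            "merges": [
                {
                    "members_a": list(m.members_a),
                    "members_b": list(m.members_b),
                    "cost": m.cost,
                    "semipartial_r2": m.semipartial_r2,
                }
                for m in self.merges
            ],
            "tree": self.root.to_dict(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def summary(self) -> str:
        lines = ["Ward minimum-variance clustering", "=" * 40]
        lines.append(f"{len(self.root.members)} plants, "
                     f"{self.standardized.frame.shape[1]} range-standardized features")
        lines.append("")
        lines.append("Merge  Cluster members                          dESS     spR2")
        for i, m in enumerate(self.merges, start=1):
            members = ",".join(sorted(m.members_a + m.members_b))
            if len(members) > 38:
                members = members[:35] + "..."
            lines.append(f"{i:>5}  {members:<38} {m.cost:>8.4f} {m.semipartial_r2:>8.4f}")
        return "\n".join(lines)

    def plot_dendrogram(self, ax=None):
        """Plot the merge tree with scipy/matplotlib (optional dependency)."""
        import matplotlib.pyplot as plt
        from scipy.cluster import hierarchy

        linkage = self._linkage_matrix()
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        hierarchy.dendrogram(
            linkage, labels=sorted(self.root.members), ax=ax,
            color_threshold=0.0, above_threshold_color="k",
        )
        ax.set_ylabel("merge cost (delta-ESS)")
        return ax

    def _linkage_matrix(self) -> np.ndarray:
        """Scipy-format linkage matrix (heights = delta-ESS, monotone)."""
        order = sorted(self.root.members)
        index = {(pid,): i for i, pid in enumerate(order)}
        n = len(order)
        z = np.zeros((n - 1, 4))
        for i, m in enumerate(self.merges):
            a = index.pop(tuple(sorted(m.members_a)))
            b = index.pop(tuple(sorted(m.members_b)))
            z[i] = (min(a, b), max(a, b), m.cost, len(m.members_a) + len(m.members_b))
            index[tuple(sorted(m.members_a + m.members_b))] = n + i
        return z
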