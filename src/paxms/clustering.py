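"""Uncentered-Pearson hierarchical clustering and single-bait selection.

Proteins are clustered by their bait-association profiles (mean normalized
spectral counts) using the uncentered Pearson correlation, i.e. the
correlation computed about zero rather than about the profile means:

    r(x, y) = (1/n) sum_i (x_i / sx)(y_i / sy),   s = root mean square

which equals the cosine of the angle between the profiles.  Distance is
1 - r.  Agglomerative clustering (average linkage by default) is
implemented with Lance-Williams updates and a deterministic tie-break so
that merge sequences are reproducible.

Single-bait interactors — proteins with signal for exactly one bait — are
the highest-confidence candidates because the remaining baits act as
internal negative controls; proteins binding every bait are likely
non-specific.  ``bait_pure_clusters`` extracts the maximal subtrees whose
leaves all share one bait assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .identifications import CountMatrix

__all__ = [
    "Dendrogram",
    "uncentered_pearson",
    "distance_matrix",
    "hierarchical_cluster",
    "single_bait_interactors",
    "bait_pure_clusters",
    "write_cdt_gtr",
]

LINKAGES = ("single", "complete", "average")


def uncentered_pearson(x, y) -> float:
    """Uncentered Pearson correlation of two equal-length profiles.

    Normalizes by the root-mean-square about zero instead of the standard
    deviation, so profiles are compared by their direction from the origin.
    Always in [-1, 1]; undefined (error) for an all-zero profile.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1 or xv.size < 1:
        raise ValueError("profiles must be equal-length 1-D arrays with n >= 1")
    nx = np.sqrt(np.dot(xv, xv))
    ny = np.sqrt(np.dot(yv, yv))
    if nx == 0 or ny == 0:
        raise ValueError("uncentered Pearson undefined for an all-zero profile")
    r = float(np.dot(xv, yv) / (nx * ny))
    return max(-1.0, min(1.0, r))


def distance_matrix(m: CountMatrix) -> tuple[list[str], np.ndarray]:
    """Pairwise 1 - uncentered-Pearson distances between protein profiles."""
    if m.stage != "replicate_mean":
        raise ValueError(f"distance_matrix expects a replicate_mean matrix, got {m.stage!r}")
    values = m.data.to_numpy(dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 proteins to build a distance matrix")
    norms = np.sqrt((values ** 2).sum(axis=1))
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        names = [m.proteins[i] for i in zero]
        raise ValueError(f"all-zero profile(s): similarity undefined for {names}")
    unit = values / norms[:, None]
    sim = np.clip(unit @ unit.T, -1.0, 1.0)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    return list(m.proteins), (dist + dist.T) / 2.0


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative tree over labelled leaves.

    Leaves are nodes 0..n-1 (in input order); merge ``i`` creates internal
    node ``n + i``.  ``merges`` is the ordered list of (node_a, node_b,
    distance) with node_a the cluster containing the lowest leaf index.
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.labels) - 1:
            raise ValueError("a dendrogram over N leaves requires N-1 merges")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def children(self) -> dict[int, tuple[int, int]]:
        n = self.n_leaves
        return {n + i: (a, b) for i, (a, b, _) in enumerate(self.merges)}

    def leaf_order(self) -> list[int]:
        """Left-to-right leaf indices after tree construction."""
        if self.n_leaves == 1:
            return [0]
        kids = self.children()
        root = self.n_leaves + len(self.merges) - 1
        order: list[int] = []
        stack = [root]
        while stack:
            node = stack.pop()
            if node < self.n_leaves:
                order.append(node)
            else:
                a, b = kids[node]
                stack.append(b)
                stack.append(a)
        return order

    def leaf_labels_in_order(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order()]


def _min_leaf_key(members: dict[int, list[int]]):
    return {node: min(leaves) for node, leaves in members.items()}


def hierarchical_cluster(
    distmat: np.ndarray,
    linkage: str = "average",
    labels: Sequence[str] | None = None,
) -> Dendrogram:
    """Agglomerative clustering of a precomputed distance matrix.

    Average linkage (unweighted mean pairwise distance between members) by
    default; ``single`` and ``complete`` are also available.  Ties on the
    minimum distance are broken toward the pair whose clusters contain the
    lowest leaf indices, making the merge sequence fully deterministic.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    d = np.asarray(distmat, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if labels is None:
        labels = [str(i) for i in range(n)]
    if len(labels) != n:
        raise ValueError("labels length must match the matrix size")

    # working copy indexed by active node id
    dist: dict[tuple[int, int], float] = {}
    active: list[int] = list(range(n))
    size = {i: 1 for i in range(n)}
    min_leaf = {i: i for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(d[i, j])

    def get(a: int, b: int) -> float:
        return dist[(a, b) if a < b else (b, a)]

    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        # pick the minimum-distance pair; tie-break on lowest contained
        # leaf indices (primary: smaller min leaf, secondary: the other's)
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = active[ii], active[jj]
                dd = get(a, b)
                la, lb = sorted((min_leaf[a], min_leaf[b]))
                key = (dd, la, lb)
                if best is None or key < best[0]:
                    best = (key, a, b)
        (_, _, _), a, b = best
        if min_leaf[a] > min_leaf[b]:
            a, b = b, a
        h = get(a, b)
        merges.append((a, b, h))
        new = next_id
        next_id += 1
        # Lance-Williams update for the new cluster's distances
        for c in active:
            if c in (a, b):
                continue
            dac, dbc = get(a, c), get(b, c)
            if linkage == "single":
                dnew = min(dac, dbc)
            elif linkage == "complete":
                dnew = max(dac, dbc)
            else:
                dnew = (size[a] * dac + size[b] * dbc) / (size[a] + size[b])
            dist[(min(new, c), max(new, c))] = dnew
        size[new] = size[a] + size[b]
        min_leaf[new] = min(min_leaf[a], min_leaf[b])
        active = [c for c in active if c not in (a, b)] + [new]
    return Dendrogram(tuple(labels), tuple(merges))


def single_bait_interactors(m: CountMatrix, tau: float = 0.0) -> dict[str, str]:
    """Select proteins with mean signal above ``tau`` for exactly one bait.

    The control peptide counts as a bait column here: a protein whose only
    signal is on the control is 'control-specific' and is removed later by
    the control-elimination step, while a protein touching several baits is
    dropped as non-selective.
    """
    if m.stage != "replicate_mean":
        raise ValueError(f"single_bait_interactors expects replicate_mean, got {m.stage!r}")
    assign: dict[str, str] = {}
    baits = list(m.data.columns)
    arr = m.data.to_numpy(dtype=float)
    for i, protein in enumerate(m.proteins):
        above = np.flatnonzero(arr[i] > tau)
        if above.size == 1:
            assign[protein] = baits[above[0]]
    return assign


def bait_pure_clusters(
    dend: Dendrogram, assignment: dict[str, str]
) -> list[tuple[str, list[str]]]:
    """Maximal subtrees whose leaves all share one bait assignment.

    Every leaf must be assigned.  Returns (bait, [proteins]) with proteins
    in dendrogram leaf order; each leaf belongs to exactly one cluster.
    """
    missing = [l for l in dend.labels if l not in assignment]
    if missing:
        raise ValueError(f"unassigned leaves: {missing}")
    n = dend.n_leaves
    kids = dend.children()

    label_of: dict[int, str | None] = {}
    leaves_of: dict[int, list[int]] = {}
    for i in range(n):
        label_of[i] = assignment[dend.labels[i]]
        leaves_of[i] = [i]
    for k, (a, b, _) in enumerate(dend.merges):
        node = n + k
        la, lb = label_of[a], label_of[b]
        label_of[node] = la if (la is not None and la == lb) else None
        leaves_of[node] = leaves_of[a] + leaves_of[b]

    clusters: list[tuple[str, list[str]]] = []
    order_index = {leaf: pos for pos, leaf in enumerate(dend.leaf_order())}

    def collect(node: int) -> None:
        if label_of[node] is not None:
            leaves = sorted(leaves_of[node], key=order_index.__getitem__)
            clusters.append((label_of[node], [dend.labels[i] for i in leaves]))
            return
        a, b = kids[node]
        collect(a)
        collect(b)

    root = n + len(dend.merges) - 1 if n > 1 else 0
    collect(root)
    clusters.sort(key=lambda c: order_index[
        next(i for i in range(n) if dend.labels[i] == c[1][0])
    ])
    return clusters


def write_cdt_gtr(m: CountMatrix, dend: Dendrogram, prefix) -> tuple[str, str]:
    """Write a TreeView-compatible clustered data table (.cdt) and gene tree (.gtr).

    The .gtr stores each merge as ``NODEkX  child_a  child_b  similarity``
    with similarity = 1 - merge distance; the .cdt lists rows in dendrogram
    leaf order with GID identifiers.  Returns the two file paths.
    """
    if m.stage != "replicate_mean":
        raise ValueError("write_cdt_gtr expects a replicate_mean matrix")
    if list(dend.labels) != list(m.proteins):
        raise ValueError("dendrogram leaves and matrix rows are inconsistent")
    n = dend.n_leaves

    def node_name(idx: int) -> str:
        return f"GENE{idx}X" if idx < n else f"NODE{idx - n + 1}X"

    gtr_path = f"{prefix}.gtr"
    cdt_path = f"{prefix}.cdt"
    with open(gtr_path, "w", newline="") as fh:
        for k, (a, b, dd) in enumerate(dend.merges):
            fh.write(f"NODE{k + 1}X\t{node_name(a)}\t{node_name(b)}\t{1.0 - dd:.6g}\n")
    baits = [str(b) for b in m.data.columns]
    with open(cdt_path, "w", newline="") as fh:
        fh.write("GID\tUNIQID\tNAME\tGWEIGHT\t" + "\t".join(baits) + "\n")
        fh.write("EWEIGHT\t\t\t\t" + "\t".join(["1"] * len(baits)) + "\n")
        for i in dend.leaf_order():
            protein = dend.labels[i]
            row = m.data.loc[protein]
            vals = "\t".join(f"{v:.6g}" for v in row.to_numpy(dtype=float))
            fh.write(f"GENE{i}X\t{protein}\t{protein}\t1\t{vals}\n")
    return cdt_path, gtr_path
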