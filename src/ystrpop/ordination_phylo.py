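"""Ordination and phylogeny on population-level distance/frequency matrices.

Three standard views of population structure:

* classical (Torgerson) metric MDS of a pairwise distance matrix — the
  eigendecomposition of B = -1/2 J D2 J, with coordinates scaled by the
  square roots of the positive eigenvalues, so a Euclidean-embeddable
  matrix is reproduced exactly;
* PCA of a populations x haplogroup-frequency matrix via column mean
  centering and SVD, with per-axis explained-variance fractions;
* neighbor-joining (Saitou & Nei) tree construction, which recovers any
  additive distance matrix exactly, serialized to Newick.

Negative off-diagonal entries (possible for Rst estimates) are floored at
zero by default before MDS/NJ, since both interpret inputs as distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import IO, Sequence

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .haplotype_io import _ensure_text_stream

__all__ = [
    "OrdinationResult",
    "TreeNode",
    "PhyloTree",
    "classical_mds",
    "pca_frequencies",
    "nj_tree",
    "write_newick",
    "newick_string",
]


@dataclass
class OrdinationResult:
    labels: list[str]
    coordinates: np.ndarray  # len(labels) x k
    eigenvalues: np.ndarray  # descending, full set
    explained_fraction: np.ndarray  # per retained axis


@dataclass
class TreeNode:
    """Node of an (un)rooted phylogeny; children carry branch lengths."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree anchored at an internal node of degree 3 (or a single
    cherry for 2 taxa). Leaf labels are the input population ids."""

    root: TreeNode

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def cophenetic(self, labels: Sequence[str] | None = None) -> tuple[list[str], np.ndarray]:
        """Path-length distances between all leaf pairs (the additive metric
        the tree induces); used to check additivity-exactness."""
        order = list(labels) if labels is not None else self.leaf_labels
        index = {lab: i for i, lab in enumerate(order)}
        n = len(order)
        dist = np.zeros((n, n))

        def walk(node: TreeNode, depth: float, acc: list[tuple[int, float]]) -> list[tuple[int, float]]:
            if node.is_leaf:
                return [(index[node.name], depth)]
            below: list[list[tuple[int, float]]] = []
            for child, blen in node.children:
                below.append(walk(child, depth + blen, acc))
            for a in range(len(below)):
                for b in range(a + 1, len(below)):
                    for i, di in below[a]:
                        for j, dj in below[b]:
                            dist[i, j] = dist[j, i] = di + dj - 2 * depth
            return [pair for sub in below for pair in sub]

        walk(self.root, 0.0, [])
        return order, dist


def _validate_distance_matrix(d: np.ndarray, floor_negative: bool) -> np.ndarray:
    d = np.asarray(d, dtype=float).copy()
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError(f"distance matrix must be square, got {d.shape}")
    if np.max(np.abs(d - d.T)) > 1e-9:
        raise ValidationError("distance matrix asymmetric beyond 1e-9")
    if np.max(np.abs(np.diag(d))) > 1e-9:
        raise ValidationError("distance matrix diagonal must be zero")
    np.fill_diagonal(d, 0.0)
    if floor_negative:
        d[d < 0] = 0.0
    elif (d < 0).any():
        raise ValidationError("negative distances (pass floor_negative=True to clamp)")
    return d


def classical_mds(
    distance_matrix: np.ndarray,
    k: int = 2,
    labels: Sequence[str] | None = None,
    floor_negative: bool = True,
) -> OrdinationResult:
    """Torgerson double-centering MDS.

    Negative eigenvalues (non-Euclidean input) are reported in
    ``eigenvalues`` but never used for axes; if fewer than k positive
    eigenvalues exist, k is reduced with a warning.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    d = _validate_distance_matrix(distance_matrix, floor_negative)
    n = d.shape[0]
    labels = list(labels) if labels is not None else [f"pop{i}" for i in range(n)]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_pos = int(np.sum(eigval > max(1e-12, 1e-12 * abs(eigval[0]))))
    if k > n_pos:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; reducing k from {k}", stacklevel=2
        )
        k = max(n_pos, 0)
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    pos_sum = eigval[eigval > 0].sum()
    explained = eigval[:k] / pos_sum if pos_sum > 0 else np.zeros(k)
    return OrdinationResult(labels, coords, eigval, explained)


def pca_frequencies(
    freq_matrix: np.ndarray,
    labels: Sequence[str] | None = None,
    k: int | None = None,
) -> OrdinationResult:
    """PCA of a populations x haplogroup-frequency matrix.

    Columns are mean-centered (no scaling: frequencies share a unit) and
    the covariance eigenstructure is obtained through SVD. Explained
    fractions are eigenvalues over their total, summing to 1.
    """
    x = np.asarray(freq_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise DegenerateInputError("need at least 3 populations (rows)")
    n = x.shape[0]
    labels = list(labels) if labels is not None else [f"pop{i}" for i in range(n)]
    centered = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    eigval = s * s / (n - 1)
    total = eigval.sum()
    explained_all = eigval / total if total > 0 else np.zeros_like(eigval)
    k = len(eigval) if k is None else min(k, len(eigval))
    scores = u[:, :k] * s[:k]
    return OrdinationResult(labels, scores, eigval, explained_all[:k])


def nj_tree(
    distance_matrix: np.ndarray,
    labels: Sequence[str] | None = None,
    floor_negative: bool = True,
) -> PhyloTree:
    """Neighbor-joining (Saitou & Nei) from a distance matrix.

    Q-criterion ties are broken by the lowest (row, column) index pair so
    the result is deterministic. For an additive matrix the tree's
    path-length metric equals the input exactly.
    """
    d = _validate_distance_matrix(distance_matrix, floor_negative)
    n = d.shape[0]
    if n < 3:
        raise DegenerateInputError("neighbor-joining needs at least 3 taxa")
    labels = list(labels) if labels is not None else [f"pop{i}" for i in range(n)]
    if len(labels) != n:
        raise ValidationError("label count does not match matrix size")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    dist = d.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = dist.sum(axis=1)
        q = (m - 2) * dist - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) among minima: flat argmin scans row-major, i < j half
        iu = np.triu_indices(m, 1)
        flat = q[iu]
        best = int(np.flatnonzero(flat == flat.min())[0])
        i, j = int(iu[0][best]), int(iu[1][best])
        bi = 0.5 * dist[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        bj = dist[i, j] - bi
        parent = TreeNode(children=[(nodes[i], bi), (nodes[j], bj)])
        new_d = 0.5 * (dist[i, :] + dist[j, :] - dist[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        reduced = np.zeros((m - 1, m - 1))
        reduced[:-1, :-1] = dist[np.ix_(keep, keep)]
        reduced[-1, :-1] = reduced[:-1, -1] = new_d[keep]
        dist = reduced
        nodes = [nodes[x] for x in keep] + [parent]
    # three-point formulas for the final unrooted join
    (a, b, c) = nodes
    da = 0.5 * (dist[0, 1] + dist[0, 2] - dist[1, 2])
    db = 0.5 * (dist[0, 1] + dist[1, 2] - dist[0, 2])
    dc = 0.5 * (dist[0, 2] + dist[1, 2] - dist[0, 1])
    root = TreeNode(children=[(a, da), (b, db), (c, dc)])
    return PhyloTree(root)


def _newick_label(name: str) -> str:
    if any(ch in name for ch in " \t(),:;'[]"):
        return "'" + name.replace("'", "''") + "'"
    return name


def _newick_node(node: TreeNode) -> str:
    if node.is_leaf:
        return _newick_label(node.name or "")
    inner = ",".join(
        f"{_newick_node(child)}:{blen:.10g}" for child, blen in node.children
    )
    return f"({inner})"


def newick_string(tree: PhyloTree) -> str:
    """Standard Newick with branch lengths; negative NJ lengths kept as-is."""
    return _newick_node(tree.root) + ";"


def write_newick(tree: PhyloTree, stream: IO[str] | str) -> None:
    with _ensure_text_stream(stream, "w") as fh:
        fh.write(newick_string(tree) + "\n")
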