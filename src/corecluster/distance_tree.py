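"""Core-derived distance matrices and Fitch-Margoliash distance trees.

The distance between two members of a core is computed on the core
columns only: a rigid superposition of one member onto the other
restricted to those columns, followed by a two-term combination of mean
per-column C-alpha deviation (Angstrom) and mean per-column property
dissimilarity (each property term in [0, 1]).  The matrix of all pairs
is normalized to a maximum entry of 1.

Trees are fitted under the Fitch-Margoliash weighted least-squares
criterion

    Q(T) = sum_{i<j} (d_ij - p_ij)^2 / d_ij^2

where p_ij is the path length between leaves i and j.  The search is
standard practice for distance trees: a neighbor-joining starting
topology, non-negative weighted least-squares branch lengths, and
nearest-neighbor-interchange hill climbing until no move lowers Q.
Everything is deterministic.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass

import numpy as np
import skbio
from scipy.optimize import nnls
from skbio.tree import TreeNode

from corecluster.core_builder import StructuralCore
from corecluster.pairwise_align import BLOSUM_UNIT, as_view, kabsch_superpose
from corecluster.structure_io import StructureModel

__all__ = [
    "DistanceMatrix",
    "pair_core_distance",
    "build_distance_matrix",
    "fitch_margoliash_tree",
    "write_newick",
    "read_newick",
    "wls_objective",
]

_EPS_WEIGHT = 1e-6  # floor for d_ij in the 1/d^2 WLS weights


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal, max-normalized distance matrix."""

    labels: list[str]
    data: np.ndarray
    normalized: bool = True

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("negative distances")
        self.data = d

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.data[i, j])

    def write_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("label\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.data):
                fh.write(lab + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")

    def write_phylip(self, path: str | os.PathLike) -> None:
        """PHYLIP-style lower-triangle export."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for i, lab in enumerate(self.labels):
                cells = " ".join(f"{self.data[i, j]:.6f}" for j in range(i))
                fh.write(f"{lab:<12s}{cells}\n".rstrip() + "\n")


def _property_dissimilarity(va, vb, idx_a: np.ndarray, idx_b: np.ndarray, rot: np.ndarray) -> float:
    """Mean per-column property dissimilarity; each term in [0, 1].

    Mirrors the alignment score terms (amino acid, local geometry,
    backbone direction) plus a burial term from the neighbor count;
    undefined (terminal) geometry entries are dropped from the mean.
    """
    terms = []
    pa, pb = va.aa_profile[idx_a], vb.aa_profile[idx_b]
    terms.append(1.0 - np.einsum("ij,jk,ik->i", pa, BLOSUM_UNIT, pb))

    dth = np.abs(va.theta[idx_a] - vb.theta[idx_b])
    dta = np.abs(va.tau[idx_a] - vb.tau[idx_b]) % 360.0
    dta = np.where(dta > 180.0, 360.0 - dta, dta)
    terms.append((dth + dta / 2.0) / 270.0)

    db = vb.direction[idx_b] @ rot.T
    cosang = np.einsum("ij,ij->i", va.direction[idx_a], db)
    terms.append((1.0 - cosang) / 2.0)

    dn = np.abs(va.neighbor_count[idx_a] - vb.neighbor_count[idx_b])
    terms.append(np.minimum(dn, 10.0) / 10.0)

    stacked = np.concatenate(terms)
    return float(np.nanmean(stacked))


def pair_core_distance(
    core: StructuralCore,
    a: str,
    b: str,
    weights: tuple[float, float] = (1.0, 1.0),
) -> float:
    """Distance between two core members over the core columns.

    ``weights = (w_xyz, w_prop)`` scale the geometric term (mean
    per-column C-alpha deviation after superposition, Angstrom) and the
    property term.  Zero for identical members and for rigidly moved
    copies (the superposition removes rigid motion).
    """
    for m in (a, b):
        if m not in core.col_index:
            raise KeyError(f"unknown member {m!r}")
    if a == b:
        return 0.0
    w_xyz, w_prop = weights
    ma, mb = core.models[a], core.models[b]
    idx_a, idx_b = core.col_index[a], core.col_index[b]
    xa, xb = ma.ca_coords[idx_a], mb.ca_coords[idx_b]
    sup = kabsch_superpose(xa, xb)
    dev = float(np.mean(np.linalg.norm(xa - sup.apply(xb), axis=1)))
    prop = _property_dissimilarity(as_view(ma), as_view(mb), idx_a, idx_b, sup.rotation)
    return w_xyz * dev + w_prop * prop


def build_distance_matrix(
    core: StructuralCore,
    weights: tuple[float, float] = (1.0, 1.0),
) -> DistanceMatrix:
    """All pairwise core distances, divided by the maximum entry.

    An all-zero matrix (identical members) is returned un-normalized
    with ``normalized=False`` and a warning.
    """
    labels = sorted(core.members)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 members for a distance matrix")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pair_core_distance(core, labels[i], labels[j], weights)
    dmax = d.max()
    if dmax <= 1e-9:  # all-identical members; avoid dividing by numeric dust
        warnings.warn("all pairwise distances are zero; matrix left un-normalized")
        return DistanceMatrix(labels=labels, data=np.zeros_like(d), normalized=False)
    return DistanceMatrix(labels=labels, data=d / dmax, normalized=True)


# ---------------------------------------------------------------------------
# Fitch-Margoliash fitting


def _canonical_order(tree: TreeNode) -> None:
    """Sort children by smallest descendant leaf name (determinism)."""
    for node in tree.postorder(include_self=True):
        if node.children:
            node.children.sort(key=lambda c: min(t.name for t in c.tips()) if c.children else c.name)


def _edges(tree: TreeNode) -> list[TreeNode]:
    """Every non-root node stands for the edge to its parent."""
    return [n for n in tree.preorder(include_self=False)]


def _path_matrix(tree: TreeNode, labels: list[str]) -> tuple[np.ndarray, list[TreeNode]]:
    """Binary incidence of leaf pairs (rows) on edges (columns)."""
    edges = _edges(tree)
    edge_pos = {id(e): k for k, e in enumerate(edges)}
    leaf_sets: dict[int, frozenset] = {}
    for node in tree.postorder(include_self=False):
        if node.children:
            leaf_sets[id(node)] = frozenset().union(*(leaf_sets[id(c)] for c in node.children))
        else:
            leaf_sets[id(node)] = frozenset([node.name])
    npairs = len(labels) * (len(labels) - 1) // 2
    a = np.zeros((npairs, len(edges)))
    row = 0
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            li, lj = labels[i], labels[j]
            for e in edges:
                below = leaf_sets[id(e)]
                if (li in below) != (lj in below):
                    a[row, edge_pos[id(e)]] = 1.0
            row += 1
    return a, edges


def _condensed(d: np.ndarray) -> np.ndarray:
    n = len(d)
    return np.array([d[i, j] for i in range(n) for j in range(i + 1, n)])


def _fit_lengths(tree: TreeNode, labels: list[str], dvec: np.ndarray, w: np.ndarray) -> float:
    """Non-negative WLS branch lengths in place; returns the objective."""
    a, edges = _path_matrix(tree, labels)
    sw = np.sqrt(w)
    x, _ = nnls(a * sw[:, None], dvec * sw)
    for e, length in zip(edges, x):
        e.length = float(length)
    resid = dvec - a @ x
    return float(np.sum(w * resid**2))


def wls_objective(tree: TreeNode, m: DistanceMatrix) -> float:
    """Fitch-Margoliash objective of a tree against a matrix."""
    dvec = _condensed(m.data)
    w = 1.0 / np.maximum(dvec, _EPS_WEIGHT) ** 2
    labels = list(m.labels)
    a, edges = _path_matrix(tree, labels)
    x = np.array([e.length if e.length is not None else 0.0 for e in edges])
    resid = dvec - a @ x
    return float(np.sum(w * resid**2))


def _nni_candidates(tree: TreeNode):
    """Deterministic list of NNI moves: (internal node v, child of v,
    swap partner on the parent side)."""
    moves = []
    for v in tree.preorder(include_self=False):
        if not v.children:
            continue
        u = v.parent
        partners = [c for c in u.children if c is not v]
        if not partners:
            continue
        partner = partners[0]
        for child in v.children:
            moves.append((v, child, partner))
    return moves


def _apply_nni(tree: TreeNode, v_path: tuple[int, ...], child_idx: int, partner_path: tuple[int, ...]) -> TreeNode:
    """Apply an NNI on a deep copy addressed by child-index paths."""
    new = tree.copy()

    def _at(path):
        node = new
        for k in path:
            node = node.children[k]
        return node

    v = _at(v_path)
    partner = _at(partner_path)
    child = v.children[child_idx]
    u = v.parent
    ci = u.children.index(partner)
    vi = v.children.index(child)
    u.children[ci] = child
    child.parent = u
    v.children[vi] = partner
    partner.parent = v
    return new


def _node_path(tree: TreeNode, node: TreeNode) -> tuple[int, ...]:
    path = []
    while node.parent is not None:
        path.append(node.parent.children.index(node))
        node = node.parent
    return tuple(reversed(path))


def fitch_margoliash_tree(m: DistanceMatrix) -> TreeNode:
    """Fit an unrooted weighted least-squares (Fitch-Margoliash) tree.

    Neighbor-joining start topology, non-negative WLS branch lengths,
    then NNI hill climbing accepting the best improving move per sweep.
    The returned :class:`skbio.tree.TreeNode` is rooted at an internal
    trifurcation, the usual textual representation of an unrooted tree.
    """
    labels = list(m.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 labels")
    dvec = _condensed(m.data)
    w = 1.0 / np.maximum(dvec, _EPS_WEIGHT) ** 2

    if n == 3:
        tree = TreeNode.read(io.StringIO(f"({labels[0]},{labels[1]},{labels[2]});"))
    else:
        sk_dm = skbio.DistanceMatrix(m.data, ids=labels)
        tree = skbio.tree.nj(sk_dm)
    _canonical_order(tree)
    best_q = _fit_lengths(tree, labels, dvec, w)

    improved = True
    while improved:
        improved = False
        best_move = None
        for v, child, partner in _nni_candidates(tree):
            cand = _apply_nni(
                tree,
                _node_path(tree, v),
                v.children.index(child),
                _node_path(tree, partner),
            )
            q = _fit_lengths(cand, labels, dvec, w)
            if q < best_q - 1e-12 and (best_move is None or q < best_move[0]):
                best_move = (q, cand)
        if best_move is not None:
            best_q, tree = best_move
            _canonical_order(tree)
            _fit_lengths(tree, labels, dvec, w)
            improved = True
    return tree


def write_newick(tree: TreeNode, path: str | os.PathLike) -> None:
    """Serialize with branch lengths; internal names (e.g. jackknife
    support fractions) are written as internal node labels."""
    tree.write(os.fspath(path), format="newick")


def read_newick(path: str | os.PathLike) -> TreeNode:
    return TreeNode.read(os.fspath(path), format="newick")
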