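"""Low-dimensional summaries of a distance matrix: classical MDS and
neighbor-joining trees.

Both consume a symmetric distance matrix with zero diagonal — typically the
clamped (non-negative) view of a pairwise Rst matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import rst as rst_mod


@dataclass(frozen=True)
class EmbeddingResult:
    """Classical (Torgerson) MDS embedding of a distance matrix."""

    labels: list[str]
    coordinates: np.ndarray  #: (n, dims)
    eigenvalues: np.ndarray  #: all eigenvalues of the centered matrix, descending
    positive_mass_captured: float  #: share of positive-eigenvalue mass in the kept axes

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coordinates,
            columns=[f"dim{i + 1}" for i in range(self.coordinates.shape[1])],
        )
        df.insert(0, "label", self.labels)
        df["positive_mass_captured"] = self.positive_mass_captured
        return df


def _as_matrix(D, labels=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(D, rst_mod.DistanceMatrix):
        return D.clamped().to_numpy(dtype=float), D.labels
    if isinstance(D, pd.DataFrame):
        return D.to_numpy(dtype=float), [str(x) for x in D.index]
    A = np.asarray(D, dtype=float)
    if labels is None:
        labels = [str(i) for i in range(A.shape[0])]
    return A, list(labels)


def _check_distance_matrix(A: np.ndarray) -> None:
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(A, A.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(A), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal must be zero")
    if (A < 0).any():
        raise ValueError("negative distances: clamp Rst estimates at zero first")


def classical_mds(D, dims: int = 2, labels: list[str] | None = None) -> EmbeddingResult:
    """Torgerson metric multidimensional scaling.

    Double-centers the squared distances, ``B = -1/2 J D^2 J``, and embeds
    on the top ``dims`` eigenpairs.  Axes are ordered by descending
    eigenvalue and sign-fixed so the first nonzero coordinate on each axis
    is positive.  If fewer than ``dims`` positive eigenvalues exist the
    remaining axes are zero-padded (with a warning).
    """
    A, labels = _as_matrix(D, labels)
    _check_distance_matrix(A)
    n = A.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (A**2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    tol = max(1e-12, 1e-9 * max(abs(evals[0]), 1.0))
    n_pos = int(np.sum(evals > tol))
    if dims > n_pos:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; padding {dims - n_pos} axes with zeros",
            stacklevel=2,
        )
    coords = np.zeros((n, dims))
    for k in range(min(dims, n_pos)):
        coords[:, k] = evecs[:, k] * np.sqrt(evals[k])
    # deterministic sign: first nonzero coordinate of each axis positive
    for k in range(dims):
        col = coords[:, k]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, k] = -col
    pos_mass = float(evals[evals > tol].sum())
    kept = float(evals[: min(dims, n_pos)].clip(min=0).sum())
    captured = kept / pos_mass if pos_mass > 0 else 0.0
    return EmbeddingResult(labels, coords, evals, captured)


def neighbor_joining(D, labels: list[str] | None = None) -> TreeNode:
    """Saitou-Nei neighbor joining on a distance matrix.

    Agglomerates the pair minimizing
    ``Q(i,j) = (r - 2) d(i,j) - R_i - R_j`` (``R_i`` the row sum, ``r`` the
    current taxon count).  Ties are broken by the lexicographically smallest
    (sorted) label pair so the result is independent of input order.
    Negative limb lengths are clamped to zero with the deficit moved onto
    the sibling limb (standard practice; NJ limb estimates may go negative
    on non-additive input).  Returns an unrooted tree represented with a
    trifurcating root.
    """
    A, labels = _as_matrix(D, labels)
    _check_distance_matrix(A)
    n = A.shape[0]
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    if len(set(labels)) != n:
        raise ValueError("duplicate labels")

    d = {}
    nodes: dict[str, TreeNode] = {}
    # sort keys: (is_internal, label) so ties prefer original taxa, then lexicographic
    sort_key: dict[str, tuple] = {}
    for i, a in enumerate(labels):
        nodes[a] = TreeNode(name=a)
        sort_key[a] = (0, a)
        for j, b in enumerate(labels):
            if i < j:
                d[frozenset((a, b))] = A[i, j]
    active = sorted(labels)
    internal_count = 0

    def dist(a: str, b: str) -> float:
        return d[frozenset((a, b))]

    while len(active) > 3:
        r = len(active)
        rowsum = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        best_pair = None
        for ii in range(r):
            for jj in range(ii + 1, r):
                a, b = active[ii], active[jj]
                q = (r - 2) * dist(a, b) - rowsum[a] - rowsum[b]
                pair_key = tuple(sorted((sort_key[a], sort_key[b])))
                if best is None or q < best - 1e-12 or (abs(q - best) <= 1e-12 and pair_key < best_pair):
                    best, best_pair = q, pair_key
                    fi, fj = a, b
        a, b = fi, fj
        dab = dist(a, b)
        la = 0.5 * dab + (rowsum[a] - rowsum[b]) / (2 * (r - 2))
        lb = dab - la
        # clamp negative limbs, moving the deficit to the sibling limb
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        internal_count += 1
        uname = f"__internal{internal_count}"
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length, nb.length = float(max(la, 0.0)), float(max(lb, 0.0))
        nodes[uname] = TreeNode(children=[na, nb])
        sort_key[uname] = (1, min(sort_key[a], sort_key[b]))
        for c in active:
            if c in (a, b):
                continue
            d[frozenset((uname, c))] = 0.5 * (dist(a, c) + dist(b, c) - dab)
        active = sorted((x for x in active if x not in (a, b)), )
        active.append(uname)
        active.sort()

    x, y, z = active
    lx = 0.5 * (dist(x, y) + dist(x, z) - dist(y, z))
    ly = 0.5 * (dist(x, y) + dist(y, z) - dist(x, z))
    lz = 0.5 * (dist(x, z) + dist(y, z) - dist(x, y))
    children = []
    for name, length in ((x, lx), (y, ly), (z, lz)):
        node = nodes.pop(name)
        node.length = float(max(length, 0.0))
        children.append(node)
    return TreeNode(children=children)


def tip_distances(tree: TreeNode) -> pd.DataFrame:
    """Leaf-to-leaf path-length matrix of a tree."""
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


def is_cherry(tree: TreeNode, a: str, b: str) -> bool:
    """True if tips ``a`` and ``b`` are siblings (joined by one internal node)."""
    ta = tree.find(a)
    tb = tree.find(b)
    return ta.parent is tb.parent and ta.parent is not None


def plot_mds(result: EmbeddingResult, path: str) -> None:
    """Scatter plot of a 2-D embedding (static file output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    xs, ys = result.coordinates[:, 0], result.coordinates[:, 1]
    ax.scatter(xs, ys)
    for lab, x, y in zip(result.labels, xs, ys):
        ax.annotate(lab, (x, y), textcoords="offset points", xytext=(4, 4))
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    ax.set_title("Classical MDS of pairwise Rst")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
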