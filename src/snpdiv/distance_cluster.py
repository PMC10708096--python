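"""Genotype distances, UPGMA dendrograms and principal coordinate analysis.

The allele-sharing distance treats a diploid unphased call as an unordered
allele pair: per locus, distance = 1 - (shared alleles)/2, i.e. |dosage
difference| / 2, averaged over loci where both calls are present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import MISSING, GenotypeMatrix


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # symmetric, zero diagonal
    comparable_loci: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal not zero")


@dataclass
class TreeNode:
    """Rooted tree node; leaves carry names, edges carry lengths."""

    name: str | None = None
    length: float | None = None  # branch length to parent
    height: float = 0.0  # ultrametric height of this node
    children: list["TreeNode"] = field(default_factory=list)

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def internal_nodes(self) -> list["TreeNode"]:
        if not self.children:
            return []
        out = [self]
        for c in self.children:
            out.extend(c.internal_nodes())
        return out


@dataclass
class PcoaResult:
    ids: list[str]
    coordinates: np.ndarray  # accessions x axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    pct_variance: np.ndarray  # fraction of positive-eigenvalue total, per axis
    negative_eigenvalues: np.ndarray


def allele_sharing_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Mean over comparable loci of |dosage_i - dosage_j| / 2.

    AA vs AA -> 0, AA vs AB -> 0.5, AA vs BB -> 1, AB vs AB -> 0.
    """
    if g.n_accessions < 2:
        raise ValueError("need at least two accessions")
    d = g.dosage.astype(float)
    present = g.dosage != MISSING
    d[~present] = 0.0
    n = g.n_accessions
    dist = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = present[i] & present
        diff = np.abs(d[i] - d) / 2.0
        diff[~both] = 0.0
        c = both.sum(axis=1)
        comp[i] = c
        with np.errstate(invalid="ignore"):
            dist[i] = diff.sum(axis=1) / c
    np.fill_diagonal(dist, 0.0)
    zero = np.argwhere((comp == 0) & ~np.eye(n, dtype=bool))
    if zero.size:
        i, j = (int(x) for x in zero[0])
        raise ValueError(
            f"zero comparable loci for pair ({g.accession_ids[i]}, {g.accession_ids[j]})"
        )
    dist = (dist + dist.T) / 2.0
    return DistanceMatrix(ids=list(g.accession_ids), d=dist, comparable_loci=comp)


def write_distance_csv(dm: DistanceMatrix, path) -> None:
    """Square labeled distance-matrix CSV (header row + label column)."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([""] + dm.ids)
        for i, name in enumerate(dm.ids):
            w.writerow([name] + [f"{v:.12g}" for v in dm.d[i]])


def read_distance_csv(path) -> DistanceMatrix:
    import csv
    from pathlib import Path

    with Path(path).open(newline="") as fh:
        rows = list(csv.reader(fh))
    ids = rows[0][1:]
    d = np.array([[float(v) for v in row[1:]] for row in rows[1:]])
    return DistanceMatrix(ids=ids, d=d)


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomeration into a rooted ultrametric tree.

    New cluster distances are size-weighted arithmetic means; node height is
    half the merge distance. Ties are broken on the lexicographically
    smallest pair of sorted member-id tuples, making the tree independent of
    input order.
    """
    if not np.isfinite(dm.d).all():
        raise ValueError("non-finite distances")
    nodes: dict[frozenset[str], TreeNode] = {
        frozenset([name]): TreeNode(name=name, height=0.0) for name in dm.ids
    }
    dist: dict[frozenset[frozenset[str]], float] = {}
    keys = list(nodes)
    index = {frozenset([name]): i for i, name in enumerate(dm.ids)}
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            dist[frozenset({keys[a], keys[b]})] = float(
                dm.d[index[keys[a]], index[keys[b]]]
            )

    while len(nodes) > 1:
        best_pair = None
        best = (np.inf, None)
        for pair, val in dist.items():
            a, b = sorted(pair, key=lambda s: tuple(sorted(s)))
            key = (val, (tuple(sorted(a)), tuple(sorted(b))))
            if key < best:
                best = key
                best_pair = (a, b)
        a, b = best_pair
        dmin = best[0]
        height = dmin / 2.0
        na, nb = nodes.pop(a), nodes.pop(b)
        merged = TreeNode(height=height, children=[na, nb])
        na.length = height - na.height
        nb.length = height - nb.height
        union = a | b
        wa, wb = len(a), len(b)
        for other in list(nodes):
            d_new = (
                wa * dist.pop(frozenset({a, other})) + wb * dist.pop(frozenset({b, other}))
            ) / (wa + wb)
            dist[frozenset({union, other})] = d_new
        del dist[frozenset({a, b})]
        nodes[union] = merged
    root = next(iter(nodes.values()))
    root.length = None
    return root


def cut_tree(tree: TreeNode, k: int) -> list[set[str]]:
    """Partition leaves into ``k`` blocks by removing the k-1 highest
    internal nodes (ties resolved deterministically by member names)."""
    leaves = tree.leaf_names()
    n = len(leaves)
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range 1..{n}")
    internal = tree.internal_nodes()
    internal.sort(key=lambda nd: (-nd.height, sorted(nd.leaf_names())))
    removed = set(id(nd) for nd in internal[: k - 1])
    blocks: list[set[str]] = []

    def collect(node: TreeNode) -> None:
        if id(node) in removed:
            for c in node.children:
                collect(c)
        else:
            blocks.append(set(node.leaf_names()))

    collect(tree)
    return sorted(blocks, key=lambda b: sorted(b)[0])


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Classical MDS: Gower double-centering of -0.5 d^2, eigendecomposition,
    coordinates scaled by sqrt of positive eigenvalues. Negative eigenvalues
    are excluded from the percent-variance denominator and reported apart."""
    n = len(dm.ids)
    d2 = dm.d**2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centerer @ d2 @ centerer
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-9 * max(1.0, float(np.abs(eigvals).max()))
    positive = eigvals > tol
    pos_vals = eigvals[positive]
    pos_vecs = eigvecs[:, positive]
    if n_axes is None:
        n_axes = len(pos_vals)
    if n_axes > len(pos_vals):
        n_axes = len(pos_vals)  # truncated: fewer positive axes than requested
    coords = pos_vecs[:, :n_axes] * np.sqrt(pos_vals[:n_axes])
    pct = pos_vals / pos_vals.sum() if pos_vals.size else pos_vals
    return PcoaResult(
        ids=list(dm.ids),
        coordinates=coords,
        eigenvalues=pos_vals,
        pct_variance=pct,
        negative_eigenvalues=eigvals[eigvals < -tol],
    )
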