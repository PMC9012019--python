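"""Population structure: PCA with Patterson normalization and
neighbor-joining trees with Newick output.

PCA centers each site by twice the sample ALT frequency and scales by
sqrt(2 p (1 - p)) — the drift-variance normalization used by
EIGENSOFT — with per-site mean imputation of missing genotypes, and
reports per-component variance-explained percentages.

The neighbor-joining implementation is the Saitou-Nei agglomeration
with the standard Q-criterion.  Ties in Q resolve to the
lexicographically smallest pair of cluster labels (each cluster is
labelled by its smallest leaf), so the construction is deterministic.
Negative branch-length estimates are clamped to zero with the excess
moved onto the sibling branch, preserving the pairwise sum.  On an
additive distance matrix the recovered tree reproduces the input path
distances exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .vcfio import GenotypeMatrix

__all__ = ["PcaResult", "PhyloTree", "pca", "nj_tree", "write_newick",
           "population_distance_matrix"]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PcaResult:
    samples: list[str]
    coords: np.ndarray  # (n_samples, n_components) PC scores
    variance_pct: np.ndarray  # non-increasing, sums to <= 100
    n_sites: int

    def to_tsv(self) -> str:
        ncomp = self.coords.shape[1]
        lines = ["sample\t" + "\t".join(f"PC{i+1}" for i in range(ncomp))]
        for s, row in zip(self.samples, self.coords):
            lines.append(s + "\t" + "\t".join(f"{v:.6g}" for v in row))
        return "\n".join(lines) + "\n"


def pca(gm: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """Principal components of the genotype matrix.

    Missing genotypes are mean-imputed per site; monomorphic sites are
    dropped.  Variance-explained is eigenvalue over trace of the sample
    covariance, as a percentage.
    """
    if gm.n_samples < 2 or gm.n_sites < 2:
        raise ValueError("PCA needs at least two samples and two sites")
    g = gm.geno.astype(float)
    called = g >= 0
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, g, 0.0).sum(axis=0) / (2.0 * n_called)
    keep = (n_called > 0) & (p > 0.0) & (p < 1.0)
    if not np.any(keep):
        raise ValueError("no polymorphic site available for PCA")
    g = g[:, keep]
    p = p[keep]
    x = np.where(called[:, keep], g, 2.0 * p)
    x = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))

    cov = x @ x.T / x.shape[1]
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = eigvec[:, order]
    ncomp = min(n_components, gm.n_samples - 1)
    coords = eigvec[:, :ncomp] * np.sqrt(eigval[:ncomp])
    var_pct = 100.0 * eigval[:ncomp] / eigval.sum()
    return PcaResult(list(gm.samples), coords, var_pct, int(keep.sum()))


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """Unrooted tree as an adjacency map with branch lengths."""

    adjacency: dict[int, list[tuple[int, float]]]
    leaf_labels: dict[int, str] = field(default_factory=dict)

    @property
    def leaves(self) -> list[str]:
        return sorted(self.leaf_labels.values())

    def _node_of(self, label: str) -> int:
        for node, lab in self.leaf_labels.items():
            if lab == label:
                return node
        raise KeyError(f"unknown leaf label {label!r}")

    def path_distance(self, a: str, b: str) -> float:
        """Sum of branch lengths along the unique path between leaves."""
        start, goal = self._node_of(a), self._node_of(b)
        stack = [(start, -1, 0.0)]
        while stack:
            node, parent, dist = stack.pop()
            if node == goal:
                return dist
            for nxt, length in self.adjacency[node]:
                if nxt != parent:
                    stack.append((nxt, node, dist + length))
        raise RuntimeError("disconnected tree")

    def distance_matrix(self) -> tuple[np.ndarray, list[str]]:
        labs = self.leaves
        d = np.zeros((len(labs), len(labs)))
        for i, j in itertools.combinations(range(len(labs)), 2):
            d[i, j] = d[j, i] = self.path_distance(labs[i], labs[j])
        return d, labs

    # -- newick -----------------------------------------------------------
    def to_newick(self, root_at: str | None = None, sigfigs: int = 6) -> str:
        def fmt(x: float) -> str:
            return f"{x:.{sigfigs}g}"

        def render(node: int, parent: int) -> str:
            children = [(n, l) for n, l in self.adjacency[node] if n != parent]
            if not children:
                return self.leaf_labels[node]
            inner = ",".join(f"{render(n, node)}:{fmt(l)}" for n, l in children)
            return f"({inner})"

        if root_at is None:
            # root the rendering at an internal node (or the first leaf's
            # neighbor for a 2-node tree)
            internal = [n for n in self.adjacency if n not in self.leaf_labels]
            top = internal[0] if internal else next(iter(self.adjacency))
            return render(top, -1) + ";"

        leaf = self._node_of(root_at)
        (nbr, length), = self.adjacency[leaf]
        # mid-branch rooting on the outgroup's pendant edge
        half = length / 2.0
        return (
            f"({self.leaf_labels[leaf]}:{fmt(half)},{render(nbr, leaf)}:{fmt(half)});"
        )


def nj_tree(distance: np.ndarray, labels: list[str]) -> PhyloTree:
    """Saitou-Nei neighbor joining on a symmetric distance matrix."""
    d = np.asarray(distance, dtype=float)
    r = len(labels)
    if d.shape != (r, r) or not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must be square, symmetric, zero-diagonal")
    if np.any(d < 0):
        raise ValueError("distance matrix must be non-negative")
    if r < 3:
        raise ValueError("need at least three labels")
    if len(set(labels)) != r:
        raise ValueError("labels must be unique")

    adjacency: dict[int, list[tuple[int, float]]] = {i: [] for i in range(r)}
    leaf_labels = {i: labels[i] for i in range(r)}
    next_id = r
    active = list(range(r))
    dist = {(min(i, j), max(i, j)): d[i, j] for i in range(r) for j in range(i + 1, r)}
    tag = {i: labels[i] for i in range(r)}  # smallest leaf label under node

    def get(i: int, j: int) -> float:
        return dist[(min(i, j), max(i, j))]

    def connect(a: int, b: int, length: float) -> None:
        adjacency[a].append((b, length))
        adjacency[b].append((a, length))

    while len(active) > 3:
        m = len(active)
        rsum = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for i, j in itertools.combinations(active, 2):
            q = (m - 2) * get(i, j) - rsum[i] - rsum[j]
            key = (q, tuple(sorted((tag[i], tag[j]))))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        li = 0.5 * get(i, j) + (rsum[i] - rsum[j]) / (2.0 * (m - 2))
        lj = get(i, j) - li
        if li < 0:
            li, lj = 0.0, get(i, j)
        elif lj < 0:
            li, lj = get(i, j), 0.0
        new = next_id
        next_id += 1
        adjacency[new] = []
        connect(new, i, li)
        connect(new, j, lj)
        for k in active:
            if k in (i, j):
                continue
            dist[(min(new, k), max(new, k))] = 0.5 * (get(i, k) + get(j, k) - get(i, j))
        active = [k for k in active if k not in (i, j)] + [new]
        tag[new] = min(tag[i], tag[j])

    a, b, c = active
    center = next_id
    adjacency[center] = []
    la = 0.5 * (get(a, b) + get(a, c) - get(b, c))
    lb = 0.5 * (get(a, b) + get(b, c) - get(a, c))
    lc = 0.5 * (get(a, c) + get(b, c) - get(a, b))
    for node, length in ((a, la), (b, lb), (c, lc)):
        connect(center, node, max(length, 0.0))
    return PhyloTree(adjacency, leaf_labels)


def population_distance_matrix(
    d_samples: np.ndarray, populations: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Collapse a sample-level distance matrix to population level by
    averaging across-population sample pairs (within-pair mean for the
    diagonal is discarded; the population diagonal is zero)."""
    labels = list(dict.fromkeys(populations))
    pops = np.asarray(populations, dtype=object)
    k = len(labels)
    out = np.zeros((k, k))
    for x, y in itertools.combinations(range(k), 2):
        mask_x = pops == labels[x]
        mask_y = pops == labels[y]
        out[x, y] = out[y, x] = float(d_samples[np.ix_(mask_x, mask_y)].mean())
    return out, labels


def write_newick(tree: PhyloTree, path, root_at: str | None = None) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(tree.to_newick(root_at=root_at) + "\n")
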