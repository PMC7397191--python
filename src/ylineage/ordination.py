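"""Non-metric MDS (Kruskal stress-1) and complete-linkage clustering.

NMDS starts from the classical (Torgerson) scaling of the
double-centred squared-distance matrix, then alternates isotonic
(monotone) regression of the configuration distances on the input
dissimilarity order with Guttman-transform updates, minimising Kruskal's
stress-1:

    stress1 = sqrt( sum_ij (d_ij - dhat_ij)^2 / sum_ij d_ij^2 )

Both the stress of the starting configuration ("initial stress") and the
optimised stress are reported, as fractions in [0, 1].

The hierarchical clustering is standard agglomerative complete linkage
(cluster distance = max member pairwise distance) with a deterministic
tie-break: among equally close cluster pairs the lexicographically
smallest pair of cluster leader labels merges first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .distances import DistanceMatrix


@dataclass(frozen=True)
class MDSResult:
    ids: tuple[str, ...]
    coordinates: np.ndarray  # (n, dims)
    stress_initial: float
    stress_final: float
    converged: bool
    n_iter: int


def _classical_scaling(d: np.ndarray, dims: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(lam)
    # sign convention: largest-magnitude coordinate of each axis positive,
    # so the start (hence the stress path) ignores object order
    for k in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]
    return coords


def _stress_and_disparities(
    delta: np.ndarray, coords: np.ndarray
) -> tuple[float, np.ndarray]:
    n = coords.shape[0]
    iu = np.triu_indices(n, 1)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    dv, deltav = d[iu], delta[iu]
    iso = IsotonicRegression()
    dhat = iso.fit_transform(deltav, dv)
    # scale disparities to the configuration's sum of squares
    ssd = (dv**2).sum()
    ssh = (dhat**2).sum()
    if ssh > 0:
        dhat = dhat * np.sqrt(ssd / ssh)
    denom = ssd
    stress = float(np.sqrt(((dv - dhat) ** 2).sum() / denom)) if denom > 0 else 0.0
    full = np.zeros_like(delta)
    full[iu] = dhat
    return stress, full + full.T


def _guttman_update(dhat: np.ndarray, coords: np.ndarray) -> np.ndarray:
    n = coords.shape[0]
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 1e-12, dhat / d, 0.0)
    b = -ratio
    b[np.arange(n), np.arange(n)] = ratio.sum(axis=1)
    return (b @ coords) / n


def nmds(
    dm: DistanceMatrix,
    dims: int = 2,
    max_iter: int = 500,
    tol: float = 1e-9,
    seed: int | None = None,
) -> MDSResult:
    """Non-metric MDS of a distance matrix, reporting initial/final stress.

    ``seed`` is accepted for interface uniformity; the classical-scaling
    start makes the procedure deterministic.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("NMDS needs at least 3 objects")
    if dims >= n:
        raise ValueError("dims must be smaller than the object count")
    delta = np.asarray(dm.values, dtype=float)
    if dm.has_negative:
        raise ValueError("negative dissimilarities; floor them upstream (DistanceMatrix.floored)")
    if not (delta > 0).any():
        raise ValueError("all distances are zero")

    coords = _classical_scaling(delta, dims)
    stress_initial, dhat = _stress_and_disparities(delta, coords)
    stress = stress_initial
    best_stress, best_coords = stress_initial, coords
    converged = stress <= tol
    it = 0
    while not converged and it < max_iter:
        coords = _guttman_update(dhat, coords)
        new_stress, dhat = _stress_and_disparities(delta, coords)
        if new_stress < best_stress:
            best_stress, best_coords = new_stress, coords
        if abs(stress - new_stress) < tol:
            converged = True
        stress = new_stress
        it += 1
    return MDSResult(dm.ids, best_coords, stress_initial, best_stress, converged, it)


def write_coordinates(res: MDSResult, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stress_initial={res.stress_initial:.6f}\n")
        fh.write(f"# stress_final={res.stress_final:.6f}\n")
        fh.write("id\tx\ty\n" if res.coordinates.shape[1] == 2 else "id\tcoords\n")
        for name, xy in zip(res.ids, res.coordinates):
            fh.write(name + "\t" + "\t".join(f"{v:.6f}" for v in xy) + "\n")


# ---------------------------------------------------------------------------
# Complete-linkage hierarchical clustering


@dataclass
class DendrogramNode:
    """Binary merge tree; leaves carry labels, internal nodes a height."""

    height: float = 0.0
    label: str | None = None
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return self.children[0].leaves() + self.children[1].leaves()

    def to_newick(self) -> str:
        def fmt(node: DendrogramNode, parent_h: float) -> str:
            bl = parent_h - node.height
            if node.is_leaf:
                return f"{node.label}:{bl:.6g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{bl:.6g}"

        if self.is_leaf:
            return f"{self.label};"
        inner = ",".join(fmt(c, self.height) for c in self.children)
        return f"({inner});"


def hclust_complete(dm: DistanceMatrix) -> DendrogramNode:
    """Agglomerative complete-linkage clustering of a distance matrix.

    Ties are broken deterministically: the candidate pair whose sorted
    leader labels are lexicographically smallest merges first.  Heights
    are non-decreasing from leaves to root.
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("clustering needs at least 2 objects")
    d = np.asarray(dm.values, dtype=float).copy()
    nodes: dict[int, DendrogramNode] = {
        i: DendrogramNode(0.0, dm.ids[i]) for i in range(n)
    }
    leaders: dict[int, str] = {i: dm.ids[i] for i in range(n)}
    active = list(range(n))
    big = np.inf
    np.fill_diagonal(d, big)
    last_height = 0.0
    while len(active) > 1:
        sub = d[np.ix_(active, active)]
        dmin = sub.min()
        best: tuple[str, str] | None = None
        best_pair: tuple[int, int] | None = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                if sub[ai, aj] <= dmin + 1e-12:
                    i, j = active[ai], active[aj]
                    key = tuple(sorted((leaders[i], leaders[j])))
                    if best is None or key < best:
                        best = key
                        best_pair = (i, j)
        i, j = best_pair
        height = max(d[i, j], last_height)  # guard fp wobble; complete linkage is monotone
        merged = DendrogramNode(height, None, (nodes[i], nodes[j]))
        # Lance-Williams complete-linkage update into slot i
        for k in active:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = max(d[i, k], d[j, k])
        leaders[i] = min(leaders[i], leaders[j])
        nodes[i] = merged
        active.remove(j)
        last_height = height
    return nodes[active[0]]


def cut_tree(root: DendrogramNode, k: int) -> list[list[str]]:
    """Cut into k clusters by undoing the k-1 highest merges."""
    n_leaves = len(root.leaves())
    if not 1 <= k <= n_leaves:
        raise ValueError(f"k must be in [1, {n_leaves}]")
    clusters = [root]
    while len(clusters) < k:
        # split the cluster with the highest merge height
        idx = max(
            range(len(clusters)),
            key=lambda i: -1.0 if clusters[i].is_leaf else clusters[i].height,
        )
        node = clusters.pop(idx)
        clusters.extend(node.children)
    return [sorted(c.leaves()) for c in clusters]


@dataclass(frozen=True)
class PurityReport:
    n_leaves: int
    n_misfit: int
    proportion: float
    within_major: int
    cross_major: int
    misfits: tuple[str, ...]


def cluster_purity(
    root: DendrogramNode,
    labels: dict[str, str],
    k: int,
    major_of: dict[str, str] | None = None,
) -> PurityReport:
    """Leaves disagreeing with their cluster's majority haplogroup.

    Each of the k cut clusters is assigned its majority label; a misfit
    is a leaf with a different label.  With ``major_of`` (fine label ->
    major haplogroup), misfits are split into those whose major
    haplogroup still matches the cluster majority's ("within") and those
    crossing major haplogroups.
    """
    clusters = cut_tree(root, k)
    misfits: list[str] = []
    within = cross = 0
    for members in clusters:
        counts: dict[str, int] = {}
        for leaf in members:
            counts[labels[leaf]] = counts.get(labels[leaf], 0) + 1
        majority = max(sorted(counts), key=lambda lab: counts[lab])
        for leaf in members:
            if labels[leaf] != majority:
                misfits.append(leaf)
                if major_of is not None:
                    if major_of.get(labels[leaf]) == major_of.get(majority):
                        within += 1
                    else:
                        cross += 1
    n = sum(len(c) for c in clusters)
    return PurityReport(
        n_leaves=n,
        n_misfit=len(misfits),
        proportion=len(misfits) / n,
        within_major=within,
        cross_major=cross,
        misfits=tuple(sorted(misfits)),
    )
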