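"""Genetic and geographic distances, isolation by distance, and trees.

Pairwise differentiation estimates are linearized as F_ST/(1-F_ST),
which under two-dimensional isolation by distance is expected to grow
linearly with the logarithm of geographic separation.  The Mantel test
correlates the two distance matrices under joint row/column
permutations.  Population relationships are summarised by UPGMA
(ultrametric average-linkage) or neighbor-joining trees, with branch
confidence from bootstrap resampling of loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .differentiation import pairwise_locus_components, pairwise_theta
from .matrix import BandMatrix, PopulationTable

__all__ = [
    "DistanceSet",
    "MantelResult",
    "PopulationTree",
    "rousset_linearize",
    "geographic_distance",
    "distance_set",
    "mantel_test",
    "build_tree",
    "bootstrap_support",
]

EARTH_RADIUS_KM = 6371.0


def rousset_linearize(theta_pair: pd.DataFrame) -> pd.DataFrame:
    """Elementwise F_ST/(1-F_ST) with a zero diagonal."""
    values = theta_pair.to_numpy(dtype=float)
    if np.any(np.diag(values) != 0):
        raise ValueError("pairwise theta matrix must have a zero diagonal")
    off = ~np.eye(len(values), dtype=bool)
    if np.any(values[off] >= 1.0):
        raise ValueError("pairwise theta of 1 gives an infinite linearized distance")
    lin = values / (1.0 - values)
    np.fill_diagonal(lin, 0.0)
    return pd.DataFrame(lin, index=theta_pair.index, columns=theta_pair.columns)


def _haversine(lat1, lon1, lat2, lon2) -> float:
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def geographic_distance(pops: PopulationTable, order=None) -> pd.DataFrame:
    """Great-circle distances in km between population coordinates."""
    names = list(order) if order is not None else pops.names
    coords = pops.coordinates(names)
    n = len(names)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _haversine(*coords[i], *coords[j])
    return pd.DataFrame(out, index=names, columns=names)


@dataclass
class DistanceSet:
    """Matched genetic and geographic distance matrices."""

    genetic: pd.DataFrame  # linearized Fst/(1-Fst)
    geographic_km: pd.DataFrame

    @property
    def log_geographic(self) -> pd.DataFrame:
        g = self.geographic_km.to_numpy(dtype=float)
        off = ~np.eye(len(g), dtype=bool)
        if np.any(g[off] <= 0):
            raise ValueError("non-positive geographic distance; cannot log-transform")
        out = np.zeros_like(g)
        out[off] = np.log(g[off])
        return pd.DataFrame(out, index=self.geographic_km.index,
                            columns=self.geographic_km.columns)

    def mean_genetic(self) -> float:
        v = self.genetic.to_numpy()
        iu = np.triu_indices(len(v), k=1)
        return float(v[iu].mean())


def distance_set(m: BandMatrix, pops: PopulationTable) -> DistanceSet:
    """Pairwise linearized theta and great-circle km for one dataset."""
    theta = pairwise_theta(m)
    order = list(theta.index)
    return DistanceSet(
        genetic=rousset_linearize(theta),
        geographic_km=geographic_distance(pops, order),
    )


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    seed: int | None = None


def mantel_test(
    genetic: pd.DataFrame,
    geographic: pd.DataFrame,
    n_perm: int = 10000,
    log_transform: bool = True,
    seed: int | None = None,
) -> MantelResult:
    """Mantel correlation between genetic and geographic distances.

    ``r`` is the Pearson correlation of the off-diagonal upper
    triangles; the null distribution permutes rows and columns of the
    genetic matrix jointly.  The p-value is two-sided with +1 smoothing.
    Geographic distances are log-transformed (natural log) by default,
    the isolation-by-distance scale for two-dimensional habitats.
    """
    G = genetic.to_numpy(dtype=float)
    D = geographic.to_numpy(dtype=float)
    n = len(G)
    if n < 4:
        raise ValueError("need >=4 populations")
    if G.shape != D.shape:
        raise ValueError("matrix shapes differ")
    iu = np.triu_indices(n, k=1)
    if log_transform:
        zeros = [(genetic.index[i], genetic.index[j])
                 for i, j in zip(*iu) if D[i, j] <= 0]
        if zeros:
            raise ValueError(f"zero geographic distance for pair(s) {zeros}; cannot log-transform")
        D = np.where(np.eye(n, dtype=bool), 0.0, np.log(np.where(D > 0, D, 1.0)))
    x = D[iu]
    y = G[iu]
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = G[np.ix_(perm, perm)][iu]
        if abs(float(np.corrcoef(x, yp)[0, 1])) >= abs(r_obs) - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p, n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclass
class PopulationTree:
    """A population tree with optional bootstrap support per branch."""

    tree: TreeNode
    method: str
    support: dict[frozenset, float] | None = None
    n_bootstrap: int = 0
    seed: int | None = None

    def leaves(self) -> list[str]:
        return sorted(t.name for t in self.tree.tips())

    def clades(self) -> set[frozenset]:
        """Leaf sets of internal edges, canonicalised for comparison.

        For unrooted comparison, the side of each split not containing
        the alphabetically first leaf is used.
        """
        all_leaves = frozenset(self.leaves())
        ref = min(all_leaves)
        out: set[frozenset] = set()
        for node in self.tree.non_tips(include_self=False):
            below = frozenset(t.name for t in node.tips())
            if ref in below:
                below = all_leaves - below
            if 1 < len(below) < len(all_leaves) - 1 or (len(below) > 1 and self.method == "upgma"):
                out.add(below)
        return out

    def to_newick(self, include_support: bool = True) -> str:
        tree = self.tree.copy()
        if include_support and self.support is not None:
            all_leaves = frozenset(self.leaves())
            ref = min(all_leaves)
            for node in tree.non_tips(include_self=False):
                below = frozenset(t.name for t in node.tips())
                key = all_leaves - below if ref in below else below
                if key in self.support:
                    node.name = f"{self.support[key]:.0f}"
        return str(tree).strip()

    def root_leaf_depths(self) -> np.ndarray:
        """Root-to-leaf path lengths (equal for an ultrametric tree)."""
        return np.array([tip.accumulate_to_ancestor(self.tree) for tip in self.tree.tips()])


def _upgma_newick(d: np.ndarray, labels: list[str]) -> str:
    """Average-linkage agglomeration; ties broken lexicographically."""
    n = len(labels)
    active: dict[int, dict] = {
        i: {"newick": labels[i], "size": 1, "height": 0.0, "repr": labels[i]}
        for i in range(n)
    }
    dist = {(i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(active) > 1:
        best = None
        for (i, j), v in dist.items():
            key = (v, *sorted((active[i]["repr"], active[j]["repr"])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        v = dist[(i, j)]
        h = v / 2.0
        ci, cj = active.pop(i), active.pop(j)
        first, second = sorted((ci, cj), key=lambda c: c["repr"])
        newick = (
            f"({first['newick']}:{h - first['height']:.10g},"
            f"{second['newick']}:{h - second['height']:.10g})"
        )
        merged = {
            "newick": newick,
            "size": ci["size"] + cj["size"],
            "height": h,
            "repr": first["repr"],
        }
        # average linkage: size-weighted mean of member distances
        for k in list(active):
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            dist[(min(next_id, k), max(next_id, k))] = (
                ci["size"] * dik + cj["size"] * djk
            ) / (ci["size"] + cj["size"])
        del dist[(i, j)]
        active[next_id] = merged
        next_id += 1
    root = next(iter(active.values()))
    return root["newick"] + ";"


def build_tree(d: pd.DataFrame, method: str = "upgma") -> PopulationTree:
    """UPGMA or neighbor-joining tree from a symmetric distance matrix."""
    values = d.to_numpy(dtype=float)
    if not np.allclose(values, values.T):
        raise ValueError("distance matrix is not symmetric")
    labels = [str(c) for c in d.columns]
    if len(labels) < 3:
        raise ValueError("need >=3 leaves")
    if method == "upgma":
        newick = _upgma_newick(values, labels)
        tree = TreeNode.read([newick])
    elif method == "nj":
        dm = DistanceMatrix(values, ids=labels)
        tree = _skbio_nj(dm)
    else:
        raise ValueError(f"unknown method {method!r}")
    return PopulationTree(tree=tree, method=method)


def bootstrap_support(
    m: BandMatrix,
    method: str = "upgma",
    n_boot: int = 1000,
    seed: int | None = None,
) -> PopulationTree:
    """Locus-bootstrap branch support for the population tree.

    Loci are resampled with replacement; for each replicate the pairwise
    theta matrix is recomputed (variance components are additive over
    loci, so replicates are resampled sums), linearized, and a tree is
    rebuilt.  Support of a branch is the percentage of replicate trees
    containing the same split.
    """
    pops, comps = pairwise_locus_components(m)
    L = next(iter(comps.values()))[0].shape[0]
    if L < 2:
        raise ValueError("need >=2 loci")
    K = len(pops)
    index = {p: i for i, p in enumerate(pops)}

    def theta_matrix(idx: np.ndarray | slice) -> pd.DataFrame:
        out = np.zeros((K, K))
        for (pi, pj), (a, dd) in comps.items():
            asum = float(a[idx].sum())
            dsum = float(dd[idx].sum())
            th = asum / dsum if dsum != 0 else 0.0
            th = min(th, 1.0 - 1e-9)
            out[index[pi], index[pj]] = out[index[pj], index[pi]] = th
        return pd.DataFrame(out, index=pops, columns=pops)

    base = build_tree(rousset_linearize(theta_matrix(slice(None))), method)
    target = base.clades()
    counts = {c: 0 for c in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        idx = rng.integers(0, L, size=L)
        rep = build_tree(rousset_linearize(theta_matrix(idx)), method)
        for c in rep.clades():
            if c in counts:
                counts[c] += 1
    base.support = {c: 100.0 * v / n_boot for c, v in counts.items()}
    base.n_bootstrap = n_boot
    base.seed = seed
    return base
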