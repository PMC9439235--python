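"""Population trees and isolation by distance.

Neighbor-joining (Saitou–Nei agglomeration with the Studier–Keppler Q
criterion) over a population distance matrix, bootstrap support by
resampling loci, and the Mantel isolation-by-distance test on linearized
F_ST = F_ST / (1 - F_ST) against ln(1 + great-circle distance).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from island_popgen.genotype_io import GenotypeMatrix
from island_popgen.popgen_stats import DistanceMatrix, da_distance

__all__ = [
    "PopTree", "MantelResult", "nj_tree", "bootstrap_support",
    "ibd_test", "haversine_matrix", "mantel",
]


@dataclass
class _Node:
    name: str | None = None  # leaf label, None for internal
    children: list[tuple["_Node", float]] = field(default_factory=list)
    support: float | None = None  # bootstrap %, internal nodes only

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PopTree:
    """Unrooted population tree (rooted representation at the final join)."""

    root: _Node

    @property
    def leaf_names(self) -> list[str]:
        return sorted(self.root.leaves())

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each named by its smaller/canonical side."""
        all_leaves = frozenset(self.root.leaves())
        parts: set[frozenset[str]] = set()

        def visit(node: _Node) -> None:
            for child, _ in node.children:
                below = frozenset(child.leaves())
                if 1 < len(below) < len(all_leaves) - 1:
                    parts.add(self._canonical(below, all_leaves))
                visit(child)

        visit(self.root)
        return parts

    @staticmethod
    def _canonical(side: frozenset[str], universe: frozenset[str]) -> frozenset[str]:
        other = universe - side
        if len(side) < len(other):
            return side
        if len(other) < len(side):
            return other
        return min(side, other, key=lambda s: sorted(s))

    def path_lengths(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length matrix (sums of branch lengths)."""
        dists: dict[str, dict[str, float]] = {}

        def down(node: _Node, acc: float, target: dict[str, float]) -> None:
            if node.is_leaf:
                target[node.name] = acc  # type: ignore[index]
                return
            for child, bl in node.children:
                down(child, acc + bl, target)

        # distances via each node acting as junction
        leaves = self.leaf_names
        m = {a: {b: 0.0 for b in leaves} for a in leaves}

        def visit(node: _Node) -> None:
            subs = []
            for child, bl in node.children:
                d: dict[str, float] = {}
                down(child, bl, d)
                subs.append(d)
            for d1, d2 in itertools.combinations(subs, 2):
                for a, da_ in d1.items():
                    for b, db in d2.items():
                        m[a][b] = m[b][a] = da_ + db
            for child, _ in node.children:
                visit(child)

        visit(self.root)
        labels = leaves
        arr = np.array([[m[a][b] for b in labels] for a in labels])
        return DistanceMatrix(labels, arr, "tree")

    def newick(self, include_support: bool = False) -> str:
        def fmt(node: _Node, bl: float | None) -> str:
            if node.is_leaf:
                core = node.name
            else:
                inner = ",".join(fmt(c, l) for c, l in node.children)
                label = ""
                if include_support and node.support is not None:
                    label = f"{node.support:.0f}"
                core = f"({inner}){label}"
            return core if bl is None else f"{core}:{bl:.6f}"

        return fmt(self.root, None) + ";"


@dataclass
class MantelResult:
    r: float
    r_squared: float
    slope: float
    p_value: float
    n_perm: int
    n_pairs: int
    tail: str


def nj_tree(d: DistanceMatrix) -> PopTree:
    """Neighbor joining with deterministic label-order tie-breaking.

    Negative branch lengths are truncated to zero with the deficit
    transferred to the sister branch so the joined pair's distance is
    preserved.
    """
    labels = list(d.labels)
    if len(labels) < 2:
        raise ValueError("need >= 2 labels")
    if np.any(np.isnan(d.values)):
        raise ValueError("distance matrix contains NaN")
    nodes: dict[str, _Node] = {lab: _Node(name=lab) for lab in labels}
    dist = {
        (a, b): float(d.values[i, j])
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i < j
    }

    def get(a: str, b: str) -> float:
        return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    active = sorted(labels)
    if len(active) == 2:
        a, b = active
        root = _Node(children=[(nodes[a], get(a, b) / 2), (nodes[b], get(a, b) / 2)])
        return PopTree(root)
    counter = 0
    while len(active) > 3:
        r = len(active)
        tot = {a: sum(get(a, b) for b in active if b != a) for a in active}
        best = None
        best_q = math.inf
        for a, b in itertools.combinations(active, 2):  # active kept sorted
            q = (r - 2) * get(a, b) - tot[a] - tot[b]
            if q < best_q - 1e-12:
                best_q = q
                best = (a, b)
        a, b = best  # type: ignore[misc]
        dab = get(a, b)
        va = dab / 2 + (tot[a] - tot[b]) / (2 * (r - 2))
        vb = dab - va
        if va < 0:
            va, vb = 0.0, dab
        elif vb < 0:
            va, vb = dab, 0.0
        new_label = f"__internal{counter}"
        counter += 1
        nodes[new_label] = _Node(children=[(nodes[a], va), (nodes[b], vb)])
        for c in active:
            if c in (a, b):
                continue
            dist[(new_label, c)] = (get(a, c) + get(b, c) - dab) / 2
        active = sorted(
            [c for c in active if c not in (a, b)] + [new_label]
        )
    a, b, c = active
    va = (get(a, b) + get(a, c) - get(b, c)) / 2
    vb = (get(a, b) + get(b, c) - get(a, c)) / 2
    vc = (get(a, c) + get(b, c) - get(a, b)) / 2
    kids = []
    for lab, v in ((a, va), (b, vb), (c, vc)):
        kids.append((nodes[lab], max(v, 0.0)))
    return PopTree(_Node(children=kids))


def bootstrap_support(
    g: GenotypeMatrix,
    n_boot: int = 1000,
    seed: int = 0,
    distance: Callable[[GenotypeMatrix], DistanceMatrix] = da_distance,
) -> PopTree:
    """NJ tree on the full data with locus-bootstrap support percentages.

    Loci are resampled with replacement ``n_boot`` times; support for each
    internal edge of the full-data tree is the percentage of replicate
    trees containing the same bipartition of population labels.
    """
    if g.n_loci < 2:
        raise ValueError("bootstrap needs >= 2 loci")
    rng = np.random.default_rng(seed)
    full = nj_tree(distance(g))
    target = {bp: 0 for bp in full.bipartitions()}
    for _ in range(n_boot):
        picks = rng.integers(0, g.n_loci, size=g.n_loci)
        res = GenotypeMatrix(
            list(g.individual_ids),
            [f"L{k}" for k in range(g.n_loci)],
            g.alleles[:, picks, :].copy(),
            list(g.pop_labels),
        )
        reps = nj_tree(distance(res)).bipartitions()
        for bp in target:
            if bp in reps:
                target[bp] += 1
    universe = frozenset(full.root.leaves())

    def annotate(node: _Node) -> None:
        for child, _ in node.children:
            below = frozenset(child.leaves())
            if 1 < len(below) < len(universe) - 1:
                bp = PopTree._canonical(below, universe)
                child.support = 100.0 * target[bp] / n_boot
            annotate(child)

    annotate(full.root)
    return full


# ---------------------------------------------------------------------------
# isolation by distance


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km (mean Earth radius 6371 km)."""
    rlat1, rlon1, rlat2, rlon2 = map(math.radians, (lat1, lon1, lat2, lon2))
    dlat = rlat2 - rlat1
    dlon = rlon2 - rlon1
    h = math.sin(dlat / 2) ** 2 + math.cos(rlat1) * math.cos(rlat2) * math.sin(dlon / 2) ** 2
    return 2 * 6371.0 * math.asin(min(1.0, math.sqrt(h)))


def haversine_matrix(
    labels: Sequence[str], coordinates: dict[str, tuple[float, float]]
) -> DistanceMatrix:
    n = len(labels)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        (la1, lo1), (la2, lo2) = coordinates[labels[i]], coordinates[labels[j]]
        m[i, j] = m[j, i] = haversine_km(la1, lo1, la2, lo2)
    return DistanceMatrix(list(labels), m, "km")


def _offdiag_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    return iu


def mantel(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 9999,
    seed: int = 0,
    tail: str = "greater",
    mask: np.ndarray | None = None,
) -> tuple[float, float, int]:
    """Mantel matrix correlation with row/column permutations of ``y``.

    ``mask`` (boolean, upper-triangle semantics applied to the full
    square) restricts the correlation to selected pairs; the mask is tied
    to matrix positions of ``x`` and is not permuted. If ``n_perm`` is at
    least n! - 1 every permutation is enumerated and the p-value is exact.
    Returns (r, p, n_perm_used).
    """
    n = x.shape[0]
    iu = _offdiag_pairs(n)
    sel = np.ones(iu[0].size, dtype=bool) if mask is None else mask[iu]
    xv = x[iu][sel]

    def corr(mat: np.ndarray) -> float:
        yv = mat[iu][sel]
        if np.std(xv) == 0 or np.std(yv) == 0:
            return np.nan
        return float(np.corrcoef(xv, yv)[0, 1])

    r_obs = corr(y)
    n_total = math.factorial(n)
    exhaustive = n_perm + 1 >= n_total
    if exhaustive:
        perms = [np.array(p) for p in itertools.permutations(range(n))]
        stats = [corr(y[np.ix_(p, p)]) for p in perms]
        used = len(stats) - 1  # identity included in the reference set
        if tail == "greater":
            p = float(np.mean([s >= r_obs - 1e-12 for s in stats]))
        elif tail == "less":
            p = float(np.mean([s <= r_obs + 1e-12 for s in stats]))
        else:
            p = float(np.mean([abs(s) >= abs(r_obs) - 1e-12 for s in stats]))
        return r_obs, p, used
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        p_idx = rng.permutation(n)
        s = corr(y[np.ix_(p_idx, p_idx)])
        if np.isnan(s):
            continue
        if tail == "greater":
            hits += s >= r_obs - 1e-12
        elif tail == "less":
            hits += s <= r_obs + 1e-12
        else:
            hits += abs(s) >= abs(r_obs) - 1e-12
    return r_obs, (hits + 1) / (n_perm + 1), n_perm


def ibd_test(
    fst: DistanceMatrix,
    geo: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
    min_distance_km: float | None = None,
    tail: str = "greater",
) -> MantelResult:
    """Isolation-by-distance Mantel test.

    x = ln(1 + distance_km), y = F_ST / (1 - F_ST). Pairs with F_ST = 1
    (undefined y) are dropped with a warning; ``min_distance_km``
    restricts the test to pairs farther apart than the threshold (the
    over-270-km analysis). ``tail`` is one-sided "greater" for the
    positive-IBD test or "two-sided" for subset correlations.
    """
    if fst.labels != geo.labels:
        raise ValueError("label sets/order of fst and geo must match")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    n = len(fst.labels)
    x = np.log1p(geo.values)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = fst.values / (1.0 - fst.values)
    mask = np.ones((n, n), dtype=bool)
    bad = ~np.isfinite(y)
    np.fill_diagonal(bad, False)
    if bad.any():
        import warnings

        warnings.warn(f"dropping {bad[np.triu_indices(n, 1)].sum()} pairs with F_ST = 1")
        mask &= ~bad
        y = np.where(bad, 0.0, y)
    if min_distance_km is not None:
        mask &= geo.values > min_distance_km
    r, p, used = mantel(x, y, n_perm=n_perm, seed=seed, tail=tail, mask=mask)
    iu = np.triu_indices(n, 1)
    sel = mask[iu]
    xv, yv = x[iu][sel], y[iu][sel]
    slope = float(np.polyfit(xv, yv, 1)[0]) if xv.size >= 2 else np.nan
    return MantelResult(
        r=r, r_squared=r * r, slope=slope, p_value=p,
        n_perm=used, n_pairs=int(sel.sum()), tail=tail,
    )


def ibd_pair_table(fst: DistanceMatrix, geo: DistanceMatrix) -> pd.DataFrame:
    """Long table of pairs: labels, km, ln(1+km), F_ST, linearized F_ST."""
    rows = []
    for i, j in itertools.combinations(range(len(fst.labels)), 2):
        f = fst.values[i, j]
        rows.append(
            {
                "pop1": fst.labels[i], "pop2": fst.labels[j],
                "km": geo.values[i, j], "ln1p_km": math.log1p(geo.values[i, j]),
                "fst": f, "fst_linear": f / (1 - f) if f < 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
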