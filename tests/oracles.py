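"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration) and shares no code with the package's estimators.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_allelic_richness(copies: list[int], g_size: int) -> float:
    """Mean number of distinct alleles over all C(N, g) subsamples."""
    total = 0
    count = 0
    for combo in itertools.combinations(range(len(copies)), g_size):
        total += len({copies[i] for i in combo})
        count += 1
    return total / count


def brute_h_o(genotypes: list[tuple[int, int]]) -> float:
    het = sum(1 for a, b in genotypes if a != b)
    return het / len(genotypes)


def brute_h_e(genotypes: list[tuple[int, int]]) -> float:
    """Nei's unbiased gene diversity by explicit counting."""
    n = len(genotypes)
    copies = [a for g in genotypes for a in g]
    freqs = {}
    for a in copies:
        freqs[a] = freqs.get(a, 0) + 1
    ss = sum((k / (2 * n)) ** 2 for k in freqs.values())
    return (2 * n / (2 * n - 1)) * (1 - ss)


def brute_da(freq_x: dict[int, float], freq_y: dict[int, float]) -> float:
    """Single-locus Nei D_A from two frequency dicts."""
    s = 0.0
    for a in set(freq_x) | set(freq_y):
        s += math.sqrt(freq_x.get(a, 0.0) * freq_y.get(a, 0.0))
    return 1.0 - s


def brute_da_multilocus(pops_freqs_x, pops_freqs_y) -> float:
    terms = [1.0 - brute_da(x, y) for x, y in zip(pops_freqs_x, pops_freqs_y)]
    return 1.0 - sum(terms) / len(terms)


def brute_theta(pop_genotypes: list[list[tuple[int, int]]]) -> float:
    """Multilocus Weir–Cockerham theta via literal variance components.

    ``pop_genotypes[locus][...]`` is a list per population? No:
    ``pop_genotypes`` is a list over loci; each entry is a list over
    populations of genotype lists.
    """
    a_tot = b_tot = c_tot = 0.0
    for pops in pop_genotypes:
        pops = [p for p in pops if p]
        r = len(pops)
        if r < 2:
            continue
        ns = [len(p) for p in pops]
        nbar = sum(ns) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
        alleles = sorted({a for p in pops for g in p for a in g})
        if len(alleles) < 2:
            continue
        for al in alleles:
            p_i = []
            h_i = []
            for p in pops:
                copies = [a for g in p for a in g]
                p_i.append(copies.count(al) / len(copies))
                h_i.append(
                    sum(1 for g in p if g[0] != g[1] and al in g) / len(p)
                )
            pbar = sum(n * x for n, x in zip(ns, p_i)) / (r * nbar)
            s2 = sum(n * (x - pbar) ** 2 for n, x in zip(ns, p_i)) / ((r - 1) * nbar)
            hbar = sum(n * h for n, h in zip(ns, h_i)) / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            a_tot += a
            b_tot += b
            c_tot += c
    return a_tot / (a_tot + b_tot + c_tot)


def brute_mantel_exhaustive(x: np.ndarray, y: np.ndarray, tail: str = "greater"):
    """Exact Mantel p by enumerating every label permutation."""
    n = x.shape[0]
    iu = np.triu_indices(n, 1)
    xv = x[iu]

    def corr(mat):
        yv = mat[iu]
        return float(np.corrcoef(xv, yv)[0, 1])

    r_obs = corr(y)
    stats = []
    for p in itertools.permutations(range(n)):
        idx = np.array(p)
        stats.append(corr(y[np.ix_(idx, idx)]))
    if tail == "greater":
        p_val = np.mean([s >= r_obs - 1e-12 for s in stats])
    else:
        p_val = np.mean([abs(s) >= abs(r_obs) - 1e-12 for s in stats])
    return r_obs, float(p_val)


def additive_matrix_from_tree(
    edges: dict[str, tuple[str, float]], leaves: list[str]
) -> np.ndarray:
    """Path-length matrix of a tree given parent pointers (child -> (parent, length))."""

    def path_to_root(node):
        out = {}
        acc = 0.0
        while node in edges:
            parent, bl = edges[node]
            acc += bl
            out[parent] = acc
            node = parent
        return out

    n = len(leaves)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        pi = path_to_root(leaves[i])
        pj = path_to_root(leaves[j])
        best = math.inf
        for anc, d1 in pi.items():
            if anc in pj:
                best = min(best, d1 + pj[anc])
        m[i, j] = m[j, i] = best
    return m
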