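"""Diversity and differentiation statistics for diploid microsatellites.

Per-population statistics: rarefied allelic richness ``A_R``
(hypergeometric rarefaction to a common number of gene copies), observed
heterozygosity ``H_O``, Nei's unbiased gene diversity ``H_E``, and the
Weir–Cockerham within-population fixation index ``F_IS`` with an
allele-randomization test. Between populations: Weir–Cockerham theta
(``F_ST``) and Nei et al. (1983) ``D_A`` distance. A configurable
DIYABC-style summary-statistic vector serves the ABC machinery.

Missing genotypes are excluded locus-wise throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from island_popgen.genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "allele_frequencies",
    "allelic_richness",
    "heterozygosities",
    "fis",
    "pairwise_fst",
    "da_distance",
    "abc_summary_vector",
    "summary_stat_names",
    "diversity_table",
    "multilocus_theta",
    "DistanceMatrix",
    "DiversityTable",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise matrix over population labels."""

    labels: list[str]
    values: np.ndarray
    kind: str  # "fst" or "da"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix is not symmetric")

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_long(self) -> pd.DataFrame:
        rows = [
            {"pop1": self.labels[i], "pop2": self.labels[j],
             "value": self.values[i, j]}
            for i in range(len(self.labels))
            for j in range(i + 1, len(self.labels))
        ]
        return pd.DataFrame(rows)

    def write_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for i, lab in enumerate(self.labels):
                vals = " ".join(f"{v:.6f}" for v in self.values[i])
                fh.write(f"{lab:<12s}{vals}\n")


@dataclass
class DiversityTable:
    """Per-population x locus diversity statistics plus population means."""

    per_locus: pd.DataFrame  # columns: population, locus, A_R, H_O, H_E
    means: pd.DataFrame      # index: population; columns: n, A_R, H_O, H_E, F_IS, F_IS_p

    def write(self, per_locus_path: str | Path, means_path: str | Path) -> None:
        self.per_locus.to_csv(per_locus_path, index=False)
        self.means.to_csv(means_path)


# ---------------------------------------------------------------------------
# allele counts / frequencies


def _allele_counts(g: GenotypeMatrix) -> dict[str, list[dict[int, int]]]:
    """Per population, per locus: {allele: gene-copy count} (missing excluded)."""
    out: dict[str, list[dict[int, int]]] = {}
    for pop in g.populations():
        idx = g.population_indices(pop)
        per_locus = []
        for j in range(g.n_loci):
            col = g.alleles[idx, j, :].ravel()
            col = col[col != MISSING]
            vals, cnts = np.unique(col, return_counts=True)
            per_locus.append(dict(zip(vals.tolist(), cnts.tolist())))
        out[pop] = per_locus
    return out


def allele_frequencies(g: GenotypeMatrix) -> dict[str, list[dict[int, float] | None]]:
    """Allele frequency vectors per population x locus.

    A locus with no observed gene copies in a population is flagged
    ``None`` so downstream statistics can skip it.
    """
    counts = _allele_counts(g)
    out: dict[str, list[dict[int, float] | None]] = {}
    for pop, per_locus in counts.items():
        freqs: list[dict[int, float] | None] = []
        for c in per_locus:
            tot = sum(c.values())
            freqs.append(None if tot == 0 else {a: k / tot for a, k in c.items()})
        out[pop] = freqs
    return out


# ---------------------------------------------------------------------------
# allelic richness


def _rarefied_richness(counts: Mapping[int, int], g_size: int) -> float:
    """Expected allele count in a random draw of ``g_size`` gene copies.

    A_R(g) = sum_i [1 - C(N - N_i, g) / C(N, g)] with N total observed
    copies and N_i copies of allele i (hypergeometric rarefaction).
    """
    N = sum(counts.values())
    if g_size > N:
        raise ValueError(f"rarefaction size {g_size} exceeds observed copies {N}")
    denom = math.comb(N, g_size)
    return float(sum(1.0 - math.comb(N - ni, g_size) / denom for ni in counts.values()))


def allelic_richness(
    g: GenotypeMatrix, rarefaction_size: int | str = "auto"
) -> pd.DataFrame:
    """Rarefied allelic richness per population x locus.

    ``rarefaction_size="auto"`` uses, per locus, the minimum number of
    observed gene copies over populations (FSTAT's convention); an integer
    applies one size to every locus. Returns a long DataFrame with columns
    ``population, locus, A_R`` (NaN where a population has fewer observed
    copies than the rarefaction size, or none at all).
    """
    counts = _allele_counts(g)
    pops = g.populations()
    rows = []
    for j, locus in enumerate(g.locus_names):
        totals = [sum(counts[p][j].values()) for p in pops]
        if rarefaction_size == "auto":
            observed = [t for t in totals if t > 0]
            if not observed:
                g_size = None
            else:
                g_size = min(observed)
        else:
            g_size = int(rarefaction_size)
        if g_size is not None and g_size < 2:
            raise ValueError("rarefaction size must be >= 2")
        for p, tot in zip(pops, totals):
            if g_size is None or tot < g_size or tot == 0:
                ar = np.nan
            else:
                ar = _rarefied_richness(counts[p][j], g_size)
            rows.append({"population": p, "locus": locus, "A_R": ar})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# heterozygosities


def heterozygosities(g: GenotypeMatrix) -> pd.DataFrame:
    """Observed heterozygosity and Nei's unbiased gene diversity.

    H_O is the proportion of heterozygous individuals among those typed;
    H_E = (2n / (2n - 1)) (1 - sum p_i^2) with n typed individuals.
    H_E needs n >= 2 and is NaN otherwise.
    """
    rows = []
    for pop in g.populations():
        idx = g.population_indices(pop)
        for j, locus in enumerate(g.locus_names):
            geno = g.alleles[idx, j, :]
            typed = geno[geno[:, 0] != MISSING]
            n = typed.shape[0]
            if n == 0:
                rows.append({"population": pop, "locus": locus,
                             "n_typed": 0, "H_O": np.nan, "H_E": np.nan})
                continue
            h_o = float(np.mean(typed[:, 0] != typed[:, 1]))
            if n >= 2:
                _, cnts = np.unique(typed.ravel(), return_counts=True)
                p = cnts / (2 * n)
                h_e = (2 * n / (2 * n - 1)) * (1.0 - float(np.sum(p**2)))
            else:
                h_e = np.nan
            rows.append({"population": pop, "locus": locus,
                         "n_typed": n, "H_O": h_o, "H_E": h_e})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# F_IS (Weir & Cockerham f) with randomization test


def _fis_components(geno: np.ndarray) -> tuple[float, float]:
    """Sum of W&C (b + c) and c variance components over alleles, one locus.

    ``geno``: (n, 2) typed genotypes. Returns (sum_b_plus_c, sum_c);
    f = 1 - sum_c / sum_(b+c) accumulated over loci.
    """
    n = geno.shape[0]
    if n < 2:
        return 0.0, 0.0
    alleles, cnts = np.unique(geno.ravel(), return_counts=True)
    if alleles.size < 2:
        return 0.0, 0.0
    bc_sum = 0.0
    c_sum = 0.0
    het = geno[:, 0] != geno[:, 1]
    for a, cnt in zip(alleles, cnts):
        p = cnt / (2 * n)
        h = float(np.mean(het & ((geno[:, 0] == a) | (geno[:, 1] == a))))
        b = (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
        c = h / 2
        bc_sum += b + c
        c_sum += c
    return bc_sum, c_sum


def _fis_value(cols: Sequence[np.ndarray]) -> float:
    bc = 0.0
    c = 0.0
    for geno in cols:
        b_i, c_i = _fis_components(geno)
        bc += b_i
        c += c_i
    if bc == 0.0:
        return np.nan
    return 1.0 - c / bc


def fis(g: GenotypeMatrix, n_perm: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Multilocus Weir–Cockerham f per population with randomization p.

    The null distribution shuffles gene copies among individuals within
    the population, locus by locus; p is the two-sided proportion of
    replicates with |f| >= |observed| (with the +1 correction). NaN f
    (monomorphic population) yields NaN p.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for pop in g.populations():
        idx = g.population_indices(pop)
        cols = []
        for j in range(g.n_loci):
            geno = g.alleles[idx, j, :]
            cols.append(geno[geno[:, 0] != MISSING])
        f_obs = _fis_value(cols)
        if np.isnan(f_obs):
            rows.append({"population": pop, "F_IS": np.nan, "F_IS_p": np.nan})
            continue
        hits = 0
        for _ in range(n_perm):
            perm_cols = []
            for geno in cols:
                flat = geno.ravel().copy()
                rng.shuffle(flat)
                perm_cols.append(flat.reshape(-1, 2))
            f_p = _fis_value(perm_cols)
            if not np.isnan(f_p) and abs(f_p) >= abs(f_obs):
                hits += 1
        rows.append({"population": pop, "F_IS": f_obs,
                     "F_IS_p": (hits + 1) / (n_perm + 1)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weir–Cockerham theta


def _theta_components(genos: Sequence[np.ndarray]) -> tuple[float, float]:
    """Sum of W&C (1984) a and a+b+c over alleles for one locus.

    ``genos``: typed (n_i, 2) genotype arrays, one per population.
    """
    genos = [x for x in genos if x.shape[0] > 0]
    r = len(genos)
    if r < 2:
        return 0.0, 0.0
    ns = np.array([x.shape[0] for x in genos], dtype=float)
    nbar = ns.mean()
    if nbar <= 1:
        return 0.0, 0.0
    nc = (r * nbar - np.sum(ns**2) / (r * nbar)) / (r - 1)
    alleles = np.unique(np.concatenate([x.ravel() for x in genos]))
    if alleles.size < 2:
        return 0.0, 0.0
    a_sum = 0.0
    abc_sum = 0.0
    for al in alleles:
        p_i = np.array([np.mean(x.ravel() == al) for x in genos])
        het = np.array(
            [np.mean((x[:, 0] != x[:, 1]) & ((x[:, 0] == al) | (x[:, 1] == al)))
             for x in genos]
        )
        pbar = float(np.sum(ns * p_i) / (r * nbar))
        s2 = float(np.sum(ns * (p_i - pbar) ** 2) / ((r - 1) * nbar))
        hbar = float(np.sum(ns * het) / (r * nbar))
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum += a
        abc_sum += a + b + c
    return a_sum, abc_sum


def multilocus_theta(genos_by_locus: Sequence[Sequence[np.ndarray]]) -> float:
    """Weir–Cockerham theta over loci: sum a / sum (a+b+c)."""
    a_tot = 0.0
    abc_tot = 0.0
    for genos in genos_by_locus:
        a, abc = _theta_components(genos)
        a_tot += a
        abc_tot += abc
    if abc_tot == 0.0:
        return np.nan
    return a_tot / abc_tot


def _typed_genotypes(g: GenotypeMatrix) -> dict[str, list[np.ndarray]]:
    out: dict[str, list[np.ndarray]] = {}
    for pop in g.populations():
        idx = g.population_indices(pop)
        cols = []
        for j in range(g.n_loci):
            geno = g.alleles[idx, j, :]
            cols.append(geno[geno[:, 0] != MISSING])
        out[pop] = cols
    return out


def pairwise_fst(g: GenotypeMatrix) -> DistanceMatrix:
    """Multilocus Weir–Cockerham theta for every population pair.

    Negative estimates are reported as computed, not truncated.
    """
    pops = g.populations()
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    typed = _typed_genotypes(g)
    n = len(pops)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        theta = multilocus_theta(
            [(typed[pops[i]][l], typed[pops[j]][l]) for l in range(g.n_loci)]
        )
        m[i, j] = m[j, i] = theta
    return DistanceMatrix(pops, m, "fst")


# ---------------------------------------------------------------------------
# Nei's D_A


def da_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Nei et al. (1983) D_A = 1 - (1/L) sum_loci sum_alleles sqrt(x y)."""
    pops = g.populations()
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    freqs = allele_frequencies(g)
    n = len(pops)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        terms = []
        for l in range(g.n_loci):
            x, y = freqs[pops[i]][l], freqs[pops[j]][l]
            if x is None or y is None:
                continue
            shared = set(x) & set(y)
            terms.append(sum(math.sqrt(x[a] * y[a]) for a in shared))
        if not terms:
            m[i, j] = m[j, i] = np.nan
        else:
            m[i, j] = m[j, i] = 1.0 - float(np.mean(terms))
    return DistanceMatrix(pops, m, "da")


# ---------------------------------------------------------------------------
# diversity table


def diversity_table(
    g: GenotypeMatrix,
    rarefaction_size: int | str = "auto",
    n_perm: int = 10_000,
    seed: int = 0,
) -> DiversityTable:
    """Assemble the per-population diversity surface (A_R, H_O, H_E, F_IS)."""
    ar = allelic_richness(g, rarefaction_size)
    het = heterozygosities(g)
    per_locus = ar.merge(het, on=["population", "locus"])
    fis_df = fis(g, n_perm=n_perm, seed=seed).set_index("population")
    means = per_locus.groupby("population", sort=False).agg(
        A_R=("A_R", "mean"), H_O=("H_O", "mean"), H_E=("H_E", "mean")
    )
    counts = pd.Series(g.pop_labels).value_counts()
    means.insert(0, "n", counts.reindex(means.index).astype(int))
    means["F_IS"] = fis_df["F_IS"]
    means["F_IS_p"] = fis_df["F_IS_p"]
    return DiversityTable(per_locus, means)


# ---------------------------------------------------------------------------
# ABC summary statistics


def summary_stat_names(groups: Sequence[str]) -> list[str]:
    """Fixed ordering of the summary-statistic vector for sorted groups."""
    groups = sorted(groups)
    names = []
    for grp in groups:
        names += [f"{grp}:mean_allele_number", f"{grp}:mean_He",
                  f"{grp}:mean_size_variance", f"{grp}:mean_M_ratio"]
    for g1, g2 in itertools.combinations(groups, 2):
        names += [f"{g1}-{g2}:fst", f"{g1}-{g2}:mean_dmu2"]
    return names


def abc_summary_vector(
    g: GenotypeMatrix, grouping: Mapping[str, str]
) -> tuple[np.ndarray, list[str]]:
    """DIYABC-style summary statistics over pooled population groups.

    Per group (pooling all member populations): mean over loci of allele
    number, unbiased H_E, allele-size variance (divisor N over gene
    copies), and the Garza–Williamson M-ratio (alleles / (size range + 1),
    sizes in repeat units). Per group pair: multilocus Weir–Cockerham
    theta and the mean squared difference of mean allele size (delta-mu
    squared). Loci with < 2 gene copies in a group are skipped for that
    group's statistics. Returns (vector, names) in the fixed order of
    :func:`summary_stat_names`.
    """
    missing = set(g.populations()) - set(grouping)
    if missing:
        raise ValueError(f"grouping does not cover populations: {sorted(missing)}")
    groups = sorted(set(grouping[p] for p in g.populations()))
    labels = np.asarray(g.pop_labels, dtype=object)
    member_idx = {
        grp: np.flatnonzero(
            np.isin(labels, [p for p in g.populations() if grouping[p] == grp])
        )
        for grp in groups
    }
    # per group x locus typed gene copies
    copies: dict[str, list[np.ndarray]] = {}
    for grp, idx in member_idx.items():
        cols = []
        for j in range(g.n_loci):
            geno = g.alleles[idx, j, :]
            typed = geno[geno[:, 0] != MISSING]
            cols.append(typed)
        copies[grp] = cols

    values: list[float] = []
    for grp in groups:
        a_num, he, var, mr = [], [], [], []
        for typed in copies[grp]:
            flat = typed.ravel()
            if flat.size < 2:
                continue
            vals, cnts = np.unique(flat, return_counts=True)
            a_num.append(float(vals.size))
            n = typed.shape[0]
            p = cnts / flat.size
            he.append((2 * n / (2 * n - 1)) * (1 - float(np.sum(p**2))))
            var.append(float(np.var(flat)))  # divisor N
            mr.append(vals.size / (float(vals.max() - vals.min()) + 1.0))
        if not a_num:
            values += [np.nan] * 4
        else:
            values += [float(np.mean(a_num)), float(np.mean(he)),
                       float(np.mean(var)), float(np.mean(mr))]
    for g1, g2 in itertools.combinations(groups, 2):
        theta = multilocus_theta(
            [(copies[g1][l], copies[g2][l]) for l in range(g.n_loci)]
        )
        dmu2 = []
        for l in range(g.n_loci):
            x, y = copies[g1][l].ravel(), copies[g2][l].ravel()
            if x.size == 0 or y.size == 0:
                continue
            dmu2.append((float(x.mean()) - float(y.mean())) ** 2)
        values += [theta, float(np.mean(dmu2)) if dmu2 else np.nan]
    return np.asarray(values, dtype=float), summary_stat_names(groups)
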