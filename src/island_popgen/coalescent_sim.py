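"""Coalescent simulation of diploid microsatellites under island demographies.

Genealogies come from the standard backward-in-time coalescent with
piecewise-constant diploid sizes, population splits/budding, and backward
migration (delegated to msprime, exact exponential waiting times per
epoch). Microsatellite alleles are produced by a generalized stepwise
mutation (GSM) overlay authored here: mutations are Poisson on branch
length, each changes the repeat count by k steps with
P(k) = (1 - P_GSM) * P_GSM**(k-1), k >= 1, sign +/- with probability 1/2,
reflected at repeat count 1. P_GSM = 0 recovers the strict stepwise model.

The demographic catalogue covers three single-population size-change
models (SNM/PGM/SRM) and five three-group divergence models over the
Bonin (B), Volcano (V) and Yaeyama+Daito (YD) groups with optional
migration patterns. The five divergence topologies and the migration
patterns are a documented reconstruction (see docs/methods.md): the
shipped defaults are

* M1 — V buds from YD, then B and YD join the root,
* M2 — V basal: YD buds from B, then B and V join the root,
* M3 — V buds from B after the B/(Y+D) split,
* M4 — B basal: YD buds from V, then V and B join the root,
* M5 — simultaneous trichotomy at a single divergence time.

Migration patterns: "M1" B<->V only, "M2" all pairs, "M3" stepping-stone
B<->V and B<->YD, "none" no migration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import msprime
import numpy as np
import tskit

from island_popgen.genotype_io import GenotypeMatrix

__all__ = [
    "SizeChangeModel", "DivergenceModel", "CustomDemographyModel",
    "SampleConfig", "simulate_genealogy", "mutate_gsm", "simulate_dataset",
    "DIVERGENCE_TOPOLOGIES", "MIGRATION_PATTERNS",
]

DIVERGENCE_TOPOLOGIES = ("M1", "M2", "M3", "M4", "M5")
MIGRATION_PATTERNS = ("none", "M1", "M2", "M3")

# (derived, parent) budding at T1, then (a, b) joining the root at T2.
_TOPOLOGY_EVENTS = {
    "M1": (("V", "YD"), ("B", "YD")),
    "M2": (("YD", "B"), ("B", "V")),
    "M3": (("V", "B"), ("B", "YD")),
    "M4": (("YD", "V"), ("V", "B")),
}

_PATTERN_PAIRS = {
    "none": [],
    "M1": [("B", "V")],
    "M2": [("B", "V"), ("B", "YD"), ("V", "YD")],
    "M3": [("B", "V"), ("B", "YD")],
}


@dataclass
class SizeChangeModel:
    """Single population with at most one stepwise size change.

    ``kind`` is SNM (constant size), PGM (growth: ancestral smaller,
    RN_ANC < 1) or SRM (reduction: ancestral larger, RN_ANC > 1).
    ``rn_anc`` is the ancestral/current size ratio; the ancestral diploid
    size is ``rn_anc * n_cur`` for t > ``t_change`` generations ago.
    """

    kind: str
    n_cur: float
    rn_anc: float = 1.0
    t_change: float = 0.0
    mu: float = 5e-4
    p_gsm: float = 0.3

    def __post_init__(self) -> None:
        if self.kind not in ("SNM", "PGM", "SRM"):
            raise ValueError(f"unknown size-change kind {self.kind!r}")
        if self.n_cur < 2:
            raise ValueError("n_cur must be >= 2")
        if self.kind == "PGM" and not self.rn_anc < 1:
            raise ValueError("PGM requires rn_anc < 1")
        if self.kind == "SRM" and not self.rn_anc > 1:
            raise ValueError("SRM requires rn_anc > 1")
        if self.kind != "SNM":
            if self.t_change <= 0:
                raise ValueError("t_change must be > 0 for PGM/SRM")
            if self.rn_anc * self.n_cur < 2:
                raise ValueError("ancestral size must be >= 2")
        if not 0 <= self.p_gsm < 1:
            raise ValueError("p_gsm must be in [0, 1)")

    def demography(self) -> msprime.Demography:
        d = msprime.Demography()
        d.add_population(name="P", initial_size=self.n_cur)
        if self.kind != "SNM":
            d.add_population_parameters_change(
                time=self.t_change, population="P",
                initial_size=self.rn_anc * self.n_cur,
            )
        return d

    @property
    def deme_names(self) -> list[str]:
        return ["P"]


@dataclass
class DivergenceModel:
    """Three-group divergence over B, V, YD with optional migration.

    B and YD share one current diploid size (``n_byd``); V has ``n_v``;
    the root population has ``n_anc``. ``t1 < t2`` in generations; M5 uses
    ``t1`` as its single simultaneous divergence time. ``migration`` maps
    unordered extant pairs to per-generation backward rates; the
    ``migration_pattern`` tag records which template generated it.
    """

    topology: str
    n_byd: float
    n_v: float
    n_anc: float
    t1: float
    t2: float = 0.0
    mu: float = 5e-4
    p_gsm: float = 0.3
    migration_pattern: str = "none"
    migration: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.topology not in DIVERGENCE_TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        for nm, v in (("n_byd", self.n_byd), ("n_v", self.n_v), ("n_anc", self.n_anc)):
            if v < 2:
                raise ValueError(f"{nm} must be >= 2")
        if self.topology != "M5" and not self.t1 < self.t2:
            raise ValueError("need t1 < t2")
        if self.t1 <= 0:
            raise ValueError("t1 must be > 0")
        if self.migration_pattern not in MIGRATION_PATTERNS:
            raise ValueError(f"unknown migration pattern {self.migration_pattern!r}")
        if self.migration_pattern == "none" and any(self.migration.values()):
            raise ValueError("pattern 'none' requires a zero migration matrix")
        if any(v < 0 for v in self.migration.values()):
            raise ValueError("migration rates must be >= 0")
        if not 0 <= self.p_gsm < 1:
            raise ValueError("p_gsm must be in [0, 1)")

    @classmethod
    def with_pattern(
        cls, topology: str, pattern: str, rate: float, **kwargs
    ) -> "DivergenceModel":
        mig = {pair: rate for pair in _PATTERN_PAIRS[pattern]}
        return cls(topology=topology, migration_pattern=pattern, migration=mig, **kwargs)

    def demography(self) -> msprime.Demography:
        d = msprime.Demography()
        d.add_population(name="B", initial_size=self.n_byd)
        d.add_population(name="V", initial_size=self.n_v)
        d.add_population(name="YD", initial_size=self.n_byd)
        d.add_population(name="ANC", initial_size=self.n_anc)
        for (a, b), rate in sorted(self.migration.items()):
            if rate > 0:
                d.set_symmetric_migration_rate([a, b], rate)
        if self.topology == "M5":
            d.add_population_split(
                time=self.t1, derived=["B", "V", "YD"], ancestral="ANC"
            )
        else:
            (derived, parent), (ra, rb) = _TOPOLOGY_EVENTS[self.topology]
            # budding: all lineages of `derived` move into `parent`
            d.add_mass_migration(
                time=self.t1, source=derived, dest=parent, proportion=1.0
            )
            for (a, b), rate in sorted(self.migration.items()):
                if rate > 0 and derived in (a, b):
                    d.add_migration_rate_change(time=self.t1, rate=0, source=a, dest=b)
                    d.add_migration_rate_change(time=self.t1, rate=0, source=b, dest=a)
            d.add_population_split(time=self.t2, derived=[ra, rb], ancestral="ANC")
        d.sort_events()
        return d

    @property
    def deme_names(self) -> list[str]:
        return ["B", "V", "YD"]


@dataclass
class CustomDemographyModel:
    """Escape hatch: an arbitrary msprime demography with GSM mutation."""

    demography_builder: object  # callable -> msprime.Demography
    demes: list[str]
    mu: float = 5e-4
    p_gsm: float = 0.3

    def demography(self) -> msprime.Demography:
        return self.demography_builder()

    @property
    def deme_names(self) -> list[str]:
        return list(self.demes)


@dataclass
class SampleConfig:
    """Sampling layout: diploid individuals per deme and loci to simulate."""

    samples: dict[str, int]
    n_loci: int
    mu: float | None = None       # override the model's rate
    p_gsm: float | None = None
    ancestral_state: int = 20

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("need >= 1 locus")
        if not self.samples or any(n < 1 for n in self.samples.values()):
            raise ValueError("need >= 1 individual per sampled deme")


def _msprime_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def simulate_genealogy(
    model, config: SampleConfig, seed: int
) -> Iterator[tskit.TreeSequence]:
    """Independent per-locus genealogies (branch lengths in generations)."""
    unknown = set(config.samples) - set(model.deme_names)
    if unknown:
        raise ValueError(f"sampled demes not in model: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    return msprime.sim_ancestry(
        samples=dict(config.samples),
        demography=model.demography(),
        ploidy=2,
        random_seed=_msprime_seed(rng),
        num_replicates=config.n_loci,
    )


def mutate_gsm(
    tree_sequence: tskit.TreeSequence,
    mu: float,
    p_gsm: float,
    ancestral_state: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Drop GSM mutations on a single-tree genealogy; return leaf states.

    Returns an array of repeat counts indexed by sample node id. Mutation
    counts per branch are Poisson(mu * branch length); each mutation moves
    the repeat count by a signed geometric step, reflected at 1.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if not 0 <= p_gsm < 1:
        raise ValueError("p_gsm must be in [0, 1)")
    tree = tree_sequence.first()
    order = tree.preorder()
    parent = tree.parent_array
    times = tree_sequence.tables.nodes.time
    branch = np.where(
        parent[order] == tskit.NULL, 0.0, times[parent[order]] - times[order]
    )
    n_mut = rng.poisson(mu * branch)
    total = int(n_mut.sum())
    all_steps = rng.geometric(1.0 - p_gsm, size=total)
    all_steps[rng.random(total) < 0.5] *= -1
    offsets = np.concatenate([[0], np.cumsum(n_mut)])
    states = np.zeros(tree_sequence.num_nodes, dtype=np.int64)
    for k, u in enumerate(order):
        p = parent[u]
        if p == tskit.NULL:
            states[u] = ancestral_state
            continue
        state = int(states[p])
        nm = int(n_mut[k])
        if nm:
            steps = all_steps[offsets[k]:offsets[k + 1]]
            state = _reflected_walk(state, steps)
        states[u] = state
    return states[tree_sequence.samples()]


def _reflected_walk(state: int, steps: np.ndarray) -> int:
    """Apply signed steps with per-mutation reflection at repeat count 1.

    Equivalent to the mutation-by-mutation update ``state += s; if
    state < 1: state = 2 - state`` (i.e. z = state - 1 follows
    z -> |z + s|), but processed in vectorized stretches between
    boundary crossings.
    """
    z = state - 1
    i = 0
    n = steps.size
    while i < n:
        cs = z + np.cumsum(steps[i:])
        neg = np.nonzero(cs < 0)[0]
        if neg.size == 0:
            return int(cs[-1]) + 1
        j = int(neg[0])
        z = -int(cs[j])  # reflect: |z_prev + s|
        i += j + 1
    return z + 1


def simulate_dataset(
    model,
    config: SampleConfig,
    seed: int,
    pop_prefix: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Simulate a diploid GenotypeMatrix under ``model``.

    Population labels default to the model's deme names (override with
    ``pop_prefix``); individuals are the diploid pairs msprime samples.
    """
    rng = np.random.default_rng(seed)
    mu = config.mu if config.mu is not None else model.mu
    p_gsm = config.p_gsm if config.p_gsm is not None else model.p_gsm
    reps = simulate_genealogy(model, config, _msprime_seed(rng))
    alleles = None
    labels: list[str] = []
    ids: list[str] = []
    for j, ts in enumerate(reps):
        leaf_states = mutate_gsm(ts, mu, p_gsm, config.ancestral_state, rng)
        if alleles is None:
            n_ind = ts.num_individuals
            alleles = np.zeros((n_ind, config.n_loci, 2), dtype=np.int64)
            name_of = {p.id: p.metadata.get("name", str(p.id)) for p in ts.populations()}
            sample_nodes = ts.samples()
            node_pos = {int(nd): k for k, nd in enumerate(sample_nodes)}
            ind_nodes = []
            for ind in ts.individuals():
                ind_nodes.append([int(n) for n in ind.nodes])
                deme = name_of[ts.node(ind.nodes[0]).population]
                label = pop_prefix.get(deme, deme) if pop_prefix else deme
                labels.append(label)
                ids.append(f"{label}_{sum(l == label for l in labels)}")
        for i, nds in enumerate(ind_nodes):
            alleles[i, j, 0] = leaf_states[node_pos[nds[0]]]
            alleles[i, j, 1] = leaf_states[node_pos[nds[1]]]
    assert alleles is not None
    return GenotypeMatrix(ids, [f"L{j + 1}" for j in range(config.n_loci)], alleles, labels)
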