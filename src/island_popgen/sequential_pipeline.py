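"""Three-step sequential ABC-RF demographic inference and descriptive runs.

Step 1 fits single-population size-change models (SNM/PGM/SRM) to each
island group separately. Step 2 compares the five three-group divergence
models without migration, iteratively pruning models with a high
confusion-row error or a low vote share and re-comparing (the 5 -> 4 -> 2
cascade). Step 3 pits the winning topology against the same topology with
each migration pattern. The winner's parameters are then estimated by
rejection + local-linear regression and checked by posterior predictive
goodness of fit.

Simulation budgets are configurable; the defaults are scaled to desk-size
experiments and are documented in docs/methods.md. Observed group sample
sizes are subsampled to the simulated sizes so summary statistics are
computed at matching sample sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from island_popgen import abc_engine as abc
from island_popgen import coalescent_sim as coal
from island_popgen import popgen_stats as stats
from island_popgen import structure_geo as sg
from island_popgen.genotype_io import GenotypeMatrix, subsample

__all__ = [
    "PipelineConfig", "PipelineResult", "DescriptiveResult",
    "run_demography", "run_descriptive",
    "single_pop_model_specs", "divergence_model_specs",
    "DEFAULT_SINGLE_POP_PRIORS", "DEFAULT_DIVERGENCE_PRIORS",
]

P = abc.Prior

DEFAULT_SINGLE_POP_PRIORS: dict[str, abc.PriorSpec] = {
    "SNM": {
        "N_CUR": P("log10-uniform", 1e2, 1e5),
        "mu": P("log10-uniform", 1e-4, 1e-3),
        "P_GSM": P("uniform", 0.0, 0.8),
    },
    "PGM": {
        "N_CUR": P("log10-uniform", 1e2, 1e5),
        "RN_ANC": P("log10-uniform", 1e-2, 1.0),
        "T_CHANGE": P("log10-uniform", 10, 1e4),
        "mu": P("log10-uniform", 1e-4, 1e-3),
        "P_GSM": P("uniform", 0.0, 0.8),
    },
    "SRM": {
        "N_CUR": P("log10-uniform", 1e2, 1e5),
        "RN_ANC": P("log10-uniform", 1.0, 1e2),
        "T_CHANGE": P("log10-uniform", 10, 1e4),
        "mu": P("log10-uniform", 1e-4, 1e-3),
        "P_GSM": P("uniform", 0.0, 0.8),
    },
}

_DIV_COMMON: abc.PriorSpec = {
    "N_BYD": P("log10-uniform", 1e2, 1e5),
    "N_V": P("log10-uniform", 1e2, 1e5),
    "N_ANC": P("log10-uniform", 1e2, 1e5),
    "T_1": P("log10-uniform", 10, 1e4),
    "T_2": P("log10-uniform", 1e2, 3e4),
    "mu": P("log10-uniform", 1e-4, 1e-3),
    "P_GSM": P("uniform", 0.0, 0.8),
}

DEFAULT_DIVERGENCE_PRIORS: dict[str, abc.PriorSpec] = {
    **{f"Model{k}": dict(_DIV_COMMON) for k in (1, 2, 3, 4)},
    "Model5": {k: v for k, v in _DIV_COMMON.items() if k != "T_2"} | {
        "T_1": P("log10-uniform", 1e2, 3e4)
    },
}

# Migration-rate prior floor keeps the migration models identifiable:
# with per-generation rates below ~1e-3 the migration variants collapse
# onto the no-migration model (4Nm << 1 over most of the size prior) and
# the comparison degenerates into a nested-model coin flip.
DEFAULT_MIGRATION_PRIOR = P("log10-uniform", 1e-3, 1e-1)


# ---------------------------------------------------------------------------
# coalescent-backed model specs


def _nan_vector(n_groups: int) -> np.ndarray:
    n = 4 * n_groups + 2 * (n_groups * (n_groups - 1) // 2)
    return np.full(n, np.nan)


def single_pop_model_specs(
    n_diploid: int,
    n_loci: int,
    priors: Mapping[str, abc.PriorSpec] | None = None,
) -> list[abc.ModelSpec]:
    """SNM/PGM/SRM ModelSpecs simulating one deme of ``n_diploid`` samples."""
    priors = dict(priors or DEFAULT_SINGLE_POP_PRIORS)
    config = coal.SampleConfig(samples={"P": n_diploid}, n_loci=n_loci)

    def make(kind: str) -> abc.ModelSpec:
        def simulate(params: Mapping[str, float], seed: int) -> np.ndarray:
            try:
                model = coal.SizeChangeModel(
                    kind=kind,
                    n_cur=params["N_CUR"],
                    rn_anc=params.get("RN_ANC", 1.0),
                    t_change=params.get("T_CHANGE", 0.0),
                    mu=params["mu"],
                    p_gsm=params["P_GSM"],
                )
            except ValueError:
                return _nan_vector(1)
            g = coal.simulate_dataset(model, config, seed)
            vec, _ = stats.abc_summary_vector(g, {"P": "P"})
            return vec

        return abc.ModelSpec(kind, priors[kind], simulate)

    return [make(k) for k in ("SNM", "PGM", "SRM")]


def divergence_model_specs(
    samples: Mapping[str, int],
    n_loci: int,
    topologies: Sequence[str] = ("Model1", "Model2", "Model3", "Model4", "Model5"),
    priors: Mapping[str, abc.PriorSpec] | None = None,
    migration: Mapping[str, tuple[str, str, abc.Prior]] | None = None,
) -> list[abc.ModelSpec]:
    """Divergence-model ModelSpecs over demes B, V, YD.

    ``topologies`` name the no-migration catalogue entries ``Model1`` ..
    ``Model5`` (topology ``Mk``). ``migration`` adds entries
    ``{name: (topology, pattern, rate_prior)}`` such as
    ``{"Model3M1": ("M3", "M1", Prior(...))}``. Draws violating the
    ``T_1 < T_2`` order return NaN statistics and are resampled by the
    reference-table builder, i.e. the joint prior is order-conditioned.
    """
    priors = dict(priors or DEFAULT_DIVERGENCE_PRIORS)
    config = coal.SampleConfig(samples=dict(samples), n_loci=n_loci)
    grouping = {d: d for d in ("B", "V", "YD")}

    def make(name: str, topo: str, pattern: str, rate_prior: abc.Prior | None):
        spec_priors = dict(priors[f"Model{topo[1:]}"] if name not in priors else priors[name])
        if rate_prior is not None:
            spec_priors = dict(spec_priors)
            spec_priors["M_RATE"] = rate_prior

        def simulate(params: Mapping[str, float], seed: int) -> np.ndarray:
            t1 = params["T_1"]
            t2 = params.get("T_2", t1 + 1.0)
            if topo != "M5" and not t1 < t2:
                return _nan_vector(3)
            try:
                model = coal.DivergenceModel.with_pattern(
                    topology=topo,
                    pattern=pattern,
                    rate=params.get("M_RATE", 0.0),
                    n_byd=params["N_BYD"],
                    n_v=params["N_V"],
                    n_anc=params["N_ANC"],
                    t1=t1,
                    t2=t2,
                    mu=params["mu"],
                    p_gsm=params["P_GSM"],
                )
            except ValueError:
                return _nan_vector(3)
            g = coal.simulate_dataset(model, config, seed)
            vec, _ = stats.abc_summary_vector(g, grouping)
            return vec

        return abc.ModelSpec(name, spec_priors, simulate)

    specs = [make(name, f"M{name[5:]}", "none", None) for name in topologies]
    for name, (topo, pattern, rate_prior) in (migration or {}).items():
        specs.append(make(name, topo, pattern, rate_prior))
    return specs


# ---------------------------------------------------------------------------
# configuration / results


@dataclass
class PipelineConfig:
    """Configuration of the sequential demographic inference."""

    grouping: dict[str, str]               # population label -> B / V / YD
    sim_samples: dict[str, int] = field(
        default_factory=lambda: {"B": 40, "V": 20, "YD": 30}
    )
    n_step1: int = 2000
    n_step2: int = 2000
    n_step3: int = 2000
    n_trees: int = 500
    tolerance: float = 0.05
    n_gof: int = 100
    prune_vote_threshold: float = 0.15
    prune_error_threshold: float = 0.6
    seed: int = 0
    single_pop_priors: dict[str, abc.PriorSpec] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SINGLE_POP_PRIORS.items()}
    )
    divergence_priors: dict[str, abc.PriorSpec] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DIVERGENCE_PRIORS.items()}
    )
    migration_prior: abc.Prior = DEFAULT_MIGRATION_PRIOR

    def to_json(self, path: str | Path) -> None:
        """Persist the full configuration, priors included."""
        def enc_priors(spec: Mapping[str, abc.PriorSpec]) -> dict:
            return {m: {k: [p.dist, p.lower, p.upper] for k, p in s.items()}
                    for m, s in spec.items()}

        payload = {
            "grouping": self.grouping,
            "sim_samples": self.sim_samples,
            "n_step1": self.n_step1, "n_step2": self.n_step2,
            "n_step3": self.n_step3, "n_trees": self.n_trees,
            "tolerance": self.tolerance, "n_gof": self.n_gof,
            "prune_vote_threshold": self.prune_vote_threshold,
            "prune_error_threshold": self.prune_error_threshold,
            "seed": self.seed,
            "single_pop_priors": enc_priors(self.single_pop_priors),
            "divergence_priors": enc_priors(self.divergence_priors),
            "migration_prior": [self.migration_prior.dist,
                                self.migration_prior.lower,
                                self.migration_prior.upper],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())

        def dec_priors(spec: dict) -> dict[str, abc.PriorSpec]:
            return {m: {k: abc.Prior(*v) for k, v in s.items()}
                    for m, s in spec.items()}

        return cls(
            grouping=raw["grouping"],
            sim_samples=raw["sim_samples"],
            n_step1=raw["n_step1"], n_step2=raw["n_step2"],
            n_step3=raw["n_step3"], n_trees=raw["n_trees"],
            tolerance=raw["tolerance"], n_gof=raw["n_gof"],
            prune_vote_threshold=raw["prune_vote_threshold"],
            prune_error_threshold=raw["prune_error_threshold"],
            seed=raw["seed"],
            single_pop_priors=dec_priors(raw["single_pop_priors"]),
            divergence_priors=dec_priors(raw["divergence_priors"]),
            migration_prior=abc.Prior(*raw["migration_prior"]),
        )

    def validate(self) -> None:
        if set(self.grouping.values()) - {"B", "V", "YD"}:
            raise ValueError("grouping values must be B, V or YD")
        for nm in ("n_step1", "n_step2", "n_step3"):
            if getattr(self, nm) < 100:
                raise ValueError(
                    f"budget {nm}={getattr(self, nm)} is below the minimum of 100 "
                    "simulations per model; raise the budget"
                )
        if not 0 < self.tolerance <= 1:
            raise ValueError("tolerance must be in (0, 1]")


@dataclass
class PruneStep:
    compared: list[str]
    votes: dict[str, float]
    best_model: str
    posterior_probability: float
    prior_error_rate: float
    dropped: list[str]
    reason: str


@dataclass
class PipelineResult:
    step1: dict[str, tuple[abc.ModelChoiceResult, abc.PosteriorResult]]
    step2_ledger: list[PruneStep]
    step2_best: str
    step3: abc.ModelChoiceResult
    final_model: str
    posterior: abc.PosteriorResult
    gof: pd.DataFrame
    seeds: dict[str, int]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        payload = {
            "step1": {
                grp: {"model_choice": mc.to_dict(), "posterior": post.to_dict()}
                for grp, (mc, post) in self.step1.items()
            },
            "step2": {
                "ledger": [asdict(s) for s in self.step2_ledger],
                "best": self.step2_best,
            },
            "step3": self.step3.to_dict(),
            "final_model": self.final_model,
            "posterior": self.posterior.to_dict(),
            "seeds": self.seeds,
        }
        (outdir / "demography.json").write_text(json.dumps(payload, indent=1))
        self.gof.to_csv(outdir / "goodness_of_fit.csv", index=False)


# ---------------------------------------------------------------------------
# demographic inference


def _pool_group(g: GenotypeMatrix, grouping: Mapping[str, str], group: str,
                label: str) -> GenotypeMatrix:
    idx = [i for i, p in enumerate(g.pop_labels) if grouping[p] == group]
    sub = g.subset(idx)
    return GenotypeMatrix(
        list(sub.individual_ids), list(sub.locus_names), sub.alleles,
        [label] * sub.n_individuals,
    )


def prepare_observed(
    g: GenotypeMatrix, config: PipelineConfig
) -> tuple[GenotypeMatrix, dict[str, np.ndarray]]:
    """Subsample groups to the simulated sizes; compute observed statistics.

    Returns the subsampled matrix and a dict with the three per-group
    4-vectors (keys B, V, YD) plus the full 18-vector (key "joint").
    """
    groups = {grp: [p for p in g.populations() if config.grouping[p] == grp]
              for grp in ("B", "V", "YD")}
    capped = g
    for grp, pops in groups.items():
        capped = subsample(
            capped, config.sim_samples[grp], {grp: pops}, seed=config.seed + 17
        )
    obs: dict[str, np.ndarray] = {}
    for grp in ("B", "V", "YD"):
        pooled = _pool_group(capped, config.grouping, grp, "P")
        obs[grp], _ = stats.abc_summary_vector(pooled, {"P": "P"})
    vec, _ = stats.abc_summary_vector(capped, dict(config.grouping))
    obs["joint"] = vec
    return capped, obs


class ForestCache:
    """Memoizes fitted ABC-RF forests by (table identity, model subset)."""

    def __init__(self) -> None:
        self._store: dict[tuple[int, tuple[str, ...]], abc.ModelChoiceForest] = {}

    def fit(self, table: abc.ReferenceTable, models: Sequence[str],
            n_trees: int, seed: int) -> abc.ModelChoiceForest:
        key = (id(table), tuple(models))
        if key not in self._store:
            sub = table if list(models) == table.models else table.restrict(models)
            self._store[key] = abc.fit_model_choice(sub, n_trees=n_trees, seed=seed)
        return self._store[key]


def build_pipeline_tables(
    config: PipelineConfig, n_loci: int
) -> dict[str, abc.ReferenceTable | dict[str, abc.ReferenceTable]]:
    """Simulate the three reference tables the pipeline needs."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    seeds = {k: int(rng.integers(0, 2**31 - 1))
             for k in ("step1_B", "step1_V", "step1_YD", "step2", "step3")}
    tables: dict[str, abc.ReferenceTable | dict[str, abc.ReferenceTable]] = {"step1": {}}
    for grp in ("B", "V", "YD"):
        specs = single_pop_model_specs(
            config.sim_samples[grp], n_loci, config.single_pop_priors
        )
        tables["step1"][grp] = abc.build_reference_table(  # type: ignore[index]
            specs, config.n_step1, seeds[f"step1_{grp}"]
        )
    div_specs = divergence_model_specs(
        config.sim_samples, n_loci, priors=config.divergence_priors
    )
    tables["step2"] = abc.build_reference_table(div_specs, config.n_step2, seeds["step2"])
    return tables


def _step3_table(
    config: PipelineConfig, n_loci: int, best_topo: str, seed: int
) -> abc.ReferenceTable:
    topo = f"M{best_topo[5:]}"
    mig = {
        f"{best_topo}M{k}": (topo, f"M{k}", config.migration_prior)
        for k in (1, 2, 3)
    }
    specs = divergence_model_specs(
        config.sim_samples, n_loci, topologies=(best_topo,),
        priors=config.divergence_priors, migration=mig,
    )
    return abc.build_reference_table(specs, config.n_step3, seed)


def run_demography(
    observed: GenotypeMatrix,
    config: PipelineConfig,
    tables: dict[str, object] | None = None,
    cache: ForestCache | None = None,
) -> PipelineResult:
    """Run the three-step sequential inference on an observed dataset.

    ``tables`` may carry prebuilt reference tables (keys ``step1`` —
    a group dict — ``step2`` and optionally ``step3:<topology>``) so many
    observed replicates can share one simulation budget; missing tables
    are built from the config and cached back into the passed mapping.
    All randomness derives from ``config.seed``.
    """
    config.validate()
    missing = set(observed.populations()) - set(config.grouping)
    if missing:
        raise ValueError(f"step 0 (input): populations missing from grouping: {sorted(missing)}")
    cache = cache or ForestCache()
    n_loci = observed.n_loci
    if tables is None:
        tables = {}
    if "step1" not in tables or "step2" not in tables:
        built = build_pipeline_tables(config, n_loci)
        tables.setdefault("step1", built["step1"])
        tables.setdefault("step2", built["step2"])
    rng = np.random.default_rng(config.seed + 1)
    _, obs = prepare_observed(observed, config)

    # step 1: size-change model per group
    step1: dict[str, tuple[abc.ModelChoiceResult, abc.PosteriorResult]] = {}
    for grp in ("B", "V", "YD"):
        table = tables["step1"][grp]  # type: ignore[index]
        forest = cache.fit(table, table.models, config.n_trees, config.seed + 11)
        mc = forest.choose(obs[grp])
        post = abc.estimate_posterior(
            table.restrict([mc.best_model]), obs[grp],
            tolerance=config.tolerance, seed=config.seed + 13,
        )
        step1[grp] = (mc, post)

    # step 2: divergence topology with pruning cascade
    table2: abc.ReferenceTable = tables["step2"]  # type: ignore[assignment]
    current = list(table2.models)
    ledger: list[PruneStep] = []
    while True:
        forest = cache.fit(table2, current, config.n_trees, config.seed + 23)
        mc2 = forest.choose(obs["joint"])
        conf = forest.confusion_matrix
        row_err = {m: 1.0 - float(conf.loc[m, m]) for m in current}
        drops = [m for m in current
                 if m != mc2.best_model and row_err[m] > config.prune_error_threshold]
        reason = "confusion-row error above threshold"
        if not drops:
            drops = [m for m in current
                     if m != mc2.best_model and mc2.votes[m] < config.prune_vote_threshold]
            reason = "vote share below threshold"
        if len(current) - len(drops) < 2:
            keep_order = sorted(
                (m for m in current if m != mc2.best_model),
                key=lambda m: -mc2.votes[m],
            )
            drops = keep_order[1:]
        ledger.append(
            PruneStep(list(current), dict(mc2.votes), mc2.best_model,
                      mc2.posterior_probability, mc2.prior_error_rate,
                      list(drops), reason if drops else "terminal comparison")
        )
        if not drops or len(current) <= 2:
            break
        current = [m for m in current if m not in drops]
    best_topo = ledger[-1].best_model

    # step 3: migration vs no migration under the best topology
    key3 = f"step3:{best_topo}"
    if key3 not in tables:
        tables[key3] = _step3_table(
            config, n_loci, best_topo, int(rng.integers(0, 2**31 - 1))
        )
    table3: abc.ReferenceTable = tables[key3]  # type: ignore[assignment]
    forest3 = cache.fit(table3, table3.models, config.n_trees, config.seed + 31)
    mc3 = forest3.choose(obs["joint"])
    final_model = mc3.best_model

    # final posterior under the winning model (pool step2+step3 rows when
    # the winner is the no-migration topology itself)
    rows3 = table3.restrict([final_model])
    if final_model == best_topo:
        rows2 = table2.restrict([best_topo])
        pooled = abc.ReferenceTable(
            np.concatenate([rows2.model_ids, rows3.model_ids]),
            pd.concat([rows2.params, rows3.params], ignore_index=True),
            np.vstack([rows2.stats, rows3.stats]),
            list(rows2.stat_names),
            rows2.priors,
            table2.seed,
        )
    else:
        pooled = rows3
    posterior = abc.estimate_posterior(
        pooled, obs["joint"], tolerance=config.tolerance, seed=config.seed + 37
    )

    # goodness of fit under the winning model
    mig_spec = None
    if final_model != best_topo:
        pattern = final_model[len(best_topo):]
        mig_spec = {final_model: (f"M{best_topo[5:]}", pattern, config.migration_prior)}
        specs = divergence_model_specs(
            config.sim_samples, n_loci, topologies=(),
            priors=config.divergence_priors, migration=mig_spec,
        )
    else:
        specs = divergence_model_specs(
            config.sim_samples, n_loci, topologies=(best_topo,),
            priors=config.divergence_priors,
        )
    sim_fn = {s.name: s.simulate for s in specs}[final_model]
    gof = abc.goodness_of_fit(
        posterior, sim_fn, obs["joint"], n_draws=config.n_gof,
        seed=config.seed + 41,
    )
    gof.insert(0, "statistic_name",
               stats.summary_stat_names(["B", "V", "YD"]))
    return PipelineResult(
        step1=step1, step2_ledger=ledger, step2_best=best_topo, step3=mc3,
        final_model=final_model, posterior=posterior, gof=gof,
        seeds={"root": config.seed},
    )


# ---------------------------------------------------------------------------
# descriptive analyses


@dataclass
class DescriptiveResult:
    diversity: stats.DiversityTable
    group_means: pd.DataFrame
    fst: stats.DistanceMatrix
    da: stats.DistanceMatrix
    tree: sg.PopTree
    mantel_all: sg.MantelResult | None
    mantel_far: sg.MantelResult | None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.diversity.write(outdir / "diversity_per_locus.csv",
                             outdir / "diversity_means.csv")
        self.group_means.to_csv(outdir / "group_means.csv")
        self.fst.to_long().to_csv(outdir / "pairwise_fst.csv", index=False)
        self.da.to_long().to_csv(outdir / "pairwise_da.csv", index=False)
        (outdir / "nj_tree.nwk").write_text(self.tree.newick(include_support=True))
        if self.mantel_all is not None:
            pd.DataFrame([
                {"subset": "all", **vars(self.mantel_all)},
                *([{"subset": "over_270km", **vars(self.mantel_far)}]
                  if self.mantel_far is not None else []),
            ]).to_csv(outdir / "ibd_mantel.csv", index=False)


def run_descriptive(
    g: GenotypeMatrix,
    island_groups: Mapping[str, str] | None = None,
    coordinates: Mapping[str, tuple[float, float]] | None = None,
    n_boot: int = 1000,
    n_perm: int = 9999,
    fis_perm: int = 1000,
    rarefaction_size: int | str = "auto",
    far_threshold_km: float = 270.0,
    seed: int = 0,
) -> DescriptiveResult:
    """Diversity table, distance matrices, NJ tree, and IBD Mantel tests.

    ``island_groups`` maps population -> island-group label for the group
    means; IBD is skipped (None results) without ``coordinates``.
    """
    div = stats.diversity_table(g, rarefaction_size, n_perm=fis_perm, seed=seed)
    means = div.means.copy()
    if island_groups:
        means["island_group"] = [island_groups.get(p, "?") for p in means.index]
        group_means = means.groupby("island_group")[["A_R", "H_O", "H_E"]].mean()
    else:
        group_means = pd.DataFrame()
    fst = stats.pairwise_fst(g)
    da = stats.da_distance(g)
    tree = (sg.bootstrap_support(g, n_boot=n_boot, seed=seed + 1)
            if g.n_loci >= 2 and len(g.populations()) >= 3
            else sg.nj_tree(da))
    mantel_all = mantel_far = None
    if coordinates is not None:
        geo = sg.haversine_matrix(fst.labels, dict(coordinates))
        mantel_all = sg.ibd_test(fst, geo, n_perm=n_perm, seed=seed + 2)
        mantel_far = sg.ibd_test(
            fst, geo, n_perm=n_perm, seed=seed + 3,
            min_distance_km=far_threshold_km, tail="two-sided",
        )
    return DescriptiveResult(div, group_means, fst, da, tree, mantel_all, mantel_far)
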