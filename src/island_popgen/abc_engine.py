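"""Approximate Bayesian computation with random forests.

Model choice follows the ABC-RF recipe: a classification forest is
trained on (summary statistics -> model id) over the reference table;
votes on the observed vector rank the models, the out-of-bag
misclassification rate is the prior error rate, and the posterior
probability of the selected model is a regression forest's prediction,
at the observed statistics, of the out-of-bag "classified correctly"
indicator.

Parameter estimation is DIYABC-style rejection plus local-linear
regression adjustment: keep the ``tolerance`` fraction of simulations
nearest to the observed vector in robustly standardized statistic space,
regress (transformed) parameters on the statistics with Epanechnikov
weights, and adjust the accepted draws to the observed point. Bounded
parameters are logit-transformed on their prior scale before adjustment,
so adjusted draws can never leave the prior support. Posterior mode via
weighted Gaussian KDE; 95% interval as the highest-posterior-density
(shortest) interval of the weighted sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

__all__ = [
    "Prior", "PriorSpec", "ModelSpec", "ReferenceTable",
    "ModelChoiceResult", "ModelChoiceForest", "PosteriorResult",
    "build_reference_table", "fit_model_choice", "rf_model_choice",
    "prune_and_recompare",
    "estimate_posterior", "goodness_of_fit",
]


@dataclass(frozen=True)
class Prior:
    """Marginal prior: uniform or log10-uniform on (lower, upper)."""

    dist: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.dist not in ("uniform", "log10-uniform"):
            raise ValueError(f"unknown prior distribution {self.dist!r}")
        if not self.lower < self.upper:
            raise ValueError("need lower < upper")
        if self.dist == "log10-uniform" and self.lower <= 0:
            raise ValueError("log10-uniform requires lower > 0")

    def sample(self, rng: np.random.Generator) -> float:
        if self.dist == "uniform":
            return float(rng.uniform(self.lower, self.upper))
        return float(10 ** rng.uniform(np.log10(self.lower), np.log10(self.upper)))

    # transforms used by the regression adjustment -----------------------
    def to_unbounded(self, x: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds_transformed()
        z = (self._fwd(x) - lo) / (hi - lo)
        z = np.clip(z, 1e-12, 1 - 1e-12)
        return np.log(z / (1 - z))

    def from_unbounded(self, u: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds_transformed()
        z = 1.0 / (1.0 + np.exp(-u))
        return self._bwd(lo + z * (hi - lo))

    def _fwd(self, x):
        return np.log10(x) if self.dist == "log10-uniform" else np.asarray(x, float)

    def _bwd(self, t):
        return 10**t if self.dist == "log10-uniform" else t

    def bounds_transformed(self) -> tuple[float, float]:
        return (float(self._fwd(self.lower)), float(self._fwd(self.upper)))


PriorSpec = dict[str, Prior]


@dataclass
class ModelSpec:
    """A named generative model for the reference table.

    ``simulate(params, seed) -> 1-D summary-statistic vector``; the
    callable owns dataset generation and summary computation.
    """

    name: str
    priors: PriorSpec
    simulate: Callable[[Mapping[str, float], int], np.ndarray]
    validate: Callable[[Mapping[str, float]], None] | None = None

    def draw_params(self, rng: np.random.Generator) -> dict[str, float]:
        return {k: p.sample(rng) for k, p in self.priors.items()}


@dataclass
class ReferenceTable:
    """Per-simulation (model id, parameters, summary statistics) records."""

    model_ids: np.ndarray          # (n,) str
    params: pd.DataFrame           # (n, P) union of per-model parameters
    stats: np.ndarray              # (n, S)
    stat_names: list[str]
    priors: dict[str, PriorSpec] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.model_ids = np.asarray(self.model_ids, dtype=object)
        self.stats = np.asarray(self.stats, dtype=float)
        if np.isnan(self.stats).any():
            raise ValueError("reference table contains undefined statistics")
        if len(self.model_ids) != len(self.params) or len(self.model_ids) != len(self.stats):
            raise ValueError("row-count mismatch")

    @property
    def models(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.model_ids:
            seen.setdefault(m)
        return list(seen)

    def restrict(self, models: Sequence[str]) -> "ReferenceTable":
        mask = np.isin(self.model_ids, list(models))
        return ReferenceTable(
            self.model_ids[mask],
            self.params.loc[mask].reset_index(drop=True),
            self.stats[mask],
            list(self.stat_names),
            {m: self.priors[m] for m in models if m in self.priors},
            self.seed,
        )

    def write(self, tsv_path: str | Path) -> None:
        """Persist as TSV plus a JSON sidecar with priors and metadata."""
        tsv_path = Path(tsv_path)
        df = pd.concat(
            [pd.Series(self.model_ids, name="model"),
             self.params.add_prefix("param:"),
             pd.DataFrame(self.stats, columns=[f"stat:{s}" for s in self.stat_names])],
            axis=1,
        )
        df.to_csv(tsv_path, sep="\t", index=False)
        sidecar = {
            "models": self.models,
            "stat_names": self.stat_names,
            "seed": self.seed,
            "priors": {
                m: {k: [p.dist, p.lower, p.upper] for k, p in spec.items()}
                for m, spec in self.priors.items()
            },
        }
        tsv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read(cls, tsv_path: str | Path) -> "ReferenceTable":
        tsv_path = Path(tsv_path)
        df = pd.read_csv(tsv_path, sep="\t")
        meta = json.loads(tsv_path.with_suffix(".json").read_text())
        pcols = [c for c in df.columns if c.startswith("param:")]
        scols = [c for c in df.columns if c.startswith("stat:")]
        priors = {
            m: {k: Prior(*v) for k, v in spec.items()}
            for m, spec in meta["priors"].items()
        }
        return cls(
            df["model"].to_numpy(dtype=object),
            df[pcols].rename(columns=lambda c: c[len("param:"):]),
            df[scols].to_numpy(dtype=float),
            meta["stat_names"],
            priors,
            meta.get("seed"),
        )


@dataclass
class ModelChoiceResult:
    votes: dict[str, float]
    best_model: str
    posterior_probability: float
    prior_error_rate: float
    confusion_matrix: pd.DataFrame  # rows: true model, columns: OOB-predicted
    n_trees: int

    def to_dict(self) -> dict:
        return {
            "votes": self.votes,
            "best_model": self.best_model,
            "posterior_probability": self.posterior_probability,
            "prior_error_rate": self.prior_error_rate,
            "confusion_matrix": self.confusion_matrix.to_dict(),
            "n_trees": self.n_trees,
        }


@dataclass
class PosteriorResult:
    parameters: list[str]
    samples: pd.DataFrame          # accepted, regression-adjusted draws
    weights: np.ndarray            # Epanechnikov weights, sum to 1
    modes: dict[str, float]
    hpd_intervals: dict[str, tuple[float, float]]
    priors: PriorSpec

    def summary(self) -> pd.DataFrame:
        rows = []
        for p in self.parameters:
            lo, hi = self.hpd_intervals[p]
            rows.append({"parameter": p, "mode": self.modes[p],
                         "hpd_lower": lo, "hpd_upper": hi})
        return pd.DataFrame(rows).set_index("parameter")

    def to_dict(self) -> dict:
        return {
            p: {"mode": self.modes[p], "hpd_95": list(self.hpd_intervals[p])}
            for p in self.parameters
        }


# ---------------------------------------------------------------------------
# reference table


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def build_reference_table(
    models: Sequence[ModelSpec],
    n_per_model: int,
    seed: int,
    min_per_model: int = 100,
) -> ReferenceTable:
    """Simulate ``n_per_model`` prior draws per model.

    Draws whose statistics contain NaN (degenerate simulations) are
    resampled. Reproducible under ``seed``; per-simulation seeds derive
    from the root generator by counter, so the table is independent of
    evaluation order.
    """
    if n_per_model < min_per_model:
        raise ValueError(f"n_per_model must be >= {min_per_model}")
    rng = np.random.default_rng(seed)
    ids: list[str] = []
    rows: list[dict[str, float]] = []
    stats: list[np.ndarray] = []
    stat_names: list[str] | None = None
    for spec in models:
        done = 0
        while done < n_per_model:
            params = spec.draw_params(rng)
            if spec.validate is not None:
                spec.validate(params)
            vec = np.asarray(spec.simulate(params, _child_seed(rng)), dtype=float)
            if np.isnan(vec).any():
                continue
            ids.append(spec.name)
            rows.append(params)
            stats.append(vec)
            done += 1
        if stat_names is None:
            stat_names = [f"S{k}" for k in range(len(stats[0]))]
    return ReferenceTable(
        np.array(ids, dtype=object),
        pd.DataFrame(rows),
        np.vstack(stats),
        stat_names or [],
        {m.name: dict(m.priors) for m in models},
        seed,
    )


# ---------------------------------------------------------------------------
# RF model choice


def _drop_constant(stats: np.ndarray, names: Sequence[str]):
    keep = np.ptp(stats, axis=0) > 0
    if not keep.all():
        import warnings

        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping constant statistic columns: {dropped}")
    return stats[:, keep], keep


@dataclass
class ModelChoiceForest:
    """Trained ABC-RF classifier, reusable across observed vectors."""

    clf: RandomForestClassifier
    reg: RandomForestRegressor
    models: list[str]
    keep: np.ndarray
    prior_error_rate: float
    confusion_matrix: pd.DataFrame
    n_trees: int

    def choose(self, observed: np.ndarray) -> ModelChoiceResult:
        obs = np.asarray(observed, dtype=float)[self.keep].reshape(1, -1)
        votes_count = dict.fromkeys(self.models, 0)
        classes = self.clf.classes_
        for est in self.clf.estimators_:
            proba = est.predict_proba(obs)[0]
            votes_count[classes[int(np.argmax(proba))]] += 1
        votes = {m: votes_count[m] / self.n_trees for m in self.models}
        best = max(votes, key=lambda m: (votes[m], m))
        post_prob = float(np.clip(self.reg.predict(obs)[0], 0.0, 1.0))
        return ModelChoiceResult(
            votes, best, post_prob, self.prior_error_rate,
            self.confusion_matrix, self.n_trees,
        )


def fit_model_choice(
    table: ReferenceTable, n_trees: int = 500, seed: int = 0
) -> ModelChoiceForest:
    """Train the ABC-RF classification and posterior-probability forests.

    Single-threaded and exactly reproducible under ``seed``.
    """
    models = table.models
    if len(models) < 2:
        raise ValueError("need >= 2 models in the reference table")
    X, keep = _drop_constant(table.stats, table.stat_names)
    y = table.model_ids.astype(str)
    clf = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, bootstrap=True,
        random_state=seed, n_jobs=1,
    )
    clf.fit(X, y)
    classes = clf.classes_
    oob = clf.oob_decision_function_
    valid = ~np.isnan(oob).any(axis=1)
    oob_pred = np.array([classes[i] for i in np.argmax(oob[valid], axis=1)])
    truth = y[valid]
    prior_error = float(np.mean(oob_pred != truth))
    confusion = pd.crosstab(
        pd.Series(truth, name="true"), pd.Series(oob_pred, name="predicted"),
        normalize="index",
    ).reindex(index=models, columns=models, fill_value=0.0)
    # posterior probability: regression forest on the OOB success indicator
    success = (oob_pred == truth).astype(float)
    reg = RandomForestRegressor(
        n_estimators=n_trees, random_state=seed + 1, n_jobs=1
    )
    reg.fit(X[valid], success)
    return ModelChoiceForest(clf, reg, models, keep, prior_error, confusion, n_trees)


def rf_model_choice(
    table: ReferenceTable,
    observed: np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
) -> ModelChoiceResult:
    """ABC-RF model choice on a reference table (fit + choose)."""
    return fit_model_choice(table, n_trees, seed).choose(observed)


def prune_and_recompare(
    table: ReferenceTable,
    observed: np.ndarray,
    exclude: Sequence[str],
    n_trees: int = 500,
    seed: int = 0,
) -> ModelChoiceResult:
    """Re-run model choice after removing ``exclude`` from the table."""
    remaining = [m for m in table.models if m not in set(exclude)]
    if len(remaining) < 2:
        raise ValueError("pruning must leave >= 2 models")
    return rf_model_choice(table.restrict(remaining), observed, n_trees, seed)


# ---------------------------------------------------------------------------
# posterior estimation


def _standardize(stats: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    med = np.median(stats, axis=0)
    mad = np.median(np.abs(stats - med), axis=0)
    sd = np.std(stats, axis=0)
    scale = np.where(mad > 0, mad, np.where(sd > 0, sd, 1.0))
    return (stats - med) / scale, med, scale


def _weighted_hpd(x: np.ndarray, w: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Smallest interval holding ``mass`` of the weighted sample."""
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cw = np.concatenate([[0.0], np.cumsum(ws)])
    cw /= cw[-1]
    best = (xs[0], xs[-1])
    width = xs[-1] - xs[0]
    j = 0
    for i in range(len(xs)):
        while j < len(xs) and cw[j + 1] - cw[i] < mass:
            j += 1
        if j >= len(xs):
            break
        if xs[j] - xs[i] < width:
            width = xs[j] - xs[i]
            best = (float(xs[i]), float(xs[j]))
    return best


def _weighted_mode(x: np.ndarray, w: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return float(x[0])
    try:
        kde = gaussian_kde(x, weights=w)
    except np.linalg.LinAlgError:
        return float(x[np.argmax(w)])
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[int(np.argmax(kde(grid)))])


def estimate_posterior(
    table: ReferenceTable,
    observed: np.ndarray,
    tolerance: float = 0.05,
    seed: int = 0,
    adjust: bool = True,
    min_accepted: int = 50,
) -> PosteriorResult:
    """Rejection + local-linear regression posterior for one model's table.

    ``table`` must be restricted to a single model. Mode and HPD are
    computed on the prior's scale (log10 for log-uniform parameters) and
    mapped back, so they respect the parameterization the priors define.
    """
    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must be in (0, 1]")
    models = table.models
    if len(models) != 1:
        raise ValueError("posterior estimation needs a single-model table")
    priors = table.priors.get(models[0], {})
    params = table.params.dropna(axis=1, how="all")
    names = list(params.columns)
    Z, med, scale = _standardize(table.stats)
    obs_z = (np.asarray(observed, dtype=float) - med) / scale
    d = np.sqrt(np.sum((Z - obs_z) ** 2, axis=1))
    n_keep = int(np.ceil(tolerance * len(d)))
    if n_keep < min_accepted:
        raise ValueError(
            f"tolerance {tolerance} keeps only {n_keep} draws (< {min_accepted}); "
            "increase n_per_model or tolerance"
        )
    order = np.argsort(d, kind="stable")[:n_keep]
    d_max = d[order][-1]
    if adjust and d_max > 0:
        w = 1.0 - (d[order] / d_max) ** 2  # Epanechnikov
        w = np.maximum(w, 1e-12)
    else:
        # plain rejection keeps the accepted draws unweighted, so the
        # tolerance -> 1 limit recovers the prior exactly
        w = np.ones(n_keep)
    w = w / w.sum()
    accepted = params.iloc[order].reset_index(drop=True).copy()
    if adjust:
        X = Z[order]  # centered at obs below
        Xc = X - obs_z
        A = np.hstack([np.ones((n_keep, 1)), Xc])
        W = w
        for name in names:
            col = accepted[name].to_numpy(dtype=float)
            prior = priors.get(name)
            t = prior.to_unbounded(col) if prior is not None else col
            # weighted least squares: t ~ intercept + stats
            Aw = A * W[:, None]
            try:
                beta, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ t, rcond=None)
            except np.linalg.LinAlgError:
                continue
            fitted = A @ beta
            t_adj = beta[0] + (t - fitted)
            accepted[name] = (
                prior.from_unbounded(t_adj) if prior is not None else t_adj
            )
    modes: dict[str, float] = {}
    hpds: dict[str, tuple[float, float]] = {}
    for name in names:
        col = accepted[name].to_numpy(dtype=float)
        prior = priors.get(name)
        if prior is not None and prior.dist == "log10-uniform":
            t = np.log10(col)
            mode = 10 ** _weighted_mode(t, w)
            lo, hi = _weighted_hpd(t, w)
            hpd = (10**lo, 10**hi)
        else:
            mode = _weighted_mode(col, w)
            hpd = _weighted_hpd(col, w)
        lo, hi = hpd
        modes[name] = float(min(max(mode, lo), hi))
        hpds[name] = (float(lo), float(hi))
    return PosteriorResult(names, accepted, w, modes, hpds, priors)


def goodness_of_fit(
    posterior: PosteriorResult,
    simulate: Callable[[Mapping[str, float], int], np.ndarray],
    observed: np.ndarray,
    n_draws: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Posterior-predictive two-sided p-value per summary statistic.

    Parameters are resampled from the weighted posterior sample, datasets
    simulated, and p = 2 min(P(sim <= obs), P(sim >= obs)) computed with
    the (count + 1)/(n + 1) correction.
    """
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(posterior.weights), size=n_draws, p=posterior.weights)
    sims = []
    for i in idx:
        params = posterior.samples.iloc[int(i)].to_dict()
        sims.append(np.asarray(simulate(params, _child_seed(rng)), dtype=float))
    sims = np.vstack(sims)
    obs = np.asarray(observed, dtype=float)
    le = (np.sum(sims <= obs[None, :], axis=0) + 1) / (n_draws + 1)
    ge = (np.sum(sims >= obs[None, :], axis=0) + 1) / (n_draws + 1)
    p = np.minimum(1.0, 2 * np.minimum(le, ge))
    return pd.DataFrame({"statistic": np.arange(len(obs)), "observed": obs,
                         "predictive_mean": sims.mean(axis=0), "p_value": p})
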