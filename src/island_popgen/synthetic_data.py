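"""Synthetic datasets with the statistical structure of the island study.

``make_study_mimic`` generates a genotype table with the study's exact
sampling design — 28 populations on 14 islands in 4 island groups, 11
microsatellite loci, per-population sample sizes 10-44 totalling 663
individuals — under a three-group divergence demography with a
bottlenecked Volcano group, so that the qualitative diversity ordering
(continental Yaeyama highest, young oceanic Volcano lowest) emerges from
the coalescent rather than being painted on. Island coordinates are
approximate real island locations; per-population jitter is synthetic.

``make_recovery_set`` produces replicate datasets with a JSON truth
sidecar for power/coverage experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import msprime
import numpy as np

from island_popgen import coalescent_sim as coal
from island_popgen.genotype_io import GenotypeMatrix, PopulationMeta

__all__ = ["FixtureSpec", "make_study_mimic", "make_recovery_set", "STUDY_DESIGN"]

# (pop_id, island, island_group, n_samples, island_area_ha, lat, lon)
# Sample sizes and areas follow the study design; coordinates are
# approximate island positions with synthetic per-population offsets.
STUDY_DESIGN: list[tuple[str, str, str, int, float, float, float]] = [
    ("MM",        "Mukojima",       "Bonin",   32,  256, 27.68, 142.14),
    ("CO1",       "Otoutojima",     "Bonin",   22,  520, 27.17, 142.17),
    ("CO2",       "Otoutojima",     "Bonin",   39,  520, 27.18, 142.18),
    ("CA1",       "Anijima",        "Bonin",   44,  788, 27.12, 142.21),
    ("CA2",       "Anijima",        "Bonin",   29,  788, 27.13, 142.19),
    ("CN",        "Nishijima",      "Bonin",   12,   48, 27.11, 142.15),
    ("CC1",       "Chichijima",     "Bonin",   20, 2344, 27.09, 142.19),
    ("CC2",       "Chichijima",     "Bonin",   21, 2344, 27.08, 142.21),
    ("CC3",       "Chichijima",     "Bonin",   17, 2344, 27.07, 142.22),
    ("CC4",       "Chichijima",     "Bonin",   35, 2344, 27.06, 142.20),
    ("CC4_dubia", "Chichijima",     "Bonin",   17, 2344, 27.06, 142.20),
    ("CC5",       "Chichijima",     "Bonin",   24, 2344, 27.05, 142.18),
    ("CC6",       "Chichijima",     "Bonin",   20, 2344, 27.04, 142.19),
    ("CC7",       "Chichijima",     "Bonin",   24, 2344, 27.03, 142.21),
    ("CC8",       "Chichijima",     "Bonin",   21, 2344, 27.02, 142.20),
    ("HHa1",      "Hahajima",       "Bonin",   23, 1988, 26.68, 142.16),
    ("HHa2",      "Hahajima",       "Bonin",   23, 1988, 26.66, 142.15),
    ("HHa3",      "Hahajima",       "Bonin",   23, 1988, 26.64, 142.17),
    ("HHa4",      "Hahajima",       "Bonin",   20, 1988, 26.62, 142.16),
    ("HHa5",      "Hahajima",       "Bonin",   25, 1988, 26.60, 142.14),
    ("HMu",       "Mukoujima",      "Bonin",   20,  138, 26.67, 142.13),
    ("HI",        "Imoutojima",     "Bonin",   10,  123, 26.58, 142.12),
    ("HMe",       "Meijima",        "Bonin",   23,   87, 26.55, 142.15),
    ("VM",        "Minamiiwoto",    "Volcano", 35,  354, 24.23, 141.46),
    ("DK",        "Kitadaitojima",  "Daito",   26, 1194, 25.95, 131.30),
    ("DM",        "Minamidaitojima","Daito",   23, 3057, 25.83, 131.23),
    ("YIs",       "Ishigakijima",   "Yaeyama", 14, 22250, 24.40, 124.18),
    ("YIr",       "Iriomotejima",   "Yaeyama", 21, 28930, 24.33, 123.80),
]

ISLAND_GROUP_TO_DEME = {"Bonin": "B", "Volcano": "V", "Daito": "D", "Yaeyama": "Y"}

# Mimic demography (diploid sizes and split times, generations):
# Yaeyama-rooted colonization with a founder-limited Volcano group.
# Sizes chosen so locus diversity sits in the study's range
# (theta = 8 N mu of order 1-10, giving H_E around 0.5-0.7).
_MIMIC = {
    "N_Y": 2200.0, "N_B": 1300.0, "N_D": 900.0, "N_V": 400.0,
    "N_POP": {"Bonin": 1000.0, "Volcano": 400.0, "Daito": 800.0, "Yaeyama": 1800.0},
    "T_POP": 100.0,    # local populations bud from their group deme
    "T_DUBIA": 20.0,   # CC4_dubia buds from CC4 (same site, two ecotypes)
    "T_V": 1500.0,     # Volcano buds from Bonin
    "T_D": 2000.0,     # Daito buds from Yaeyama
    "T_B": 8000.0,     # Bonin splits from the Yaeyama root lineage
    "MU": 5e-4, "P_GSM": 0.3,
}


def _mimic_demography() -> msprime.Demography:
    d = msprime.Demography()
    for grp, size in (("Y", _MIMIC["N_Y"]), ("B", _MIMIC["N_B"]),
                      ("D", _MIMIC["N_D"]), ("V", _MIMIC["N_V"])):
        d.add_population(name=grp, initial_size=size)
    for pop_id, island, group, n, *_ in STUDY_DESIGN:
        d.add_population(name=pop_id, initial_size=_MIMIC["N_POP"][group])
    d.add_mass_migration(
        time=_MIMIC["T_DUBIA"], source="CC4_dubia", dest="CC4", proportion=1.0
    )
    for grp, members in _members_by_deme().items():
        d.add_population_split(
            time=_MIMIC["T_POP"], derived=members, ancestral=grp
        )
    d.add_mass_migration(time=_MIMIC["T_V"], source="V", dest="B", proportion=1.0)
    d.add_mass_migration(time=_MIMIC["T_D"], source="D", dest="Y", proportion=1.0)
    d.add_mass_migration(time=_MIMIC["T_B"], source="B", dest="Y", proportion=1.0)
    d.sort_events()
    return d


def _members_by_deme() -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for pop_id, island, group, *_ in STUDY_DESIGN:
        out.setdefault(ISLAND_GROUP_TO_DEME[group], []).append(pop_id)
    return out


def make_study_mimic(
    seed: int, n_loci: int = 11
) -> tuple[GenotypeMatrix, list[PopulationMeta], dict[str, str]]:
    """Study-design mimic dataset.

    Returns the genotype matrix (663 individuals, 28 populations, 11
    loci), per-population metadata with synthetic coordinates, and the
    population -> inference-group map (B / V / YD, Daito pooled with
    Yaeyama as in the three-group analyses).
    """
    model = coal.CustomDemographyModel(
        demography_builder=_mimic_demography,
        demes=[row[0] for row in STUDY_DESIGN],
        mu=_MIMIC["MU"],
        p_gsm=_MIMIC["P_GSM"],
    )
    config = coal.SampleConfig(
        samples={row[0]: row[3] for row in STUDY_DESIGN}, n_loci=n_loci
    )
    g = coal.simulate_dataset(model, config, seed)
    meta = [
        PopulationMeta(pop, island, group, n, (lat, lon), area)
        for pop, island, group, n, area, lat, lon in STUDY_DESIGN
    ]
    grouping = {
        row[0]: {"Bonin": "B", "Volcano": "V", "Daito": "YD", "Yaeyama": "YD"}[row[2]]
        for row in STUDY_DESIGN
    }
    return g, meta, grouping


@dataclass
class FixtureSpec:
    """Named scenario for replicate recovery experiments."""

    name: str
    model: object            # SizeChangeModel | DivergenceModel | custom
    samples: dict[str, int]
    n_loci: int = 11
    seed: int = 0

    def truth(self) -> dict:
        m = self.model
        record: dict[str, object] = {"scenario": self.name, "seed": self.seed,
                                     "model": type(m).__name__}
        for k, v in vars(m).items():
            if isinstance(v, (int, float, str)):
                record[k] = v
        return record


def make_recovery_set(
    spec: FixtureSpec, n_replicates: int
) -> tuple[list[GenotypeMatrix], list[dict]]:
    """Replicate datasets plus truth records under one fixed scenario."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(spec.seed)
    config = coal.SampleConfig(samples=dict(spec.samples), n_loci=spec.n_loci)
    datasets = []
    truths = []
    for rep in range(n_replicates):
        s = int(rng.integers(0, 2**31 - 1))
        datasets.append(coal.simulate_dataset(spec.model, config, s))
        truths.append({**spec.truth(), "replicate": rep, "replicate_seed": s})
    return datasets, truths


def write_recovery_set(
    spec: FixtureSpec, n_replicates: int, outdir: str | Path, format: str = "csv_wide"
) -> None:
    from island_popgen.genotype_io import write_genotypes

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    datasets, truths = make_recovery_set(spec, n_replicates)
    ext = "gen" if format == "genepop" else "csv"
    for rep, g in enumerate(datasets):
        write_genotypes(g, outdir / f"{spec.name}_rep{rep:02d}.{ext}", format)
    (outdir / f"{spec.name}_truth.json").write_text(json.dumps(truths, indent=1))
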