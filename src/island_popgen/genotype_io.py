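"""Reading, validating, writing, and reshaping diploid microsatellite data.

Genotypes are stored as an ``(n_individuals, n_loci, 2)`` integer array of
allele states (repeat counts or fragment sizes) with ``0`` reserved for
missing. Two on-disk dialects are supported:

* ``genepop`` — classic GenePop: title line, one locus name per line (or a
  single comma-separated line), ``pop`` separators, rows of
  ``id , 095105 102102 ...`` with 2- or 3-digit alleles, 0 = missing.
* ``csv_wide`` — one row per individual with columns ``individual_id``,
  ``population`` and two columns ``<locus>.1``/``<locus>.2`` per locus.

Missing data are handled locus-wise: an individual missing one locus still
contributes to every other locus. Half-missing genotypes (one allele 0,
the other observed) are rejected at load.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = 0


class GenotypeParseError(ValueError):
    """Raised when a genotype file violates its dialect."""


@dataclass
class GenotypeMatrix:
    """Diploid allele table for ``n`` individuals at ``L`` loci.

    Attributes
    ----------
    individual_ids
        Unique identifier per individual, order matches ``alleles`` rows.
    locus_names
        Unique locus names, order matches the second axis of ``alleles``.
    alleles
        ``(n, L, 2)`` integer array; 0 encodes a missing genotype and must
        occur in pairs (both gene copies missing).
    pop_labels
        Population identifier per individual.
    """

    individual_ids: list[str]
    locus_names: list[str]
    alleles: np.ndarray
    pop_labels: list[str]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        self.validate()

    # -- basic interface -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.pop_labels:
            seen.setdefault(p)
        return list(seen)

    def population_indices(self, pop: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.pop_labels, dtype=object) == pop)
        if idx.size == 0:
            raise KeyError(f"unknown population label {pop!r}")
        return idx

    def subset(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=np.intp)
        return GenotypeMatrix(
            [self.individual_ids[i] for i in idx],
            list(self.locus_names),
            self.alleles[idx].copy(),
            [self.pop_labels[i] for i in idx],
        )

    def validate(self) -> None:
        n, L = self.n_individuals, self.n_loci
        if self.alleles.shape != (n, L, 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} != {(n, L, 2)}"
            )
        if len(self.pop_labels) != n:
            raise ValueError("pop_labels length mismatch")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if len(set(self.locus_names)) != L:
            raise ValueError("duplicate locus names")
        if np.any(self.alleles < 0):
            raise ValueError("negative allele states")
        half = (self.alleles == MISSING).sum(axis=2) == 1
        if np.any(half):
            i, j = np.argwhere(half)[0]
            raise ValueError(
                "half-missing genotype for individual "
                f"{self.individual_ids[i]!r} at locus {self.locus_names[j]!r}"
            )

    def missingness(self) -> pd.Series:
        """Per-locus fraction of missing genotypes."""
        miss = (self.alleles[:, :, 0] == MISSING).mean(axis=0)
        return pd.Series(miss, index=self.locus_names, name="missing_fraction")

    def to_repeat_counts(self, motif_lengths: Mapping[str, int]) -> "GenotypeMatrix":
        """Convert fragment sizes to repeat counts, locus by locus.

        ``motif_lengths`` maps locus name to its repeat-motif length in bp.
        The smallest observed allele at each locus is mapped to repeat
        count 1 and the rest follow by integer motif steps; non-integer
        steps raise. Conversion is always explicit, never implicit.
        """
        out = self.alleles.copy()
        for j, name in enumerate(self.locus_names):
            motif = int(motif_lengths[name])
            col = out[:, j, :]
            obs = col[col != MISSING]
            if obs.size == 0:
                continue
            lo = obs.min()
            if np.any((obs - lo) % motif):
                raise ValueError(f"locus {name!r}: sizes not on a {motif}-bp ladder")
            col[col != MISSING] = (col[col != MISSING] - lo) // motif + 1
        return GenotypeMatrix(
            list(self.individual_ids), list(self.locus_names), out, list(self.pop_labels)
        )


@dataclass
class PopulationMeta:
    """Descriptive metadata for one population."""

    pop_id: str
    island: str
    island_group: str
    n_samples: int
    coordinates: tuple[float, float] | None = None  # (lat, lon) degrees
    island_area: float | None = None  # hectares

    def check_against(self, g: GenotypeMatrix) -> None:
        n = int(np.sum(np.asarray(g.pop_labels, dtype=object) == self.pop_id))
        if n != self.n_samples:
            raise ValueError(
                f"{self.pop_id}: metadata says {self.n_samples} samples, matrix has {n}"
            )


def read_population_meta(path: str | Path) -> list[PopulationMeta]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        coords = None
        if "lat" in df.columns and pd.notna(row.get("lat")):
            coords = (float(row["lat"]), float(row["lon"]))
        area = float(row["area"]) if "area" in df.columns and pd.notna(row.get("area")) else None
        out.append(
            PopulationMeta(
                str(row["pop_id"]), str(row["island"]), str(row["island_group"]),
                int(row["n_samples"]), coords, area,
            )
        )
    return out


def write_population_meta(meta: Sequence[PopulationMeta], path: str | Path) -> None:
    rows = []
    for m in meta:
        rows.append(
            {
                "pop_id": m.pop_id, "island": m.island, "island_group": m.island_group,
                "n_samples": m.n_samples,
                "lat": m.coordinates[0] if m.coordinates else np.nan,
                "lon": m.coordinates[1] if m.coordinates else np.nan,
                "area": m.island_area if m.island_area is not None else np.nan,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# readers / writers


def read_genotypes(path: str | Path, format: str) -> GenotypeMatrix:
    """Read a genotype file in the ``genepop`` or ``csv_wide`` dialect."""
    if format == "genepop":
        return _read_genepop(Path(path).read_text())
    if format == "csv_wide":
        return _read_csv_wide(path)
    raise ValueError(f"unknown format {format!r}")


def write_genotypes(g: GenotypeMatrix, path: str | Path, format: str) -> None:
    if format == "genepop":
        Path(path).write_text(_format_genepop(g))
    elif format == "csv_wide":
        _write_csv_wide(g, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_csv_wide(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype={"individual_id": str, "population": str})
    if "individual_id" not in df.columns or "population" not in df.columns:
        raise GenotypeParseError("csv_wide needs 'individual_id' and 'population' columns")
    allele_cols = [c for c in df.columns if c.endswith(".1") or c.endswith(".2")]
    loci: list[str] = []
    for c in allele_cols:
        base = c[:-2]
        if base not in loci:
            loci.append(base)
    for base in loci:
        for suf in (".1", ".2"):
            if base + suf not in df.columns:
                raise GenotypeParseError(f"locus {base!r} missing column {base + suf!r}")
    n = len(df)
    alleles = np.zeros((n, len(loci), 2), dtype=np.int64)
    for j, base in enumerate(loci):
        alleles[:, j, 0] = df[base + ".1"].fillna(MISSING).astype(np.int64)
        alleles[:, j, 1] = df[base + ".2"].fillna(MISSING).astype(np.int64)
    return GenotypeMatrix(
        list(df["individual_id"]), loci, alleles, list(df["population"])
    )


def _write_csv_wide(g: GenotypeMatrix, path: str | Path) -> None:
    data: dict[str, object] = {
        "individual_id": g.individual_ids,
        "population": g.pop_labels,
    }
    for j, name in enumerate(g.locus_names):
        data[f"{name}.1"] = g.alleles[:, j, 0]
        data[f"{name}.2"] = g.alleles[:, j, 1]
    pd.DataFrame(data).to_csv(path, index=False)


def _read_genepop(text: str) -> GenotypeMatrix:
    """Parse GenePop text.

    Population labels: if the id field has the form ``label|indid`` (the
    form this package writes), both are recovered exactly; otherwise the
    block's first id names the population (common GenePop practice) and
    duplicate ids are disambiguated with numeric suffixes.
    """
    lines = text.splitlines()
    if not lines:
        raise GenotypeParseError("empty GenePop file")
    body = lines[1:]  # first line is the title
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        chunk = body[i].strip()
        if chunk:
            loci.extend(s.strip() for s in chunk.split(",") if s.strip())
        i += 1
    if i == len(body):
        raise GenotypeParseError("no 'pop' separator found")
    ids: list[str] = []
    labels: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    block_label: str | None = None
    while i < len(body):
        lineno = i + 2  # 1-based, counting the title line
        line = body[i].strip()
        i += 1
        if line.lower() == "pop":
            block_label = None
            continue
        if not line:
            continue
        if "," not in line:
            raise GenotypeParseError(f"line {lineno}: missing ',' separator")
        ind_id, geno_part = line.split(",", 1)
        ind_id = ind_id.strip()
        if "|" in ind_id:
            label, ind_id = ind_id.split("|", 1)
        else:
            if block_label is None:
                block_label = ind_id or f"pop{len(set(labels)) + 1}"
            label = block_label
        block_label = block_label or label
        fields = geno_part.split()
        if len(fields) != len(loci):
            raise GenotypeParseError(
                f"line {lineno}: expected {len(loci)} genotypes, got {len(fields)}"
            )
        row = []
        for f_idx, tok in enumerate(fields):
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise GenotypeParseError(
                    f"line {lineno}, locus {loci[f_idx]!r}: bad genotype token "
                    f"{tok!r} (need 4 or 6 digits)"
                )
            half = len(tok) // 2
            row.append((int(tok[:half]), int(tok[half:])))
        ids.append(ind_id)
        labels.append(label)
        rows.append(row)
    if not rows:
        raise GenotypeParseError("no genotype rows")
    uniq_ids: list[str] = []
    seen: dict[str, int] = {}
    for k, raw in enumerate(ids):
        base = raw or f"ind{k + 1}"
        seen[base] = seen.get(base, 0) + 1
        uniq_ids.append(base if seen[base] == 1 else f"{base}_{seen[base]}")
    alleles = np.array(rows, dtype=np.int64)
    return GenotypeMatrix(uniq_ids, loci, alleles, labels)


def _format_genepop(g: GenotypeMatrix) -> str:
    obs = g.alleles[g.alleles != MISSING]
    digits = 3 if obs.size and obs.max() > 99 else 2
    if obs.size and obs.max() >= 10 ** digits:
        raise ValueError("allele states too large for GenePop 3-digit encoding")
    buf = io.StringIO()
    buf.write("island_popgen export\n")
    for name in g.locus_names:
        buf.write(name + "\n")
    current: object = object()
    for i in range(g.n_individuals):
        if g.pop_labels[i] != current:
            current = g.pop_labels[i]
            buf.write("pop\n")
        toks = [
            f"{g.alleles[i, j, 0]:0{digits}d}{g.alleles[i, j, 1]:0{digits}d}"
            for j in range(g.n_loci)
        ]
        buf.write(f"{g.pop_labels[i]}|{g.individual_ids[i]} ,  " + " ".join(toks) + "\n")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# reshaping


def merge_populations(g: GenotypeMatrix, merge_map: Mapping[str, str]) -> GenotypeMatrix:
    """Relabel populations according to ``merge_map`` (old -> new).

    Labels absent from the map are kept. Individual count is conserved.
    """
    present = set(g.pop_labels)
    unknown = set(merge_map) - present
    if unknown:
        raise KeyError(f"merge_map references unknown populations: {sorted(unknown)}")
    new_labels = [merge_map.get(p, p) for p in g.pop_labels]
    return GenotypeMatrix(
        list(g.individual_ids), list(g.locus_names), g.alleles.copy(), new_labels
    )


def subsample(
    g: GenotypeMatrix,
    per_group_cap: int,
    groups: Mapping[str, Sequence[str]] | Sequence[str],
    seed: int,
) -> GenotypeMatrix:
    """Randomly cap the number of individuals in named groups.

    ``groups`` is either a list of population labels (each its own group)
    or a mapping group-name -> list of population labels whose pooled
    membership is capped jointly. Individuals outside any group are kept.
    Deterministic under ``seed``.
    """
    if per_group_cap < 1:
        raise ValueError("per_group_cap must be >= 1")
    if not isinstance(groups, Mapping):
        groups = {p: [p] for p in groups}
    rng = np.random.default_rng(seed)
    labels = np.asarray(g.pop_labels, dtype=object)
    keep = np.ones(g.n_individuals, dtype=bool)
    for gname in sorted(groups):
        members = np.flatnonzero(np.isin(labels, list(groups[gname])))
        if members.size == 0:
            raise ValueError(f"group {gname!r} is empty")
        if members.size > per_group_cap:
            chosen = rng.choice(members, size=per_group_cap, replace=False)
            drop = np.setdiff1d(members, chosen)
            keep[drop] = False
    return g.subset(np.flatnonzero(keep))
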