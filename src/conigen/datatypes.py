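"""Core in-memory containers shared by every analysis stage.

The substrate of all statistics is a sample x locus matrix of biallelic
dosages (0/1/2 alternate-allele copies, NaN = missing) together with a
hierarchical population map (region -> population -> individual, with
coordinates) and a per-sample table of continuous environmental variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "PopulationMap", "EnvironmentTable"]

_ALLOWED = frozenset({0.0, 1.0, 2.0})


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages for a set of samples.

    Attributes
    ----------
    sample_ids : list of str
        Row labels, unique.
    locus_ids : list of str
        Column labels, unique.
    scaffold : np.ndarray of str
        Per-locus scaffold/chromosome identifier.
    position : np.ndarray of int
        Per-locus 1-based base-pair coordinate; (scaffold, position)
        pairs are unique.
    dosage : np.ndarray, shape (n_samples, n_loci), float
        Count of alternate alleles in {0, 1, 2}; missing calls are NaN.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    scaffold: np.ndarray
    position: np.ndarray
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.scaffold = np.asarray(self.scaffold, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.float64)
        n, m = self.dosage.shape
        if len(self.sample_ids) != n or len(self.locus_ids) != m:
            raise ValueError("dosage shape does not match sample/locus ids")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs")
        if len(set(self.locus_ids)) != m:
            raise ValueError("duplicate locus IDs")
        if self.scaffold.shape[0] != m or self.position.shape[0] != m:
            raise ValueError("scaffold/position length does not match loci")
        if np.any(self.position <= 0):
            raise ValueError("positions must be positive (1-based)")
        keys = list(zip(self.scaffold.tolist(), self.position.tolist()))
        if len(set(keys)) != m:
            raise ValueError("(scaffold, position) pairs must be unique")
        finite = self.dosage[~np.isnan(self.dosage)]
        if finite.size and not set(np.unique(finite)).issubset(_ALLOWED):
            raise ValueError("dosages must be in {0, 1, 2} or NaN")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def missing_fraction(self) -> float:
        """Overall proportion of missing genotype calls."""
        return float(np.isnan(self.dosage).mean()) if self.dosage.size else 0.0

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in ids], dtype=np.intp)

    def subset(self, samples=None, loci=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given sample/locus labels
        (order preserved as given) or boolean/integer index arrays."""
        rows = np.arange(self.n_samples)
        cols = np.arange(self.n_loci)
        if samples is not None:
            if len(samples) and isinstance(samples[0], str):
                rows = self.sample_index(samples)
            else:
                rows = np.asarray(samples)
                if rows.dtype == bool:
                    rows = np.flatnonzero(rows)
        if loci is not None:
            if len(loci) and isinstance(loci[0], str):
                lookup = {l: j for j, l in enumerate(self.locus_ids)}
                cols = np.array([lookup[l] for l in loci], dtype=np.intp)
            else:
                cols = np.asarray(loci)
                if cols.dtype == bool:
                    cols = np.flatnonzero(cols)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in rows],
            locus_ids=[self.locus_ids[j] for j in cols],
            scaffold=self.scaffold[cols],
            position=self.position[cols],
            dosage=self.dosage[np.ix_(rows, cols)],
        )


@dataclass
class PopulationMap:
    """Hierarchical strata: sample -> population -> region, plus coordinates.

    Backed by a DataFrame indexed by sample id with columns
    ``population``, ``region``, ``lat``, ``lon``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"population", "region"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"population map missing columns: {sorted(missing)}")
        for col in ("lat", "lon"):
            if col not in self.table.columns:
                self.table[col] = np.nan
            else:
                self.table[col] = pd.to_numeric(self.table[col], errors="coerce")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample IDs in population map")
        # every population must belong to exactly one region
        per_pop = self.table.groupby("population")["region"].nunique()
        bad = per_pop[per_pop > 1]
        if len(bad):
            raise ValueError(f"populations mapped to multiple regions: {list(bad.index)}")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    @property
    def populations(self) -> list[str]:
        return sorted(self.table["population"].unique())

    @property
    def regions(self) -> list[str]:
        return sorted(self.table["region"].unique())

    def population_of(self, sample: str) -> str:
        return self.table.loc[sample, "population"]

    def region_of_population(self, population: str) -> str:
        regions = self.table.loc[self.table["population"] == population, "region"]
        return regions.iloc[0]

    def samples_in_population(self, population: str) -> list[str]:
        return list(self.table.index[self.table["population"] == population])

    def samples_in_region(self, region: str) -> list[str]:
        return list(self.table.index[self.table["region"] == region])

    def populations_in_region(self, region: str) -> list[str]:
        return sorted(self.table.loc[self.table["region"] == region, "population"].unique())

    def coordinates(self, samples=None) -> pd.DataFrame:
        tbl = self.table if samples is None else self.table.loc[samples]
        return tbl[["lat", "lon"]]

    def check_covers(self, g: GenotypeMatrix) -> None:
        unmapped = [s for s in g.sample_ids if s not in self.table.index]
        if unmapped:
            raise ValueError(f"samples absent from population map: {unmapped[:5]}")

    def subset(self, samples) -> "PopulationMap":
        return PopulationMap(self.table.loc[list(samples)].copy())


@dataclass
class EnvironmentTable:
    """Per-sample continuous environmental variables (climate + topography).

    The default set of five dimensions follows common practice for tropical
    savanna species-distribution work: annual rainfall (mm), maximum
    temperature of the hottest month (degC), minimum temperature of the
    coldest month (degC), elevation (m) and a terrain ruggedness index.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample IDs in environment table")
        values = self.table.to_numpy(dtype=float)
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("environment table contains missing/non-finite values")

    @property
    def variables(self) -> list[str]:
        return list(self.table.columns)

    def values_for(self, samples) -> np.ndarray:
        return self.table.loc[list(samples)].to_numpy(dtype=float)
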