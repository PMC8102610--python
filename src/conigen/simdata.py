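"""Synthetic genotype, population-map and environment generator.

Generates datasets with the hierarchical allele-frequency structure the
downstream analyses assume: a two-level Balding-Nichols model in which
region frequencies drift from a shared ancestral frequency and population
frequencies drift from their region frequency.  Genotypes are drawn under
Hardy-Weinberg equilibrium within populations, missing calls are dropped
completely at random, and parent-offspring pairs can be planted by
Mendelian transmission.  Environmental vectors are region-specific
Gaussians and coordinates scatter around per-population centroids.

The generator deliberately contains no migration or coalescent machinery:
every statistic consumed downstream depends on allele-frequency structure
only, which the Beta (Balding-Nichols) hierarchy controls directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import EnvironmentTable, GenotypeMatrix, PopulationMap

__all__ = ["SimulationConfig", "simulate_dataset", "expected_fst"]

# Default environmental niches: two regions ("mainland" vs "islands")
# separated by far more than 6 pooled SD in the rainfall dimension, so the
# regions occupy disjoint niches, as in strongly contrasted coastal systems.
_ENV_VARS = ["rainfall_mm", "tmax_hot_c", "tmin_cold_c", "elevation_m", "ruggedness"]
_ENV_MEANS = {
    0: np.array([1300.0, 34.0, 19.0, 120.0, 30.0]),
    1: np.array([1900.0, 32.0, 17.0, 40.0, 10.0]),
}
_ENV_SD = {
    0: np.array([60.0, 0.5, 0.6, 40.0, 8.0]),
    1: np.array([50.0, 0.4, 0.5, 15.0, 4.0]),
}
# Population centroids (lat, lon): two widely separated mainland sites
# (~800 km apart) and two adjacent island sites.
_GEO = {
    0: [(-11.33, 132.50), (-14.80, 125.80)],
    1: [(-11.63, 130.25), (-11.55, 131.00)],
}

_KM_PER_DEG = 111.19  # great-circle km per degree of latitude


@dataclass
class SimulationConfig:
    """Parameters of the hierarchical Balding-Nichols generator.

    ``f_region`` and ``f_pop`` are drift (divergence) coefficients in
    [0, 1): the expected pairwise differentiation is ``f_pop`` within a
    region and ``1 - (1 - f_region)(1 - f_pop)`` between regions.  Defaults
    emulate a drift-dominated two-lineage system: strong between-lineage
    divergence (expected F_ST ~ 0.6) and moderate within-lineage divergence
    (~0.2), ~2% missing data and ~10^4 unlinked loci.
    """

    n_regions: int = 2
    pops_per_region: tuple[int, ...] = (2, 2)
    n_per_pop: tuple[int, ...] = (15, 10, 6, 11)
    n_loci: int = 10_000
    f_region: float = 0.5
    f_pop: float = 0.2
    ancestral_maf_range: tuple[float, float] = (0.1, 0.5)
    missing_rate: float = 0.02
    n_kin_pairs: int = 0
    n_duplicate_loci: int = 0
    env_means: dict | None = None
    env_sd: dict | None = None
    geo_layout: dict | None = None
    scatter_km: float = 2.0
    loci_per_scaffold: int = 500
    locus_spacing_bp: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1 or len(self.pops_per_region) != self.n_regions:
            raise ValueError("pops_per_region must list one count per region")
        if sum(self.pops_per_region) != len(self.n_per_pop):
            raise ValueError("n_per_pop must list one count per population")
        if any(n < 1 for n in self.n_per_pop) or self.n_loci < 1:
            raise ValueError("counts must be positive")
        for name, val in (("f_region", self.f_region), ("f_pop", self.f_pop)):
            if not 0.0 <= val < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("ancestral_maf_range must lie in (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_kin_pairs < 0 or self.n_duplicate_loci < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_pops(self) -> int:
        return int(sum(self.pops_per_region))

    def region_of_pop(self) -> np.ndarray:
        """Region index of each population, in population order."""
        out = []
        for r, k in enumerate(self.pops_per_region):
            out.extend([r] * k)
        return np.array(out)


def expected_fst(f_region: float, f_pop: float) -> tuple[float, float]:
    """Model-expected pairwise differentiation (between-region, within-region).

    Drift compounds multiplicatively in (1 - F): two populations in
    different regions have total divergence ``1 - (1-f_region)(1-f_pop)``;
    two populations in the same region share the region frequency and
    diverge only by ``f_pop``.
    """
    for val in (f_region, f_pop):
        if not 0.0 <= val < 1.0:
            raise ValueError("divergence parameters must be in [0, 1)")
    between = 1.0 - (1.0 - f_region) * (1.0 - f_pop)
    return between, f_pop


def _drift(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Balding-Nichols Beta drift of allele frequencies ``p`` with coefficient
    ``f``; the f = 0 limit is no drift (frequencies copied exactly)."""
    if f == 0.0:
        return p.copy()
    scale = (1.0 - f) / f
    out = rng.beta(p * scale, (1.0 - p) * scale)
    # Beta samples can underflow to exactly 0/1; harmless for binomial draws
    return out


def _mendelian_offspring(rng: np.random.Generator, d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """Offspring dosage from two parental dosage vectors: each parent
    transmits an alternate allele with probability dosage/2."""
    a1 = rng.random(d1.shape) < d1 / 2.0
    a2 = rng.random(d2.shape) < d2 / 2.0
    return (a1.astype(float) + a2.astype(float))


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, PopulationMap, EnvironmentTable]:
    """Draw one complete synthetic dataset.

    Returns the genotype matrix, the population map (with coordinates) and
    the environment table.  Identical config (including seed) gives a
    bit-identical dataset.  Planted kin pairs are recorded on the returned
    map as ``map.kin_pairs`` -> list of (offspring, parent1, parent2).
    """
    rng = np.random.default_rng(config.seed)
    L = config.n_loci
    region_of_pop = config.region_of_pop()

    # ancestral frequencies, folded to the minor-allele range
    lo, hi = config.ancestral_maf_range
    p0 = rng.uniform(lo, hi, size=L)

    # region then population frequencies under the Beta hierarchy
    p_region = np.stack([_drift(rng, p0, config.f_region) for _ in range(config.n_regions)])
    p_pop = np.stack([_drift(rng, p_region[region_of_pop[k]], config.f_pop)
                      for k in range(config.n_pops)])

    # genotypes: Binomial(2, p) per individual under HWE
    sample_ids: list[str] = []
    pop_labels: list[str] = []
    region_labels: list[str] = []
    blocks = []
    pop_names = []
    for k in range(config.n_pops):
        r = region_of_pop[k]
        pop = f"pop{k + 1}"
        pop_names.append(pop)
        n = config.n_per_pop[k]
        blocks.append(rng.binomial(2, p_pop[k], size=(n, L)).astype(float))
        for i in range(n):
            sample_ids.append(f"{pop}_ind{i + 1}")
            pop_labels.append(pop)
            region_labels.append(f"region{r + 1}")
    dosage = np.vstack(blocks)

    # planted parent-offspring pairs: replace one individual with an
    # offspring of two others in the same population (needs n >= 3)
    kin_pairs: list[tuple[str, str, str]] = []
    eligible = [k for k in range(config.n_pops) if config.n_per_pop[k] >= 3]
    if config.n_kin_pairs and not eligible:
        raise ValueError("kin planting requires a population with >= 3 individuals")
    offsets = np.concatenate([[0], np.cumsum(config.n_per_pop)])
    used: dict[int, set[int]] = {k: set() for k in range(config.n_pops)}
    for j in range(config.n_kin_pairs):
        k = eligible[j % len(eligible)]
        free = [i for i in range(config.n_per_pop[k]) if i not in used[k]]
        if len(free) < 3:
            raise ValueError("not enough unused individuals to plant kin pair")
        child, par1, par2 = free[0], free[1], free[2]
        used[k].update((child, par1, par2))
        base = offsets[k]
        dosage[base + child] = _mendelian_offspring(rng, dosage[base + par1], dosage[base + par2])
        kin_pairs.append(
            (sample_ids[base + child], sample_ids[base + par1], sample_ids[base + par2])
        )

    # optional fully correlated locus pairs for LD-pruning tests: each
    # planted pair copies a locus onto its immediate neighbour
    dup_pairs: list[tuple[int, int]] = []
    if config.n_duplicate_loci:
        if config.n_duplicate_loci * 2 > L:
            raise ValueError("too many duplicate loci requested")
        for d in range(config.n_duplicate_loci):
            j = 2 * d
            dosage[:, j + 1] = dosage[:, j]
            dup_pairs.append((j, j + 1))

    # missing completely at random
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    # locus coordinates: evenly spaced along synthetic scaffolds
    scaffold = np.array(
        [f"scaffold{j // config.loci_per_scaffold + 1}" for j in range(L)], dtype=object
    )
    position = np.array(
        [(j % config.loci_per_scaffold) * config.locus_spacing_bp + 1 for j in range(L)],
        dtype=np.int64,
    )
    locus_ids = [f"{scaffold[j]}:{position[j]}" for j in range(L)]

    g = GenotypeMatrix(sample_ids, locus_ids, scaffold, position, dosage)

    # coordinates around per-population centroids
    geo = config.geo_layout or {
        r: list(_GEO.get(r, [(-12.0 - r, 130.0 + 2 * i) for i in range(k)]))
        for r, k in enumerate(config.pops_per_region)
    }
    lat = np.empty(len(sample_ids))
    lon = np.empty(len(sample_ids))
    for k in range(config.n_pops):
        r = region_of_pop[k]
        idx_in_region = k - int(np.sum(np.array(config.pops_per_region)[:r]))
        clat, clon = geo[r][idx_in_region % len(geo[r])]
        base = offsets[k]
        n = config.n_per_pop[k]
        dlat = rng.normal(0.0, config.scatter_km / _KM_PER_DEG, size=n)
        dlon = rng.normal(
            0.0, config.scatter_km / (_KM_PER_DEG * np.cos(np.radians(clat))), size=n
        )
        lat[base:base + n] = clat + dlat
        lon[base:base + n] = clon + dlon

    popmap = PopulationMap(
        pd.DataFrame(
            {"population": pop_labels, "region": region_labels, "lat": lat, "lon": lon},
            index=pd.Index(sample_ids, name="sample"),
        )
    )
    popmap.kin_pairs = kin_pairs
    popmap.duplicate_locus_pairs = dup_pairs

    # environmental vectors: region-specific Gaussians
    means = config.env_means or _ENV_MEANS
    sds = config.env_sd or _ENV_SD
    env = np.empty((len(sample_ids), len(_ENV_VARS)))
    for k in range(config.n_pops):
        r = region_of_pop[k]
        mu = np.asarray(means.get(r, _ENV_MEANS[r % 2]), dtype=float)
        sd = np.asarray(sds.get(r, _ENV_SD[r % 2]), dtype=float)
        base = offsets[k]
        n = config.n_per_pop[k]
        env[base:base + n] = rng.normal(mu, sd, size=(n, len(_ENV_VARS)))
    envtable = EnvironmentTable(
        pd.DataFrame(env, columns=_ENV_VARS, index=pd.Index(sample_ids, name="sample"))
    )
    return g, popmap, envtable
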