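"""Multilocus spatial autocorrelation (Smouse-Peakall correlogram).

Squared individual genetic distances are double-centred into a covariance
matrix C; for each geographic distance class the autocorrelation
coefficient is the ratio of the summed between-individual covariances of
pairs in the class to the summed self-covariances of the individuals
involved.  The null envelope comes from permuting whole genotypes across
geographic locations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, PopulationMap
from .popstats import prevosti_distance_matrix

__all__ = ["Correlogram", "geo_distances", "autocorrelation", "DEFAULT_CLASS_EDGES"]

EARTH_RADIUS_KM = 6371.0

# log-spaced edges chosen to resolve both fine-scale (<5 km) decay and
# long-range (>100 km) persistence of autocorrelation
DEFAULT_CLASS_EDGES = (0.0, 1.0, 5.0, 10.0, 50.0, 100.0, 500.0, 1000.0)


def geo_distances(popmap: PopulationMap, samples=None) -> pd.DataFrame:
    """Pairwise great-circle (haversine) distances in km.

    Individuals with missing coordinates are excluded (listed on the
    result frame's ``attrs['excluded']``).
    """
    coords = popmap.coordinates(samples)
    ok = coords.notna().all(axis=1)
    excluded = list(coords.index[~ok])
    coords = coords[ok]
    lat = np.radians(coords["lat"].to_numpy())
    lon = np.radians(coords["lon"].to_numpy())
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    out = pd.DataFrame(d, index=coords.index, columns=coords.index)
    out.attrs["excluded"] = excluded
    return out


@dataclass
class Correlogram:
    table: pd.DataFrame  # class_low, class_high, n_pairs, r, env_low, env_high, p_value
    n_permutations: int
    class_edges: tuple


def _center(d2: np.ndarray) -> np.ndarray:
    """Double-centre a squared-distance matrix into covariance form."""
    row = d2.mean(axis=1, keepdims=True)
    col = d2.mean(axis=0, keepdims=True)
    grand = d2.mean()
    return -0.5 * (d2 - row - col + grand)


def _class_r(C: np.ndarray, pair_mask: np.ndarray) -> float:
    """r for one distance class: sum of c_ij over unordered pairs in the
    class over sum of c_ii of the individuals those pairs involve."""
    iu = np.triu_indices_from(C, k=1)
    in_class = pair_mask[iu]
    if not in_class.any():
        return np.nan
    num = C[iu][in_class].sum()
    members = np.zeros(C.shape[0], dtype=bool)
    members[iu[0][in_class]] = True
    members[iu[1][in_class]] = True
    den = C[np.diag_indices_from(C)][members].sum()
    return float(num / den) if den != 0.0 else np.nan


def autocorrelation(
    g: GenotypeMatrix,
    popmap: PopulationMap,
    class_edges=DEFAULT_CLASS_EDGES,
    n_perm: int = 999,
    region: str | None = None,
    seed: int | None = None,
) -> Correlogram:
    """Smouse-Peakall multilocus autocorrelation correlogram.

    ``region`` restricts the analysis to individuals of one region (e.g.
    the mainland subset).  Genetic distances are Prevosti distances,
    squared before double-centering.  The permutation null shuffles
    genotype identities across the fixed geographic locations.
    """
    edges = tuple(class_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("class edges must be strictly increasing")
    samples = list(g.sample_ids)
    if region is not None:
        keep = set(popmap.samples_in_region(region))
        samples = [s for s in samples if s in keep]
    geo = geo_distances(popmap, samples)
    samples = [s for s in samples if s in geo.index]
    if len(samples) < 2:
        raise ValueError("need >= 2 individuals with genotypes and coordinates")
    sub = g.subset(samples=samples)
    gd = prevosti_distance_matrix(sub).to_numpy()
    C = _center(gd * gd)
    geo_m = geo.loc[samples, samples].to_numpy()

    masks = []
    for lo, hi in zip(edges, edges[1:]):
        masks.append((geo_m >= lo) & (geo_m < hi))
    r_obs = np.array([_class_r(C, m) for m in masks])

    rng = np.random.default_rng(seed)
    null = np.full((n_perm, len(masks)), np.nan)
    n = len(samples)
    for b in range(n_perm):
        perm = rng.permutation(n)
        Cp = C[np.ix_(perm, perm)]
        null[b] = [_class_r(Cp, m) for m in masks]

    rows = []
    for k, (lo, hi) in enumerate(zip(edges, edges[1:])):
        iu = np.triu_indices(n, k=1)
        n_pairs = int(masks[k][iu].sum())
        obs = r_obs[k]
        col = null[:, k]
        col = col[np.isfinite(col)]
        if n_perm > 0 and col.size and np.isfinite(obs):
            env_lo, env_hi = np.percentile(col, [2.5, 97.5])
            p = (1.0 + np.sum(np.abs(col) >= abs(obs))) / (col.size + 1.0)
        else:
            env_lo = env_hi = p = np.nan
        rows.append(
            {"class_low": lo, "class_high": hi, "n_pairs": n_pairs, "r": obs,
             "env_low": env_lo, "env_high": env_hi, "p_value": p}
        )
    return Correlogram(pd.DataFrame(rows), n_perm, edges)
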