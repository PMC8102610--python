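"""Per-population diversity, pairwise differentiation, kinship and PCoA.

Differentiation follows the Nei (1987) gene-diversity framework with the
Nei & Chesser (1983) small-sample corrections of H_S and H_T, aggregated
across loci as a ratio of sums, plus Meirmans & Hedrick's standardised
G''_ST on the same components.  Significance is assessed by permuting
individuals between the population pair.

The kinship screen uses a dosage allele-sharing estimator (Weir-Goudet
style): pairwise allele matching centred by the mean matching among all
within-population pairs, which puts unrelated pairs near zero and a
parent-offspring pair near the pedigree kinship of 0.25.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, PopulationMap

__all__ = [
    "DiversityTable",
    "DifferentiationMatrices",
    "KinshipResult",
    "Ordination",
    "diversity_table",
    "pairwise_fst",
    "kinship_screen",
    "pcoa",
    "nei_distance_matrix",
    "prevosti_distance_matrix",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# diversity table

@dataclass
class DiversityTable:
    """Per-population means of standard diversity parameters."""

    table: pd.DataFrame  # index: population; columns A, A_E, H_O, H_E, F_IS, P_E, n
    excluded: list[str] = field(default_factory=list)


def diversity_table(
    g: GenotypeMatrix, popmap: PopulationMap, min_n: int = 6
) -> DiversityTable:
    """Population means of A, A_E, H_O, H_E (small-sample corrected), F_IS
    and P_E over loci with at least one genotyped individual.

    F_IS is the mean of per-locus ``1 - H_O/H_E`` over polymorphic loci
    (H_E > 0); monomorphic loci contribute to the other columns but are
    excluded from the F_IS mean.  Populations with fewer than ``min_n``
    samples are excluded (listed on the result).
    """
    popmap.check_covers(g)
    rows, excluded = {}, []
    for pop in popmap.populations:
        samples = popmap.samples_in_population(pop)
        if len(samples) < min_n:
            excluded.append(pop)
            log.info("population %s excluded from diversity table (n=%d < %d)",
                     pop, len(samples), min_n)
            continue
        sub = g.dosage[g.sample_index(samples), :]
        called = ~np.isnan(sub)
        n = called.sum(axis=0).astype(float)
        ok = n > 0
        alt = np.nansum(sub, axis=0)[ok]
        n = n[ok]
        p = alt / (2.0 * n)
        q = 1.0 - p
        a = np.where((p > 0) & (p < 1), 2.0, 1.0)
        a_e = 1.0 / (p * p + q * q)
        h_o = (sub == 1).sum(axis=0)[ok] / n
        p_e = 2.0 * p * q
        h_e = (2.0 * n / (2.0 * n - 1.0)) * p_e
        poly = h_e > 0
        fis = 1.0 - h_o[poly] / h_e[poly]
        rows[pop] = {
            "A": a.mean(),
            "A_E": a_e.mean(),
            "H_O": h_o.mean(),
            "H_E": h_e.mean(),
            "F_IS": fis.mean() if poly.any() else np.nan,
            "P_E": p_e.mean(),
            "n": len(samples),
        }
    return DiversityTable(pd.DataFrame(rows).T, excluded)


# ---------------------------------------------------------------------------
# pairwise differentiation

@dataclass
class DifferentiationMatrices:
    fst: pd.DataFrame
    gst_hedrick: pd.DataFrame
    p_value: pd.DataFrame
    n_per_pop: pd.Series
    n_permutations: int = 0


def _pair_components(d1: np.ndarray, d2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus Nei-Chesser corrected (H_S, H_T) for a pair of populations.

    Loci without at least one genotyped individual in each population (and
    harmonic mean sample size > 1) come back NaN.
    """
    out_hs = np.full(d1.shape[1], np.nan)
    out_ht = np.full(d1.shape[1], np.nan)
    c1, c2 = ~np.isnan(d1), ~np.isnan(d2)
    n1, n2 = c1.sum(axis=0).astype(float), c2.sum(axis=0).astype(float)
    ok = (n1 > 0) & (n2 > 0)
    nh = 2.0 / (1.0 / np.maximum(n1, 1) + 1.0 / np.maximum(n2, 1))
    ok &= nh > 1.0
    if not ok.any():
        return out_hs, out_ht
    p1 = np.nansum(d1, axis=0)[ok] / (2.0 * n1[ok])
    p2 = np.nansum(d2, axis=0)[ok] / (2.0 * n2[ok])
    ho1 = (d1 == 1).sum(axis=0)[ok] / n1[ok]
    ho2 = (d2 == 1).sum(axis=0)[ok] / n2[ok]
    ho = (ho1 + ho2) / 2.0
    nh = nh[ok]
    sum_p2 = ((p1 * p1 + (1 - p1) ** 2) + (p2 * p2 + (1 - p2) ** 2)) / 2.0
    hs = nh / (nh - 1.0) * (1.0 - sum_p2 - ho / (2.0 * nh))
    pbar = (p1 + p2) / 2.0
    ht = 1.0 - (pbar * pbar + (1 - pbar) ** 2) + hs / (2.0 * nh) - ho / (4.0 * nh)
    out_hs[ok] = hs
    out_ht[ok] = ht
    return out_hs, out_ht


def _fst_gst_from_components(hs: np.ndarray, ht: np.ndarray) -> tuple[float, float]:
    """Multi-locus F_ST and G''_ST from per-locus corrected components.

    Components are aggregated as ratios of sums (per-locus ratios are
    unstable at low H_T).  The among-population component is scaled by the
    deme-number correction k/(k-1) (k=2 demes): D'_ST = k/(k-1) (H_T-H_S),
    H'_T = H_S + D'_ST, F_ST = D'_ST / H'_T — the form that both reaches 1
    at fixed differences and is unbiased for the drift coefficient of a
    Balding-Nichols pair.  G''_ST is Meirmans & Hedrick's standardisation
    on the same components.
    """
    ok = ~np.isnan(hs) & ~np.isnan(ht)
    if not ok.any():
        return np.nan, np.nan
    HS, HT = float(np.mean(hs[ok])), float(np.mean(ht[ok]))
    k = 2.0
    dst_p = k / (k - 1.0) * (HT - HS)
    ht_p = HS + dst_p
    if ht_p == 0.0:
        return np.nan, np.nan
    fst = dst_p / ht_p
    denom = (k * ht_p - HS) * (1.0 - HS)
    gst = k * (ht_p - HS) / denom if denom != 0.0 else np.nan
    return fst, gst


def pairwise_fst(
    g: GenotypeMatrix,
    popmap: PopulationMap,
    n_perm: int = 1000,
    seed: int | None = None,
    min_n: int = 2,
) -> DifferentiationMatrices:
    """Pairwise Nei F_ST and Hedrick G''_ST with permutation p-values.

    p-values are one-sided (observed >= permuted) with the +1 correction,
    from ``n_perm`` random reassignments of individuals between the pair;
    pairs involving a population below ``min_n`` samples are undefined.
    """
    popmap.check_covers(g)
    rng = np.random.default_rng(seed)
    pops = popmap.populations
    K = len(pops)
    if K < 2:
        raise ValueError("pairwise differentiation needs >= 2 populations")
    fst = pd.DataFrame(np.zeros((K, K)), index=pops, columns=pops)
    gst = fst.copy()
    pval = pd.DataFrame(np.full((K, K), np.nan), index=pops, columns=pops)
    sizes = pd.Series({p: len(popmap.samples_in_population(p)) for p in pops})
    members = {p: g.sample_index([s for s in popmap.samples_in_population(p)
                                  if s in set(g.sample_ids)]) for p in pops}
    for pa, pb in itertools.combinations(pops, 2):
        ia, ib = members[pa], members[pb]
        if len(ia) < min_n or len(ib) < min_n:
            fst.loc[pa, pb] = fst.loc[pb, pa] = np.nan
            gst.loc[pa, pb] = gst.loc[pb, pa] = np.nan
            continue
        da, db = g.dosage[ia], g.dosage[ib]
        hs, ht = _pair_components(da, db)
        f, gg = _fst_gst_from_components(hs, ht)
        fst.loc[pa, pb] = fst.loc[pb, pa] = f
        gst.loc[pa, pb] = gst.loc[pb, pa] = gg
        if n_perm > 0 and np.isfinite(f):
            both = np.vstack([da, db])
            na = len(ia)
            exceed = 0
            for _ in range(n_perm):
                perm = rng.permutation(both.shape[0])
                hs_p, ht_p = _pair_components(both[perm[:na]], both[perm[na:]])
                f_p, _ = _fst_gst_from_components(hs_p, ht_p)
                if np.isfinite(f_p) and f_p >= f:
                    exceed += 1
            p = (1.0 + exceed) / (n_perm + 1.0)
            pval.loc[pa, pb] = pval.loc[pb, pa] = p
    return DifferentiationMatrices(fst, gst, pval, sizes, n_perm)


# ---------------------------------------------------------------------------
# kinship screen

@dataclass
class KinshipResult:
    pairs: pd.DataFrame  # sample_a, sample_b, population, kinship, flagged
    threshold: float = 0.125
    pruned_samples: list[str] = field(default_factory=list)

    @property
    def flagged_pairs(self) -> pd.DataFrame:
        return self.pairs[self.pairs["flagged"]]


def _allele_matching(da: np.ndarray, db: np.ndarray) -> float:
    """Mean per-locus allele matching of two dosage vectors over shared
    loci: (x_a x_b + (2-x_a)(2-x_b)) / 4."""
    ok = ~np.isnan(da) & ~np.isnan(db)
    if not ok.any():
        return np.nan
    xa, xb = da[ok], db[ok]
    return float(np.mean((xa * xb + (2 - xa) * (2 - xb)) / 4.0))


def kinship_screen(
    g: GenotypeMatrix,
    popmap: PopulationMap,
    threshold: float = 0.125,
) -> KinshipResult:
    """Dosage allele-sharing kinship for every within-population pair.

    For pair (j, k): beta = (M_jk - M0) / (1 - M0), where M is the mean
    allele matching and M0 the average matching over all within-population
    pairs of that population.  Pairs above ``threshold`` are flagged; a
    greedy pruned-sample list removes the higher-missingness member of
    each flagged pair.
    """
    popmap.check_covers(g)
    rows = []
    pruned: list[str] = []
    missing = dict(zip(g.sample_ids, np.isnan(g.dosage).mean(axis=1)))
    for pop in popmap.populations:
        samples = [s for s in popmap.samples_in_population(pop) if s in set(g.sample_ids)]
        if len(samples) < 2:
            continue
        idx = g.sample_index(samples)
        M = {}
        for a, b in itertools.combinations(range(len(samples)), 2):
            M[(a, b)] = _allele_matching(g.dosage[idx[a]], g.dosage[idx[b]])
        m0 = float(np.nanmean(list(M.values())))
        for (a, b), m in M.items():
            beta = (m - m0) / (1.0 - m0) if m0 < 1.0 else np.nan
            rows.append(
                {
                    "sample_a": samples[a],
                    "sample_b": samples[b],
                    "population": pop,
                    "kinship": beta,
                    "flagged": bool(np.isfinite(beta) and beta > threshold),
                }
            )
    pairs = pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "population", "kinship", "flagged"]
    )
    # greedy pruning: for each flagged pair with both members still present,
    # drop the member with more missing data (ties: sample_b)
    present = set(g.sample_ids)
    for _, row in pairs[pairs["flagged"]].iterrows():
        a, b = row["sample_a"], row["sample_b"]
        if a in present and b in present:
            victim = a if missing[a] > missing[b] else b
            present.discard(victim)
            pruned.append(victim)
    return KinshipResult(pairs, threshold, pruned)


# ---------------------------------------------------------------------------
# distances + principal coordinates

def nei_distance_matrix(freq: pd.DataFrame) -> pd.DataFrame:
    """Nei (1972) standard genetic distance between populations from a
    populations x loci alternate-allele frequency table:
    D = -ln(J_xy / sqrt(J_x J_y)) with J the mean over loci of the sum of
    squared (or cross-multiplied) allele frequencies."""
    pops = list(freq.index)
    P = freq.to_numpy(dtype=float)
    D = np.zeros((len(pops), len(pops)))
    for a, b in itertools.combinations(range(len(pops)), 2):
        pa, pb = P[a], P[b]
        ok = np.isfinite(pa) & np.isfinite(pb)
        if not ok.any():
            D[a, b] = D[b, a] = np.nan
            continue
        xa, xb = pa[ok], pb[ok]
        jx = np.mean(xa * xa + (1 - xa) ** 2)
        jy = np.mean(xb * xb + (1 - xb) ** 2)
        jxy = np.mean(xa * xb + (1 - xa) * (1 - xb))
        D[a, b] = D[b, a] = -np.log(jxy / np.sqrt(jx * jy))
    return pd.DataFrame(D, index=pops, columns=pops)


def prevosti_distance_matrix(g: GenotypeMatrix) -> pd.DataFrame:
    """Prevosti distance between individuals: mean per-locus absolute
    dosage difference / 2 over pairwise-complete loci."""
    n = g.n_samples
    D = np.zeros((n, n))
    X = g.dosage
    for a in range(n):
        diff = np.abs(X[a] - X[a + 1:]) / 2.0  # NaN where either missing
        D[a, a + 1:] = np.nanmean(diff, axis=1) if diff.size else 0.0
    D = D + D.T
    return pd.DataFrame(D, index=g.sample_ids, columns=g.sample_ids)


@dataclass
class Ordination:
    coordinates: pd.DataFrame
    percent_variance: np.ndarray
    level: str = "population"
    distance: str = "nei_population"
    degenerate: bool = False
    n_negative_eigenvalues: int = 0


def pcoa(distances: pd.DataFrame, level: str = "population",
         distance_name: str | None = None) -> Ordination:
    """Classical metric multidimensional scaling of a square symmetric
    distance matrix (double-centering + eigendecomposition).

    Axes are ordered by decreasing eigenvalue; percent variance is each
    positive eigenvalue over the sum of positive eigenvalues.  Negative
    eigenvalues are logged and excluded from the denominator.
    """
    D = distances.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, equal_nan=True):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    D2 = D * D
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-9 * max(abs(evals[0]), 1.0))
    n_neg = int((evals < -tol).sum())
    if n_neg:
        log.info("pcoa: %d negative eigenvalues excluded from variance", n_neg)
    pos = evals > tol
    if not pos.any():
        coords = pd.DataFrame(
            np.zeros((n, 1)), index=distances.index, columns=["PCo1"]
        )
        return Ordination(coords, np.array([0.0]), level,
                          distance_name or "", degenerate=True,
                          n_negative_eigenvalues=n_neg)
    lam = evals[pos]
    coords = evecs[:, pos] * np.sqrt(lam)
    pct = 100.0 * lam / lam.sum()
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return Ordination(
        pd.DataFrame(coords, index=distances.index, columns=cols),
        pct, level, distance_name or "", degenerate=False,
        n_negative_eigenvalues=n_neg,
    )
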