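"""Rarefied allelic richness and maximum-coverage conservation planning.

Allelic richness per locus is standardised to a fixed number of gene
copies g by hypergeometric rarefaction: AR = sum_a [1 - C(N-N_a, g)/C(N, g)],
the expected number of distinct alleles in a random subsample of g copies.
Leave-one-out contributions measure the proportional loss of pooled
rarefied richness if one population group were lost.

The reserve-selection analysis repeatedly subsamples a fixed number of
individuals per group, builds an allele-presence matrix, and solves the
maximum-coverage problem (choose b groups covering the most alleles)
exactly by subset enumeration, with unit cost per group.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import GenotypeMatrix, PopulationMap

log = logging.getLogger(__name__)

__all__ = [
    "RichnessResult",
    "PrioritizationResult",
    "rarefied_locus_ar",
    "rarefied_ar",
    "loo_contributions",
    "max_coverage",
    "group_assignment",
]


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def rarefied_locus_ar(counts: np.ndarray, g: int) -> np.ndarray:
    """Rarefied allele count per locus from a (loci x alleles) count array.

    For a locus with allele counts N_a summing to N >= g, the expected
    number of distinct alleles among g copies drawn without replacement is
    sum_a [1 - C(N - N_a, g) / C(N, g)].  Rows with N < g return NaN.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[None, :]
    N = counts.sum(axis=1)
    out = np.full(counts.shape[0], np.nan)
    ok = N >= g
    if not ok.any():
        return out
    Nk, ck = N[ok], counts[ok]
    terms = np.zeros(ck.shape)
    rem = Nk[:, None] - ck
    can = rem >= g  # C(N - N_a, g) is zero when N - N_a < g
    ratio = np.zeros(ck.shape)
    ratio[can] = np.exp(
        _log_comb(rem[can], g) - _log_comb(np.broadcast_to(Nk[:, None], ck.shape)[can], g)
    )
    present = ck > 0
    terms[present] = 1.0 - ratio[present]
    out[ok] = terms.sum(axis=1)
    return out


def group_assignment(popmap: PopulationMap, merge: dict | None = None) -> dict:
    """Map population -> group label; ``merge`` renames/combines
    populations into a priori groups (e.g. pooling two sparsely sampled
    neighbouring populations)."""
    merge = merge or {}
    return {p: merge.get(p, p) for p in popmap.populations}


def _group_counts(
    g: GenotypeMatrix, popmap: PopulationMap, groups: dict
) -> tuple[list[str], np.ndarray]:
    """Biallelic allele counts per group: array (groups, loci, 2) of
    (ref copies, alt copies) among genotyped calls."""
    labels = sorted(set(groups.values()))
    counts = np.zeros((len(labels), g.n_loci, 2))
    sample_set = set(g.sample_ids)
    for gi, lab in enumerate(labels):
        samples = [
            s
            for p, grp in groups.items()
            if grp == lab
            for s in popmap.samples_in_population(p)
            if s in sample_set
        ]
        sub = g.dosage[g.sample_index(samples)]
        called = ~np.isnan(sub)
        alt = np.nansum(sub, axis=0)
        tot = 2.0 * called.sum(axis=0)
        counts[gi, :, 0] = tot - alt
        counts[gi, :, 1] = alt
    return labels, counts


@dataclass
class RichnessResult:
    per_group: pd.DataFrame  # mean AR, sd, n_loci per group
    total_ar: float
    contributions: pd.DataFrame | None = None  # AR(-i), C_i per group
    g_copies: int = 8
    loci_used: int = 0


def _included_loci(counts: np.ndarray, g_copies: int) -> np.ndarray:
    """Listwise locus inclusion: every group must have >= g_copies
    genotyped gene copies at the locus."""
    return (counts.sum(axis=2) >= g_copies).all(axis=0)


def rarefied_ar(
    g: GenotypeMatrix,
    popmap: PopulationMap,
    g_copies: int = 8,
    merge: dict | None = None,
) -> RichnessResult:
    """Mean rarefied allelic richness per locus for each group and for the
    pooled dataset, standardised to ``g_copies`` gene copies."""
    groups = group_assignment(popmap, merge)
    labels, counts = _group_counts(g, popmap, groups)
    ok = _included_loci(counts, g_copies)
    if not ok.any():
        bad = [
            labels[i]
            for i in range(len(labels))
            if not (counts[i].sum(axis=1) >= g_copies).any()
        ]
        raise ValueError(
            f"no loci with >= {g_copies} gene copies in every group"
            + (f"; groups below threshold everywhere: {bad}" if bad else "")
        )
    counts = counts[:, ok, :]
    rows = {}
    for i, lab in enumerate(labels):
        ar = rarefied_locus_ar(counts[i], g_copies)
        rows[lab] = {"mean_AR": np.nanmean(ar), "sd_AR": np.nanstd(ar, ddof=1),
                     "n_loci": int(np.isfinite(ar).sum())}
    pooled = counts.sum(axis=0)
    total = float(np.nanmean(rarefied_locus_ar(pooled, g_copies)))
    return RichnessResult(pd.DataFrame(rows).T, total, None, g_copies, int(ok.sum()))


def loo_contributions(
    g: GenotypeMatrix,
    popmap: PopulationMap,
    g_copies: int = 8,
    merge: dict | None = None,
) -> RichnessResult:
    """Leave-one-out contribution of each group to pooled rarefied AR:
    C_i = (AR(t) - AR(-i)) / (AR(t) - 1).  Negative values are allowed: a
    depauperate group can lower the pooled richness."""
    res = rarefied_ar(g, popmap, g_copies, merge)
    groups = group_assignment(popmap, merge)
    labels, counts = _group_counts(g, popmap, groups)
    ok = _included_loci(counts, g_copies)
    counts = counts[:, ok, :]
    if len(labels) < 2:
        raise ValueError("leave-one-out contributions need >= 2 groups")
    if res.total_ar <= 1.0:
        raise ValueError("total rarefied AR is 1 (all loci monomorphic): "
                         "contributions undefined")
    rows = {}
    for i, lab in enumerate(labels):
        rest = counts[[j for j in range(len(labels)) if j != i]].sum(axis=0)
        ar_minus = float(np.nanmean(rarefied_locus_ar(rest, g_copies)))
        rows[lab] = {
            "AR_minus_i": ar_minus,
            "contribution": (res.total_ar - ar_minus) / (res.total_ar - 1.0),
        }
    res.contributions = pd.DataFrame(rows).T
    return res


# ---------------------------------------------------------------------------
# maximum coverage

@dataclass
class PrioritizationResult:
    selection_frequency: pd.DataFrame  # budgets x groups
    coverage: pd.Series  # mean covered-allele proportion per budget
    richness: pd.Series  # mean rarefied AR of selected union per budget
    iterations: list = field(default_factory=list)  # per-iteration optimal sets
    budgets: tuple = ()
    n_iter: int = 100
    n_per_pop: int = 4


def _solve_max_coverage(
    presence: np.ndarray, budget: int, union_counts_fn
) -> tuple[int, ...]:
    """Exact maximum coverage by enumerating all C(G, b) subsets.

    Ties on covered-allele count are broken by larger rarefied AR of the
    pooled selected counts, then lexicographic subset order (both
    deterministic; selection-frequency splits must reflect resampling
    variation only, never randomised tie-splitting).
    """
    G = presence.shape[0]
    best, best_cov, best_ar = None, -1, -np.inf
    for combo in itertools.combinations(range(G), budget):
        cov = int(presence[list(combo)].any(axis=0).sum())
        if cov < best_cov:
            continue
        if cov > best_cov:
            best, best_cov, best_ar = combo, cov, None
            continue
        # tie on coverage: compare rarefied AR (computed lazily)
        if best_ar is None:
            best_ar = union_counts_fn(best)
        ar = union_counts_fn(combo)
        if ar > best_ar + 1e-12:
            best, best_ar = combo, ar
    return best


def max_coverage(
    g: GenotypeMatrix,
    popmap: PopulationMap,
    budgets=(1, 2, 3, 4, 5),
    n_iter: int = 100,
    n_per_pop: int = 4,
    g_copies: int = 8,
    merge: dict | None = None,
    seed: int | None = None,
) -> PrioritizationResult:
    """Resampled exact maximum-coverage prioritisation.

    Each iteration draws ``n_per_pop`` individuals per group without
    replacement, marks each allele present in a group iff observed in that
    subsample, and solves max coverage exactly for every budget.  Reports
    per-budget selection frequencies, mean proportion of the iteration's
    pooled alleles covered, and the mean rarefied AR of the selected
    union.
    """
    rng = np.random.default_rng(seed)
    groups = group_assignment(popmap, merge)
    labels = sorted(set(groups.values()))
    G = len(labels)
    capped = [min(b, G) for b in budgets]
    if capped != list(budgets):
        log.warning("budgets exceeding %d groups capped", G)
    budgets = tuple(dict.fromkeys(capped))
    sample_set = set(g.sample_ids)
    members = {}
    for lab in labels:
        samples = [
            s
            for p, grp in groups.items()
            if grp == lab
            for s in popmap.samples_in_population(p)
            if s in sample_set
        ]
        if len(samples) < n_per_pop:
            raise ValueError(f"group {lab} has fewer than {n_per_pop} individuals")
        members[lab] = g.sample_index(samples)

    sel = {b: {lab: 0 for lab in labels} for b in budgets}
    cov_sum = {b: 0.0 for b in budgets}
    ar_sum = {b: 0.0 for b in budgets}
    iterations = []
    for _ in range(n_iter):
        counts = np.zeros((G, g.n_loci, 2))
        for gi, lab in enumerate(labels):
            pick = rng.choice(members[lab], size=n_per_pop, replace=False)
            sub = g.dosage[pick]
            called = ~np.isnan(sub)
            alt = np.nansum(sub, axis=0)
            tot = 2.0 * called.sum(axis=0)
            counts[gi, :, 0] = tot - alt
            counts[gi, :, 1] = alt
        presence = (counts > 0).reshape(G, -1)  # group x (locus, allele)
        pooled_present = presence.any(axis=0)
        total_alleles = int(pooled_present.sum())

        def union_ar(combo, counts=counts):
            pooled = counts[list(combo)].sum(axis=0)
            ar = rarefied_locus_ar(pooled, g_copies)
            return float(np.nanmean(ar)) if np.isfinite(ar).any() else -np.inf

        record = {}
        for b in budgets:
            combo = _solve_max_coverage(presence, b, union_ar)
            chosen = [labels[i] for i in combo]
            for lab in chosen:
                sel[b][lab] += 1
            cov = int(presence[list(combo)].any(axis=0).sum())
            cov_sum[b] += cov / total_alleles if total_alleles else np.nan
            ar_sum[b] += union_ar(combo)
            record[b] = tuple(chosen)
        iterations.append(record)

    freq = pd.DataFrame(
        {lab: [sel[b][lab] / n_iter for b in budgets] for lab in labels},
        index=pd.Index(budgets, name="budget"),
    )
    coverage = pd.Series({b: cov_sum[b] / n_iter for b in budgets}, name="coverage")
    richness = pd.Series({b: ar_sum[b] / n_iter for b in budgets}, name="mean_AR")
    return PrioritizationResult(freq, coverage, richness, iterations,
                                budgets, n_iter, n_per_pop)
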