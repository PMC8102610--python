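"""Genotype / metadata IO and the post-calling SNP filter cascade.

The filter cascade reproduces a standard reduced-representation SNP
cleaning workflow, applied in a fixed order: (1) locus call rate, (2)
minor allele count, (3) observed-heterozygosity ceiling (paralog screen),
(4) linkage-disequilibrium pruning within a physical window, (5) removal
of high-missingness samples.  Stage counts depend on this order; the
order is fixed and recorded in the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import EnvironmentTable, GenotypeMatrix, PopulationMap

__all__ = [
    "FilterConfig",
    "FilterReport",
    "read_genotypes",
    "read_popmap",
    "read_environment",
    "write_vcf",
    "write_dosage_csv",
    "write_popmap_csv",
    "write_environment_csv",
    "filter_snps",
    "allele_frequencies",
]

log = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Thresholds of the five-stage filter cascade.

    ``ld_threshold`` is compared against the dosage correlation |r| by
    default (``ld_use_r_squared=False``); switch to r^2 via config.
    """

    min_locus_call_rate: float = 0.80
    min_minor_allele_count: int = 3
    max_obs_het: float = 0.5
    ld_threshold: float = 0.5
    ld_use_r_squared: bool = False
    ld_window_bp: int = 100_000
    ld_min_shared: int = 10
    max_sample_missing: float = 0.25

    def __post_init__(self) -> None:
        for name, val, lo, hi in (
            ("min_locus_call_rate", self.min_locus_call_rate, 0.0, 1.0),
            ("max_obs_het", self.max_obs_het, 0.0, 1.0),
            ("ld_threshold", self.ld_threshold, 0.0, 1.0),
            ("max_sample_missing", self.max_sample_missing, 0.0, 1.0),
        ):
            if not lo <= val <= hi:
                raise ValueError(f"{name} must be in [{lo}, {hi}]")
        if self.min_minor_allele_count < 0 or self.ld_window_bp <= 0:
            raise ValueError("counts/window must be positive")


@dataclass
class FilterReport:
    """Per-stage removal counts, in application order."""

    stages: list[dict] = field(default_factory=list)
    n_samples_in: int = 0
    n_loci_in: int = 0
    n_samples_out: int = 0
    n_loci_out: int = 0
    missing_fraction: float = 0.0
    ld_metric: str = "|r|"

    def add_stage(self, name: str, kind: str, removed: int, retained: int) -> None:
        self.stages.append(
            {"stage": name, "kind": kind, "removed": removed, "retained": retained}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)

    def removed(self, stage: str) -> int:
        for s in self.stages:
            if s["stage"] == stage:
                return s["removed"]
        raise KeyError(stage)


# ---------------------------------------------------------------------------
# readers / writers

def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from a VCF (plain or bgzipped) or a dosage CSV.

    VCF genotypes become alternate-allele dosages; ``./.`` becomes missing.
    Multi-allelic records are rejected (skipped with a logged count).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "matrix"
    if format == "vcf":
        return _read_vcf(path)
    if format == "matrix":
        return _read_dosage_csv(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample IDs in VCF header")
    scaffold, position, locus_ids, rows = [], [], [], []
    n_multiallelic = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multiallelic += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        rows.append(dos)
        scaffold.append(var.CHROM)
        position.append(var.POS)
        locus_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
    vcf.close()
    if n_multiallelic:
        log.info("skipped %d multi-allelic records", n_multiallelic)
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")
    return GenotypeMatrix(
        sample_ids=samples,
        locus_ids=locus_ids,
        scaffold=np.array(scaffold, dtype=object),
        position=np.array(position, dtype=np.int64),
        dosage=np.vstack(rows).T,
    )


def _read_dosage_csv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate sample IDs in dosage matrix")
    loci = list(df.columns)
    scaffold, position = [], []
    for l in loci:
        if ":" in l:
            sc, pos = l.rsplit(":", 1)
            scaffold.append(sc)
            position.append(int(pos))
        else:
            scaffold.append("scaffold1")
            position.append(len(position) + 1)
    return GenotypeMatrix(
        sample_ids=[str(s) for s in df.index],
        locus_ids=loci,
        scaffold=np.array(scaffold, dtype=object),
        position=np.array(position, dtype=np.int64),
        dosage=df.to_numpy(dtype=float),
    )


def read_popmap(path) -> PopulationMap:
    df = pd.read_csv(path, index_col=0)
    return PopulationMap(df)


def read_environment(path) -> EnvironmentTable:
    return EnvironmentTable(pd.read_csv(path, index_col=0))


_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCFv4.2 with GT-only genotypes (``./.`` = missing)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=conigen\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for sc in dict.fromkeys(g.scaffold.tolist()):
            fh.write(f"##contig=<ID={sc}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.sample_ids) + "\n")
        for j in range(g.n_loci):
            calls = [
                "./." if np.isnan(d) else _GT[d] for d in g.dosage[:, j]
            ]
            fh.write(
                f"{g.scaffold[j]}\t{g.position[j]}\t{g.locus_ids[j]}\tA\tT\t.\t.\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def write_dosage_csv(g: GenotypeMatrix, path) -> None:
    pd.DataFrame(g.dosage, index=g.sample_ids, columns=g.locus_ids).to_csv(
        path, index_label="sample", na_rep="NA"
    )


def write_popmap_csv(popmap: PopulationMap, path) -> None:
    popmap.table.to_csv(path, index_label="sample")


def write_environment_csv(env: EnvironmentTable, path) -> None:
    env.table.to_csv(path, index_label="sample")


# ---------------------------------------------------------------------------
# filter cascade

def filter_snps(g: GenotypeMatrix, cfg: FilterConfig | None = None) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the five-stage filter cascade in its fixed order."""
    cfg = cfg or FilterConfig()
    if g.n_loci == 0 or g.n_samples == 0:
        raise ValueError("empty genotype matrix")
    report = FilterReport(
        n_samples_in=g.n_samples,
        n_loci_in=g.n_loci,
        ld_metric="r^2" if cfg.ld_use_r_squared else "|r|",
    )
    dosage = g.dosage

    # stage 1: locus call rate
    called = ~np.isnan(dosage)
    call_rate = called.mean(axis=0)
    keep = call_rate >= cfg.min_locus_call_rate
    report.add_stage("locus_call_rate", "loci", int((~keep).sum()), int(keep.sum()))
    g = g.subset(loci=keep)

    # stage 2: minor allele count
    dosage = g.dosage
    called = ~np.isnan(dosage)
    alt = np.nansum(dosage, axis=0)
    copies = 2.0 * called.sum(axis=0)
    mac = np.minimum(alt, copies - alt)
    keep = mac >= cfg.min_minor_allele_count
    report.add_stage("minor_allele_count", "loci", int((~keep).sum()), int(keep.sum()))
    g = g.subset(loci=keep)

    # stage 3: observed heterozygosity ceiling
    dosage = g.dosage
    called = ~np.isnan(dosage)
    n_called = called.sum(axis=0)
    het = (dosage == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        obs_het = np.where(n_called > 0, het / np.maximum(n_called, 1), 0.0)
    keep = obs_het <= cfg.max_obs_het
    report.add_stage("observed_heterozygosity", "loci", int((~keep).sum()), int(keep.sum()))
    g = g.subset(loci=keep)

    # stage 4: LD pruning
    drop = _ld_prune(g, cfg)
    keep = np.ones(g.n_loci, dtype=bool)
    keep[list(drop)] = False
    report.add_stage("ld_pruning", "loci", int(len(drop)), int(keep.sum()))
    g = g.subset(loci=keep)
    if g.n_loci == 0:
        raise ValueError("empty panel: all loci removed by filters")

    # stage 5: sample missingness
    missing = np.isnan(g.dosage).mean(axis=1)
    keep_s = missing <= cfg.max_sample_missing
    report.add_stage("sample_missingness", "samples", int((~keep_s).sum()), int(keep_s.sum()))
    g = g.subset(samples=keep_s)
    if g.n_samples == 0:
        raise ValueError("empty panel: all samples removed by filters")

    report.n_samples_out = g.n_samples
    report.n_loci_out = g.n_loci
    report.missing_fraction = g.missing_fraction()
    return g, report


def _pairwise_r(x: np.ndarray, y: np.ndarray, min_shared: int) -> float | None:
    """Pearson correlation of two dosage vectors on pairwise-complete
    observations; None when fewer than ``min_shared`` shared calls or a
    vector is constant on the shared set."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < min_shared:
        return None
    xs, ys = x[ok], y[ok]
    sx, sy = xs.std(), ys.std()
    if sx == 0.0 or sy == 0.0:
        return None
    return float(np.mean((xs - xs.mean()) * (ys - ys.mean())) / (sx * sy))


def _ld_prune(g: GenotypeMatrix, cfg: FilterConfig) -> set[int]:
    """Within-scaffold sliding pairwise scan; for each correlated pair
    closer than the window, drop the member with more missing data, then
    the later position (deterministic)."""
    drop: set[int] = set()
    missing = np.isnan(g.dosage).sum(axis=0)
    order = np.lexsort((g.position, g.scaffold.astype(str)))
    thr = cfg.ld_threshold
    for sc in np.unique(g.scaffold.astype(str)):
        idx = order[g.scaffold.astype(str)[order] == sc]
        pos = g.position[idx]
        for a in range(len(idx)):
            i = idx[a]
            if i in drop:
                continue
            for b in range(a + 1, len(idx)):
                j = idx[b]
                if pos[b] - pos[a] >= cfg.ld_window_bp:
                    break
                if j in drop:
                    continue
                r = _pairwise_r(g.dosage[:, i], g.dosage[:, j], cfg.ld_min_shared)
                if r is None:
                    continue
                stat = r * r if cfg.ld_use_r_squared else abs(r)
                # strict ">" with a float guard: dosage data can produce
                # correlations exactly at the threshold (rational values),
                # which must consistently NOT be pruned
                if stat > thr + 1e-9:
                    if missing[i] > missing[j]:
                        drop.add(i)
                        break  # i is gone; stop scanning its pairs
                    elif missing[j] > missing[i]:
                        drop.add(j)
                    else:  # tie: drop the later position
                        drop.add(j)
        # note: when i is dropped mid-scan we break and move on
    return drop


# ---------------------------------------------------------------------------
# allele frequencies

def allele_frequencies(
    g: GenotypeMatrix, popmap: PopulationMap
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-population alternate-allele frequencies and gene-copy counts.

    Returns ``(freq, copies)`` DataFrames (populations x loci).  Cells
    where a population has no genotyped sample are NaN frequency with 0
    copies.
    """
    popmap.check_covers(g)
    pops = popmap.populations
    freq = np.full((len(pops), g.n_loci), np.nan)
    copies = np.zeros((len(pops), g.n_loci))
    for i, pop in enumerate(pops):
        samples = [s for s in popmap.samples_in_population(pop) if s in set(g.sample_ids)]
        sub = g.dosage[g.sample_index(samples), :]
        called = ~np.isnan(sub)
        n2 = 2.0 * called.sum(axis=0)
        alt = np.nansum(sub, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n2 > 0, alt / np.maximum(n2, 1.0), np.nan)
        freq[i] = p
        copies[i] = n2
    return (
        pd.DataFrame(freq, index=pops, columns=g.locus_ids),
        pd.DataFrame(copies, index=pops, columns=g.locus_ids),
    )
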