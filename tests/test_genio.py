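import numpy as np
import pytest

from conigen.genio import (
    FilterConfig,
    allele_frequencies,
    filter_snps,
    read_genotypes,
    write_dosage_csv,
    write_vcf,
)
from conigen.simdata import SimulationConfig, simulate_dataset

from conftest import make_matrix, make_popmap


class TestIO:
    def test_vcf_round_trip(self, tmp_path, two_lineage_dataset):
        g = two_lineage_dataset[0].subset(loci=np.arange(200))
        path = tmp_path / "g.vcf"
        write_vcf(g, path)
        back = read_genotypes(path)
        assert back.sample_ids == g.sample_ids
        np.testing.assert_array_equal(back.dosage, g.dosage)
        np.testing.assert_array_equal(back.position, g.position)

    def test_dosage_csv_round_trip(self, tmp_path, two_lineage_dataset):
        g = two_lineage_dataset[0].subset(loci=np.arange(50))
        path = tmp_path / "g.csv"
        write_dosage_csv(g, path)
        back = read_genotypes(path, format="matrix")
        assert back.sample_ids == g.sample_ids
        np.testing.assert_array_equal(back.dosage, g.dosage)

    def test_vcf_gt_codes_and_multiallelic_skip(self, tmp_path):
        text = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "chr1\t10\t.\tA\tT\t.\t.\t.\tGT\t0/1\t./.\n"
            "chr1\t20\t.\tA\tT,C\t.\t.\t.\tGT\t0/1\t1/2\n"
            "chr1\t30\t.\tG\tC\t.\t.\t.\tGT\t1/1\t0/0\n"
        )
        path = tmp_path / "t.vcf"
        path.write_text(text)
        g = read_genotypes(path)
        assert g.n_loci == 2  # multi-allelic record skipped
        assert g.dosage[0, 0] == 1.0 and np.isnan(g.dosage[1, 0])
        assert g.dosage[0, 1] == 2.0 and g.dosage[1, 1] == 0.0

    def test_missing_file_raises(self):
        with pytest.raises(FileNotFoundError):
            read_genotypes("does_not_exist.vcf")


class TestFilterStages:
    def test_low_call_rate_removed(self):
        # locus 1 genotyped in 7/10 samples (70%) -> removed at stage 1
        col = [0] * 7 + [None] * 3
        good = [0, 2] * 5
        g = make_matrix(list(zip(col, good)))
        _, report = filter_snps(g, FilterConfig(min_minor_allele_count=0, ld_threshold=1.0))
        assert report.removed("locus_call_rate") == 1

    def test_low_mac_removed(self):
        col = [0] * 8 + [1] * 2  # MAC = 2
        keep = [0, 2] * 5  # MAC = 10
        g = make_matrix(list(zip(col, keep)))
        _, report = filter_snps(g, FilterConfig(ld_threshold=1.0))
        assert report.removed("minor_allele_count") == 1

    def test_high_het_removed(self):
        het = [1] * 10  # H_O = 1
        ok = [0, 2] * 5
        g = make_matrix(list(zip(het, ok)))
        _, report = filter_snps(g, FilterConfig(ld_threshold=1.0))
        assert report.removed("observed_heterozygosity") == 1

    def test_duplicate_pair_prunes_exactly_one(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, size=30).astype(float)
        g = make_matrix(np.column_stack([col, col]), positions=[1, 50_001])
        filtered, report = filter_snps(g, FilterConfig(min_minor_allele_count=0,
                                                       max_obs_het=1.0))
        assert report.removed("ld_pruning") == 1
        assert filtered.n_loci == 1

    def test_distant_duplicates_not_pruned(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, size=30).astype(float)
        g = make_matrix(np.column_stack([col, col]), positions=[1, 200_001])
        _, report = filter_snps(g, FilterConfig(min_minor_allele_count=0,
                                                max_obs_het=1.0))
        assert report.removed("ld_pruning") == 0

    def test_high_missing_sample_removed(self):
        rng = np.random.default_rng(1)
        dosage = rng.integers(0, 3, size=(10, 40)).astype(float)
        dosage[0, :12] = np.nan  # 30% missing
        g = make_matrix(dosage)
        filtered, report = filter_snps(
            g, FilterConfig(min_locus_call_rate=0.0, min_minor_allele_count=0,
                            max_obs_het=1.0, ld_threshold=1.0))
        assert report.removed("sample_missingness") == 1
        assert "s1" not in filtered.sample_ids

    def test_empty_panel_errors(self):
        g = make_matrix([[1, 1], [1, 1], [1, 1]])  # all loci H_O = 1
        with pytest.raises(ValueError, match="empty panel"):
            filter_snps(g, FilterConfig(min_minor_allele_count=0))

    def test_report_counts_match_independent_recount(self):
        """200-locus randomized fixture: stage-by-stage fates recounted by
        a plain-loop checker equal the FilterReport."""
        rng = np.random.default_rng(42)
        n, m = 24, 200
        p = rng.uniform(0.02, 0.5, size=m)
        dosage = rng.binomial(2, p, size=(n, m)).astype(float)
        dosage[rng.random((n, m)) < 0.08] = np.nan
        dosage[:, 5] = np.where(np.isnan(dosage[:, 4]), np.nan, dosage[:, 4])  # LD pair
        dosage[0, : int(0.4 * m)] = np.nan  # high-missingness sample
        g = make_matrix(dosage, positions=[(j + 1) * 1000 for j in range(m)])
        cfg = FilterConfig()
        _, report = filter_snps(g, cfg)
        expected = _recount(dosage, g.position, cfg)
        for stage, count in expected.items():
            assert report.removed(stage) == count, stage

    def test_idempotence(self, two_lineage_dataset):
        g, _, _ = two_lineage_dataset
        f1, _ = filter_snps(g)
        f2, report2 = filter_snps(f1)
        assert f2.n_loci == f1.n_loci
        assert f2.n_samples == f1.n_samples
        assert all(s["removed"] == 0 for s in report2.stages)


def _recount(dosage, position, cfg):
    """Independent sequential recount of per-stage removals."""
    d = dosage.copy()
    out = {}
    # stage 1
    keep = []
    removed = 0
    for j in range(d.shape[1]):
        col = d[:, j]
        rate = np.mean(~np.isnan(col))
        if rate < cfg.min_locus_call_rate:
            removed += 1
        else:
            keep.append(j)
    out["locus_call_rate"] = removed
    d, position = d[:, keep], position[keep]
    # stage 2
    keep, removed = [], 0
    for j in range(d.shape[1]):
        col = d[:, j][~np.isnan(d[:, j])]
        mac = min(col.sum(), 2 * len(col) - col.sum())
        if mac < cfg.min_minor_allele_count:
            removed += 1
        else:
            keep.append(j)
    out["minor_allele_count"] = removed
    d, position = d[:, keep], position[keep]
    # stage 3
    keep, removed = [], 0
    for j in range(d.shape[1]):
        col = d[:, j][~np.isnan(d[:, j])]
        if len(col) and np.mean(col == 1) > cfg.max_obs_het:
            removed += 1
        else:
            keep.append(j)
    out["observed_heterozygosity"] = removed
    d, position = d[:, keep], position[keep]
    # stage 4 (same deterministic scan semantics, written independently)
    dropped = set()
    order = np.argsort(position, kind="stable")
    for ai in range(len(order)):
        i = order[ai]
        if i in dropped:
            continue
        for bi in range(ai + 1, len(order)):
            j = order[bi]
            if position[j] - position[i] >= cfg.ld_window_bp:
                break
            if j in dropped:
                continue
            ok = ~np.isnan(d[:, i]) & ~np.isnan(d[:, j])
            if ok.sum() < cfg.ld_min_shared:
                continue
            xi, xj = d[ok, i], d[ok, j]
            if xi.std() == 0 or xj.std() == 0:
                continue
            r = np.corrcoef(xi, xj)[0, 1]
            if abs(r) > cfg.ld_threshold + 1e-9:  # boundary values not pruned
                mi, mj = np.isnan(d[:, i]).sum(), np.isnan(d[:, j]).sum()
                if mi > mj:
                    dropped.add(i)
                    break
                dropped.add(j)
    out["ld_pruning"] = len(dropped)
    keep = [j for j in range(d.shape[1]) if j not in dropped]
    d = d[:, keep]
    # stage 5
    out["sample_missingness"] = int(
        np.sum(np.isnan(d).mean(axis=1) > cfg.max_sample_missing)
    )
    return out


class TestAlleleFrequencies:
    def test_simple_frequency(self):
        g = make_matrix([[0], [1], [2]])
        pm = make_popmap({"s1": ("a", "r"), "s2": ("a", "r"), "s3": ("a", "r")})
        freq, copies = allele_frequencies(g, pm)
        assert freq.loc["a", "L1"] == 0.5
        assert copies.loc["a", "L1"] == 6

    def test_all_missing_is_undefined(self):
        g = make_matrix([[None, 1], [None, 2]])
        pm = make_popmap({"s1": ("a", "r"), "s2": ("a", "r")})
        freq, copies = allele_frequencies(g, pm)
        assert np.isnan(freq.loc["a", "L1"])
        assert copies.loc["a", "L1"] == 0

    def test_hand_computed_fixture(self):
        g = make_matrix([[0, 2], [1, 2], [None, 1], [2, 0]])
        pm = make_popmap({"s1": ("a", "r"), "s2": ("a", "r"),
                          "s3": ("b", "r"), "s4": ("b", "r")})
        freq, copies = allele_frequencies(g, pm)
        assert freq.loc["a", "L1"] == pytest.approx(1 / 4)
        assert freq.loc["a", "L2"] == pytest.approx(1.0)
        assert freq.loc["b", "L1"] == pytest.approx(1.0)
        assert freq.loc["b", "L2"] == pytest.approx(1 / 4)
        assert copies.loc["b", "L1"] == 2

    def test_frequencies_in_unit_interval(self, two_lineage_dataset):
        g, pm, _ = two_lineage_dataset
        freq, _ = allele_frequencies(g, pm)
        vals = freq.to_numpy()
        vals = vals[np.isfinite(vals)]
        assert np.all((vals >= 0) & (vals <= 1))
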