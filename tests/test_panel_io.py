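import numpy as np
import pytest

from genolrt.panel_io import (
    HaplotypePanel,
    PanelFormatError,
    joint_genotype_freq,
    ld_stats,
    read_hapmatrix,
    read_vcf,
    write_hapmatrix,
    write_vcf,
)

from conftest import make_panel

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS0\tS1\tS2\tS3\n"
)


def write_vcf_text(path, records):
    path.write_text(VCF_HEADER + "".join(records))
    return str(path)


def record(pos, gts, ref="A", alt="T", vid=None):
    vid = vid or f"rs{pos}"
    return f"19\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"


class TestReadVcf:
    def test_phased_biallelic_sites_parse_to_haplotype_matrix(self, tmp_path):
        path = write_vcf_text(
            tmp_path / "toy.vcf",
            [
                record(100, ["0|1", "0|0", "1|0", "0|0"]),
                record(200, ["0|0", "0|1", "0|0", "0|1"]),
                record(300, ["1|1", "0|1", "0|0", "0|0"]),
            ],
        )
        panel = read_vcf(path, maf_min=0.001)
        assert panel.haplotypes.shape == (8, 3)
        assert list(panel.variant_meta["pos"]) == [100, 200, 300]
        # first site: haplotype order sample-major, allele-within-sample
        assert list(panel.haplotypes[:, 0]) == [0, 1, 0, 0, 1, 0, 0, 0]

    def test_low_maf_site_is_excluded(self, tmp_path):
        # one singleton among 8 haplotypes has MAF 0.125; with maf_min=0.2
        # it is dropped while the common site survives
        path = write_vcf_text(
            tmp_path / "toy.vcf",
            [
                record(100, ["0|1", "0|0", "0|0", "0|0"]),
                record(200, ["0|1", "1|0", "0|1", "1|0"]),
            ],
        )
        panel = read_vcf(path, maf_min=0.2)
        assert panel.n_variants == 1
        assert panel.variant_meta["pos"].iloc[0] == 200

    def test_unphased_call_is_a_hard_error_naming_the_site(self, tmp_path):
        path = write_vcf_text(
            tmp_path / "toy.vcf",
            [record(100, ["0/1", "0|0", "0|1", "0|0"])],
        )
        with pytest.raises(PanelFormatError, match="19:100"):
            read_vcf(path)

    def test_missing_genotype_is_a_hard_error(self, tmp_path):
        path = write_vcf_text(
            tmp_path / "toy.vcf",
            [record(100, [".|.", "0|0", "0|1", "0|1"])],
        )
        with pytest.raises(PanelFormatError, match="missing"):
            read_vcf(path)

    def test_multiallelic_record_is_excluded(self, tmp_path):
        path = write_vcf_text(
            tmp_path / "toy.vcf",
            [
                record(100, ["0|1", "0|0", "1|0", "0|1"], alt="T,G"),
                record(200, ["0|1", "1|0", "0|1", "0|0"]),
            ],
        )
        panel = read_vcf(path)
        assert panel.n_variants == 1

    def test_major_alt_is_recoded_so_one_means_minor(self, tmp_path):
        path = write_vcf_text(
            tmp_path / "toy.vcf",
            [record(100, ["1|1", "1|1", "1|0", "1|1"])],
        )
        panel = read_vcf(path)
        assert panel.maf()[0] == pytest.approx(1 / 8)
        assert not panel.variant_meta["minor_is_alt"].iloc[0]


class TestRoundTrips:
    def test_hapmatrix_round_trip_is_bit_exact(self, tmp_path, apoe_panel):
        path = tmp_path / "panel.csv"
        write_hapmatrix(apoe_panel, path)
        back = read_hapmatrix(path)
        assert np.array_equal(back.haplotypes, apoe_panel.haplotypes)
        assert list(back.variant_meta["id"]) == list(apoe_panel.variant_meta["id"])

    def test_vcf_round_trip_preserves_haplotypes(self, tmp_path):
        panel = make_panel(
            [[0, 1], [1, 0], [0, 0], [1, 1], [0, 1], [0, 0], [1, 0], [0, 0]]
        )
        path = tmp_path / "panel.vcf"
        write_vcf(panel, str(path))
        back = read_vcf(str(path), maf_min=0.0)
        assert np.array_equal(back.haplotypes, panel.haplotypes)

    def test_genotypes_are_haplotype_row_pair_sums(self, apoe_panel):
        g = apoe_panel.genotypes()
        manual = apoe_panel.haplotypes[0::2] + apoe_panel.haplotypes[1::2]
        assert np.array_equal(g, manual)


class TestLdStats:
    def test_identical_columns_have_r2_and_dprime_one(self):
        panel = make_panel([[1, 1], [0, 0], [1, 1], [0, 0]])
        s = ld_stats(panel, 0, 1)
        assert s.r2 == pytest.approx(1.0)
        assert s.D_prime == pytest.approx(1.0)

    def test_constructed_independence_gives_zero_d(self):
        # all four haplotype combinations at equal frequency: p11 = p1 p2
        panel = make_panel([[0, 0], [0, 1], [1, 0], [1, 1]])
        s = ld_stats(panel, 0, 1)
        assert s.D == pytest.approx(0.0, abs=1e-15)
        assert s.r2 == pytest.approx(0.0, abs=1e-15)

    def test_r2_equals_squared_pearson_correlation_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            hap = rng.integers(0, 2, size=(10, 2)).astype(np.int8)
            if len(set(hap[:, 0])) < 2 or len(set(hap[:, 1])) < 2:
                continue
            panel = make_panel(hap)
            s = ld_stats(panel, 0, 1)
            oracle = np.corrcoef(hap[:, 0], hap[:, 1])[0, 1] ** 2
            assert s.r2 == pytest.approx(oracle, abs=1e-12)

    def test_brute_force_two_by_two_haplotype_count_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(2, 7)) * 2  # <= 12 haplotypes
            hap = rng.integers(0, 2, size=(n, 2)).astype(np.int8)
            if len(set(hap[:, 0])) < 2 or len(set(hap[:, 1])) < 2:
                continue
            panel = make_panel(hap)
            s = ld_stats(panel, 0, 1)
            p1 = hap[:, 0].mean()
            p2 = hap[:, 1].mean()
            p11 = (hap[:, 0] & hap[:, 1]).mean()
            assert s.D == pytest.approx(p11 - p1 * p2, abs=1e-12)
            assert s.r2 == pytest.approx(
                (p11 - p1 * p2) ** 2 / (p1 * (1 - p1) * p2 * (1 - p2)), abs=1e-12
            )

    def test_monomorphic_column_is_rejected(self):
        panel = make_panel([[1, 1], [0, 1], [1, 1], [0, 1]])
        # column 1 is monomorphic only after mutation; build directly
        hap = panel.haplotypes.copy()
        with pytest.raises(ValueError):
            ld_stats(make_panel(np.column_stack([hap[:, 0], hap[:, 0]])), 0, 0)


class TestJointGenotypeFreq:
    def test_identical_vectors_give_diagonal_table(self):
        g = np.array([0, 1, 2, 1, 0, 2, 1, 1])
        j = joint_genotype_freq(g, g)
        assert np.allclose(j.table, np.diag(np.bincount(g, minlength=3) / g.size))

    def test_margins_match_univariate_frequencies(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, 50)
        d = rng.integers(0, 3, 50)
        j = joint_genotype_freq(g, d)
        assert np.allclose(j.candidate_margin, np.bincount(g, minlength=3) / 50)
        assert np.allclose(j.disease_margin, np.bincount(d, minlength=3) / 50)
        assert j.table.sum() == pytest.approx(1.0)

    def test_ten_individual_table_matches_hand_count(self):
        g = np.array([0, 0, 1, 1, 2, 0, 1, 2, 0, 1])
        d = np.array([0, 1, 1, 1, 2, 0, 0, 2, 0, 1])
        j = joint_genotype_freq(g, d)
        expected = np.zeros((3, 3))
        for a, b in zip(g, d):
            expected[a, b] += 0.1
        assert np.allclose(j.table, expected)

    def test_empty_input_is_rejected(self):
        with pytest.raises(ValueError):
            joint_genotype_freq(np.array([]), np.array([]))


class TestPanelInvariants:
    def test_monomorphic_columns_are_rejected_at_construction(self):
        with pytest.raises(ValueError, match="monomorphic"):
            make_panel([[0, 1], [0, 0], [0, 1], [0, 0]])

    def test_odd_haplotype_count_is_rejected(self):
        import pandas as pd

        hap = np.array([[0], [1], [1]], dtype=np.int8)
        meta = pd.DataFrame({"id": ["v0"], "pos": [1], "ref": "A", "alt": "T"})
        with pytest.raises(ValueError, match="even"):
            HaplotypePanel(haplotypes=hap, variant_meta=meta)
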