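import numpy as np
import pandas as pd
import pytest

from haploscan.iodata import (
    FormatError,
    PhasedPanel,
    SnpRecord,
    read_genetic_map,
    read_phased_vcf,
    read_phenotypes,
    read_summary_stats,
    write_genetic_map,
    write_phased_vcf,
    write_phenotypes,
    write_summary_stats,
)
from haploscan.simulate import SimConfig, simulate_cohort

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
)


def _write(tmp_path, body, name="x.vcf"):
    p = tmp_path / name
    p.write_text(VCF_HEADER + body)
    return p


def _tiny_panel():
    snps = [
        SnpRecord("rs1", "1", 100, float("nan"), ("A", "G")),
        SnpRecord("rs2", "1", 200, float("nan"), ("C", "T")),
        SnpRecord("rs3", "1", 300, float("nan"), ("G", "A")),
    ]
    haps = np.array(
        [[0, 1, 0], [1, 0, 0], [0, 0, 1], [1, 1, 1]], dtype=np.uint8
    )
    return PhasedPanel(snps, ["S1", "S2"], haps)


class TestPhasedVcf:
    def test_round_trip_identity(self, tmp_path):
        panel = _tiny_panel()
        path = tmp_path / "t.vcf"
        write_phased_vcf(panel, path)
        back = read_phased_vcf(path)
        assert back.individuals == panel.individuals
        assert np.array_equal(back.haps, panel.haps)
        assert [s.bp for s in back.snps] == [s.bp for s in panel.snps]
        assert [s.alleles for s in back.snps] == [s.alleles for s in panel.snps]

    def test_simulator_output_round_trips(self, tmp_path):
        cfg = SimConfig(n_individuals=50, n_snps=200, seed=1)
        panel, _, _, _ = simulate_cohort(cfg)
        path = tmp_path / "sim.vcf"
        write_phased_vcf(panel, path)
        back = read_phased_vcf(path)
        assert np.array_equal(back.haps, panel.haps)
        assert back.individuals == panel.individuals

    def test_unphased_genotype_rejected(self, tmp_path):
        p = _write(tmp_path, "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/1\t0|0\n")
        with pytest.raises(FormatError, match="unphased"):
            read_phased_vcf(p)

    def test_missing_genotype_rejected(self, tmp_path):
        p = _write(tmp_path, "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t.|.\t0|0\n")
        with pytest.raises(FormatError, match="missing"):
            read_phased_vcf(p)

    def test_multiallelic_rejected(self, tmp_path):
        p = _write(tmp_path, "1\t100\trs1\tA\tG,T\t.\t.\t.\tGT\t0|1\t0|2\n")
        with pytest.raises(FormatError, match="biallelic"):
            read_phased_vcf(p)

    def test_unsorted_bp_rejected(self, tmp_path):
        body = (
            "1\t200\trs1\tA\tG\t.\t.\t.\tGT\t0|1\t0|0\n"
            "1\t100\trs2\tA\tG\t.\t.\t.\tGT\t0|1\t0|0\n"
        )
        with pytest.raises(FormatError, match="increasing"):
            read_phased_vcf(_write(tmp_path, body))


class TestGeneticMap:
    def test_basic_parse(self, tmp_path):
        p = tmp_path / "map.txt"
        p.write_text(
            "Chromosome Position(bp) Rate(cM/Mb) Map(cM)\n"
            "1 1000 1.0 0.0\n1 2000 1.0 0.001\n"
        )
        gmap = read_genetic_map(p)
        assert len(gmap) == 2
        assert gmap["bp"].tolist() == [1000, 2000]
        assert gmap["cm"].tolist() == [0.0, 0.001]

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        with pytest.raises((FormatError, Exception)):
            read_genetic_map(p)

    def test_decreasing_cm_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("1 1000 1.0 0.5\n1 2000 1.0 0.3\n")
        with pytest.raises(FormatError, match="non-monotone"):
            read_genetic_map(p)

    @pytest.mark.parametrize("seed", [1, 2])
    def test_simulator_map_round_trips(self, tmp_path, seed):
        _, _, gmap, _ = simulate_cohort(
            SimConfig(n_individuals=20, n_snps=100, seed=seed)
        )
        path = tmp_path / "map.txt"
        write_genetic_map(gmap, path)
        back = read_genetic_map(path)
        assert np.array_equal(back["bp"].values, gmap["bp"].values)
        np.testing.assert_allclose(back["cm"].values, gmap["cm"].values, rtol=1e-12)


class TestPhenotypes:
    def test_valid_table(self, tmp_path):
        p = tmp_path / "ph.tsv"
        p.write_text("iid\ty\tsex\tage\nA\t0\t1\t40\nB\t1\t0\t55\n")
        df = read_phenotypes(p)
        assert df["y"].tolist() == [0, 1]

    def test_non_binary_y_rejected(self, tmp_path):
        p = tmp_path / "ph.tsv"
        p.write_text("iid\ty\tsex\tage\nA\t2\t1\t40\n")
        with pytest.raises(FormatError, match="binary"):
            read_phenotypes(p)

    def test_duplicate_iid_rejected(self, tmp_path):
        p = tmp_path / "ph.tsv"
        p.write_text("iid\ty\tsex\tage\nA\t0\t1\t40\nA\t1\t0\t50\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_phenotypes(p)

    def test_discovery_style_case_fraction(self, tmp_path):
        # 2605 cases among 18,773 phenotyped individuals -> 13.9% prevalence
        n_case, n_ctrl = 2605, 16168
        df = pd.DataFrame(
            {
                "iid": [f"i{k}" for k in range(n_case + n_ctrl)],
                "y": [1] * n_case + [0] * n_ctrl,
                "sex": 0,
                "age": 50.0,
            }
        )
        p = tmp_path / "ph.tsv"
        write_phenotypes(df, p)
        back = read_phenotypes(p)
        assert back["y"].mean() == pytest.approx(0.1387, abs=5e-4)

    def test_round_trip(self, tmp_path, sim_cohort):
        _, phen, _, _ = sim_cohort
        p = tmp_path / "ph.tsv"
        write_phenotypes(phen, p)
        back = read_phenotypes(p)
        assert back["y"].tolist() == phen["y"].tolist()
        np.testing.assert_allclose(back["age"].values, phen["age"].values, rtol=1e-11)


class TestSummaryStats:
    def test_round_trip_lossless(self, tmp_path):
        rng = np.random.default_rng(5)
        n = 20
        df = pd.DataFrame(
            {
                "chrom": ["1"] * n,
                "start_bp": np.arange(1, n + 1) * 1000,
                "end_bp": np.arange(1, n + 1) * 1000 + 500,
                "window_cm": 0.25,
                "allele_string": ["0101"] * n,
                "freq": rng.uniform(0.005, 0.5, n),
                "hwe_x2": rng.chisquare(1, n),
                "beta": rng.normal(0, 0.05, n),
                "se": rng.uniform(0.005, 0.05, n),
                "p": 10.0 ** rng.uniform(-9, 0, n),
                "or_": rng.uniform(1, 2, n),
                "or_lo": rng.uniform(0.8, 1, n),
                "or_hi": rng.uniform(2, 3, n),
            }
        )
        path = tmp_path / "res.tsv"
        write_summary_stats(df, path)
        back = read_summary_stats(path)
        np.testing.assert_allclose(back["p"].values, df["p"].values, rtol=1e-11)
        np.testing.assert_allclose(back["beta"].values, df["beta"].values, rtol=1e-11)
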