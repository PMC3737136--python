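import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bsvm.data_model import (GenotypeDataset, drop_monomorphic,
                             read_genotypes, read_matrix_tsv,
                             summarize_variants, write_genotypes,
                             write_matrix_tsv, write_phenotypes)
from tests.conftest import make_dataset


def write_vcf(path, sample_ids, rows):
    """rows: list of (variant_id, ref, alts, [genotype strings])."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n##contig=<ID=1>\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for pos, (vid, ref, alts, gts) in enumerate(rows, start=1):
            fh.write(f"1\t{pos}\t{vid}\t{ref}\t{alts}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def write_pheno(path, pairs):
    with open(path, "w") as fh:
        fh.write("sample_id\tstatus\n")
        for sid, status in pairs:
            fh.write(f"{sid}\t{status}\n")


class TestGenotypeDataset:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="0, 1 or 2"):
            GenotypeDataset(np.array([[3], [0]]), [1, -1], ["v"])
        with pytest.raises(ValueError, match=r"\+1 .* or -1"):
            GenotypeDataset(np.array([[1], [0]]), [1, 0], ["v"])
        with pytest.raises(ValueError, match="unique"):
            GenotypeDataset(np.array([[1, 0], [0, 1]]), [1, -1], ["v", "v"])
        with pytest.raises(ValueError, match="at least one case"):
            GenotypeDataset(np.array([[1], [0]]), [1, 1], ["v"])


class TestReadGenotypes:
    def test_het_hom_counts(self, tmp_path):
        vcf, ph = tmp_path / "a.vcf", tmp_path / "a.tsv"
        write_vcf(vcf, ["s1", "s2"], [("rs1", "A", "T", ["0/1", "0/0"])])
        write_pheno(ph, [("s1", "case"), ("s2", "control")])
        data = read_genotypes(vcf, ph)
        assert data.counts.tolist() == [[1], [0]]
        assert data.labels.tolist() == [1, -1]

    def test_alt_major_polarity_flip(self, tmp_path):
        # ALT frequency 0.75: REF is the minor allele, so 1/1 counts 0
        vcf, ph = tmp_path / "a.vcf", tmp_path / "a.tsv"
        write_vcf(vcf, ["s1", "s2"],
                  [("rs1", "A", "T", ["1/1", "0/1"])])
        write_pheno(ph, [("s1", "case"), ("s2", "control")])
        data = read_genotypes(vcf, ph)
        assert data.counts.tolist() == [[0], [1]]

    def test_frequency_tie_counts_alt(self, tmp_path):
        vcf, ph = tmp_path / "a.vcf", tmp_path / "a.tsv"
        write_vcf(vcf, ["s1", "s2"], [("rs1", "A", "T", ["1/1", "0/0"])])
        write_pheno(ph, [("s1", "case"), ("s2", "control")])
        assert read_genotypes(vcf, ph).counts.tolist() == [[2], [0]]

    def test_unknown_sample_errors(self, tmp_path):
        vcf, ph = tmp_path / "a.vcf", tmp_path / "a.tsv"
        write_vcf(vcf, ["s1", "s2"], [("rs1", "A", "T", ["0/1", "0/0"])])
        write_pheno(ph, [("s1", "case"), ("sX", "control")])
        with pytest.raises(ValueError, match="sX"):
            read_genotypes(vcf, ph)

    def test_sample_order_follows_phenotype_file(self, tmp_path):
        vcf, ph = tmp_path / "a.vcf", tmp_path / "a.tsv"
        write_vcf(vcf, ["s1", "s2"], [("rs1", "A", "T", ["0/1", "0/0"])])
        write_pheno(ph, [("s2", "case"), ("s1", "control")])
        data = read_genotypes(vcf, ph)
        assert data.sample_ids == ["s2", "s1"]
        assert data.counts.tolist() == [[0], [1]]

    def test_missing_genotype_policy(self, tmp_path):
        vcf, ph = tmp_path / "a.vcf", tmp_path / "a.tsv"
        write_vcf(vcf, ["s1", "s2"], [("rs1", "A", "T", ["./.", "0/1"])])
        write_pheno(ph, [("s1", "case"), ("s2", "control")])
        with pytest.raises(ValueError, match="missing genotype"):
            read_genotypes(vcf, ph)
        data = read_genotypes(vcf, ph, missing_policy="impute_zero")
        assert data.counts.tolist() == [[0], [1]]

    def test_multiallelic_rejected_or_split(self, tmp_path):
        vcf, ph = tmp_path / "a.vcf", tmp_path / "a.tsv"
        write_vcf(vcf, ["s1", "s2"], [("rs1", "A", "T,G", ["1/2", "0/1"])])
        write_pheno(ph, [("s1", "case"), ("s2", "control")])
        with pytest.raises(ValueError, match="multi-allelic"):
            read_genotypes(vcf, ph)
        data = read_genotypes(vcf, ph, split_multiallelic=True)
        assert data.n_variants == 2
        assert data.counts.tolist() == [[1, 1], [1, 0]]


class TestSummaries:
    def test_direct_sums(self):
        data = make_dataset([[1], [0], [1]], [[0], [0], [0]])
        s = summarize_variants(data)[0]
        assert (s.m_case, s.m_ctrl, s.m_total) == (2, 0, 2)

    def test_monomorphic_column(self):
        data = make_dataset([[0, 1], [0, 1]], [[0, 0], [0, 1]])
        s = summarize_variants(data)[0]
        assert (s.m_case, s.m_ctrl, s.m_total) == (0, 0, 0)
        filtered, dropped = drop_monomorphic(data)
        assert dropped == ["v0"] and filtered.n_variants == 1

    def test_published_ifih1_layout(self):
        # 480 cases and 480 controls carrying 7 vs 23 minor alleles
        case = np.zeros((480, 1), int)
        case[:7] = 1
        ctrl = np.zeros((480, 1), int)
        ctrl[:23] = 1
        s = summarize_variants(make_dataset(case, ctrl))[0]
        assert (s.m_case, s.m_ctrl, s.m_total) == (7, 23, 30)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_allele_conservation(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 3, size=(12, 5))
        labels = rng.permutation([1] * 6 + [-1] * 6)
        data = GenotypeDataset(counts, labels,
                               [f"v{j}" for j in range(5)])
        for j, s in enumerate(summarize_variants(data)):
            assert s.m_case + s.m_ctrl == counts[:, j].sum()


class TestRoundTrips:
    @pytest.mark.parametrize("seed", range(8))
    def test_vcf_round_trip(self, seed, tmp_path):
        rng = np.random.default_rng(seed)
        counts = rng.binomial(2, 0.2, size=(8, 4))
        labels = rng.permutation([1] * 4 + [-1] * 4)
        data = GenotypeDataset(counts, labels,
                               [f"v{j}" for j in range(4)])
        write_genotypes(data, tmp_path / "x.vcf", tmp_path / "x.tsv")
        back = read_genotypes(tmp_path / "x.vcf", tmp_path / "x.tsv")
        assert np.array_equal(back.counts, data.counts)
        assert np.array_equal(back.labels, data.labels)
        assert back.variant_ids == data.variant_ids

    def test_matrix_tsv_round_trip(self, tmp_path):
        data = make_dataset([[1, 0], [2, 1]], [[0, 0], [0, 2]])
        write_matrix_tsv(data, tmp_path / "m.tsv")
        write_phenotypes(data, tmp_path / "p.tsv")
        back = read_matrix_tsv(tmp_path / "m.tsv", tmp_path / "p.tsv")
        assert np.array_equal(back.counts, data.counts)
        assert np.array_equal(back.labels, data.labels)
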