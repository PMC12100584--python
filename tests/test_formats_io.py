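import numpy as np
import pytest

from hybridpaint import formats_io as fio
from hybridpaint import synthetic_data as sd

from conftest import random_genotype_matrix


TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:DP\t0/0:10\t0/1:8\t1/1:5
chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT:DP\t./.:3\t0/0:9\t0/1:7
chr1\t300\t.\tG\tA\t.\tPASS\t.\tGT:DP\t1/1:4\t1/1:6\t0/0:11
chr1\t400\t.\tT\tC\t.\tPASS\t.\tGT:DP\t0/1:2\t./.:0\t0/1:9
chr1\t500\t.\tA\tC\t.\tPASS\t.\tGT:DP\t0/0:12\t0/1:13\t1/1:14
"""


class TestVcf:
    def test_toy_vcf_transcription(self, tmp_path):
        """Dosages count alt alleles and ./. becomes missing with its depth kept."""
        path = tmp_path / "toy.vcf"
        path.write_text(TOY_VCF)
        gm = fio.read_vcf(str(path))
        assert gm.individuals == ["s1", "s2", "s3"]
        expect = np.array(
            [[0, 1, 2], [fio.MISSING, 0, 1], [2, 2, 0], [1, fio.MISSING, 1], [0, 1, 2]]
        )
        assert np.array_equal(gm.dosage, expect)
        assert gm.depth[1, 0] == 3 and gm.depth[3, 1] == 0
        assert list(gm.sites.pos) == [100, 200, 300, 400, 500]

    def test_multiallelic_and_indel_records_dropped(self, tmp_path):
        lines = TOY_VCF.splitlines()
        lines.insert(6, "chr1\t50\t.\tA\tG,T\t.\tPASS\t.\tGT:DP\t0/1:5\t0/0:5\t0/0:5")
        lines.insert(7, "chr1\t60\t.\tAT\tA\t.\tPASS\t.\tGT:DP\t0/1:5\t0/0:5\t0/0:5")
        path = tmp_path / "multi.vcf"
        path.write_text("\n".join(lines) + "\n")
        gm = fio.read_vcf(str(path), filter_biallelic=True)
        assert gm.n_sites == 5

    def test_duplicate_position_rejected(self, tmp_path):
        path = tmp_path / "dup.vcf"
        path.write_text(TOY_VCF + "chr1\t500\t.\tA\tC\t.\tPASS\t.\tGT:DP\t0/0:1\t0/0:1\t0/0:1\n")
        with pytest.raises(fio.ValidationError, match="duplicate"):
            fio.read_vcf(str(path))

    def test_empty_matrix_round_trips_as_header_only(self, tmp_path):
        empty = fio.GenotypeMatrix(
            fio.SiteTable(np.array([], dtype=object), np.array([], dtype=np.int64),
                          np.array([], dtype=object), np.array([], dtype=object)),
            ["a", "b"],
            np.zeros((0, 2), dtype=np.int8),
            np.zeros((0, 2), dtype=np.int32),
        )
        path = tmp_path / "empty.vcf"
        fio.write_vcf(empty, str(path))
        text = path.read_text()
        assert all(line.startswith("#") for line in text.splitlines())
        back = fio.read_vcf(str(path))
        assert back.n_sites == 0 and back.individuals == ["a", "b"]

    def test_het_dosage_encodes_as_0_slash_1(self, tmp_path):
        gm = random_genotype_matrix(0, n_sites=4, n_ind=1, missing_rate=0)
        gm.dosage[:] = np.array([[0], [1], [2], [1]], dtype=np.int8)
        path = tmp_path / "gt.vcf"
        fio.write_vcf(gm, str(path))
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert body[1].split("\t")[-1].startswith("0/1:")

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_identity(self, seed, tmp_path):
        gm = random_genotype_matrix(seed)
        path = tmp_path / "rt.vcf"
        fio.write_vcf(gm, str(path))
        back = fio.read_vcf(str(path))
        assert back.individuals == gm.individuals
        assert np.array_equal(back.dosage, gm.dosage)
        assert np.array_equal(back.depth, gm.depth)
        assert list(back.sites.pos) == list(gm.sites.pos)
        assert list(back.sites.ref) == list(gm.sites.ref)

    def test_unsorted_sites_refused(self):
        with pytest.raises(fio.ValidationError, match="unsorted"):
            fio.SiteTable(
                np.array(["c", "c"], dtype=object), np.array([20, 10]),
                np.array(["A", "C"], dtype=object), np.array(["G", "T"], dtype=object),
            )


class TestBeagle:
    def test_single_row_parses_and_normalises(self, tmp_path):
        path = tmp_path / "gl.beagle"
        path.write_text(
            "marker\tallele1\tallele2\tind1\tind1\tind1\tind2\tind2\tind2\n"
            "chr1_100\t0\t1\t0.9\t0.1\t0.0\t1\t1\t1\n"
        )
        lm = fio.read_beagle_gl(str(path))
        assert lm.individuals == ["ind1", "ind2"]
        assert lm.sites.chrom[0] == "chr1" and lm.sites.pos[0] == 100
        assert lm.sites.ref[0] == "A" and lm.sites.alt[0] == "C"
        np.testing.assert_allclose(lm.gl[0, 0], [0.9, 0.1, 0.0])
        # all-equal triple is uniform no-data
        np.testing.assert_allclose(lm.gl[0, 1], [1 / 3] * 3)
        assert lm.missing[0, 1] and not lm.missing[0, 0]

    def test_wrong_column_count_rejected(self, tmp_path):
        path = tmp_path / "bad.beagle"
        path.write_text("marker\tallele1\tallele2\tind1\tind1\n" "chr1_1\tA\tC\t1\t0\n")
        with pytest.raises(fio.ParseError):
            fio.read_beagle_gl(str(path))

    def test_negative_likelihood_rejected(self, tmp_path):
        path = tmp_path / "neg.beagle"
        path.write_text(
            "marker\tallele1\tallele2\tind1\tind1\tind1\nchr1_1\tA\tC\t-0.1\t0.5\t0.6\n"
        )
        with pytest.raises(fio.ValidationError):
            fio.read_beagle_gl(str(path))

    def test_triple_order_is_homref_het_homalt(self, tmp_path, small_panels):
        """A hom-ref genotype at high depth puts its mass in the first column."""
        gm = small_panels.gm
        lm = sd.genotypes_to_likelihoods(gm, depth_mean=30, error_rate=0.01, seed=0)
        path = tmp_path / "order.beagle"
        fio.write_beagle_gl(lm, str(path))
        back = fio.read_beagle_gl(str(path))
        hom_ref = (gm.dosage == 0) & ~back.missing
        assert np.all(back.gl.argmax(axis=2)[hom_ref] == 0)

    @pytest.mark.parametrize("seed", range(3))
    def test_round_trip_within_1e9(self, seed, tmp_path, small_panels):
        lm = sd.genotypes_to_likelihoods(small_panels.gm, 6, 0.02, seed)
        path = tmp_path / "rt.beagle"
        fio.write_beagle_gl(lm, str(path))
        back = fio.read_beagle_gl(str(path))
        assert back.individuals == lm.individuals
        np.testing.assert_allclose(back.gl, lm.gl, atol=1e-9)

    def test_empty_matrix_header_only(self, tmp_path):
        lm = fio.LikelihoodMatrix(
            fio.SiteTable(np.array([], dtype=object), np.array([], dtype=np.int64),
                          np.array([], dtype=object), np.array([], dtype=object)),
            ["x"],
            np.zeros((0, 1, 3)),
        )
        path = tmp_path / "empty.beagle"
        fio.write_beagle_gl(lm, str(path))
        assert path.read_text().count("\n") == 1


class TestPanelsAndChromMap:
    def test_panel_roles_read(self, tmp_path):
        path = tmp_path / "panels.tsv"
        rows = ["id\trole\tsex"]
        rows += [f"A{i}\tparentA_ref\tmale" for i in range(3)]
        rows += [f"B{i}\tparentB_ref\tfemale" for i in range(3)]
        rows += ["h1\thybrid\tmale", "h2\thybrid\tfemale", "o1\toutgroup\tunknown",
                 "o2\toutgroup\tmale"]
        path.write_text("\n".join(rows) + "\n")
        panels = fio.read_panels(str(path))
        assert len(panels.parent_a) == 3 and len(panels.parent_b) == 3
        assert panels.hybrids == ["h1", "h2"]
        assert panels.sex["h2"] == "female"

    def test_unknown_role_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id\trole\tsex\nx\tparentC\tmale\n")
        with pytest.raises(fio.ValidationError):
            fio.read_panels(str(path))

    @pytest.mark.parametrize(
        "length,expected",
        [
            (45_000_000, "macro"),
            (40_000_000, "intermediate"),  # boundary goes to the smaller class
            (30_000_000, "intermediate"),
            (20_000_000, "micro"),
            (15_000_000, "micro"),
        ],
    )
    def test_size_classification(self, length, expected):
        assert fio.classify_size(length) == expected

    def test_chrom_map_round_trip_and_duplicates(self, tmp_path):
        cmap = fio.ChromosomeMap.from_lengths(
            {"chr1": 45_000_000, "chr2": 25_000_000, "chrZ": 72_000_000}, ["chrZ"]
        )
        path = tmp_path / "map.tsv"
        fio.write_chrom_map(cmap, str(path))
        back = fio.read_chrom_map(str(path))
        assert back.size_class("chr1") == "macro"
        assert back.is_sex_linked("chrZ") and not back.is_sex_linked("chr1")
        path.write_text("chrom\tlength\tsex_linked\nc1\t100\tfalse\nc1\t200\tfalse\n")
        with pytest.raises(fio.ValidationError):
            fio.read_chrom_map(str(path))

    def test_nonpositive_length_rejected(self):
        with pytest.raises(fio.ValidationError):
            fio.ChromosomeMap.from_lengths({"c": 0})
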