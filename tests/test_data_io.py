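import numpy as np
import pandas as pd
import pytest

from mlgwas import data_io
from mlgwas.data_io import (
    GenotypeDataset,
    GenotypeParseError,
    PhenotypeTable,
    align_samples,
    impute_missing,
    read_genotype,
    read_phenotype,
    read_square_matrix,
    write_genotype,
    write_results,
)
from mlgwas.simulate import SimSpec, simulate_genotypes


def _tiny_dataset():
    info = pd.DataFrame(
        {
            "name": ["m1", "m2", "m3", "m4", "m5"],
            "chrom": ["1", "1", "1", "2", "2"],
            "pos": [100, 200, 300, 100, 200],
            "major": ["A", "G", "C", "T", "A"],
            "minor": ["G", "A", "T", "C", "C"],
            "maf": [0.25, 0.375, 0.5, 0.125, 0.25],
        }
    )
    codes = np.array(
        [
            [1, 0, 1, 1, -1],
            [1, -1, -1, 1, 0],
            [0, 1, 0, 1, 1],
            [1, 0, 0, 0, 1],
        ],
        dtype=float,
    )
    return GenotypeDataset(
        individuals=["s1", "s2", "s3", "s4"], info=info, codes=codes
    )


class TestGenotypeReading:
    def test_hapmap_coding_convention(self, tmp_path):
        """AA/AG/GG with A more frequent codes to +1/0/-1."""
        path = tmp_path / "g.hmp.txt"
        header = "\t".join(data_io.HAPMAP_COLUMNS + ["i1", "i2", "i3"])
        row = "\t".join(
            ["rs1", "A/G", "1", "500", "+", "NA", "NA", "NA", "NA", "NA", "NA",
             "AA", "AG", "GG"]
        )
        path.write_text(header + "\n" + row + "\n")
        ds = read_genotype(str(path), "Hmp")
        assert np.array_equal(ds.codes[:, 0], [1.0, 0.0, -1.0])
        assert ds.info["major"].iat[0] == "A"
        assert ds.info["maf"].iat[0] == pytest.approx(3 / 6)

    def test_hapmap_allele_listing_is_irrelevant(self, tmp_path):
        """Flipping the alleles column never changes the codes (data decides)."""
        codes = {}
        for listed in ("A/G", "G/A"):
            path = tmp_path / f"g_{listed[0]}.txt"
            header = "\t".join(data_io.HAPMAP_COLUMNS + ["i1", "i2", "i3", "i4"])
            row = "\t".join(
                ["rs1", listed, "1", "500", "+"] + ["NA"] * 6 + ["AA", "AA", "AG", "GG"]
            )
            path.write_text(header + "\n" + row + "\n")
            codes[listed] = read_genotype(str(path), "Hmp").codes
        assert np.array_equal(codes["A/G"], codes["G/A"])

    def test_numeric_identity(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("rs,chr,pos,i1,i2,i3\nm1,1,100,1,-1,0\n")
        ds = read_genotype(str(path), "Num")
        assert np.array_equal(ds.codes[:, 0], [1.0, -1.0, 0.0])

    def test_unknown_token_names_row_and_column(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("rs,chr,pos,i1,i2\nm1,1,100,1,7\n")
        with pytest.raises(GenotypeParseError, match="m1.*i2"):
            read_genotype(str(path), "Num")

    def test_duplicate_marker_names_rejected(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("rs,chr,pos,i1\nm1,1,100,1\nm1,1,200,0\n")
        with pytest.raises(GenotypeParseError, match="duplicate"):
            read_genotype(str(path), "Num")

    def test_markers_sorted_by_position_within_chromosome(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text(
            "rs,chr,pos,i1\nm1,1,300,1\nm2,1,100,0\nm3,2,50,1\n"
        )
        ds = read_genotype(str(path), "Num")
        assert list(ds.info["name"]) == ["m2", "m1", "m3"]

    @pytest.mark.parametrize("fmt", ["Num", "Cha", "Hmp"])
    def test_roundtrip_all_dialects(self, fmt, tmp_path):
        """write(read(f)) reproduces the codes matrix bit-exactly."""
        ds = simulate_genotypes(SimSpec(n=20, m=100, chromosomes=2, seed=7))
        p1 = tmp_path / f"g1.{fmt}.csv"
        write_genotype(ds, str(p1), fmt)
        ds2 = read_genotype(str(p1), fmt)
        assert np.array_equal(ds.codes, ds2.codes)
        assert list(ds.info["name"]) == list(ds2.info["name"])
        p2 = tmp_path / f"g2.{fmt}.csv"
        write_genotype(ds2, str(p2), fmt)
        assert p1.read_text() == p2.read_text()


class TestPhenotype:
    def test_selector_and_rows(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("id,t1,t2\na,1.0,5\nb,2.0,6\nc,3.0,7\nd,4.5,8\n")
        tab = read_phenotype(str(path), [1])
        assert tab.traits == ["t1"]
        assert tab.values.shape == (4, 1)

    def test_out_of_range_selector(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("id,t1\na,1.0\n")
        with pytest.raises(ValueError, match="out of range"):
            read_phenotype(str(path), [2])

    def test_empty_selector(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("id,t1\na,1.0\n")
        with pytest.raises(ValueError, match="empty"):
            read_phenotype(str(path), [])

    def test_blank_cell_marks_missing(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("id,t1,t2\na,1.0,2\nb,,3\n")
        tab = read_phenotype(str(path), [1, 2])
        assert tab.missing.sum() == 1
        assert tab.missing[1, 0]

    def test_non_numeric_cell_reports_coordinates(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("id,t1\na,1.0\nb,oops\n")
        with pytest.raises(ValueError, match="row 3.*t1"):
            read_phenotype(str(path), [1])


class TestSquareMatrix:
    def test_identity_kinship(self, tmp_path):
        path = tmp_path / "k.csv"
        path.write_text("id,a,b\na,1,0\nb,0,1\n")
        ids, K = read_square_matrix(str(path), "kinship")
        assert ids == ["a", "b"]
        assert np.array_equal(K, np.eye(2))

    def test_asymmetric_kinship_rejected(self, tmp_path):
        path = tmp_path / "k.csv"
        path.write_text("id,a,b\na,1,0.5\nb,0.2,1\n")
        with pytest.raises(ValueError, match="symmetric"):
            read_square_matrix(str(path), "kinship")

    def test_q_matrix_drops_one_column(self, tmp_path):
        path = tmp_path / "q.csv"
        path.write_text("id,q1,q2,q3\na,0.2,0.3,0.5\nb,0.6,0.1,0.3\n")
        block = read_square_matrix(str(path), "structure", "Q")
        assert block.values.shape == (2, 2)
        assert block.labels == ["q1", "q2"]


class TestAlignImpute:
    def test_align_in_genotype_order(self):
        ds = _tiny_dataset()
        phe = PhenotypeTable(
            individuals=["s3", "s1", "s4", "s2"],
            traits=["t"],
            values=np.array([[3.0], [1.0], [4.0], [2.0]]),
        )
        bundle = align_samples(ds, phe)
        assert bundle.genotype.individuals == ["s1", "s2", "s3", "s4"]
        assert np.array_equal(bundle.phenotype.values[:, 0], [1, 2, 3, 4])

    def test_align_drops_missing_id(self):
        ds = _tiny_dataset()
        phe = PhenotypeTable(
            individuals=["s1", "s2", "s3"],
            traits=["t"],
            values=np.arange(3.0)[:, None],
        )
        bundle = align_samples(ds, phe)
        assert bundle.genotype.n == 3

    def test_align_idempotent(self):
        ds = _tiny_dataset()
        phe = PhenotypeTable(
            individuals=list(ds.individuals),
            traits=["t"],
            values=np.arange(4.0)[:, None],
        )
        b1 = align_samples(ds, phe)
        b2 = align_samples(b1.genotype, b1.phenotype)
        assert b2.genotype.individuals == b1.genotype.individuals
        assert np.array_equal(b2.genotype.codes, b1.genotype.codes)

    def test_disjoint_ids_error(self):
        ds = _tiny_dataset()
        phe = PhenotypeTable(
            individuals=["x1", "x2"], traits=["t"], values=np.zeros((2, 1))
        )
        with pytest.raises(ValueError, match="no common sample IDs"):
            align_samples(ds, phe)

    @pytest.mark.parametrize(
        "column,expected",
        [([1, 1, np.nan], 1.0), ([1, -1, np.nan], 0.0), ([0, 1, np.nan], 0.0)],
    )
    def test_impute_snaps_to_alphabet(self, column, expected):
        col = np.asarray(column, float)
        miss = ~np.isfinite(col)
        info = pd.DataFrame(
            {"name": ["m1"], "chrom": ["1"], "pos": [1], "major": ["A"],
             "minor": ["B"], "maf": [0.3]}
        )
        ds = GenotypeDataset(
            ["a", "b", "c"], info, np.where(miss, 0.0, col)[:, None], miss[:, None]
        )
        out = impute_missing(ds)
        assert out.codes[2, 0] == expected
        assert out.is_imputed

    def test_fully_missing_marker_is_error(self):
        info = pd.DataFrame(
            {"name": ["bad"], "chrom": ["1"], "pos": [1], "major": ["A"],
             "minor": ["B"], "maf": [0.0]}
        )
        ds = GenotypeDataset(
            ["a", "b"], info, np.zeros((2, 1)), np.ones((2, 1), bool)
        )
        with pytest.raises(ValueError, match="bad"):
            impute_missing(ds)


class TestWriteResults:
    def test_file_count_and_empty_table(self, tmp_path):
        qtns = pd.DataFrame(columns=data_io.FINAL_COLUMNS)
        results = {
            (t, m): {"qtns": qtns, "candidates": None}
            for t in ("t1", "t2")
            for m in ("mrMLM", "FASTmrMLM")
        }
        paths = write_results(results, str(tmp_path))
        files = list(tmp_path.glob("*.csv"))
        assert len(files) == 8  # 4 final + 4 intermediate
        header = open(paths[("t1", "mrMLM")]["final"]).readline().strip()
        assert header.split(",") == data_io.FINAL_COLUMNS

    def test_unwritable_dir_fails_fast(self, tmp_path):
        blocker = tmp_path / "not_a_dir"
        blocker.write_text("occupied")
        with pytest.raises(OSError):
            data_io.check_writable(str(blocker))
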