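import numpy as np
import pandas as pd
import pytest

from conjfdr.errors import ConfigurationError, InputError
from conjfdr.sumstats import (
    DEFAULT_EXCLUSION_REGIONS,
    GenomicRegion,
    apply_exclusion_regions,
    harmonize_pair,
    read_bed_regions,
    read_pair,
    read_sumstats,
    write_pair,
)


class TestReadSumstats:
    def test_all_valid_records_kept(self, sumstats_writer):
        path = sumstats_writer(
            "a.tsv",
            [("rs1", 1, 100, "A", "G", 0.5, 0.5),
             ("rs2", 1, 200, "C", "T", 1.0, 1.0),
             ("rs3", 2, 300, "G", "A", -2.0, 0.01)],
        )
        df = read_sumstats(path)
        assert len(df) == 3
        assert list(df.columns[:7]) == ["snp_id", "chrom", "pos", "a1", "a2", "z", "p"]

    def test_p_zero_is_dropped(self, sumstats_writer):
        path = sumstats_writer(
            "a.tsv",
            [("rs1", 1, 100, "A", "G", 0.5, 0.0),
             ("rs2", 1, 200, "C", "T", 1.0, 0.3)],
        )
        df = read_sumstats(path)
        assert list(df["snp_id"]) == ["rs2"]

    @pytest.mark.parametrize("bad_p", [-0.1, 1.5, "NA"])
    def test_invalid_p_dropped(self, sumstats_writer, bad_p):
        path = sumstats_writer(
            "a.tsv",
            [("rs1", 1, 100, "A", "G", 0.5, bad_p),
             ("rs2", 1, 200, "C", "T", 1.0, 0.3)],
        )
        assert list(read_sumstats(path)["snp_id"]) == ["rs2"]

    def test_non_acgt_alleles_dropped(self, sumstats_writer):
        # 10 records, 2 with non-nucleotide alleles -> 8 retained
        rows = [(f"rs{i}", 1, 100 * (i + 1), "A", "G", 0.1, 0.5) for i in range(8)]
        rows.append(("rsI", 1, 10_000, "I", "G", 0.1, 0.5))
        rows.append(("rsD", 1, 11_000, "A", "D", 0.1, 0.5))
        df = read_sumstats(sumstats_writer("a.tsv", rows))
        assert len(df) == 8

    def test_missing_mandatory_column_raises(self, sumstats_writer):
        path = sumstats_writer("a.tsv", [("rs1", 1, 100, "A", "G", 0.5, 0.5)])
        with pytest.raises(ConfigurationError):
            read_sumstats(path, column_map={"p": "PVALUE"})

    def test_zero_valid_records_raises(self, sumstats_writer):
        path = sumstats_writer("a.tsv", [("rs1", 1, 100, "A", "G", 0.5, 0.0)])
        with pytest.raises(InputError):
            read_sumstats(path)

    def test_duplicate_positions_keep_smallest_p(self, sumstats_writer):
        path = sumstats_writer(
            "a.tsv",
            [("rs1", 1, 100, "A", "G", 0.5, 0.5),
             ("rs1b", 1, 100, "A", "C", 3.0, 0.001)],
        )
        df = read_sumstats(path)
        assert list(df["snp_id"]) == ["rs1b"]

    def test_z_derived_from_beta_se(self, sumstats_writer):
        path = sumstats_writer(
            "a.tsv",
            [("rs1", 1, 100, "A", "G", 0.5, 0.1, 0.5)],
            header="SNP CHR BP A1 A2 BETA SE P",
        )
        df = read_sumstats(path)
        assert df["z"].iloc[0] == pytest.approx(5.0)

    def test_output_sorted_by_chrom_pos(self, sumstats_writer):
        path = sumstats_writer(
            "a.tsv",
            [("rs3", 10, 50, "A", "G", 0.1, 0.5),
             ("rs1", 2, 900, "A", "G", 0.1, 0.5),
             ("rs2", 2, 100, "A", "G", 0.1, 0.5)],
        )
        df = read_sumstats(path)
        assert list(df["snp_id"]) == ["rs2", "rs1", "rs3"]


def _table(rows):
    return pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "a1", "a2", "z", "p"]
    )


class TestHarmonize:
    def test_identical_alleles_keep_z2(self):
        a = _table([("rs1", "1", 100, "A", "G", 1.0, 0.3)])
        b = _table([("rs1", "1", 100, "A", "G", 1.7, 0.1)])
        m = harmonize_pair(a, b)
        assert m["z2"].iloc[0] == pytest.approx(1.7)

    def test_swapped_alleles_flip_z2(self):
        a = _table([("rs1", "1", 100, "A", "G", 1.0, 0.3)])
        b = _table([("rs1", "1", 100, "G", "A", 1.7, 0.1)])
        m = harmonize_pair(a, b)
        assert m["z2"].iloc[0] == pytest.approx(-1.7)

    def test_ambiguous_and_mismatched_dropped(self):
        # 10 shared positions: 1 strand-ambiguous A/T, 1 allele mismatch -> 8 kept
        rows_a, rows_b = [], []
        for i in range(8):
            rows_a.append((f"rs{i}", "1", 100 + i, "A", "G", 1.0, 0.5))
            rows_b.append((f"rs{i}", "1", 100 + i, "A", "G", 1.0, 0.5))
        rows_a.append(("rsAT", "1", 500, "A", "T", 1.0, 0.5))
        rows_b.append(("rsAT", "1", 500, "A", "T", 1.0, 0.5))
        rows_a.append(("rsMM", "1", 600, "A", "G", 1.0, 0.5))
        rows_b.append(("rsMM", "1", 600, "A", "C", 1.0, 0.5))
        m = harmonize_pair(_table(rows_a), _table(rows_b))
        assert len(m) == 8
        assert "rsAT" not in set(m["snp_id"])
        assert "rsMM" not in set(m["snp_id"])

    def test_empty_intersection_raises(self):
        a = _table([("rs1", "1", 100, "A", "G", 1.0, 0.3)])
        b = _table([("rs2", "2", 200, "A", "G", 1.0, 0.3)])
        with pytest.raises(InputError):
            harmonize_pair(a, b)

    def test_role_swap_symmetry(self):
        """Harmonizing (a,b) then swapping roles matches harmonizing (b,a)."""
        a = _table(
            [("rs1", "1", 100, "A", "G", 1.0, 0.3),
             ("rs2", "1", 200, "C", "T", -0.5, 0.7)]
        )
        b = _table(
            [("rs1", "1", 100, "G", "A", 1.7, 0.1),
             ("rs2", "1", 200, "C", "T", 0.2, 0.9)]
        )
        ab = harmonize_pair(a, b)
        ba = harmonize_pair(b, a)
        assert np.allclose(ab["z1"], ba["z2"] * np.where(ab["a1"] == ba["a1"], 1, -1))
        assert np.allclose(ab["p1"], ba["p2"])
        assert np.allclose(ab["p2"], ba["p1"])


class TestExclusionRegions:
    @pytest.mark.parametrize(
        "chrom,pos,removed",
        [
            ("6", 30_000_000, True),    # inside the HLA block
            ("17", 41_000_000, True),   # inside the MAPT block
            ("6", 25_119_105, False),   # one bp below the inclusive HLA start
            ("6", 25_119_106, True),    # exactly at the inclusive start
            ("17", 47_000_000, True),   # exactly at the inclusive end
            ("17", 47_000_001, False),
            ("1", 30_000_000, False),   # other chromosome untouched
        ],
    )
    def test_default_region_boundaries(self, chrom, pos, removed):
        pair = pd.DataFrame(
            {"snp_id": ["s"], "chrom": [chrom], "pos": [pos], "a1": "A",
             "a2": "G", "z1": 0.0, "p1": 0.5, "z2": 0.0, "p2": 0.5}
        )
        out = apply_exclusion_regions(pair)
        assert (len(out) == 0) == removed

    def test_idempotent_and_empty_region_noop(self, worked_pair):
        once = apply_exclusion_regions(worked_pair)
        twice = apply_exclusion_regions(once)
        pd.testing.assert_frame_equal(once, twice)
        pd.testing.assert_frame_equal(
            apply_exclusion_regions(worked_pair, []), worked_pair
        )

    def test_invalid_region_rejected(self):
        with pytest.raises(ConfigurationError):
            GenomicRegion("1", 10, 5)


def test_bed_regions_are_converted_to_1_based(tmp_path):
    bed = tmp_path / "r.bed"
    bed.write_text("chr6\t25119105\t33854733\n")
    (region,) = read_bed_regions(bed)
    assert (region.chrom, region.start, region.end) == ("6", 25119106, 33854733)


def test_pair_roundtrip_through_tsv(tmp_path, worked_pair):
    path = tmp_path / "pair.tsv"
    write_pair(worked_pair, path, header_lines=["lambda_trait1=1.0"])
    back = read_pair(path)
    pd.testing.assert_frame_equal(back, worked_pair, check_dtype=False)
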