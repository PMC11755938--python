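"""Chain parsing, point liftover, disease overlap and damage reports."""

import numpy as np
import pandas as pd
import pytest

import rviskit as rk
from rviskit.liftover import (ChainParseError, DamagingVariant, invert_chain,
                              lift_position, overlap_disease_variants,
                              parse_chain, rank_by_cadd, set_damage_report)
from rviskit.stats import GeneSet


def write_chain(path, text):
    path.write_text(text)
    return path


SIMPLE = """\
chain 100 chr1 1000 + 100 200 chr1 2000 + 1100 1200 1
100
"""

GAPPED = """\
chain 100 chr1 1000 + 100 300 chr1 2000 + 500 690 1
80 20 10
100
"""

MINUS = """\
chain 100 chr1 1000 + 100 200 chr1 500 - 0 100 1
100
"""


class TestParseChain:
    def test_single_block(self, tmp_path):
        idx = parse_chain(write_chain(tmp_path / "a.chain", SIMPLE))
        (block,) = idx.blocks["chr1"]
        assert (block.src_start, block.src_end) == (100, 200)
        assert (block.dst_start, block.dst_chrom) == (1100, "chr1")

    def test_gapped_chain_offsets_second_block(self, tmp_path):
        idx = parse_chain(write_chain(tmp_path / "g.chain", GAPPED))
        b1, b2 = idx.blocks["chr1"]
        # block 1: src [100,180) -> dst [500,580); then dt=20, dq=10
        assert (b1.src_start, b1.src_end, b1.dst_start) == (100, 180, 500)
        assert (b2.src_start, b2.src_end, b2.dst_start) == (200, 300, 590)

    def test_truncated_file_rejected(self, tmp_path):
        bad = "chain 100 chr1 1000 + 100 300 chr1 2000 + 500 690 1\n80 20 10\n"
        with pytest.raises(ChainParseError, match="truncated"):
            parse_chain(write_chain(tmp_path / "t.chain", bad))

    def test_arithmetic_mismatch_rejected(self, tmp_path):
        bad = "chain 100 chr1 1000 + 100 200 chr1 2000 + 1100 1201 1\n100\n"
        with pytest.raises(ChainParseError, match="chain 1"):
            parse_chain(write_chain(tmp_path / "m.chain", bad))

    def test_empty_file_rejected(self, tmp_path):
        with pytest.raises(ChainParseError, match="no chains"):
            parse_chain(write_chain(tmp_path / "e.chain", "\n"))


class TestLiftPosition:
    def test_identity_block(self, tmp_path):
        text = "chain 1 chr1 1000 + 100 200 chr1 1000 + 100 200 1\n100\n"
        idx = parse_chain(write_chain(tmp_path / "i.chain", text))
        assert lift_position(idx, "chr1", 150) == ("chr1", 150, "+")

    def test_offset_block(self, tmp_path):
        idx = parse_chain(write_chain(tmp_path / "o.chain", SIMPLE))
        # src [100,200) -> dst [1100,1200): 1-based 150 maps to 1150
        assert lift_position(idx, "chr1", 150) == ("chr1", 1150, "+")

    def test_outside_block_unmapped(self, tmp_path):
        idx = parse_chain(write_chain(tmp_path / "o.chain", SIMPLE))
        assert lift_position(idx, "chr1", 250) is None
        assert lift_position(idx, "chr1", 100) is None  # 0-based 99 < 100
        assert lift_position(idx, "chr9", 150) is None

    def test_gap_position_unmapped(self, tmp_path):
        idx = parse_chain(write_chain(tmp_path / "g.chain", GAPPED))
        assert lift_position(idx, "chr1", 190) is None  # inside dt gap
        assert lift_position(idx, "chr1", 150) == ("chr1", 550, "+")
        assert lift_position(idx, "chr1", 250) == ("chr1", 640, "+")

    def test_minus_strand_reflection(self, tmp_path):
        idx = parse_chain(write_chain(tmp_path / "m.chain", MINUS))
        # 0-based src 100 -> reversed dst 0 -> forward 500-1-0 = 499 (1-based 500)
        assert lift_position(idx, "chr1", 101) == ("chr1", 500, "-")
        assert lift_position(idx, "chr1", 200) == ("chr1", 401, "-")

    def test_highest_score_chain_wins(self, tmp_path):
        text = (
            "chain 50 chr1 1000 + 100 200 chr1 5000 + 100 200 1\n100\n\n"
            "chain 900 chr1 1000 + 100 200 chr1 5000 + 3100 3200 2\n100\n"
        )
        idx = parse_chain(write_chain(tmp_path / "two.chain", text))
        assert lift_position(idx, "chr1", 150) == ("chr1", 3150, "+")

    def test_round_trip_through_inverse(self, tmp_path, small_bundle):
        idx = parse_chain(small_bundle.chain)
        inv_path = tmp_path / "inverse.chain"
        invert_chain(small_bundle.chain, inv_path)
        inv = parse_chain(inv_path)
        rng = np.random.default_rng(0)
        n_checked = 0
        for _ in range(200):
            chrom = f"chr{int(rng.integers(1, 5))}"
            pos = int(rng.integers(1, 20_000))
            fwd = lift_position(idx, chrom, pos)
            if fwd is None:
                continue
            back = lift_position(inv, fwd[0], fwd[1])
            assert back == (chrom, pos, "+")
            n_checked += 1
        assert n_checked > 50


def dmg(chrom="chr1", pos=150, ref="A", alt="G", gene="G1", cadd=None):
    return DamagingVariant(chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                           polyphen_damaging=True, cadd=cadd)


class TestOverlap:
    def catalog(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "disease"])

    def test_empty_damaging_list(self, tmp_path):
        idx = parse_chain(write_chain(tmp_path / "s.chain", SIMPLE))
        out = overlap_disease_variants([], idx, self.catalog([]))
        assert len(out) == 0

    def test_single_constructed_match_requires_alleles(self, tmp_path):
        idx = parse_chain(write_chain(tmp_path / "s.chain", SIMPLE))
        catalog = self.catalog(
            [("chr1", 1150, "A", "G", "ASD"), ("chr1", 1160, "C", "T", "ID")]
        )
        out = overlap_disease_variants([dmg(pos=150)], idx, catalog)
        assert len(out) == 1
        assert out.iloc[0]["disease"] == "ASD"
        # same position, different allele: no match
        out2 = overlap_disease_variants([dmg(pos=150, alt="T")], idx, catalog)
        assert len(out2) == 0

    def test_planted_matches_recovered_exactly(self, small_bundle):
        import json
        from rviskit.liftover import read_damaging_table, read_disease_catalog

        idx = parse_chain(small_bundle.chain)
        damaging = read_damaging_table(small_bundle.damaging_variants)
        disease = read_disease_catalog(small_bundle.disease_variants)
        out = overlap_disease_variants(damaging, idx, disease)
        meta = json.loads(small_bundle.metadata.read_text())
        assert len(out) == meta["n_planted_disease_matches"]


class TestDamageReport:
    def test_proportions_and_rounding(self):
        sets = [GeneSet("S", frozenset(f"g{i}" for i in range(16)))]
        damaging = [dmg(gene="g0")]
        report = set_damage_report(sets, damaging)
        row = report.iloc[0]
        assert row["n_genes_in_db"] == 16 and row["n_genes_with_damaging"] == 1
        assert row["proportion_pct"] == 6.3  # 6.25 rounds half-up

    def test_no_damaged_genes_is_zero(self):
        report = set_damage_report([GeneSet("S", frozenset(["a", "b"]))], [])
        assert report.iloc[0]["proportion_pct"] == 0.0

    def test_duplicated_variants_leave_report_unchanged(self):
        sets = [GeneSet("S", frozenset(["a", "b", "c"]))]
        base = [dmg(gene="a"), dmg(gene="b", pos=200)]
        r1 = set_damage_report(sets, base)
        r2 = set_damage_report(sets, base * 3)
        pd.testing.assert_frame_equal(r1, r2)


class TestCaddRanking:
    def test_descending_with_top_n(self):
        variants = [dmg(pos=1, cadd=45.0), dmg(pos=2, cadd=40.0),
                    dmg(pos=3, cadd=37.0)]
        out = rank_by_cadd(variants, top_n=2)
        assert list(out["cadd"]) == [45.0, 40.0]

    def test_tie_broken_by_position(self):
        variants = [dmg(pos=100, cadd=35.0), dmg(pos=50, cadd=35.0)]
        out = rank_by_cadd(variants)
        assert list(out["pos"]) == [50, 100]

    def test_unscored_variants_excluded(self):
        out = rank_by_cadd([dmg(pos=1, cadd=30.0), dmg(pos=2)])
        assert len(out) == 1

    def test_no_cadd_at_all_errors(self):
        with pytest.raises(ValueError, match="CADD"):
            rank_by_cadd([dmg()])

    def test_matches_independent_sort(self):
        rng = np.random.default_rng(7)
        variants = [
            dmg(chrom=f"chr{int(rng.integers(1, 4))}", pos=int(p),
                cadd=float(c))
            for p, c in zip(rng.integers(1, 10_000, 100),
                            rng.uniform(10, 50, 100))
        ]
        out = rank_by_cadd(variants, top_n=100)
        expected = sorted(
            variants,
            key=lambda d: (-d.cadd, int(d.chrom[3:]), d.pos),
        )
        assert list(out["cadd"]) == [d.cadd for d in expected]


def test_damaging_variant_requires_a_source_flag():
    with pytest.raises(ValueError, match="source flag"):
        DamagingVariant(chrom="chr1", pos=1, ref="A", alt="G", gene="g")
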