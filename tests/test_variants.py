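"""Variant ingestion, MAF stratification, sharing tables, pooled-design arithmetic."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ucevar import (
    FrequencyClass,
    GenomicInterval,
    IntervalSet,
    PoolDesign,
    VariantRecord,
    VariantSet,
    classify_maf,
    intersect_callsets,
    per_allele_coverage,
    read_vcf_snvs,
    sharing_table,
    snv_rate,
    write_vcf,
)
from ucevar.errors import DataError

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1,length=100000>\n"
    "##contig=<ID=chr2,length=100000>\n"
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def make_vcf(tmp_path, body, name="x.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + body)
    return path


# ---------------------------------------------------------------------------
# classify_maf
# ---------------------------------------------------------------------------

class TestClassifyMaf:
    @pytest.mark.parametrize(
        "maf,expected",
        [
            (0.004, FrequencyClass.RARE),
            (0.06, FrequencyClass.PREVALENT),
            (0.02, FrequencyClass.INTERMEDIATE),
            (0.005, FrequencyClass.INTERMEDIATE),  # boundary closed into middle
            (0.05, FrequencyClass.INTERMEDIATE),
            (0.0, FrequencyClass.RARE),
            (0.5, FrequencyClass.PREVALENT),
        ],
    )
    def test_thresholds(self, maf, expected):
        assert classify_maf(maf) is expected

    def test_out_of_range_errors(self):
        with pytest.raises(DataError):
            classify_maf(0.6)
        with pytest.raises(DataError):
            classify_maf(-0.01)

    @given(st.floats(min_value=0.0, max_value=0.5, allow_nan=False))
    @settings(derandomize=True, max_examples=200)
    def test_partitions_valid_range(self, maf):
        assert classify_maf(maf) in set(FrequencyClass)


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

class TestReadVcf:
    def test_af_folding(self, tmp_path):
        path = make_vcf(tmp_path, "chr1\t101\t.\tA\tC\t.\t.\tAF=0.96\n")
        (rec,) = list(read_vcf_snvs(path))
        assert rec.maf == pytest.approx(0.04)
        assert rec.pos == 100  # converted to 0-based

    def test_multiallelic_decomposition(self, tmp_path):
        path = make_vcf(tmp_path, "chr1\t101\t.\tA\tC,T\t.\t.\tAF=0.01,0.30\n")
        recs = sorted(read_vcf_snvs(path), key=lambda r: r.alt)
        assert [(r.alt, r.maf) for r in recs] == [("C", pytest.approx(0.01)),
                                                  ("T", pytest.approx(0.30))]

    def test_indels_excluded_and_missing_af_skipped(self, tmp_path):
        body = (
            "chr1\t101\t.\tA\tC\t.\t.\tAF=0.1\n"
            "chr1\t201\t.\tAT\tA\t.\t.\tAF=0.1\n"  # indel
            "chr1\t301\t.\tG\tGA\t.\t.\tAF=0.1\n"  # insertion
            "chr1\t401\t.\tG\tT\t.\t.\t.\n"  # no AF
        )
        vs = read_vcf_snvs(make_vcf(tmp_path, body))
        assert {(r.chrom, r.pos) for r in vs} == {("chr1", 100)}

    def test_region_filter_keeps_hand_counted_subset(self, tmp_path):
        # 10 SNVs at 1-based positions 101..1001; region covers 0-based [300, 601)
        body = "".join(
            f"chr1\t{p}\t.\tA\tG\t.\t.\tAF=0.2\n" for p in range(101, 1102, 100)
        )
        region = IntervalSet([GenomicInterval("chr1", 300, 601)])
        vs = read_vcf_snvs(make_vcf(tmp_path, body), region_filter=region)
        assert {r.pos for r in vs} == {300, 400, 500, 600}

    def test_round_trip_preserves_keys_and_mafs(self, tmp_path, rng):
        records = [
            VariantRecord("chr1", int(p), "A", alt, float(m), "POP")
            for p, alt, m in zip(
                rng.choice(10_000, size=50, replace=False),
                rng.choice(["C", "G", "T"], size=50),
                rng.uniform(0.001, 0.5, size=50),
            )
        ]
        vs = VariantSet(records, provenance="POP")
        path = tmp_path / "rt.vcf"
        write_vcf(vs, path, contigs={"chr1": 100_000})
        back = read_vcf_snvs(path, population="POP")
        assert back.keys() == vs.keys()
        for k in vs.keys():
            assert back.get(k).maf == pytest.approx(vs.get(k).maf, abs=1e-6)


# ---------------------------------------------------------------------------
# VariantSet consistency
# ---------------------------------------------------------------------------

class TestVariantSet:
    def test_duplicate_key_rejected(self):
        r = VariantRecord("chr1", 5, "A", "C", 0.1)
        with pytest.raises(DataError, match="duplicate"):
            VariantSet([r, r])

    def test_ref_mismatch_at_same_site_rejected(self):
        with pytest.raises(DataError, match="reference mismatch"):
            VariantSet([VariantRecord("chr1", 5, "A", "C", 0.1),
                        VariantRecord("chr1", 5, "G", "T", 0.1)])

    def test_record_validation(self):
        with pytest.raises(DataError):
            VariantRecord("chr1", 5, "A", "A", 0.1)
        with pytest.raises(DataError):
            VariantRecord("chr1", 5, "A", "C", 0.7)


# ---------------------------------------------------------------------------
# intersect_callsets
# ---------------------------------------------------------------------------

def _set(keys, maf, name):
    return VariantSet(
        [VariantRecord("chr1", p, "A", a, maf, name) for p, a in keys], provenance=name
    )


class TestIntersectCallsets:
    def test_identical_sets(self):
        keys = [(i, "C") for i in range(5)]
        a, b = _set(keys, 0.1, "a"), _set(keys, 0.2, "b")
        consensus, xa, xb = intersect_callsets(a, b)
        assert consensus.keys() == a.keys() and (xa, xb) == (0, 0)

    def test_disjoint_sets(self):
        a = _set([(i, "C") for i in range(3)], 0.1, "a")
        b = _set([(i, "C") for i in range(10, 13)], 0.1, "b")
        consensus, xa, xb = intersect_callsets(a, b)
        assert len(consensus) == 0 and (xa, xb) == (3, 3)

    def test_partial_overlap_counts_and_maf_provenance(self):
        a = _set([(i, "C") for i in range(10)], 0.1, "a")
        b = _set([(i, "C") for i in range(3, 13)], 0.3, "b")
        consensus, xa, xb = intersect_callsets(a, b)
        assert len(consensus) == 7 and (xa, xb) == (3, 3)
        assert all(r.maf == 0.1 for r in consensus)  # frequencies follow argument a

    def test_membership_commutative(self):
        a = _set([(i, "C") for i in range(10)], 0.1, "a")
        b = _set([(i, "C") for i in range(5, 15)], 0.3, "b")
        ab, _, _ = intersect_callsets(a, b)
        ba, _, _ = intersect_callsets(b, a)
        assert ab.keys() == ba.keys()


# ---------------------------------------------------------------------------
# sharing_table
# ---------------------------------------------------------------------------

class TestSharingTable:
    def test_identical_sets_one_cell(self):
        keys = [(i, "C") for i in range(8)]
        tab = sharing_table([_set(keys, 0.1, "x"), _set(keys, 0.1, "y")])
        assert len(tab) == 1
        assert tab.iloc[0]["count"] == 8 and tab.iloc[0]["x"] and tab.iloc[0]["y"]

    def test_disjoint_sets_singletons_only(self):
        sets = [_set([(i + 10 * j, "C") for i in range(3)], 0.1, f"s{j}")
                for j in range(3)]
        tab = sharing_table(sets)
        assert len(tab) == 3 and set(tab["count"]) == {3}
        assert (tab[[f"s{j}" for j in range(3)]].sum(axis=1) == 1).all()

    def test_cells_match_brute_force_tally_and_sum_to_union(self, rng):
        sets = [
            _set([(int(p), "C") for p in rng.choice(60, size=30, replace=False)],
                 0.1, f"s{j}")
            for j in range(3)
        ]
        tab = sharing_table(sets)
        union = set().union(*(s.keys() for s in sets))
        assert tab["count"].sum() == len(union)
        tally: dict[tuple, int] = {}
        for k in union:
            pat = tuple(k in s.keys() for s in sets)
            tally[pat] = tally.get(pat, 0) + 1
        for _, row in tab.iterrows():
            pat = tuple(bool(row[f"s{j}"]) for j in range(3))
            assert tally[pat] == row["count"]

    def test_needs_two_sets(self):
        with pytest.raises(DataError):
            sharing_table([_set([(1, "C")], 0.1, "only")])


# ---------------------------------------------------------------------------
# rates and pooled-design arithmetic
# ---------------------------------------------------------------------------

class TestRates:
    def test_rate_unit_case(self):
        assert snv_rate(10, 1_000_000, 10) == pytest.approx(1.0)

    def test_zero_snvs(self):
        assert snv_rate(0, 1_000_000, 10) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(DataError):
            snv_rate(10, 0, 10)
        with pytest.raises(DataError):
            snv_rate(10, 1e6, 0)

    def test_zero_coverage(self):
        assert per_allele_coverage(PoolDesign(100, 10, 0.0)) == 0.0

    def test_zero_pools_rejected(self):
        with pytest.raises(DataError):
            PoolDesign(100, 0, 10.0)

    def test_per_allele_formula(self):
        # 100 samples in 10 pools at 200x per pool: 200 / (2 * 10) = 10 per allele
        assert per_allele_coverage(PoolDesign(100, 10, 200.0)) == pytest.approx(10.0)
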