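"""Score tracks, G/C-matched sampling, ECDF bands, KS, positions, flanks."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ucevar import (
    BaseComposition,
    GenomicInterval,
    IntervalSet,
    PositionList,
    ScoreTrack,
    VariantRecord,
    VariantSet,
    ecdf_band,
    extract_scores,
    flank_scores,
    gc_matched_sample,
    ks_compare,
    relative_positions,
)
from ucevar.errors import DataError


def track_from_values(values, chrom="c", start=0):
    return ScoreTrack.from_segments([(chrom, start, np.asarray(values, dtype=float))])


# ---------------------------------------------------------------------------
# ScoreTrack I/O and lookup
# ---------------------------------------------------------------------------

class TestScoreTrack:
    def test_lookup_identity(self):
        t = track_from_values([1.0, 2.37, -0.5], start=10)
        vals, found = t.lookup([("c", 11)])
        assert found.all() and vals[0] == pytest.approx(2.37)

    def test_missing_position_is_explicit(self):
        t = track_from_values([1.0], start=10)
        vals, found = t.lookup([("c", 99), ("c", 10)])
        assert found.tolist() == [False, True]
        assert np.isnan(vals[0])

    def test_bedgraph_and_wiggle_agree(self, tmp_path):
        bg = tmp_path / "t.bedGraph"
        bg.write_text("c\t5\t8\t1.5\nc\t8\t10\t-2.0\n")
        wig = tmp_path / "t.wig"
        wig.write_text("fixedStep chrom=c start=6 step=1\n1.5\n1.5\n1.5\n-2.0\n-2.0\n")
        q = [("c", p) for p in range(5, 10)]
        vb, _ = ScoreTrack.from_bedgraph(bg).lookup(q)
        vw, _ = ScoreTrack.from_wiggle(wig).lookup(q)
        assert np.allclose(vb, vw)

    def test_bedgraph_round_trip(self, tmp_path, rng):
        t = track_from_values(rng.normal(size=200).round(3), start=50)
        path = tmp_path / "rt.bedGraph"
        t.write_bedgraph(path)
        back = ScoreTrack.from_bedgraph(path)
        q = [("c", p) for p in range(50, 250)]
        va, _ = t.lookup(q)
        vb, _ = back.lookup(q)
        assert np.allclose(va, vb)


class TestExtractScores:
    def test_lookup_matches_array_oracle(self, rng):
        values = rng.normal(size=1000)
        t = track_from_values(values)
        pos = rng.integers(0, 1000, size=100)
        scores, missing = extract_scores([("c", int(p)) for p in pos], t)
        assert len(missing) == 0
        assert np.allclose(scores, values[pos])  # order-preserving

    def test_empty_query(self):
        scores, missing = extract_scores(PositionList.empty(), track_from_values([1.0]))
        assert len(scores) == 0 and len(missing) == 0

    def test_all_missing_errors(self):
        with pytest.raises(DataError):
            extract_scores([("c", 500)], track_from_values([1.0]))

    def test_missing_reported_separately(self):
        t = track_from_values([1.0, 2.0])
        scores, missing = extract_scores([("c", 0), ("zzz", 5), ("c", 1)], t)
        assert np.isnan(scores[1]) and list(missing) == [("zzz", 5)]


# ---------------------------------------------------------------------------
# G/C-matched sampling
# ---------------------------------------------------------------------------

def reference_with_composition(n_gc, n_at):
    seq = np.array([b"G"] * n_gc + [b"A"] * n_at, dtype="S1")
    universe = IntervalSet([GenomicInterval("c", 0, n_gc + n_at)])
    return {"c": seq}, universe


class TestGcMatchedSample:
    def test_pure_gc_target(self):
        ref, uni = reference_with_composition(50, 50)
        pl = gc_matched_sample(uni, ref, BaseComposition(1.0), n=10, seed=0)
        assert len(pl) == 10 and (pl.pos < 50).all()

    def test_n_zero_empty(self):
        ref, uni = reference_with_composition(5, 5)
        assert len(gc_matched_sample(uni, ref, BaseComposition(0.5), n=0, seed=0)) == 0

    def test_stratum_counts_exact_every_draw(self):
        """A 60/40 target with n=1000 yields exactly 600 G/C positions, each draw."""
        ref, uni = reference_with_composition(2000, 2000)
        for seed in range(20):
            pl = gc_matched_sample(uni, ref, BaseComposition(0.6), n=1000, seed=seed)
            assert int((pl.pos < 2000).sum()) == 600

    def test_no_repeats_within_draw_and_seed_reproducible(self):
        ref, uni = reference_with_composition(100, 100)
        a = gc_matched_sample(uni, ref, BaseComposition(0.5), n=80, seed=3)
        b = gc_matched_sample(uni, ref, BaseComposition(0.5), n=80, seed=3)
        assert len(set(a.pos.tolist())) == 80
        assert a.pos.tolist() == b.pos.tolist()

    def test_insufficient_stratum_names_it(self):
        ref, uni = reference_with_composition(3, 100)
        with pytest.raises(DataError, match="G/C"):
            gc_matched_sample(uni, ref, BaseComposition(0.9), n=50, seed=0)

    def test_composition_from_bases(self):
        comp = BaseComposition.from_bases(np.array([b"G", b"C", b"A", b"T"], dtype="S1"))
        assert comp.gc == pytest.approx(0.5) and comp.at == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# ECDF band
# ---------------------------------------------------------------------------

class TestEcdfBand:
    def test_ecdf_is_one_at_sample_maximum(self, rng):
        band = ecdf_band(rng.normal(size=50), B=200, seed=0)
        assert band.evaluate(band.sample.max()) == pytest.approx(1.0)

    def test_degenerate_single_value_collapses_to_step(self):
        band = ecdf_band([2.0, 2.0, 2.0], B=100, seed=0)
        assert band.evaluate(1.9) == 0.0 and band.evaluate(2.0) == 1.0

    @given(st.integers(0, 1000))
    @settings(derandomize=True, max_examples=20)
    def test_envelope_contains_point_ecdf(self, seed):
        rng = np.random.default_rng(seed)
        band = ecdf_band(rng.normal(size=40), B=100, seed=seed)
        assert (band.lower <= band.ecdf + 1e-12).all()
        assert (band.ecdf <= band.upper + 1e-12).all()
        assert (np.diff(band.ecdf) >= 0).all()

    def test_parameter_validation(self):
        with pytest.raises(DataError):
            ecdf_band([1.0], B=100)
        with pytest.raises(DataError):
            ecdf_band([1.0, 2.0], B=10)


# ---------------------------------------------------------------------------
# KS comparison
# ---------------------------------------------------------------------------

class TestKsCompare:
    def test_identical_samples(self, rng):
        x = rng.normal(size=30)
        res = ks_compare(x, x)
        assert res.statistic == pytest.approx(0.0)

    def test_complete_separation(self):
        res = ks_compare([0, 0, 0], [1, 1, 1])
        assert res.statistic == pytest.approx(1.0)

    def test_symmetric(self, rng):
        a, b = rng.normal(size=50), rng.normal(1.0, size=60)
        ra, rb = ks_compare(a, b), ks_compare(b, a)
        assert ra.statistic == pytest.approx(rb.statistic)
        assert ra.pvalue == pytest.approx(rb.pvalue)

    def test_statistic_matches_brute_force_sup(self, rng):
        a, b = rng.normal(size=200), rng.normal(0.3, 1.2, size=200)
        res = ks_compare(a, b)
        grid = np.concatenate([a, b])
        ecdf_a = np.searchsorted(np.sort(a), grid, side="right") / len(a)
        ecdf_b = np.searchsorted(np.sort(b), grid, side="right") / len(b)
        assert res.statistic == pytest.approx(np.abs(ecdf_a - ecdf_b).max())

    def test_empty_sample_rejected(self):
        with pytest.raises(DataError):
            ks_compare([], [1.0])


# ---------------------------------------------------------------------------
# relative positions
# ---------------------------------------------------------------------------

class TestRelativePositions:
    elements = IntervalSet([GenomicInterval("c", 1000, 1200)])

    def percent_of(self, pos, elements=None):
        df = relative_positions(PositionList.from_pairs([("c", pos)]),
                                elements or self.elements)
        return df.iloc[0]

    def test_interior_midpoint(self):
        assert self.percent_of(1100)["percent"] == pytest.approx(50.0)

    def test_first_base_is_zero(self):
        row = self.percent_of(1000)
        assert row["percent"] == 0.0 and row["region"] == "inside"

    def test_upstream_flank_scaling(self):
        row = self.percent_of(950)
        assert row["percent"] == pytest.approx(-25.0)
        assert row["region"] == "upstream"

    def test_downstream_flank_scaling(self):
        row = self.percent_of(1250)
        assert row["percent"] == pytest.approx(125.0)
        assert row["region"] == "downstream"

    def test_flank_range_bounds(self):
        elements = IntervalSet([GenomicInterval("c", 1000, 1200)])
        for pos, expected in [(800, -100.0), (1399, 199.5)]:
            assert self.percent_of(pos, elements)["percent"] == pytest.approx(expected)

    def test_too_far_errors(self):
        with pytest.raises(DataError, match="farther"):
            self.percent_of(700)

    def test_ambiguous_flank_assigned_to_nearer_element(self):
        elements = IntervalSet([GenomicInterval("c", 1000, 1100),
                                GenomicInterval("c", 1200, 1300)])
        # distances measured from the last base of the left element (1099) and
        # the first base of the right element (1200)
        left = relative_positions(PositionList.from_pairs([("c", 1140)]), elements)
        right = relative_positions(PositionList.from_pairs([("c", 1160)]), elements)
        assert left.iloc[0]["host_start"] == 1000 and left.iloc[0]["region"] == "downstream"
        assert right.iloc[0]["host_start"] == 1200 and right.iloc[0]["region"] == "upstream"

    def test_exact_tie_goes_to_upstream_element(self):
        # odd-width gap so an exact midpoint exists: pos 1150 is 51 bases from
        # both elements; the upstream (leftward) element hosts it
        elements = IntervalSet([GenomicInterval("c", 1000, 1100),
                                GenomicInterval("c", 1201, 1301)])
        tie = relative_positions(PositionList.from_pairs([("c", 1150)]), elements)
        assert tie.iloc[0]["host_start"] == 1000
        assert tie.iloc[0]["region"] == "downstream"

    def test_variants_accepted_directly(self):
        vs = VariantSet([VariantRecord("c", 1100, "A", "G", 0.1)])
        df = relative_positions(vs, self.elements)
        assert df.iloc[0]["percent"] == pytest.approx(50.0)


# ---------------------------------------------------------------------------
# flank windows
# ---------------------------------------------------------------------------

class TestFlankScores:
    def test_window_positions_exclude_variant_base(self):
        values = np.arange(200, dtype=float)  # score == position
        t = track_from_values(values)
        pl = PositionList.from_pairs([("c", 100)])
        fl = flank_scores(pl, t, window=3)
        assert sorted(fl.upstream.tolist()) == [97.0, 98.0, 99.0]
        assert sorted(fl.downstream.tolist()) == [101.0, 102.0, 103.0]

    def test_window_zero_rejected(self):
        with pytest.raises(DataError):
            flank_scores(PositionList.from_pairs([("c", 5)]), track_from_values([1.0]), 0)

    def test_pooled_sample_size_without_truncation(self, rng):
        t = track_from_values(rng.normal(size=1000))
        pos = rng.integers(10, 990, size=40)
        pl = PositionList.from_pairs([("c", int(p)) for p in pos])
        fl = flank_scores(pl, t, window=3)
        assert len(fl.upstream) == 3 * 40 and len(fl.downstream) == 3 * 40
        assert fl.n_missing_upstream == 0 and fl.n_missing_downstream == 0

    def test_out_of_domain_bases_dropped_and_counted(self):
        t = track_from_values([0.0, 1.0, 2.0, 3.0, 4.0])
        fl = flank_scores(PositionList.from_pairs([("c", 1)]), t, window=3)
        assert len(fl.upstream) == 1  # only position 0 exists upstream
        assert fl.n_missing_upstream == 2
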