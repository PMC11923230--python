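"""GC-MS peak filtering, Kovats calibration and quantification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from floralshift import volatiles as vol


def peak(sample="s1", rt=10.0, area=5e5, hits=("x", "y", "z"), is_blank=False):
    return vol.PeakRecord(sample, rt, area, hits, is_blank)


CFG = vol.FilterConfig()


class TestValidation:
    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            peak(area=-1.0)

    def test_negative_or_nonfinite_retention_rejected(self):
        with pytest.raises(ValueError):
            peak(rt=-0.1)
        with pytest.raises(ValueError):
            peak(rt=float("nan"))

    def test_hits_must_be_three(self):
        with pytest.raises(ValueError):
            vol.PeakRecord("s", 1.0, 1.0, ("a", "b"))


class TestAreaAndRetentionFilters:
    @pytest.mark.parametrize(
        "area,kept",
        [(9.9e4, False), (1e5, True), (1.1e5, True)],
    )
    def test_area_threshold_is_strict_below(self, area, kept):
        out = vol.filter_area([peak(area=area)], CFG)
        assert (len(out) == 1) is kept

    @pytest.mark.parametrize("rt,kept", [(30.01, False), (30.00, True), (5.0, True)])
    def test_retention_excludes_strictly_after_30_min(self, rt, kept):
        out = vol.filter_retention([peak(rt=rt)], CFG)
        assert (len(out) == 1) is kept

    def test_area_filter_matches_brute_force_scan(self):
        rng = np.random.default_rng(11)
        peaks = [peak(area=a) for a in rng.uniform(1e4, 1e6, size=100)]
        kept = vol.filter_area(peaks, CFG)
        assert len(kept) == sum(p.area >= CFG.min_area for p in peaks)
        assert kept == [p for p in peaks if p.area >= CFG.min_area]  # order preserved

    def test_retention_filter_matches_brute_force_scan(self):
        rng = np.random.default_rng(12)
        peaks = [peak(rt=t) for t in rng.uniform(0, 60, size=100)]
        assert vol.filter_retention(peaks, CFG) == [
            p for p in peaks if p.retention_time <= CFG.max_retention
        ]


class TestBlankFilter:
    def test_removed_when_under_fivefold_of_matching_blank(self):
        sample = peak(rt=10.00, area=4e5, hits=("α-pinene", "b", "c"))
        blank = peak("bl", rt=10.05, area=1e5, hits=("α-pinene", "d", "e"), is_blank=True)
        kept, removed = vol.filter_blank_matched([sample], [blank], CFG)
        assert kept == [] and removed == [(sample, blank)]

    def test_retained_at_or_above_fivefold(self):
        sample = peak(rt=10.00, area=6e5, hits=("α-pinene", "b", "c"))
        blank = peak("bl", rt=10.05, area=1e5, hits=("α-pinene", "d", "e"), is_blank=True)
        kept, removed = vol.filter_blank_matched([sample], [blank], CFG)
        assert kept == [sample] and removed == []

    def test_no_match_outside_rt_window_or_different_hit(self):
        blank = peak("bl", rt=10.0, area=1e5, hits=("α-pinene", "d", "e"), is_blank=True)
        far = peak(rt=10.2, area=4e5, hits=("α-pinene", "b", "c"))
        other = peak(rt=10.0, area=4e5, hits=("myrcene", "b", "c"))
        kept, removed = vol.filter_blank_matched([far, other], [blank], CFG)
        assert kept == [far, other]

    def test_empty_blank_set_warns_and_retains_all(self):
        peaks = [peak(), peak(rt=12.0)]
        with pytest.warns(UserWarning, match="blank"):
            kept, removed = vol.filter_blank_matched(peaks, [], CFG)
        assert kept == peaks and removed == []

    def test_matches_all_pairs_brute_force_oracle(self):
        rng = np.random.default_rng(13)
        vocab = ["a", "b", "c", "d"]
        samples = [
            peak(rt=float(rng.uniform(5, 15)), area=float(rng.uniform(1e5, 1e6)),
                 hits=tuple(rng.choice(vocab, size=3)))
            for _ in range(60)
        ]
        blanks = [
            peak("bl", rt=float(rng.uniform(5, 15)), area=float(rng.uniform(1e5, 5e5)),
                 hits=tuple(rng.choice(vocab, size=3)), is_blank=True)
            for _ in range(20)
        ]
        kept, removed = vol.filter_blank_matched(samples, blanks, CFG)
        # oracle: O(n*m) scan over every sample-blank pair
        expected_removed = set()
        for i, s in enumerate(samples):
            for b in blanks:
                if (
                    s.top_hit == b.top_hit
                    and abs(s.retention_time - b.retention_time) <= CFG.blank_rt_window
                    and s.area < CFG.blank_fold * b.area
                ):
                    expected_removed.add(i)
                    break
        assert {samples.index(p) for p, _ in removed} == expected_removed
        assert len(kept) + len(removed) == len(samples)


class TestContaminantFilter:
    def test_all_three_contaminated_removed(self):
        p = peak(hits=("hexamethylcyclotrisiloxane", "siloxane X", "dibutyl phthalate"))
        assert vol.filter_contaminants([p], CFG) == []

    def test_one_clean_hit_retains(self):
        p = peak(hits=("siloxane A", "siloxane B", "β-myrcene"))
        assert vol.filter_contaminants([p], CFG) == [p]

    def test_matches_forall_enumeration_oracle(self):
        rng = np.random.default_rng(14)
        dirty = ["siloxane A", "silicic acid", "dibutyl phthalate"]
        clean = ["myrcene", "linalool"]
        vocab = dirty + clean
        terms = CFG.contaminant_terms
        peaks = [peak(hits=tuple(rng.choice(vocab, size=3))) for _ in range(200)]
        kept = vol.filter_contaminants(peaks, CFG)
        expected = [
            p
            for p in peaks
            if not all(any(t in h.lower() for t in terms) for h in p.library_hits)
        ]
        assert kept == expected


class TestCascade:
    def test_equals_joint_four_predicate_oracle(self):
        # each predicate depends only on the peak and the fixed blank table,
        # so the cascade equals the conjunction regardless of stage order
        rng = np.random.default_rng(15)
        vocab = ["a", "b", "siloxane A", "silicic acid", "dibutyl phthalate"]
        for _ in range(50):
            samples = [
                peak(
                    rt=float(rng.uniform(0, 40)),
                    area=float(rng.uniform(1e4, 1e6)),
                    hits=tuple(rng.choice(vocab, size=3)),
                )
                for _ in range(30)
            ]
            blanks = [
                peak("bl", rt=float(rng.uniform(0, 40)), area=float(rng.uniform(1e4, 5e5)),
                     hits=tuple(rng.choice(vocab, size=3)), is_blank=True)
                for _ in range(10)
            ]
            got = vol.filter_cascade(samples, blanks, CFG)

            def blank_matched(s):
                return any(
                    s.top_hit == b.top_hit
                    and abs(s.retention_time - b.retention_time) <= CFG.blank_rt_window
                    and s.area < CFG.blank_fold * b.area
                    for b in blanks
                )

            def contaminated(s):
                return all(
                    any(t in h.lower() for t in CFG.contaminant_terms)
                    for h in s.library_hits
                )

            expected = [
                s
                for s in samples
                if s.area >= CFG.min_area
                and s.retention_time <= CFG.max_retention
                and not blank_matched(s)
                and not contaminated(s)
            ]
            assert got == expected


class TestKovats:
    LADDER = vol.AlkaneLadder(tuple((c, 1.0 + (c - 8) * 2.0) for c in range(8, 16)))

    def test_exact_rung_returns_hundred_times_carbon(self):
        for c, t in self.LADDER.rungs:
            assert vol.kovats_index(t, self.LADDER) == pytest.approx(100 * c)

    def test_midpoint_interpolates_to_1050(self):
        ladder = vol.AlkaneLadder(((10, 10.0), (11, 12.0)))
        assert vol.kovats_index(11.0, ladder) == pytest.approx(1050.0)

    def test_hand_computed_interior_point(self):
        # rt 30% of the way between the C12 and C13 rungs -> 1230
        ladder = vol.AlkaneLadder(((12, 5.0), (13, 7.0)))
        assert vol.kovats_index(5.0 + 0.3 * 2.0, ladder) == pytest.approx(1230.0)

    def test_out_of_span_error_names_span(self):
        with pytest.raises(ValueError, match=r"span"):
            vol.kovats_index(0.5, self.LADDER)

    @given(st.floats(min_value=1.0, max_value=14.9))
    @settings(deadline=None, max_examples=50)
    def test_piecewise_linear_and_increasing(self, rt):
        ki = vol.kovats_index(rt, self.LADDER)
        eps = 1e-6
        assert vol.kovats_index(rt + eps, self.LADDER) >= ki
        assert 800.0 <= ki <= 1500.0


class TestQuantification:
    CURVE = vol.StandardCurve("α-pinene", slope=2e4, intercept=1e4)

    def test_area_at_intercept_gives_zero(self):
        rec = vol.quantify(peak(area=1e4), self.CURVE, scaling=48.0)
        assert rec.emission == 0.0

    def test_unit_construction(self):
        rec = vol.quantify(peak(area=1e4 + 48 * 2e4), self.CURVE, scaling=48.0)
        assert rec.emission == pytest.approx(1.0)

    def test_hand_computed_emission(self):
        rec = vol.quantify(peak(area=5e5), self.CURVE, scaling=48.0)
        assert rec.emission == pytest.approx((5e5 - 1e4) / 2e4 / 48, rel=1e-6)
        assert rec.emission == pytest.approx(0.5104, abs=5e-5)

    def test_negative_mass_clips_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            rec = vol.quantify(peak(area=5e3), self.CURVE, scaling=48.0)
        assert rec.emission == 0.0

    def test_missing_curve_error_names_compound(self):
        with pytest.raises(KeyError, match="linalool"):
            vol.quantify_peaks([peak(hits=("linalool", "a", "b"))], {"x": self.CURVE})

    def test_surrogate_curve_used_for_unknowns(self):
        recs = vol.quantify_peaks(
            [peak(area=5e5, hits=("unknown-1", "a", "b"))],
            {"α-pinene": self.CURVE},
            surrogates={"unknown-1": "α-pinene"},
        )
        assert recs[0].compound == "unknown-1"
        assert recs[0].emission == pytest.approx((5e5 - 1e4) / 2e4 / 48)

    def test_quantify_total_is_linear_in_area(self):
        # scaling all areas above the intercept by c scales totals by c
        rng = np.random.default_rng(16)
        areas = rng.uniform(2e4, 1e6, size=12)
        for c in (2.0, 0.5):
            t1 = vol.total_emission(
                [vol.quantify(peak(area=a), self.CURVE) for a in areas]
            )
            t2 = vol.total_emission(
                [
                    vol.quantify(peak(area=self.CURVE.intercept + c * (a - self.CURVE.intercept)), self.CURVE)
                    for a in areas
                ]
            )
            assert t2 == pytest.approx(c * t1, rel=1e-9)


class TestTotalsAndFoldChange:
    def test_empty_total_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert vol.total_emission([]) == 0.0

    def test_constructed_decomposition_sums_to_table_total(self):
        recs = [
            vol.EmissionRecord("s", c, e)
            for c, e in [("a", 3.0), ("b", 2.0), ("c", 0.036)]
        ]
        assert vol.total_emission(recs) == pytest.approx(5.036)
        assert vol.total_emission(recs) >= max(r.emission for r in recs)

    def test_random_records_match_summation_oracle(self):
        rng = np.random.default_rng(17)
        vals = rng.uniform(0, 10, size=20)
        recs = [vol.EmissionRecord("s", f"c{i}", v) for i, v in enumerate(vals)]
        assert vol.total_emission(recs) == pytest.approx(float(sum(vals)))

    @pytest.mark.parametrize(
        "a,b,expected",
        [([675.830], [291.169], 2.3211), ([1.0, 2.0], [1.0, 2.0], 1.0), ([5.036], [2.985], 1.6871)],
    )
    def test_fold_change(self, a, b, expected):
        assert vol.fold_change(a, b) == pytest.approx(expected, abs=1e-4)

    def test_zero_denominator_errors(self):
        with pytest.raises(ZeroDivisionError):
            vol.fold_change([1.0], [0.0])


class TestWelchT:
    def test_identical_groups_t_zero_p_one(self):
        t, df, p = vol.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_computed_welch(self):
        t, df, p = vol.welch_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.6742, abs=1e-4)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.0214, abs=2e-4)

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            vol.welch_t([1.0], [1.0, 2.0])

    def test_null_rejection_rate_calibrated(self):
        # both groups from the same normal: rejection at alpha=0.05 should
        # be ~0.05 within binomial Monte-Carlo error
        rng = np.random.default_rng(18)
        reps, n = 10_000, 10
        from scipy import stats as ss

        x = rng.normal(size=(reps, n))
        y = rng.normal(size=(reps, n))
        p = ss.ttest_ind(x, y, axis=1, equal_var=False).pvalue
        rate = float(np.mean(p < 0.05))
        se = math.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 4 * se


class TestIO:
    def test_peak_csv_round_trip(self, tmp_path):
        peaks = [peak(), peak(rt=12.5, area=2e5, hits=("a", "", ""))]
        path = tmp_path / "peaks.csv"
        vol.write_peaks(peaks, path)
        back = vol.read_peaks(path)
        assert [(p.retention_time, p.area, p.library_hits) for p in back] == [
            (p.retention_time, p.area, p.library_hits) for p in peaks
        ]
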