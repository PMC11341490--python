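import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from femorph.imaging import RegionMasks
from femorph.montecarlo import census_result
from femorph.morphometry import (
    KeySections,
    analyze_stack,
    classify_canal,
    compute_lengths,
    find_isthmus,
    find_trochanter_section,
    flare_indices,
    growth_rates,
    offset_section,
    per_slice_table,
    round_reported,
    section_diameters,
)


class TestFindIsthmus:
    def test_designed_isthmus_recovered(self, trumpet, trumpet_masks):
        _, _, gt = trumpet
        results = [census_result(m) for m in trumpet_masks]
        idx = find_isthmus([r.s_m for r in results], [r.slice_index for r in results])
        assert idx == gt.isthmus_slice_index

    def test_strictly_decreasing_profile_gives_last_slice(self):
        assert find_isthmus([5.0, 4.0, 3.0, 2.0]) == 3

    def test_tie_resolves_to_most_proximal(self):
        assert find_isthmus([3.0, 1.0, 2.0, 1.0]) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no accepted"):
            find_isthmus([])


class TestFindTrochanter:
    def test_designed_bump_recovered(self, trumpet, trumpet_masks):
        _, _, gt = trumpet
        idx = find_trochanter_section(trumpet_masks, window=(5, 16))
        assert idx == gt.trochanter_slice_index

    def test_constant_stack_tie_gives_first_in_window(self, disk_masks):
        masks = [
            RegionMasks(
                overall=disk_masks.overall,
                cortical=disk_masks.cortical,
                medullary=disk_masks.medullary,
                slice_index=i,
            )
            for i in range(6)
        ]
        assert find_trochanter_section(masks, window=(2, 5)) == 2

    def test_override_returned_verbatim(self, trumpet_masks):
        assert find_trochanter_section(trumpet_masks, (5, 16), override=11) == 11

    def test_empty_window_rejected(self, trumpet_masks):
        with pytest.raises(ValueError, match="window"):
            find_trochanter_section(trumpet_masks, window=(200, 210))


class TestOffsetSection:
    def test_20mm_at_5mm_interval_is_4_slices(self):
        assert offset_section(10, 20.0, 5.0, "proximal") == 6
        assert offset_section(10, 20.0, 5.0, "distal") == 14

    def test_zero_offset(self):
        assert offset_section(10, 0.0, 5.0, "distal") == 10

    def test_rounding_rule_3mm_interval(self):
        # round(20/3) = round(6.67) = 7
        assert offset_section(10, 20.0, 3.0, "distal") == 17

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            offset_section(2, 20.0, 5.0, "proximal")
        with pytest.raises(ValueError, match="out of range"):
            offset_section(8, 20.0, 5.0, "distal", n_slices=10)


class TestSectionDiameters:
    def test_phantom_inner_diameter_within_one_pixel(self, trumpet, trumpet_masks):
        spec, _, gt = trumpet
        i = 20
        inner, outer, thick = section_diameters(trumpet_masks[i], spec.pixel_spacing)
        assert inner == pytest.approx(
            2 * gt.inner_profile_mm[i, 0], abs=spec.pixel_spacing
        )
        assert outer == pytest.approx(
            2 * gt.outer_profile_mm[i, 0], abs=spec.pixel_spacing
        )
        assert thick == pytest.approx((outer - inner) / 2)

    def test_doubling_spacing_doubles_diameters(self, trumpet_masks):
        m = trumpet_masks[15]
        d1 = section_diameters(m, 0.5)
        d2 = section_diameters(m, 1.0)
        assert d2 == tuple(2 * v for v in d1)

    def test_empty_medullary_flagged(self):
        full = np.ones((8, 8), dtype=bool)
        empty = np.zeros((8, 8), dtype=bool)
        m = RegionMasks(overall=full, cortical=full, medullary=empty, slice_index=3)
        with pytest.raises(ValueError, match="empty medullary"):
            section_diameters(m, 0.5)


class TestLengthsAndRatios:
    def test_compute_lengths_arithmetic(self):
        key = KeySections(c_m0=10, c_m0_plus20=6, c_m0_minus20=14, c_m1=32)
        ih, lh = compute_lengths(key, n_slices=50, slice_interval=5.0)
        assert ih == 110.0
        assert lh == 49 * 5.0

    def test_equal_sections_give_zero_ih(self):
        key = KeySections(c_m0=10, c_m0_plus20=6, c_m0_minus20=14, c_m1=10)
        assert compute_lengths(key, 50, 5.0)[0] == 0.0

    def test_external_lh_supplied(self):
        key = KeySections(c_m0=10, c_m0_plus20=6, c_m0_minus20=14, c_m1=30)
        assert compute_lengths(key, 50, 5.0, lh_mm=446.96)[1] == 446.96

    def test_key_sections_order_validated(self):
        with pytest.raises(ValueError):
            KeySections(c_m0=10, c_m0_plus20=12, c_m0_minus20=14, c_m1=30).validate()

    def test_reported_flare_indices(self):
        f = flare_indices(t_plus20=43.24, t_minus20=18.07, t_mi=10.57, t_mo=25.20)
        assert round_reported(f["cfi"], 2) == 4.09
        assert round_reported(f["mcfi"], 2) == 2.39
        assert round_reported(f["dcfi"], 2) == 1.71
        assert round_reported(f["ci"], 2) == 0.58

    def test_reported_ih_over_lh(self):
        assert round_reported(110.40 / 446.96, 3) == 0.247

    def test_reported_growth_rates(self):
        r1, r2 = growth_rates(s_m_plus20=3313, s_m_minus20=2948, s_m1=428)
        assert round_reported(r1, 3) == 0.124
        assert round_reported(r2, 2) == 6.74

    def test_growth_rate_zero_denominator_undefined(self):
        r1, r2 = growth_rates(100.0, 0.0, 0.0)
        assert r1 is None and r2 is None

    @settings(max_examples=50, deadline=None)
    @given(
        tp=st.floats(10, 60),
        tm=st.floats(10, 60),
        ti=st.floats(5, 30),
        to=st.floats(31, 60),
    )
    def test_cfi_identity(self, tp, tm, ti, to):
        f = flare_indices(tp, tm, ti, to)
        assert f["cfi"] == pytest.approx(f["mcfi"] * f["dcfi"], rel=1e-12)


class TestClassifyCanal:
    @pytest.mark.parametrize(
        "cfi,expected",
        [
            (4.09, "normal"),
            (2.999, "chimney"),
            (3.0, "normal"),
            (4.7, "champagne"),
            (6.49, "champagne"),
            (6.5, "unclassified"),
        ],
    )
    def test_bands(self, cfi, expected):
        assert classify_canal(cfi) == expected

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            classify_canal(0.0)


class TestPerSliceTable:
    def test_equal_areas_give_q1_half_q2_one(self, disk_masks):
        from femorph.montecarlo import MCAreaResult

        r = MCAreaResult.from_counts(n=100, n1=100, n2=50, width=10, height=10)
        assert r.s_c == r.s_m
        table = per_slice_table([r])
        assert table["q_1"].iloc[0] == pytest.approx(0.5)
        assert table["q_2"].iloc[0] == pytest.approx(1.0)

    def test_q2_identity(self, trumpet_masks):
        results = [census_result(m) for m in trumpet_masks]
        table = per_slice_table(results)
        q1, q2 = table["q_1"].to_numpy(), table["q_2"].to_numpy()
        np.testing.assert_allclose(q2, q1 / (1 - q1), rtol=1e-12)


class TestAnalyzeStack:
    def test_noise_free_parameter_recovery(self, trumpet, trumpet_masks):
        spec, stack, gt = trumpet
        results = [census_result(m) for m in trumpet_masks]
        rep = analyze_stack(
            trumpet_masks,
            results,
            slice_interval=stack.slice_interval,
            pixel_spacing=stack.pixel_spacing,
            n_slices=stack.n_slices,
        )
        assert rep.key_sections.c_m1 == gt.isthmus_slice_index
        assert rep.key_sections.c_m0 == gt.trochanter_slice_index
        true_tmi = 2 * gt.inner_profile_mm[gt.isthmus_slice_index, 0]
        assert rep.t_mi == pytest.approx(true_tmi, abs=stack.pixel_spacing)
        true_ih = (
            abs(gt.isthmus_slice_index - gt.trochanter_slice_index)
            * stack.slice_interval
        )
        assert rep.ih == pytest.approx(true_ih, abs=stack.slice_interval)
        assert rep.canal_class == classify_canal(rep.cfi)
        # rounded report carries the hand-reported precision set
        for key in ("cfi", "mcfi", "dcfi", "ci", "ih_over_lh", "r_1", "r_2"):
            assert key in rep.rounded

    def test_sm_unimodal_and_q2_crossings(self, trumpet, trumpet_masks):
        _, stack, _ = trumpet
        results = [census_result(m) for m in trumpet_masks]
        rep = analyze_stack(
            trumpet_masks,
            results,
            slice_interval=stack.slice_interval,
            pixel_spacing=stack.pixel_spacing,
            n_slices=stack.n_slices,
        )
        sm = rep.per_slice["s_m"].to_numpy()
        sc = rep.per_slice["s_c"].to_numpy()
        q2 = rep.per_slice["q_2"].to_numpy()
        k = int(np.argmin(sm))
        assert 0 < k < len(sm) - 1
        assert np.all(np.diff(sm[: k + 1]) < 0) and np.all(np.diff(sm[k:]) > 0)
        np.testing.assert_array_equal(q2 > 1, sm > sc)
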