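"""Stress-band volume statistics, classification and the safety tabulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import staplecomp as sc
from staplecomp.band_safety import (
    DAMAGED,
    DAMAGED_AND_NOT_FIXED,
    NOT_FIXED,
    SAFE,
    LayerBands,
)


@pytest.fixture
def thresholds():
    return sc.Thresholds()


class TestThresholds:
    def test_defaults_are_the_study_constants(self, thresholds):
        assert thresholds.tau_low == 0.1
        assert thresholds.fix_band == (0.3, 0.6)
        assert thresholds.tau_dmg == 0.6
        assert thresholds.f_fix_min == 0.20
        assert thresholds.f_dmg_max == 0.05

    def test_band_upper_must_equal_damage_threshold(self):
        with pytest.raises(ValueError):
            sc.Thresholds(fix_band=(0.3, 0.5), tau_dmg=0.6)

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            sc.Thresholds(tau_low=0.4)
        with pytest.raises(ValueError):
            sc.Thresholds(f_fix_min=0.04, f_dmg_max=0.05)


class TestBandFractions:
    def test_ten_element_example(self, thresholds):
        # 7 elements at 0.2, 2 at 0.45, 1 at 0.7 MPa, equal volumes
        spec = [(1.0, 0.2)] * 7 + [(1.0, 0.45)] * 2 + [(1.0, 0.7)]
        step = sc.make_toy_stress_field(spec)
        bf = sc.band_fractions(step, thresholds)
        bands = bf.layers["lower"]
        assert bands.f_fix == pytest.approx(0.2)
        assert bands.f_dmg == pytest.approx(0.1)

    def test_everything_in_fixation_band(self, thresholds):
        step = sc.make_toy_stress_field([(2.0, 0.45)] * 5)
        bands = sc.band_fractions(step, thresholds).layers["lower"]
        assert bands.f_fix == pytest.approx(1.0)
        assert bands.f_dmg == 0.0

    def test_all_below_tau_low_is_no_fixation(self, thresholds):
        step = sc.make_toy_stress_field([(1.0, 0.05)] * 4)
        bands = sc.band_fractions(step, thresholds).layers["lower"]
        assert bands.no_fixation
        assert sc.classify(bands, thresholds) == NOT_FIXED

    def test_band_boundaries_inclusive_for_fixation(self, thresholds):
        step = sc.make_toy_stress_field([(1.0, 0.3), (1.0, 0.6)])
        bands = sc.band_fractions(step, thresholds).layers["lower"]
        assert bands.f_fix == pytest.approx(1.0)
        assert bands.f_dmg == 0.0

    @given(
        st.lists(
            st.tuples(st.floats(0.1, 10.0), st.floats(0.0, 1.2)),
            min_size=1, max_size=30,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_band_partition_closure(self, spec):
        """low + fixation + damage fractions sum to one when tissue is fixed."""
        thr = sc.Thresholds()
        bands = sc.band_fractions(sc.make_toy_stress_field(spec), thr).layers["lower"]
        if not bands.no_fixation:
            assert bands.f_low + bands.f_fix + bands.f_dmg == pytest.approx(1.0)
            assert bands.v_fix + bands.v_dmg <= bands.v_total + 1e-9


class TestClassify:
    @pytest.mark.parametrize(
        "f_fix,f_dmg,expected",
        [
            (0.25, 0.04, SAFE),
            (0.20, 0.00, NOT_FIXED),  # fixation requires strictly more than 20%
            (0.30, 0.05, SAFE),       # damage occurs strictly above 5%
            (0.30, 0.051, DAMAGED),
            (0.10, 0.20, DAMAGED_AND_NOT_FIXED),
        ],
    )
    def test_decision_boundaries(self, thresholds, f_fix, f_dmg, expected):
        bands = LayerBands(v_total=1.0, v_fix=f_fix, v_dmg=f_dmg)
        assert sc.classify(bands, thresholds) == expected

    @given(
        st.lists(st.tuples(st.floats(0.5, 5.0), st.floats(0.11, 1.5)),
                 min_size=2, max_size=25),
        st.floats(0.01, 0.5),
    )
    @settings(max_examples=100, deadline=None)
    def test_raising_stress_never_rescues_a_damaged_layer(self, spec, delta):
        """With all elements already fixed, extra stress cannot make a
        damaged layer safe (damage volume only grows)."""
        thr = sc.Thresholds()
        before = sc.classify(
            sc.band_fractions(sc.make_toy_stress_field(spec), thr).layers["lower"], thr
        )
        bumped = [(v, s + delta) for v, s in spec]
        after = sc.classify(
            sc.band_fractions(sc.make_toy_stress_field(bumped), thr).layers["lower"], thr
        )
        if before in (DAMAGED, DAMAGED_AND_NOT_FIXED):
            assert after != SAFE


class TestCompressionRatio:
    @pytest.mark.parametrize(
        "d,total,expected",
        [
            (1.8, 3.0, 0.60),
            (1.9, 3.0, 0.63),
            (2.3, 4.0, 0.58),  # 0.575 must round half-up, not to 0.57
            (2.5, 4.0, 0.63),
            (2.9, 5.0, 0.58),
            (3.2, 5.0, 0.64),
            (0.0, 4.0, 0.00),
        ],
    )
    def test_two_decimal_half_up(self, d, total, expected):
        assert sc.compression_ratio(d, total) == expected

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            sc.compression_ratio(1.0, 0.0)
        with pytest.raises(ValueError):
            sc.compression_ratio(5.0, 4.0)


class TestSafetyTable:
    def test_joint_gap_from_distance_sets(self, thresholds):
        stack = sc.TissueStack(2.0, 2.0)
        table = sc.safety_table(
            {"upper": [2.4, 2.5], "lower": [2.3, 2.4]}, thresholds, stack
        )
        assert table.joint_safe_gaps == (1.6,)
        assert table.safe_ratios["upper"] == (0.60, 0.63)
        assert table.safe_ratios["lower"] == (0.58, 0.60)

    def test_multiple_joint_gaps(self, thresholds):
        stack = sc.TissueStack(2.5, 2.5)
        table = sc.safety_table(
            {"upper": [2.9, 3.0, 3.1, 3.2], "lower": [2.9, 3.0]}, thresholds, stack
        )
        assert set(table.joint_safe_gaps) == {2.0, 2.1}

    def test_disjoint_layer_sets_give_empty_gaps(self, thresholds):
        stack = sc.TissueStack(1.5, 1.5)
        table = sc.safety_table({"upper": [1.9], "lower": [1.7]}, thresholds, stack)
        assert table.joint_safe_gaps == ()

    def test_uniform_engine_layers_classify_identically(self, tissue_material, thresholds):
        stack = sc.TissueStack(2.0, 2.0)
        program = sc.LoadProgram.for_stack(stack)
        results = sc.run_uniform(tissue_material, stack, program)
        table = sc.safety_table(results, thresholds, stack)
        assert table.safe_distances["upper"] == table.safe_distances["lower"]
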