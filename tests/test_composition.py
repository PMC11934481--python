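import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coda24.composition import (
    PARTS,
    ActivityComposition,
    DegenerateCompositionError,
    InfeasibleReplacementError,
    ClrCoefficients,
    close,
    clr_from_ilr,
    clr_from_pivot_beta1,
    composition_percentages,
    compositional_mean,
    inverse_pivot_ilr,
    pivot_basis,
    pivot_ilr,
    pivot_ilr_with_order,
    replace_zeros,
)

positive_minutes = st.floats(min_value=1.0, max_value=1200.0)
compositions = st.tuples(positive_minutes, positive_minutes, positive_minutes, positive_minutes)


class TestClose:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ((600, 600, 120, 120), (600, 600, 120, 120)),
            ((30, 30, 30, 30), (360, 360, 360, 360)),
        ],
    )
    def test_examples(self, raw, expected):
        assert np.allclose(close(raw).as_array(), expected)

    def test_published_means_close_to_1440(self):
        c = close([543.2, 635.8, 210.1, 50.9])
        assert c.total == pytest.approx(1440.0, rel=1e-12)
        # the printed values are already adjusted, so closure is a no-op
        assert np.allclose(c.as_array(), [543.2, 635.8, 210.1, 50.9], atol=1e-9)

    def test_ratios_preserved(self):
        c = close([100, 200, 300, 400], total=1440)
        assert c.st / c.sleep == pytest.approx(2.0)

    def test_all_zero_raises(self):
        with pytest.raises(DegenerateCompositionError):
            close([0, 0, 0, 0])


class TestReplaceZeros:
    def test_multiplicative_replacement(self):
        out = replace_zeros([700, 700, 40, 0], floor=1.0)
        shrink = (1440 - 1) / 1440
        assert np.allclose(out, [700 * shrink, 700 * shrink, 40 * shrink, 1.0])
        assert out.sum() == pytest.approx(1440.0)

    def test_no_zeros_is_identity(self):
        x = np.array([543.2, 635.8, 210.1, 50.9])
        assert np.array_equal(replace_zeros(x), x)

    def test_all_zero_raises(self):
        with pytest.raises(DegenerateCompositionError):
            replace_zeros([0, 0, 0, 0])

    def test_infeasible_floor_raises(self):
        with pytest.raises(InfeasibleReplacementError):
            replace_zeros([10, 2, 1, 0], floor=5.0)


class TestCompositionalMean:
    def test_identical_rows(self):
        rows = [close([500, 600, 250, 90])] * 5
        assert np.allclose(compositional_mean(rows).as_array(), rows[0].as_array())

    def test_two_row_geometric_mean(self):
        rows = [(400, 800, 200, 40), (800, 400, 200, 40)]
        gm = np.sqrt(np.array([400 * 800, 800 * 400, 200 * 200, 40 * 40]))
        expected = gm / gm.sum() * 1440
        assert np.allclose(compositional_mean(rows).as_array(), expected)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            compositional_mean([])


class TestPercentages:
    def test_published_shares(self, table1_means):
        pct = composition_percentages(table1_means)
        # printed shares were computed from unrounded geometric means, so
        # agreement is to the printed 1-dp precision
        assert pct["st"] == pytest.approx(44.1, abs=0.1)
        assert pct["lpa"] == pytest.approx(14.6, abs=0.1)
        assert pct["mvpa"] == pytest.approx(3.5, abs=0.1)
        assert pct["sleep"] == pytest.approx(37.7, abs=0.1)
        assert sum(pct.values()) == pytest.approx(100.0)

    def test_equal_composition(self):
        pct = composition_percentages(close([1, 1, 1, 1]))
        assert all(v == pytest.approx(25.0) for v in pct.values())


class TestPivotIlr:
    def test_equal_parts_map_to_origin(self):
        c = close([360, 360, 360, 360])
        for pivot in PARTS:
            assert np.allclose(pivot_ilr(c, pivot).as_array(), 0.0, atol=1e-12)

    def test_first_coordinate_formula(self, table1_means):
        # z1 = sqrt(3/4) ln(mvpa / geometric mean of the rest), by hand
        g = (543.2 * 635.8 * 210.1) ** (1 / 3)
        expected = math.sqrt(3 / 4) * math.log(50.9 / g)
        assert pivot_ilr(table1_means, "mvpa").z1 == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-1.822, abs=1e-3)

    def test_z1_invariant_to_rest_ordering(self, table1_means):
        rest = [p for p in PARTS if p != "mvpa"]
        z1s = {
            pivot_ilr_with_order(table1_means, "mvpa", perm).z1
            for perm in itertools.permutations(rest)
        }
        assert max(z1s) - min(z1s) < 1e-12

    def test_nonpositive_part_raises(self):
        with pytest.raises(ValueError):
            pivot_ilr(ActivityComposition(700, 700, 40, 0), "mvpa")

    def test_basis_is_orthonormal_and_zero_sum(self):
        for pivot in PARTS:
            V = pivot_basis(pivot)
            assert np.allclose(V.T @ V, np.eye(3), atol=1e-12)
            assert np.allclose(V.sum(axis=0), 0.0, atol=1e-12)

    @given(c=compositions, k=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, c, k):
        x = np.asarray(c)
        z0 = pivot_ilr(x, "st").as_array()
        z1 = pivot_ilr(k * x, "st").as_array()
        assert np.allclose(z0, z1, atol=1e-9)


class TestInversePivotIlr:
    def test_origin_maps_to_equal_shares(self):
        c = inverse_pivot_ilr([0.0, 0.0, 0.0], pivot="sleep")
        assert np.allclose(c.as_array(), 360.0)

    @pytest.mark.parametrize("pivot", PARTS)
    def test_round_trip_on_published_means(self, table1_means, pivot):
        z = pivot_ilr(table1_means, pivot)
        back = inverse_pivot_ilr(z)
        assert np.allclose(back.as_array(), table1_means.as_array(), rtol=1e-9)

    @given(c=compositions)
    @settings(max_examples=50, deadline=None)
    def test_round_trip_property(self, c):
        closed = close(np.asarray(c))
        for pivot in ("sleep", "mvpa"):
            z = pivot_ilr(closed, pivot)
            assert np.allclose(
                inverse_pivot_ilr(z).as_array(), closed.as_array(), rtol=1e-9
            )
            assert inverse_pivot_ilr(z).total == pytest.approx(1440.0, rel=1e-9)


class TestClrConversion:
    def test_published_overall_row(self):
        a = clr_from_pivot_beta1([-2.45, -0.60, -1.76, 4.81])
        assert np.allclose(
            a.as_array(), [-2.122, -0.520, -1.524, 4.166], atol=5e-4
        )

    def test_zero_and_scaling(self):
        assert np.allclose(clr_from_pivot_beta1([0, 0, 0, 0]).as_array(), 0.0)
        a = clr_from_pivot_beta1([1, -1, 0, 0])
        assert a.a_sleep == pytest.approx(math.sqrt(3 / 4))
        assert a.a_st == pytest.approx(-math.sqrt(3 / 4))

    def test_warns_when_sum_exceeds_rounding_tolerance(self):
        with pytest.warns(UserWarning, match="sum"):
            clr_from_pivot_beta1([1.0, 1.0, 1.0, 1.0])

    def test_clr_from_ilr_matches_pivot_beta1_route(self, rng):
        # a fitted ILR vector and its first-coordinate reading must agree on clr scale
        for pivot in PARTS:
            coeffs = rng.normal(size=3)
            a = clr_from_ilr(coeffs, pivot)
            assert a.sum == pytest.approx(0.0, abs=1e-12)
            beta1 = coeffs[0]
            assert a[pivot] == pytest.approx(math.sqrt(3 / 4) * beta1, abs=1e-12)

    def test_clr_sum_zero_for_exact_vectors(self):
        a = ClrCoefficients(-2.0, 0.5, 0.5, 1.0)
        assert a.sum == pytest.approx(0.0)
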