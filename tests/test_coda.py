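"""Aitchison-geometry core: closure, ilr, variation, reallocation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from movecomp import coda
from movecomp.coda import (
    BehaviourComposition,
    InfeasibleReallocationError,
    close,
    default_ilr_basis,
    geometric_mean_composition,
    ilr,
    ilr_basis_from_sbp,
    ilr_covariance_from_variation,
    ilr_inverse,
    reallocate,
    variation_matrix,
    zero_replace,
)

from conftest import WINDOW_MINUTES

positive_parts = st.lists(
    st.floats(min_value=0.05, max_value=1400, allow_nan=False), min_size=3, max_size=3
)


class TestClose:
    @pytest.mark.parametrize(
        "minutes, expected_props",
        [
            (WINDOW_MINUTES["week"], (0.93, 0.01, 0.06)),
            (WINDOW_MINUTES["weekend"], (0.98, 0.01, 0.01)),
            (WINDOW_MINUTES["four_day"], (0.95, 0.01, 0.04)),
        ],
    )
    def test_published_minutes_close_to_reported_proportions(self, minutes, expected_props):
        comp = close(np.array(minutes), total=1.0)
        assert tuple(np.round(comp.parts, 2)) == expected_props

    def test_symmetric_parts(self):
        assert np.allclose(close((1, 1, 1), 600).parts, (200, 200, 200))

    def test_idempotent(self):
        once = close((3, 2, 1), 600)
        twice = close(once.parts, 600)
        assert np.allclose(once.parts, twice.parts, rtol=1e-12)

    def test_conserves_total_exactly(self):
        comp = close((123.4, 5.6, 78.9), 600)
        assert comp.parts.sum() == pytest.approx(600, rel=1e-12)

    @pytest.mark.parametrize("bad", [(0, 1, 1), (-1, 2, 3)])
    def test_rejects_nonpositive(self, bad):
        with pytest.raises(ValueError):
            close(bad, 600)


class TestZeroReplace:
    def test_conserves_total_and_floors_zeros(self):
        out = zero_replace(np.array([600.0, 0.0, 0.0]))
        assert out.sum() == pytest.approx(600.0, rel=1e-12)
        assert out[1] == out[2] == pytest.approx(1 / 12)
        assert out[0] < 600.0

    def test_identity_without_zeros(self):
        parts = np.array([500.0, 50.0, 50.0])
        assert np.array_equal(zero_replace(parts), parts)

    def test_output_satisfies_closure_precondition(self):
        out = zero_replace(np.array([10.0, 0.0, 5.0]))
        close(out, 600)  # must not raise

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            zero_replace(np.zeros(3))


class TestGeometricMean:
    def test_identical_inputs_returned(self):
        comp = np.array([500.0, 40.0, 60.0])
        gm = geometric_mean_composition(np.tile(comp, (5, 1)), total=600)
        assert np.allclose(gm.parts, comp)

    def test_scale_invariance(self):
        a = np.array([400.0, 100.0, 100.0])
        stacked = np.vstack([a, 3.7 * a])
        gm = geometric_mean_composition(stacked, total=600)
        assert np.allclose(gm.parts, close(a, 600).parts, rtol=1e-12)

    def test_matches_log_mean_oracle(self, rng):
        comps = rng.uniform(1, 500, size=(5, 3))
        gm = geometric_mean_composition(comps, total=600)
        # independent oracle: exp of per-part mean log, then rescale
        oracle = np.exp(np.mean(np.log(comps), axis=0))
        oracle = oracle / oracle.sum() * 600
        assert np.allclose(gm.parts, oracle, rtol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            geometric_mean_composition(np.empty((0, 3)))


class TestVariationMatrix:
    def test_proportional_parts_have_zero_variation(self, rng):
        sb = rng.uniform(100, 500, size=20)
        lpa = rng.uniform(1, 50, size=20)
        comps = np.column_stack([sb, lpa, 2.5 * lpa])
        v = variation_matrix(comps)
        assert v[1, 2] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force(self, rng):
        comps = rng.uniform(1, 500, size=(10, 3))
        v = variation_matrix(comps)
        for i in range(3):
            for j in range(3):
                ratios = [math.log(row[i] / row[j]) for row in comps]
                mean = sum(ratios) / len(ratios)
                expected = sum((r - mean) ** 2 for r in ratios) / (len(ratios) - 1)
                assert v[i, j] == pytest.approx(expected, rel=1e-10)

    def test_symmetric_zero_diagonal(self, rng):
        v = variation_matrix(rng.uniform(1, 100, size=(6, 3)))
        assert np.allclose(v, v.T) and np.all(np.diag(v) == 0) and np.all(v >= 0)

    def test_closure_invariant(self, rng):
        comps = rng.uniform(1, 100, size=(8, 3))
        closed = comps / comps.sum(1, keepdims=True)
        scale = rng.uniform(0.5, 2.0, size=(8, 1))
        assert np.allclose(variation_matrix(closed), variation_matrix(comps * scale))

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            variation_matrix(np.array([[1.0, 2.0, 3.0]]))


class TestIlr:
    def test_barycentre_maps_to_origin(self):
        assert np.allclose(ilr(np.array([1 / 3, 1 / 3, 1 / 3])), 0.0, atol=1e-12)

    def test_scale_invariance(self):
        x = np.array([0.93, 0.01, 0.06])
        for total in (1.0, 600.0, 1440.0):
            assert np.allclose(ilr(close(x, total)), ilr(x), atol=1e-12)

    def test_hand_evaluated_formula(self):
        sb, lpa, mvpa = 0.93, 0.01, 0.06
        z = ilr(np.array([sb, lpa, mvpa]))
        z1 = math.sqrt(2 / 3) * math.log(sb / math.sqrt(lpa * mvpa))
        z2 = math.sqrt(1 / 2) * math.log(lpa / mvpa)
        assert z == pytest.approx([z1, z2], rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ilr(np.array([1.0, 0.0, 1.0]))

    def test_isometry_against_aitchison_distance_oracle(self, rng):
        # Aitchison distance via clr coordinates, computed independently
        def aitchison(x, y):
            lx, ly = np.log(x), np.log(y)
            cx, cy = lx - lx.mean(), ly - ly.mean()
            return float(np.linalg.norm(cx - cy))

        for _ in range(20):
            x = rng.uniform(0.5, 500, size=3)
            y = rng.uniform(0.5, 500, size=3)
            d_ilr = float(np.linalg.norm(ilr(x) - ilr(y)))
            assert d_ilr == pytest.approx(aitchison(x, y), rel=1e-10)


class TestIlrInverse:
    def test_origin_maps_to_barycentre(self):
        comp = ilr_inverse(np.zeros(2), total=600)
        assert np.allclose(comp.parts, 200.0)

    @given(parts=positive_parts)
    @settings(max_examples=50, deadline=None)
    def test_round_trip_composition(self, parts):
        x = close(np.array(parts), 600)
        back = ilr_inverse(ilr(x), total=600)
        assert np.allclose(back.parts, x.parts, rtol=1e-9)

    @given(z1=st.floats(-5, 5), z2=st.floats(-5, 5))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_coordinates(self, z1, z2):
        z = np.array([z1, z2])
        assert np.allclose(ilr(ilr_inverse(z, total=600)), z, atol=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ilr_inverse(np.array([np.nan, 0.0]), 600)


class TestReallocate:
    def test_zero_delta_identity(self):
        base = close(WINDOW_MINUTES["week"], 600)
        out = reallocate(base, "lpa", "sb", 0.0)
        assert np.allclose(out.parts, base.parts)

    def test_five_minute_swap_arithmetic(self):
        base = close(WINDOW_MINUTES["week"], 600)
        out = reallocate(base, "lpa", "sb", 5.0)
        assert np.allclose(out.parts, (554.72, 11.57, 33.71), atol=1e-9)
        assert out.parts.sum() == pytest.approx(600, rel=1e-12)

    def test_weekend_lpa_donor_infeasible(self):
        base = close(WINDOW_MINUTES["weekend"], 600)
        with pytest.raises(InfeasibleReallocationError) as err:
            reallocate(base, "mvpa", "lpa", 5.0)
        assert err.value.deficit == pytest.approx(5.0 - base["lpa"], abs=1e-9)

    def test_reallocate_then_reverse_is_identity(self):
        base = close((500.0, 40.0, 60.0), 600)
        there = reallocate(base, "mvpa", "sb", 7.5)
        back = reallocate(there, "sb", "mvpa", 7.5)
        assert np.allclose(back.parts, base.parts, rtol=1e-12)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            reallocate(close((500, 50, 50), 600), "lpa", "sb", -1.0)

    def test_same_pair_rejected(self):
        with pytest.raises(ValueError):
            reallocate(close((500, 50, 50), 600), "sb", "sb", 5.0)


class TestBases:
    def test_default_basis_orthonormal_and_zero_sum(self):
        v = default_ilr_basis(3)
        assert np.allclose(v.T @ v, np.eye(2), atol=1e-12)
        assert np.allclose(v.sum(axis=0), 0.0, atol=1e-12)

    def test_alternative_sbp_gives_different_but_orthonormal_basis(self):
        v = ilr_basis_from_sbp(np.array([[-1, -1, 1], [1, -1, 0]]))
        assert np.allclose(v.T @ v, np.eye(2), atol=1e-12)
        assert not np.allclose(v, default_ilr_basis(3))

    def test_ilr_covariance_from_variation_matches_sample_covariance(self, rng):
        # the identity linking the variation matrix and the ilr covariance
        # must hold exactly for sample moments with matching denominators
        comps = rng.uniform(1, 300, size=(40, 3))
        t = variation_matrix(comps)
        sigma = ilr_covariance_from_variation(t)
        z = ilr(comps)
        assert np.allclose(sigma, np.cov(z.T, ddof=1), rtol=1e-9)


class TestBehaviourComposition:
    def test_total_mismatch_rejected(self):
        with pytest.raises(ValueError):
            BehaviourComposition(np.array([100.0, 100.0, 100.0]), total=600)

    def test_named_access(self):
        comp = close((500, 40, 60), 600)
        assert comp["lpa"] == pytest.approx(40.0)
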