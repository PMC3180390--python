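"""Balanced end-unanchored warping: DP correctness and shift conversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtwshift.aligner import (
    _reference_cost,
    align,
    align_and_shift,
    brute_force_align,
    shifts_from_path,
)
from dtwshift.heterosim import NoiseSpec, constant_shift, make_pair, poly_model

from conftest import make_interp


class TestAlign:
    def test_identity_alignment(self, rng):
        X = make_interp(rng.normal(size=15))
        path = align(X, X)
        assert path.cost == 0.0
        assert path.omitted == frozenset()
        assert path.pairs == tuple((i, i) for i in range(1, 16))
        prof = shifts_from_path(path, X, X)
        np.testing.assert_array_equal(prof.shifts, 0.0)

    def test_forced_two_by_two(self):
        X = make_interp([1.0, 4.0])
        Y = make_interp([2.0, 2.5])
        path = align(X, Y, multi_map="query-only")
        assert path.pairs == ((1, 1), (2, 2))
        assert path.cost == (1.0 - 2.0) ** 2 + (4.0 - 2.5) ** 2

    def test_leading_omissions_are_free(self):
        # best match for (1, 2) is columns 3 and 4 of (0, 5, 1, 2)
        X = make_interp([0.0, 5.0, 1.0, 2.0])
        Y = make_interp([1.0, 2.0])
        path = align(X, Y)
        assert path.pairs == ((1, 3), (2, 4))
        assert sorted(path.omitted) == [1, 2]
        assert path.cost == 0.0

    def test_balanced_invariant_on_typical_sizes(self, rng):
        X = make_interp(rng.normal(size=40), np.linspace(0, 20, 40))
        Y = make_interp(rng.normal(size=20), np.linspace(0, 20, 20))
        path = align(X, Y)
        path.validate()  # raises on violation
        assert path.n_omitted == 20
        assert len({j for _, j in path.pairs}) == 20

    def test_shorter_reference_swaps_roles(self, rng):
        X = make_interp(rng.normal(size=5))
        Y = make_interp(rng.normal(size=9))
        path = align(X, Y)
        assert path.swapped
        assert path.ref_len == 9 and path.query_len == 5

def test_single_point_query_rejected(rng):
    X = make_interp(rng.normal(size=6))
    bad = make_interp([1.0, 2.0])
    bad.values = bad.values[:1]
    bad.times = bad.times[:1]
    with pytest.raises(ValueError):
        align(X, bad)


def test_nonfinite_values_rejected(rng):
    X = make_interp(rng.normal(size=6))
    Y = make_interp([1.0, np.nan, 2.0])
    with pytest.raises(ValueError, match="finite"):
        align(X, Y)


class TestOracleEquivalence:
    @pytest.mark.parametrize("multi_map", ["both", "query-only"])
    def test_matches_brute_force_exactly(self, multi_map, rng):
        """DP cost equals exhaustive enumeration, exactly, on 200 instances."""
        for _ in range(200):
            M = int(rng.integers(4, 11))
            N = int(rng.integers(2, min(5, M) + 1))
            X = make_interp(rng.normal(size=M))
            Y = make_interp(rng.normal(size=N))
            fast = align(X, Y, multi_map=multi_map)
            slow = brute_force_align(X, Y, multi_map=multi_map)
            assert fast.cost == slow.cost
            assert len(fast.pairs) == len(slow.pairs)
            fast.validate()
            slow.validate()

    def test_matches_python_reference_bit_exactly(self, rng):
        """The compiled DP and a plain-Python transliteration agree exactly."""
        for _ in range(100):
            M = int(rng.integers(5, 15))
            N = int(rng.integers(2, min(7, M) + 1))
            xv = rng.normal(size=M)
            yv = rng.normal(size=N)
            fast = align(make_interp(xv), make_interp(yv))
            cost, npairs = _reference_cost(list(xv), list(yv))
            assert fast.cost == cost
            assert len(fast.pairs) == npairs

    def test_brute_force_guard(self, rng):
        X = make_interp(rng.normal(size=13))
        Y = make_interp(rng.normal(size=3))
        with pytest.raises(ValueError):
            brute_force_align(X, Y)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    data=st.data(),
    M=st.integers(min_value=3, max_value=25),
)
def test_balanced_path_property(data, M):
    """Every alignment leaves exactly M-N omitted columns, uses N distinct
    columns, and keeps shifts within the domain-difference bounds."""
    N = data.draw(st.integers(min_value=2, max_value=M))
    xv = data.draw(
        st.lists(
            st.floats(-10, 10, allow_nan=False, width=32),
            min_size=M, max_size=M,
        )
    )
    yv = data.draw(
        st.lists(
            st.floats(-10, 10, allow_nan=False, width=32),
            min_size=N, max_size=N,
        )
    )
    X = make_interp(np.asarray(xv, float), np.linspace(0, 10, M))
    Y = make_interp(np.asarray(yv, float), np.linspace(0, 10, N))
    path = align(X, Y)
    path.validate()
    assert path.n_omitted == M - N
    prof = shifts_from_path(path, X, Y)
    lo = X.times[0] - Y.times[-1]
    hi = X.times[-1] - Y.times[0]
    assert np.all(prof.shifts >= lo - 1e-12)
    assert np.all(prof.shifts <= hi + 1e-12)


class TestShiftsFromPath:
    def test_direct_formula(self):
        X = make_interp([1.0, 2.0], times=[4.0, 5.0])
        Y = make_interp([1.0, 2.0], times=[1.0, 2.0])
        prof = shifts_from_path(align(X, Y), X, Y)
        np.testing.assert_allclose(prof.shifts, [3.0, 3.0])

    def test_mean_rule_for_multiple_mapping(self):
        # query point 2 (time 3) aligned to reference times 4 and 6
        from dtwshift.aligner import AlignmentPath

        X = make_interp([0.0, 1.0, 1.0], times=[2.0, 4.0, 6.0])
        Y = make_interp([0.0, 1.0], times=[1.0, 3.0])
        path = AlignmentPath(
            pairs=((1, 1), (2, 2), (2, 3)),
            omitted=frozenset({}),
            cost=0.0,
            query_len=2,
            ref_len=3,
        )
        prof = shifts_from_path(path, X, Y)
        assert prof.shifts[1] == pytest.approx(5.0 - 3.0)

    def test_reporting_scale_sign_means_query_delayed(self):
        # query ages map to younger reference ages -> query delayed -> positive
        X = make_interp([1.0, 2.0], times=[1.0, 2.0])
        Y = make_interp([1.0, 2.0], times=[2.0, 4.0])
        prof = shifts_from_path(align(X, Y), X, Y)
        assert np.all(prof.shifts < 0)  # raw: maps to younger ref times
        assert np.all(prof.reporting_shifts > 0)  # reporting: delayed

    def test_reporting_absent_for_nonpositive_times(self):
        X = make_interp([1.0, 2.0, 3.0], times=[-1.0, 0.0, 1.0])
        Y = make_interp([1.0, 3.0], times=[-1.0, 1.0])
        prof = shifts_from_path(align(X, Y), X, Y)
        assert prof.reporting_shifts is None


class TestAlignAndShift:
    def test_same_series_gives_zero_shifts(self, noisy_cubic_series):
        prof = align_and_shift(
            noisy_cubic_series, noisy_cubic_series, K_A=40, K_B=20, df=4
        )
        assert prof.N == 20
        assert np.max(np.abs(prof.shifts)) < np.ptp(noisy_cubic_series.ages) / 39

    def test_noiseless_constant_shift_recovery(self):
        """Interior estimates recover the injected shift within a grid step."""
        model = poly_model(3, 2, -1)
        ref, query = make_pair(
            model, constant_shift(2.0), NoiseSpec(sd=1e-12), rng=0
        )
        prof = align_and_shift(ref, query, K_A=40, K_B=20, df="gcv")
        step = np.diff(prof.query_times)[0]
        interior = prof.shifts[3:-3]
        assert np.all(np.abs(interior - 2.0) <= step + 1e-9)

    def test_direction_reversal_flips_sign(self):
        model = poly_model(0, 1, 0.1)
        ref, query = make_pair(
            model, constant_shift(2.0), NoiseSpec(sd=1e-12), rng=1
        )
        fwd = align_and_shift(ref, query, K_A=40, K_B=20, df="gcv")
        rev = align_and_shift(ref, query, K_A=20, K_B=40,
                              direction="A_to_B", df="gcv")
        step = np.diff(fwd.query_times)[0]
        assert abs(np.mean(fwd.shifts[4:-4]) + np.mean(rev.shifts[8:-8])) < 2 * step
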