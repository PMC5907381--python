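"""William's mean, daily profiles and activity totals."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from damrhythm import (
    activity_totals,
    group_profile,
    individual_profile,
    rebin,
    split_regimes,
    williams_mean,
)
from damrhythm.simulate import simulate_cohort

from conftest import make_series


def brute_williams(values):
    """Independent scalar-loop reference for the William's mean."""
    total = 0.0
    for v in values:
        total += math.log(v + 1.0)
    return math.exp(total / len(values)) - 1.0


class TestWilliamsMean:
    def test_zeros_give_zero(self):
        assert williams_mean([0, 0, 0]) == 0.0

    @pytest.mark.parametrize("c", [0.0, 1.0, 7.5, 300.0])
    def test_constant_sequence_is_identity(self, c):
        assert williams_mean([c] * 5) == pytest.approx(c)

    def test_hand_evaluated_example(self):
        # shifted values {2, 4, 8} have geometric mean 4; minus 1 -> 3
        assert williams_mean([1, 3, 7]) == pytest.approx(3.0)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            v = rng.gamma(1.0, 20.0, size=rng.integers(1, 30))
            assert williams_mean(v) == pytest.approx(brute_williams(v), rel=1e-12)

    def test_rejects_empty_and_negative(self):
        with pytest.raises(ValueError):
            williams_mean([])
        with pytest.raises(ValueError):
            williams_mean([1.0, -0.1])

    @given(st.lists(st.floats(0, 1e4), min_size=1, max_size=20))
    def test_never_exceeds_arithmetic_mean(self, values):
        w = williams_mean(values)
        am = float(np.mean(values))
        assert w <= am + 1e-9 * max(1.0, am)
        if max(values) - min(values) > 1e-6:
            assert w < am

    @given(
        st.lists(st.floats(0, 100), min_size=2, max_size=10),
        st.floats(0.5, 50),
    )
    def test_strictly_increasing_in_any_value(self, values, bump):
        assert williams_mean([values[0] + bump] + values[1:]) > williams_mean(values)


def _cohort_ld(n, preset="males_alone", seed=0, schedule=None):
    series, _ = simulate_cohort(preset, n, seed=seed, schedule=schedule)
    return [split_regimes(rebin(s, 6), s_sched(schedule))[0] for s in series]


def s_sched(schedule):
    from damrhythm import LightSchedule

    return schedule or LightSchedule()


class TestIndividualProfile:
    def test_identical_days_reproduce_the_day(self, schedule):
        day = np.arange(48) % 7
        series = make_series(np.tile(day, 15), schedule, bin_width=30.0)
        prof = individual_profile(series, schedule, days=(2, 3, 4))
        assert np.allclose(prof.values, day)
        assert prof.n_units == 3

    def test_single_day_is_verbatim(self, schedule):
        rng = np.random.default_rng(1)
        counts = rng.poisson(5.0, size=15 * 48)
        series = make_series(counts, schedule, bin_width=30.0)
        prof = individual_profile(series, schedule, days=(2,))
        assert np.allclose(prof.values, counts[48:96])

    def test_bin_equals_williams_of_day_values(self, schedule):
        counts = np.zeros(15 * 48, dtype=int)
        for day, v in zip((2, 3, 4), (1, 3, 7)):
            counts[(day - 1) * 48 + 20] = v
        series = make_series(counts, schedule, bin_width=30.0)
        prof = individual_profile(series, schedule)
        assert prof.values[20] == pytest.approx(3.0)

    def test_invariant_under_day_order(self, schedule):
        rng = np.random.default_rng(2)
        series = make_series(rng.poisson(4.0, 15 * 48), schedule, bin_width=30.0)
        a = individual_profile(series, schedule, days=(2, 3, 4))
        b = individual_profile(series, schedule, days=(4, 2, 3))
        assert np.allclose(a.values, b.values)

    def test_missing_day_rejected(self, schedule):
        series = make_series(np.ones(48, dtype=int), schedule, bin_width=30.0)
        with pytest.raises(ValueError, match="day 2"):
            individual_profile(series, schedule, days=(2,))


class TestGroupProfile:
    def test_single_individual_constant_days_equals_own_profile(self, schedule):
        day = np.arange(48) % 5
        series = make_series(np.tile(day, 15), schedule, bin_width=30.0)
        gp = group_profile([series], schedule)
        ip = individual_profile(series, schedule)
        assert np.allclose(gp.values, ip.values)

    def test_identical_individuals_have_zero_dispersion(self, schedule):
        rng = np.random.default_rng(3)
        counts = rng.poisson(4.0, 15 * 48)
        series = [make_series(counts, schedule, bin_width=30.0, channel_id=i + 1) for i in range(4)]
        gp = group_profile(series, schedule)
        assert np.allclose(gp.sem, 0.0)

    def test_matches_two_stage_brute_force(self, schedule):
        ld = _cohort_ld(16, seed=9, schedule=schedule)
        gp = group_profile(ld, schedule)
        # brute force: William's mean across individuals for each day/bin,
        # then arithmetic mean across days 2-4
        from damrhythm import to_zt

        buckets: dict[tuple, list] = {}
        for s in ld:
            for ts, c in zip(s.timestamps, s.counts):
                dd, zz = to_zt(ts, schedule)
                buckets.setdefault((dd, round(zz * 2)), []).append(int(c))
        expected = np.array(
            [
                np.mean([brute_williams(buckets[(d, b)]) for d in (2, 3, 4)])
                for b in range(48)
            ]
        )
        assert np.allclose(gp.values, expected)

    def test_mismatched_grids_rejected(self, schedule):
        a = make_series(np.ones(15 * 48, dtype=int), schedule, bin_width=30.0)
        b = make_series(np.ones(15 * 24, dtype=int), schedule, bin_width=60.0)
        with pytest.raises(ValueError, match="grid"):
            group_profile([a, b], schedule)


class TestActivityTotals:
    def test_all_ld_activity_gives_zero_propdd(self, schedule):
        counts = np.zeros(15 * 288, dtype=int)
        counts[:100] = 3
        tot = activity_totals(make_series(counts, schedule), schedule)
        assert tot.prop_dd == 0.0 and tot.ta_dd == 0

    def test_identity_and_bounds(self, random_series, schedule):
        tot = activity_totals(random_series, schedule)
        assert tot.ta == tot.ta_ld + tot.ta_dd
        assert 0.0 <= tot.prop_dd <= 1.0

    def test_matches_per_bin_accumulation(self, random_series, schedule):
        from damrhythm import to_zt

        tot = activity_totals(random_series, schedule)
        ld = dd = 0
        for ts, c in zip(random_series.timestamps, random_series.counts):
            day, _ = to_zt(ts, schedule)
            if day <= schedule.ld_days:
                ld += int(c)
            else:
                dd += int(c)
        assert (tot.ta_ld, tot.ta_dd) == (ld, dd)

    def test_silent_individual_has_undefined_propdd(self, schedule):
        tot = activity_totals(make_series(np.zeros(15 * 288, dtype=int), schedule), schedule)
        assert math.isnan(tot.prop_dd)

    def test_cohort_means_are_linear(self, schedule):
        series, _ = simulate_cohort("males_alone", 10, seed=4, schedule=schedule)
        tots = [activity_totals(s, schedule) for s in series]
        assert np.mean([t.ta_ld for t in tots]) + np.mean(
            [t.ta_dd for t in tots]
        ) == pytest.approx(np.mean([t.ta for t in tots]))
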