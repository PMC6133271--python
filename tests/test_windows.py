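import itertools

import numpy as np
import pytest

from deltagroom.pairing import DELAYED, WITHIN_BOUT
from deltagroom.synth import SynthConfig, generate
from deltagroom.pairing import pair_events
from deltagroom.windows import (
    aggregate_windows,
    bootstrap_test,
    loglog_fit,
    resample_null,
)

from .conftest import make_pair


@pytest.fixture(scope="module")
def synth_pairs():
    return pair_events(generate(SynthConfig(n_individuals=10, n_sessions=8, seed=11)))


class TestAggregateWindows:
    def test_partition_arithmetic(self):
        # 40-minute session, 20-minute windows -> pairs land in 2 windows
        pairs = [
            make_pair(X=60, Y=30, x_start=5 * 60),
            make_pair(a="CC", b="DD", X=60, Y=30, x_start=25 * 60),
        ]
        agg = aggregate_windows(pairs, 20)
        assert sorted(agg["window_index"]) == [0, 1]

    def test_conservation_of_condition_totals(self, synth_pairs):
        for cond in (WITHIN_BOUT, DELAYED):
            total = sum(p.X + p.Y for p in synth_pairs if p.condition == cond)
            agg = aggregate_windows(synth_pairs, 20, condition=cond)
            assert float(agg["sum_X_s"].sum() + agg["sum_Y_s"].sum()) == pytest.approx(total)

    def test_p_role_label_symmetry(self):
        # same exchange seen from either first-groomer gives the same P
        p1 = make_pair(a="AA", b="BB", X=80, Y=20, first_groomer="AA")
        p2 = make_pair(a="AA", b="BB", X=80, Y=20, first_groomer="BB", x_start=3000)
        a1 = aggregate_windows([p1], 20)
        a2 = aggregate_windows([p2], 20)
        assert float(a1["P"].iloc[0]) == pytest.approx(float(a2["P"].iloc[0]))
        assert ((a1["P"] >= 0) & (a1["P"] <= 1)).all()

    def test_windows_never_span_sessions(self, synth_pairs):
        agg = aggregate_windows(synth_pairs, 240)
        # every dyad-window key includes its session; indices restart per session
        assert (agg.groupby("session_id")["window_index"].min() == 0).any()
        assert agg["window_index"].min() == 0

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            aggregate_windows([make_pair()], 0)


class TestLogLogFit:
    def test_perfect_matching_gives_unit_slope(self):
        pairs = [
            make_pair(a=f"A{i}", b=f"B{i}", X=50 * (i + 1), Y=50 * (i + 1), x_start=0)
            for i in range(6)
        ]
        fit = loglog_fit(aggregate_windows(pairs, 20))
        assert fit.slope == pytest.approx(1.0, abs=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_too_few_rows_raises(self):
        with pytest.raises(ValueError):
            loglog_fit(aggregate_windows([make_pair()], 20))


class TestResampleNull:
    def test_degenerate_cross_section_is_identity(self):
        pairs = [make_pair(a="AA", b="BB", X=40, Y=70, x_start=i * 1000) for i in range(5)]
        out = resample_null(pairs, seed=3)
        assert all(p.X == 40 and p.Y == 70 for p in out)

    def test_same_seed_is_bit_reproducible(self, synth_pairs):
        a = resample_null(synth_pairs, seed=9)
        b = resample_null(synth_pairs, seed=9)
        assert a == b
        assert a != resample_null(synth_pairs, seed=10)

    def test_structure_preserved(self, synth_pairs):
        out = resample_null(synth_pairs, seed=1)
        for orig, new in zip(synth_pairs, out):
            assert (orig.dyad, orig.session_id, orig.delta, orig.x_start) == (
                new.dyad, new.session_id, new.delta, new.x_start,
            )

    def test_two_point_resampling_distribution(self):
        """Long-run mean over a {1, 3} cross-section converges to 2."""
        pairs = [
            make_pair(a="AA", b="BB", X=1, Y=50, x_start=0),
            make_pair(a="AA", b="BB", X=3, Y=50, x_start=1000, first_groomer="AA"),
        ]
        rng = np.random.default_rng(0)
        draws = [p.X for _ in range(2000) for p in resample_null(pairs, rng)]
        assert np.mean(draws) == pytest.approx(2.0, abs=0.05)
        assert set(draws) == {1, 3}


class TestBootstrap:
    def test_degenerate_durations_collapse_band(self):
        pairs = [
            make_pair(a="AA", b="BB", X=60, Y=60, x_start=i * 100, first_groomer="AA")
            for i in range(4)
        ] + [
            make_pair(a="AA", b="BB", X=60, Y=60, x_start=i * 100 + 50, first_groomer="BB")
            for i in range(4)
        ]
        res = bootstrap_test(pairs, 20, DELAYED, n_reps=200, seed=0)
        assert res.P_med_empirical == 0.0
        assert res.lower_crit == res.upper_crit == 0.0
        assert not res.reject

    def test_same_seed_identical_replicates(self, synth_pairs):
        a = bootstrap_test(synth_pairs, 20, DELAYED, n_reps=300, seed=5)
        b = bootstrap_test(synth_pairs, 20, DELAYED, n_reps=300, seed=5)
        assert np.array_equal(a.replicate_medians, b.replicate_medians)

    def test_unstable_flag_below_100_reps(self, synth_pairs):
        assert bootstrap_test(synth_pairs, 20, DELAYED, n_reps=50, seed=0).unstable

    def test_replicate_distribution_matches_enumeration(self):
        """Two-pair toy data: replicate medians vs exhaustive enumeration."""
        pairs = [
            make_pair(a="AA", b="BB", X=10, Y=30, x_start=0, first_groomer="AA"),
            make_pair(a="AA", b="BB", X=20, Y=40, x_start=100, first_groomer="AA"),
        ]
        # cross-sections: X-actor AA -> {10, 20}; Y-actor BB -> {30, 40};
        # both pairs share one dyad-window, so P_med = |SX-SY|/(SX+SY)
        outcomes = []
        for x1, x2, y1, y2 in itertools.product([10, 20], [10, 20], [30, 40], [30, 40]):
            sx, sy = x1 + x2, y1 + y2
            outcomes.append(abs(sx - sy) / (sx + sy))
        expected = sorted(set(round(o, 12) for o in outcomes))
        res = bootstrap_test(pairs, 20, DELAYED, n_reps=4000, seed=7)
        observed = sorted(set(round(m, 12) for m in res.replicate_medians))
        assert observed == expected
        # each equally-likely outcome appears with its enumeration frequency
        freqs = {v: outcomes.count(v) / len(outcomes) for v in set(outcomes)}
        for v, f in freqs.items():
            got = np.mean(np.round(res.replicate_medians, 12) == round(v, 12))
            assert got == pytest.approx(f, abs=0.05)

    def test_lln_signature_band_shrinks_with_window_size(self, synth_pairs):
        means = []
        for w in (20, 240):
            res = bootstrap_test(synth_pairs, w, WITHIN_BOUT, n_reps=500, seed=2)
            means.append(res.replicate_medians.mean())
        assert means[1] < means[0]
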