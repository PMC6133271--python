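import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deltagroom.metrics import (
    asymmetry_test,
    median_ci,
    mixed_regression,
    rho,
    rm_anova,
)
from deltagroom.pairing import DELAYED, WITHIN_BOUT

from .conftest import make_pair

durations = st.floats(min_value=0.5, max_value=1e6, allow_nan=False)


class TestRho:
    @pytest.mark.parametrize(
        "X,Y,expected", [(30, 30, 0.0), (90, 30, 0.5), (50, 1e-9, pytest.approx(1.0))]
    )
    def test_examples(self, X, Y, expected):
        assert rho(X, Y) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            rho(0, 10)

    @settings(max_examples=300, derandomize=True)
    @given(durations, durations, st.floats(min_value=1e-3, max_value=1e3))
    def test_range_symmetry_scale_invariance(self, X, Y, c):
        r = rho(X, Y)
        assert 0 <= r <= 1
        assert r == rho(Y, X)
        assert rho(c * X, c * Y) == pytest.approx(r, abs=1e-12)
        if X == Y:
            assert r == 0


class TestMedianCI:
    def test_constant_sample_collapses(self):
        ci = median_ci([0.3, 0.3, 0.3])
        assert (ci.lower, ci.median, ci.upper) == (0.3, 0.3, 0.3)

    def test_zero_median_never_rejects(self):
        ci = median_ci([0, 0, 0, 1])
        assert ci.median == 0 and ci.lower <= 0

    def test_matches_notch_formula_reference(self):
        # independent re-evaluation of median +/- 1.58*IQR/sqrt(n)
        rng = np.random.default_rng(42)
        vals = rng.uniform(0.01, 1, size=37)
        ci = median_ci(vals, floor_at_min=False)
        med = float(np.median(vals))
        iqr = float(np.percentile(vals, 75) - np.percentile(vals, 25))
        half = 1.58 * iqr / np.sqrt(vals.size)
        assert ci.median == pytest.approx(med, abs=1e-12)
        assert ci.lower == pytest.approx(med - half, abs=1e-12)
        assert ci.upper == pytest.approx(med + half, abs=1e-12)

    def test_floor_at_min_bounds_lower(self):
        vals = [0.05, 0.95]  # huge IQR drives the formula lower limit below min
        assert median_ci(vals, floor_at_min=True).lower == 0.05
        assert median_ci(vals, floor_at_min=False).lower < 0.05

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            median_ci([])


class TestAsymmetryTest:
    def test_perfectly_matched_dyad_not_rejected(self):
        pairs = [make_pair(X=50, Y=50, x_start=i * 500) for i in range(6)]
        table = asymmetry_test(pairs, by="dyad")
        assert list(table["reject"]) == [False]
        assert table.iloc[0]["median"] == 0

    def test_asymmetric_dyad_rejected(self):
        pairs = [make_pair(X=100, Y=20 + i, x_start=i * 500) for i in range(8)]
        table = asymmetry_test(pairs, by="dyad")
        assert list(table["reject"]) == [True]

    def test_individuals_inherit_pairs_from_both_roles(self):
        pairs = [
            make_pair(a="AA", b="BB", X=60, Y=30, x_start=0),
            make_pair(a="BB", b="CC", X=60, Y=30, x_start=500),
        ]
        table = asymmetry_test(pairs, by="individual").set_index("unit")
        assert set(table.index) == {"AA", "BB", "CC"}
        assert table.loc["BB", "n"] == 2
        assert table.loc["AA", "n"] == 1

    def test_condition_filter_omits_empty_units(self):
        pairs = [make_pair(a="AA", b="BB", delta=-10), make_pair(a="CC", b="DD", delta=50)]
        table = asymmetry_test(pairs, condition=WITHIN_BOUT)
        assert list(table["unit"]) == ["AA-BB"]


class TestRmAnova:
    @staticmethod
    def balanced_pairs(shift=0.0, n_dyads=12, per_cell=4, seed=0):
        rng = np.random.default_rng(seed)
        pairs = []
        for d in range(n_dyads):
            a, b = f"A{d:02d}", f"B{d:02d}"
            for k in range(per_cell):
                # within-bout: near-matched; delayed: shifted asymmetry
                for cond_delta, asym in ((-10, 0.0), (50, shift)):
                    base = 0.1 + 0.05 * rng.random() + asym
                    X = 100
                    Y = X * (1 - base) / (1 + base)  # rho(X, Y) == base
                    pairs.append(
                        make_pair(
                            a=a, b=b, X=X, Y=max(1, int(round(Y))),
                            delta=cond_delta, x_start=(k * 1000 + (cond_delta > 0) * 400),
                        )
                    )
        return pairs

    def test_identical_conditions_give_zero_effect(self):
        pairs = self.balanced_pairs(shift=0.0)
        res = rm_anova(pairs)
        assert res.mean_diff == pytest.approx(0.0, abs=0.05)
        assert res.F < 5

    def test_matches_independent_rm_anova_on_balanced_data(self):
        """Closed-form two-stratum decomposition vs pingouin's RM-ANOVA."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        from deltagroom.metrics import rho_frame

        pairs = self.balanced_pairs(shift=0.3)
        res = rm_anova(pairs)
        df = rho_frame(pairs)
        cells = df.groupby(["dyad", "condition"], as_index=False)["rho"].mean()
        ref = pingouin.rm_anova(data=cells, dv="rho", within="condition", subject="dyad")
        pcol = "p_unc" if "p_unc" in ref.columns else "p-unc"
        assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-8)
        assert res.p == pytest.approx(float(ref[pcol].iloc[0]), rel=1e-6)
        assert (res.df_num, res.df_den) == (int(ref["ddof1"].iloc[0]), int(ref["ddof2"].iloc[0]))

    def test_invariant_to_dyad_relabeling(self):
        pairs = self.balanced_pairs(shift=0.25)
        relabeled = []
        for p in pairs:
            new = make_pair(
                a="X" + p.dyad.a, b="Y" + p.dyad.b, X=p.X, Y=p.Y,
                delta=p.delta, x_start=p.x_start,
            )
            relabeled.append(new)
        a, b = rm_anova(pairs), rm_anova(relabeled)
        assert a.F == pytest.approx(b.F) and a.eta_sq == pytest.approx(b.eta_sq)

    def test_requires_both_conditions_in_enough_dyads(self):
        pairs = [make_pair(a="AA", b="BB", delta=-5), make_pair(a="AA", b="BB", delta=60)]
        with pytest.raises(ValueError):
            rm_anova(pairs)


class TestMixedRegression:
    def test_perfect_time_matching_line(self):
        rng = np.random.default_rng(0)
        pairs = []
        for d in range(10):
            for k in range(5):
                X = int(rng.integers(20, 500))
                pairs.append(
                    make_pair(a=f"A{d}", b=f"B{d}", X=X, Y=X, delta=5, x_start=k * 2000)
                )
        fit = mixed_regression(pairs)
        assert fit.beta == pytest.approx(1.0, abs=1e-6)
        assert fit.alpha == pytest.approx(0.0, abs=1e-4)
        assert fit.p < 1e-10

    def test_single_dyad_degrades_to_ols(self):
        rng = np.random.default_rng(1)
        pairs = []
        for k in range(20):
            X = int(rng.integers(20, 500))
            Y = max(1, int(round(50 + 0.8 * X + rng.normal(0, 10))))
            pairs.append(make_pair(X=X, Y=Y, delta=5, x_start=k * 2000))
        fit = mixed_regression(pairs)
        assert fit.singular and fit.random_intercept_sd == 0.0
        assert fit.beta == pytest.approx(0.8, abs=0.1)

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError):
            mixed_regression([make_pair()])
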