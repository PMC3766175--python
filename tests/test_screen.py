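import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirqpcr import (
    DataError,
    DifferentialExpressionScreen,
    SampleSheet,
    SynthConfig,
    confidence_tier,
    de_call,
    generate_dataset,
    group_stats,
    run_screen,
    signed_fold_change,
    welch_t,
)


def welch_oracle(x, y):
    """Welch formulas evaluated independently, term by term."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "ratio,expected,dp",
        [(1.29 / 1.16, 1.11, 2),   # published worked examples: up-regulated
         (1.04 / 2.39, -2.30, 2),  # and down-regulated group-mean ratios
         (1.0, 1.0, 6),
         (0.5, -2.0, 6)],
    )
    def test_convention(self, ratio, expected, dp):
        assert round(signed_fold_change(ratio), dp) == expected

    @pytest.mark.parametrize("bad", [0.0, -1.5, float("inf"), float("nan")])
    def test_nonpositive_ratio_rejected(self, bad):
        with pytest.raises(DataError):
            signed_fold_change(bad)

    @settings(deadline=None, max_examples=100)
    @given(st.floats(1e-6, 1e6))
    def test_antisymmetry_and_magnitude(self, r):
        fc = signed_fold_change(r)
        assert abs(fc) >= 1.0
        if r != 1.0:
            assert signed_fold_change(1.0 / r) == pytest.approx(-fc)


class TestWelch:
    def test_identical_samples(self):
        t, _, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_against_independent_formula_evaluation(self):
        x, y = (1.0, 2.0, 3.0, 4.0), (2.0, 3.0, 4.0, 5.0)
        t, df, p = welch_t(x, y)
        et, edf, ep = welch_oracle(x, y)
        assert t == pytest.approx(et, rel=1e-12)
        assert df == pytest.approx(edf, rel=1e-12)
        assert p == pytest.approx(ep, rel=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(seed=st.integers(0, 10_000), nx=st.integers(2, 12), ny=st.integers(2, 12))
    def test_random_vectors_match_formulas(self, seed, nx, ny):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(0, 1, nx), rng.normal(0.3, 2, ny)
        t, df, p = welch_t(x, y)
        et, edf, ep = welch_oracle(x, y)
        assert (t, df, p) == pytest.approx((et, edf, ep), rel=1e-10)

    def test_zero_variance_conventions(self):
        assert welch_t([2, 2], [2, 2])[2] == 1.0
        t, _, p = welch_t([3, 3], [2, 2])
        assert p == 0.0 and t == math.inf

    def test_too_few_values_rejected(self):
        with pytest.raises(DataError):
            welch_t([1], [2, 3])


class TestDeCall:
    @pytest.mark.parametrize(
        "p,mfc,mdfc,expected",
        [(0.5, -2.5, -1.1, True),   # fold-change prerequisite alone suffices
         (0.09, 1.1, 1.1, True),    # p-value prerequisite alone suffices
         (0.1, 1.0, 1.0, True),     # thresholds are inclusive
         (0.5, 1.5, -1.5, False),
         (0.5, 1.999, 2.0, True)],
    )
    def test_union_of_three_prerequisites(self, p, mfc, mdfc, expected):
        assert de_call(p, mfc, mdfc) is expected

    @settings(deadline=None, max_examples=100)
    @given(p=st.floats(0, 1), mfc=st.floats(1, 10), mdfc=st.floats(1, 10),
           dp=st.floats(0, 0.5), dfc=st.floats(0, 5))
    def test_monotone_in_evidence(self, p, mfc, mdfc, dp, dfc):
        if de_call(p, mfc, mdfc):
            assert de_call(max(p - dp, 0.0), mfc + dfc, mdfc + dfc)


class TestConfidenceTier:
    def _flags(self, good, low, values=(10, 10)):
        return pd.DataFrame(
            {"values": values, "good": good,
             "normal": [v - g - l for v, g, l in zip(values, good, low)],
             "low": low, "nd": [0, 0]},
            index=pd.Index(["endometriosis", "control"], name="group"),
        )

    def test_good_in_both_groups_no_low_is_top(self):
        assert confidence_tier(self._flags(good=[3, 1], low=[0, 0])) == "top"

    def test_all_normal_is_medium(self):
        assert confidence_tier(self._flags(good=[0, 0], low=[0, 0])) == "medium"

    def test_any_low_anywhere_is_low(self):
        assert confidence_tier(self._flags(good=[5, 5], low=[0, 1])) == "low"

    def test_good_in_one_group_only_is_medium(self):
        assert confidence_tier(self._flags(good=[2, 0], low=[0, 0])) == "medium"


class TestGroupStats:
    def _rq(self, case_vals, ctrl_vals):
        cols = [f"e{i}" for i in range(len(case_vals))] + \
               [f"c{i}" for i in range(len(ctrl_vals))]
        sheet = SampleSheet.from_groups(
            {**{f"e{i}": "endometriosis" for i in range(len(case_vals))},
             **{f"c{i}": "control" for i in range(len(ctrl_vals))}},
            calibrator="c0",
        )
        rq = pd.DataFrame([list(case_vals) + list(ctrl_vals)], index=["m1"],
                          columns=cols)
        return rq, sheet

    def test_simple_example(self):
        rq, sheet = self._rq([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        gs = group_stats(rq, sheet)
        row = gs.loc[("m1", "endometriosis")]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sd"] == pytest.approx(1.0)
        assert row["cv"] == pytest.approx(50.0)
        assert row["maxmin_r"] == pytest.approx(3.0)
        assert row["median"] == pytest.approx(2.0)
        ctrl = gs.loc[("m1", "control")]
        assert ctrl["sd"] == 0.0 and ctrl["cv"] == 0.0 and ctrl["maxmin_r"] == 1.0

    def test_random_vectors_against_two_pass_oracle(self):
        rng = np.random.default_rng(11)
        case, ctrl = rng.uniform(0.1, 5, 6), rng.uniform(0.1, 5, 5)
        rq, sheet = self._rq(case, ctrl)
        row = group_stats(rq, sheet).loc[("m1", "endometriosis")]
        mean = sum(case) / len(case)
        sd = math.sqrt(sum((v - mean) ** 2 for v in case) / (len(case) - 1))
        assert row["mean"] == pytest.approx(mean)
        assert row["sd"] == pytest.approx(sd)
        assert row["cv"] == pytest.approx(100 * sd / mean)
        assert row["maxmin_r"] == pytest.approx(max(case) / min(case))

    def test_small_group_dropped(self):
        rq, sheet = self._rq([1.0], [2.0, 3.0])
        assert len(group_stats(rq, sheet)) == 0


class TestRunScreen:
    def test_noiseless_planted_twofold_recovered_exactly(self):
        cfg = SynthConfig(n_assays=20, n_planted=1, planted_fold_changes=(2.0,),
                          loading_sd=0.0, noise_sd=0.0, seed=5)
        ds = generate_dataset(cfg)
        res = run_screen(ds.ct, ds.sheet, ds.panel,
                         case_group="endometriosis", control_group="control")
        planted = ds.truth.loc[ds.truth.fold_change != 1.0, "assay"].iloc[0]
        rec = res.records.set_index("assay")
        assert rec.loc[planted, "mean_fc"] == pytest.approx(2.0)
        assert rec.loc[planted, "de_call"]
        nulls = rec.drop(index=planted)
        assert (nulls["mean_fc"] == 1.0).all() and (~nulls["de_call"]).all()

    def test_group_swap_negates_fold_changes_keeps_p(self):
        ds = generate_dataset(SynthConfig(n_assays=15, n_planted=3, seed=9))
        a = run_screen(ds.ct, ds.sheet, ds.panel,
                       case_group="endometriosis", control_group="control")
        b = run_screen(ds.ct, ds.sheet, ds.panel,
                       case_group="control", control_group="endometriosis")
        ra = a.records.set_index("assay").sort_index()
        rb = b.records.set_index("assay").sort_index()
        np.testing.assert_allclose(ra["mean_fc"], -rb["mean_fc"])
        np.testing.assert_allclose(ra["median_fc"], -rb["median_fc"])
        np.testing.assert_allclose(ra["p_welch"], rb["p_welch"])

    def test_sample_order_invariance(self):
        from mirqpcr import CtMatrix

        ds = generate_dataset(SynthConfig(n_assays=12, n_planted=2, seed=4))
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(ds.ct.samples))
        shuffled = CtMatrix(ds.ct.values[perm])
        a = run_screen(ds.ct, ds.sheet, ds.panel, case_group="endometriosis")
        b = run_screen(shuffled, ds.sheet, ds.panel, case_group="endometriosis")
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_records_sorted_by_tier_then_p(self):
        ds = generate_dataset(SynthConfig(n_assays=40, n_planted=4, seed=21))
        res = run_screen(ds.ct, ds.sheet, ds.panel, case_group="endometriosis")
        ranks = res.records["tier"].map({"top": 0, "medium": 1, "low": 2})
        assert ranks.is_monotonic_increasing
        for _, grp in res.records.groupby("tier", sort=False):
            assert grp["p_welch"].is_monotonic_increasing

    def test_null_de_fraction_tracks_union_of_criteria(self):
        """With no planted effects, the DE rate is dominated by the p<=0.1 arm."""
        ds = generate_dataset(SynthConfig(n_assays=667, seed=13))
        res = run_screen(ds.ct, ds.sheet, ds.panel, case_group="endometriosis")
        frac_de = res.records["de_call"].mean()
        frac_p = (res.records["p_welch"] <= 0.1).mean()
        assert frac_p <= frac_de <= frac_p + 0.05
        assert 0.05 < frac_de < 0.20

    def test_estimator_surface(self):
        from sklearn.base import clone

        ds = generate_dataset(SynthConfig(n_assays=10, seed=2))
        est = DifferentialExpressionScreen(case_group="endometriosis",
                                           control_group="control")
        assert clone(est).get_params()["p_threshold"] == 0.1
        with pytest.raises(TypeError):
            est.fit(np.zeros((4, 3)), ["a", "a", "b", "b"])
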