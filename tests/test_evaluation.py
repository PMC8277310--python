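"""Longitudinal evaluation: mixed models, BH adjustment, ordinal models,
outlier rule and delta correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import bh_oracle
from nutrispace.evaluation import (
    bh_adjust,
    correlation_table,
    delta_correlations,
    fit_ordinal_mixed,
    fit_time_mixed_model,
    flag_outliers,
    required_sample_size,
    subset_by_strategy,
)


def long_frame(values_by_week, subjects=None):
    """Tidy frame from {week: [values...]} with aligned subjects."""
    rows = []
    for week, vals in values_by_week.items():
        ids = subjects or [f"S{i}" for i in range(len(vals))]
        rows += [{"participant_id": s, "week": week, "value": v}
                 for s, v in zip(ids, vals)]
    return pd.DataFrame(rows)


def simulate_cohort(rng, n, deltas=(0.0, 0.0), sd_b=1.0, sd_e=1.0, mean=0.0):
    b = rng.normal(0, sd_b, n)
    frames = {}
    for week, d in zip((0, 8, 16), (0.0,) + tuple(deltas)):
        frames[week] = mean + d + b + rng.normal(0, sd_e, n)
    return long_frame(frames)


class TestBhAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    @settings(derandomize=True, max_examples=100)
    @given(ps=st.lists(st.floats(0, 1), min_size=1, max_size=6))
    def test_matches_brute_force_oracle(self, ps):
        assert bh_adjust(ps) == pytest.approx(bh_oracle(ps), abs=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(ps=st.lists(st.floats(0, 1), min_size=2, max_size=6),
           seed=st.integers(0, 1000))
    def test_order_invariant(self, ps, seed):
        perm = np.random.default_rng(seed).permutation(len(ps))
        adj = bh_adjust(ps)
        adj_perm = bh_adjust(list(np.asarray(ps)[perm]))
        assert adj_perm == pytest.approx(np.asarray(adj)[perm], abs=1e-12)

    def test_adjusted_at_least_raw(self):
        ps = [0.001, 0.04, 0.3, 0.9]
        adj = bh_adjust(ps)
        assert (adj >= np.asarray(ps) - 1e-15).all() and (adj <= 1).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestTimeMixedModel:
    def test_subject_offset_only_gives_zero_time_effect(self):
        df = long_frame({0: [1.0, 5.0], 8: [1.0, 5.0], 16: [1.0, 5.0]})
        # constant within subject, pure between-subject shift
        res = fit_time_mixed_model(df)
        for c in res.contrasts:
            assert c.estimate == pytest.approx(0.0, abs=1e-8)

    def test_balanced_contrasts_equal_paired_differences(self):
        rng = np.random.default_rng(0)
        df = simulate_cohort(rng, 40, deltas=(1.0, 2.5))
        res = fit_time_mixed_model(df, remove_outliers=False)
        wide = df.pivot(index="participant_id", columns="week", values="value")
        for c in res.contrasts:
            paired = (wide[c.week_b] - wide[c.week_a]).mean()
            assert c.estimate == pytest.approx(paired, abs=1e-6)
        assert res.emmeans[0] == pytest.approx(wide[0].mean(), abs=1e-6)

    def test_recovers_shift_and_detects_it(self):
        rng = np.random.default_rng(1)
        df = simulate_cohort(rng, 60, deltas=(2.0, 4.0), sd_b=1.0, sd_e=1.0)
        res = fit_time_mixed_model(df)
        assert res.contrast(0, 16).estimate == pytest.approx(4.0, abs=0.75)
        assert res.overall_p < 1e-4
        assert res.contrast(0, 16).p_adj >= res.contrast(0, 16).p_raw - 1e-15

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_time_mixed_model(long_frame({0: [1.0, 1.0], 16: [1.0, 1.0]}))
        single = long_frame({0: [1.0], 8: [2.0], 16: [1.5]}, subjects=["A"])
        with pytest.raises(ValueError):
            fit_time_mixed_model(single)
        with pytest.raises(ValueError):
            fit_time_mixed_model(long_frame({0: [1.0, 2.0]}))

    def test_outlier_removed_and_refit_once(self):
        rng = np.random.default_rng(2)
        df = simulate_cohort(rng, 30, deltas=(0.0, 0.0), sd_b=0.2, sd_e=0.5)
        df.loc[5, "value"] += 30.0
        res = fit_time_mixed_model(df)
        assert res.outlier_ids == (5,)
        assert res.n_obs == len(df) - 1


class TestFlagOutliers:
    def test_boundary_is_strict(self):
        # residual exactly 3 x RMSE is not an outlier; just above is
        r = np.array([1.0, -1.0, 1.0, -1.0, 3.0])
        rmse = float(np.sqrt(np.mean(r**2)))
        assert list(flag_outliers(r * 0 + r, rmse=rmse / (3 / 3))) == []
        assert list(flag_outliers(r, rmse=1.0)) == []  # 3.0 == 3 x 1.0
        r[4] = 3.1
        assert list(flag_outliers(r, rmse=1.0)) == [4]

    def test_zero_residuals_no_flags(self):
        assert list(flag_outliers(np.zeros(10))) == []

    def test_scale_equivariant(self):
        rng = np.random.default_rng(3)
        r = rng.normal(0, 1, 200)
        r[7] = 12.0
        assert list(flag_outliers(r)) == list(flag_outliers(5.0 * r))
        assert list(flag_outliers(r)) == list(flag_outliers(r / 100.0))


class TestOrdinalMixed:
    @staticmethod
    def simulate_likert(rng, n, shift, sd_b=1.0):
        b = rng.normal(0, sd_b, n)
        rows = []
        for week, d in ((0, 0.0), (16, shift)):
            latent = 4.0 + d + b + rng.normal(0, 1.0, n)
            obs = np.clip(np.round(latent), 1, 7)
            rows += [{"participant_id": f"S{i}", "week": week, "value": v}
                     for i, v in enumerate(obs)]
        return pd.DataFrame(rows)

    def test_latent_shift_detected(self):
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(10):
            df = self.simulate_likert(rng, 150, shift=1.0)
            res = fit_ordinal_mixed(df)
            if res.overall_p < 0.05 and res.coefficients[16] > 0:
                hits += 1
        assert hits >= 9

    def test_null_rarely_rejects(self):
        rng = np.random.default_rng(5)
        rejections = sum(
            fit_ordinal_mixed(self.simulate_likert(rng, 80, 0.0)).overall_p < 0.05
            for _ in range(20))
        assert rejections <= 4

    def test_matches_fixed_effects_model_without_random_intercept(self):
        """With the random intercept disabled the CLMM must agree with the
        standard proportional-odds fit."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        rng = np.random.default_rng(6)
        df = self.simulate_likert(rng, 120, shift=0.8, sd_b=0.0)
        ours = fit_ordinal_mixed(df, random_intercept=False)
        ref = OrderedModel(df["value"].astype(int),
                           (df["week"] == 16).astype(float).to_frame("t16"),
                           distr="logit").fit(method="bfgs", disp=False)
        assert ours.coefficients[16] == pytest.approx(ref.params["t16"], abs=0.02)

    def test_constant_response_rejected(self):
        df = long_frame({0: [4, 4, 4], 16: [4, 4, 4]})
        with pytest.raises(ValueError):
            fit_ordinal_mixed(df)

    def test_missing_levels_collapse_with_warning(self):
        df = long_frame({0: [1, 1, 2, 2, 7, 1, 2, 7], 16: [2, 7, 7, 2, 7, 1, 1, 2]})
        with pytest.warns(UserWarning, match="collapsed"):
            res = fit_ordinal_mixed(df)
        assert len(res.thresholds) == 2  # 3 observed levels


class TestDeltaCorrelations:
    def test_identical_vectors(self):
        r, _ = delta_correlations([1.0, 2.0, 3.5], [1.0, 2.0, 3.5])
        assert r == pytest.approx(1.0)

    def test_negation(self):
        r, _ = delta_correlations([1.0, 2.0, 3.5], [-1.0, -2.0, -3.5])
        assert r == pytest.approx(-1.0)

    def test_affine_relation(self):
        r, _ = delta_correlations([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            delta_correlations([1, 1, 1], [1, 2, 3])

    def test_correlation_table_flags_fragile_pairs(self):
        rng = np.random.default_rng(7)
        n = 20
        noise = pd.DataFrame({"a": rng.normal(0, 1, n),
                              "b": rng.normal(0, 1, n)})
        noise.loc[0, ["a", "b"]] = [12.0, 12.0]  # one point manufactures r
        out = correlation_table(noise, ["a"], ["b"])
        row = out.iloc[0]
        assert row["p"] < 0.05 and row["fragile"]


def test_subset_by_strategy():
    records = pd.DataFrame({"participant_id": list("ABCDE"), "x": range(5)})
    strategies = {"A": ("nuts",), "B": ("fish",), "C": ("nuts", "fish"),
                  "D": ("nuts",), "E": ("dairy",)}
    got = subset_by_strategy(records, strategies, "nuts")
    assert set(got["participant_id"]) == {"A", "C", "D"}
    assert subset_by_strategy(records, strategies, "sugar_beverages").empty
    assert len(subset_by_strategy(records, {k: ("x",) for k in "ABCDE"}, "x")) == 5


def test_required_sample_size_behaves():
    n = required_sample_size(1.85, 2.67)
    assert 5 < n < 40
    assert required_sample_size(1.85, 2.67, power=0.95) > n
    with pytest.raises(ValueError):
        required_sample_size(1.0, 0.0)
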