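"""Robust rank aggregation, reference selection and health-space scoring."""

import numpy as np
import pandas as pd
import pytest

from conftest import rra_oracle
from nutrispace.healthspace import (
    FEATURES,
    HIGHER_IS_HEALTHIER,
    HealthSpaceModel,
    classification_metrics,
    fit_health_space,
    normalize_ranks,
    predict_score,
    rra_rho,
    select_healthy_reference,
    select_mets_reference,
)
from nutrispace.synthetic import generate_reference_pool


class TestNormalizeRanks:
    def test_hand_ranking_higher_healthier(self):
        ranks = normalize_ranks([1.6, 1.0, 1.2], higher_is_healthier=True)
        assert ranks == pytest.approx([1 / 3, 1.0, 2 / 3])

    def test_lower_healthier(self):
        ranks = normalize_ranks([1.6, 1.0, 1.2], higher_is_healthier=False)
        assert ranks == pytest.approx([1.0, 1 / 3, 2 / 3])

    def test_single_element(self):
        assert normalize_ranks([5.0], True) == pytest.approx([1.0])

    def test_ties_share_mean_position(self):
        ranks = normalize_ranks([2.0, 2.0, 2.0], False)
        assert ranks == pytest.approx([2 / 3] * 3)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            normalize_ranks([], True)


class TestRraRho:
    def test_single_list_is_identity(self):
        assert rra_rho([0.1]) == pytest.approx(0.1)

    def test_m2_closed_form(self):
        # min(1 - (1 - 0.2)^2, 0.5^2) = min(0.36, 0.25)
        assert rra_rho([0.2, 0.5]) == pytest.approx(0.25)

    def test_matches_binomial_tail_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            m = rng.integers(1, 7)
            r = rng.uniform(1e-6, 1.0, size=m)
            assert rra_rho(r) == pytest.approx(rra_oracle(r), abs=1e-10)

    def test_bonferroni_super_uniform(self):
        """m * rho is stochastically >= uniform under random ranks."""
        rng = np.random.default_rng(11)
        m = 3
        rho = np.array([rra_rho(rng.uniform(1e-9, 1, m)) for _ in range(4000)])
        for alpha in (0.01, 0.05, 0.2):
            assert np.mean(m * rho <= alpha) <= alpha + 3 * np.sqrt(alpha / 4000)

    def test_rank_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            rra_rho([0.0, 0.5])
        with pytest.raises(ValueError):
            rra_rho([0.5, 1.2])


def _toy_pool(n, seed, healthy_spec):
    pool = generate_reference_pool(healthy_spec, n, seed)
    # keep everyone eligible: thin bodies, quiet biomarkers
    pool["bmi"] = np.linspace(19, 24, n)
    pool["waist"] = 75.0
    pool["sbp"], pool["dbp"] = 118.0, 72.0
    pool["triglycerides"] = np.clip(pool["triglycerides"], 0.3, 1.6)
    pool["hdl"] = np.clip(pool["hdl"], 1.3, None)
    pool["glucose"] = np.clip(pool["glucose"], 4.0, 5.5)
    return pool


class TestHealthyReferenceSelection:
    def test_dominant_subject_ranks_first(self, healthy_spec):
        pool = _toy_pool(12, 3, healthy_spec)
        best = pool.index[5]
        pool.loc[best, ["triglycerides", "ldl", "glucose", "c_peptide"]] = 0.21
        pool.loc[best, "hdl"] = 3.5
        top = select_healthy_reference(pool, n_top=3)
        assert pool.loc[best, "subject_id"] in set(top["subject_id"])
        assert top.iloc[0]["subject_id"] == pool.loc[best, "subject_id"]

    def test_n_top_equals_pool(self, healthy_spec):
        pool = _toy_pool(8, 4, healthy_spec)
        top = select_healthy_reference(pool, n_top=8)
        assert set(top["subject_id"]) == set(pool["subject_id"])

    def test_matches_exhaustive_oracle(self, healthy_spec):
        pool = _toy_pool(20, 5, healthy_spec)
        top = select_healthy_reference(pool, n_top=6)
        # brute force: compute every subject's rho from scratch
        rhos = {}
        cols = {f: normalize_ranks(pool[f].to_numpy(), HIGHER_IS_HEALTHIER[f])
                for f in FEATURES}
        for i in range(len(pool)):
            rhos[pool.iloc[i]["subject_id"]] = rra_oracle(
                [cols[f][i] for f in FEATURES])
        expected = sorted(rhos, key=lambda s: (rhos[s], s))[:6]
        assert list(top["subject_id"]) == expected

    def test_monotone_transform_invariance(self, healthy_spec):
        pool = _toy_pool(15, 6, healthy_spec)
        top_a = select_healthy_reference(pool, n_top=5)
        # strictly monotone warps that keep every subject screening-eligible
        warped = pool.copy()
        warped["triglycerides"] = warped["triglycerides"] / 10.0
        warped["ldl"] = np.exp(warped["ldl"] / 2.0)
        warped["c_peptide"] = warped["c_peptide"] ** 3
        top_b = select_healthy_reference(warped, n_top=5)
        assert list(top_a["subject_id"]) == list(top_b["subject_id"])

    def test_too_few_eligible_raises(self, healthy_spec):
        pool = _toy_pool(5, 7, healthy_spec)
        with pytest.raises(ValueError):
            select_healthy_reference(pool, n_top=6)


def test_mets_reference_rule(mets_spec):
    pool = generate_reference_pool(mets_spec, 60, 9)
    pool["dbp"] = np.minimum(pool["dbp"], pool["sbp"] - 1)
    selected = select_mets_reference(pool)
    # spot-check the rule on a clear member and an empty pool
    assert len(select_mets_reference(pool.iloc[0:0])) == 0
    member = pd.DataFrame([dict(subject_id=1, sex="F", waist=100.0, bmi=33.0,
                                sbp=140.0, dbp=90.0, total_cholesterol=5.0,
                                hdl=1.0, ldl=3.0, triglycerides=2.5,
                                glucose=6.5, c_peptide=1.5)])
    assert len(select_mets_reference(member)) == 1
    clean = member.assign(waist=80.0, sbp=118.0, dbp=70.0, triglycerides=1.0,
                          hdl=1.5, glucose=5.0)
    assert len(select_mets_reference(clean)) == 0
    assert len(selected) <= len(pool)


def _groups(seed, n=120, sep=4.0):
    """Two well-separated synthetic groups for fitting checks."""
    rng = np.random.default_rng(seed)
    cols = list(FEATURES)
    healthy = pd.DataFrame(rng.normal(0.0, 1.0, (n, 5)), columns=cols)
    mets = pd.DataFrame(rng.normal(sep, 1.0, (n, 5)), columns=cols)
    healthy["hdl"] += sep + sep  # make HDL higher in healthy, rest lower
    healthy[["triglycerides", "ldl", "glucose", "c_peptide"]] += 2 * sep
    healthy["sex"] = rng.choice(["M", "F"], n)
    mets["sex"] = rng.choice(["M", "F"], n)
    return healthy, mets


class TestFitAndPredict:
    def test_separable_groups_classify_perfectly(self):
        healthy, mets = _groups(0)
        model = fit_health_space(healthy, mets)
        scores = np.r_[predict_score(model, healthy), predict_score(model, mets)]
        truth = np.r_[np.ones(len(healthy)), np.zeros(len(mets))].astype(bool)
        acc, kappa = classification_metrics(truth, scores)
        assert acc == 1.0 and kappa == 1.0

    def test_no_signal_means_flat_scores(self):
        rng = np.random.default_rng(1)
        same = pd.DataFrame(rng.normal(0, 1, (300, 5)), columns=list(FEATURES))
        same["sex"] = rng.choice(["M", "F"], 300)
        other = pd.DataFrame(rng.normal(0, 1, (300, 5)), columns=list(FEATURES))
        other["sex"] = rng.choice(["M", "F"], 300)
        model = fit_health_space(same, other, random_structure="none")
        assert all(abs(c) < 0.1 for c in model.coefficients.values())
        assert predict_score(model, same).mean() == pytest.approx(1.5, abs=0.1)

    def test_score_monotone_in_hdl(self):
        healthy, mets = _groups(2)
        model = fit_health_space(healthy, mets)
        assert model.coefficients["hdl"] > 0
        row = mets.iloc[[0]].copy()
        low = predict_score(model, row).iloc[0]
        row["hdl"] += 2.0
        assert predict_score(model, row).iloc[0] > low

    def test_healthy_mean_scores_near_two(self):
        healthy, mets = _groups(3, sep=6.0)
        model = fit_health_space(healthy, mets)
        at_mean = pd.DataFrame([healthy[list(FEATURES)].mean()])
        at_mean["sex"] = "F"
        assert predict_score(model, at_mean).iloc[0] == pytest.approx(2.0, abs=0.1)

    def test_constant_model_returns_intercept(self):
        model = HealthSpaceModel(
            features=FEATURES, means={f: 0.0 for f in FEATURES},
            sds={f: 1.0 for f in FEATURES}, intercept=1.5,
            coefficients={f: 0.0 for f in FEATURES})
        df = pd.DataFrame(np.random.default_rng(4).normal(0, 1, (5, 5)),
                          columns=list(FEATURES))
        assert predict_score(model, df).tolist() == [1.5] * 5

    def test_swapping_class_codes_reflects_scores(self):
        healthy, mets = _groups(5)
        a = fit_health_space(healthy, mets, random_structure="none")
        b = fit_health_space(healthy, mets, random_structure="none",
                             class_codes={"mets": 2.0, "healthy": 1.0})
        sa = predict_score(a, mets)
        sb = predict_score(b, mets)
        assert np.allclose(sa + sb, 3.0, atol=1e-8)

    def test_single_sex_falls_back_with_warning(self):
        healthy, mets = _groups(6)
        healthy["sex"] = "F"
        mets["sex"] = "F"
        with pytest.warns(UserWarning, match="one sex"):
            model = fit_health_space(healthy, mets)
        assert model.random_structure == "none"
        assert model.sex_adjustments == {}

    def test_unknown_sex_uses_population_coefficients(self):
        healthy, mets = _groups(7)
        model = fit_health_space(healthy, mets)
        assert model.sex_adjustments  # sex-specific fit succeeded
        row = healthy.iloc[[0]].copy()
        row["sex"] = "?"
        with pytest.warns(UserWarning, match="unknown sex"):
            predict_score(model, row)

    def test_empty_group_rejected(self):
        healthy, mets = _groups(8)
        with pytest.raises(ValueError):
            fit_health_space(healthy.iloc[0:0], mets)

    def test_json_round_trip(self, tmp_path):
        healthy, mets = _groups(9)
        model = fit_health_space(healthy, mets)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = HealthSpaceModel.from_json(path)
        assert back.coefficients == model.coefficients
        assert back.sex_adjustments == model.sex_adjustments
        x = healthy.iloc[:4]
        assert np.allclose(predict_score(back, x), predict_score(model, x))


class TestClassificationMetrics:
    def test_hand_computed_confusion(self):
        # 45/5 and 5/45: accuracy 0.9; pe = 0.5 so kappa 0.8
        truth = np.r_[np.ones(50), np.zeros(50)].astype(bool)
        scores = np.r_[np.full(45, 1.8), np.full(5, 1.2),
                       np.full(5, 1.8), np.full(45, 1.2)]
        acc, kappa = classification_metrics(truth, scores)
        assert acc == pytest.approx(0.90)
        assert kappa == pytest.approx(0.80)

    def test_perfect_prediction(self):
        truth = np.array([True, True, False, False])
        acc, kappa = classification_metrics(truth, [1.9, 1.7, 1.1, 1.3])
        assert acc == 1.0 and kappa == 1.0

    def test_chance_level_kappa_near_zero(self):
        rng = np.random.default_rng(10)
        truth = rng.random(4000) < 0.5
        scores = np.where(rng.random(4000) < 0.5, 1.8, 1.2)
        _, kappa = classification_metrics(truth, scores)
        assert abs(kappa) < 0.05

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([True, True], [1.8, 1.9])
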