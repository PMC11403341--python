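import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from reekit import (
    Subject,
    compare_groups,
    fit_to_equation,
    predict,
    random_split,
    stepwise_regression,
)
from reekit.development import CollinearityError, SplitResult, cohort_frame

from conftest import make_subject


def _cohort(n, rng, ree_fn=None, height_from_weight=False):
    subjects = []
    for i in range(n):
        sex = "male" if rng.random() < 0.5 else "female"
        weight = rng.uniform(45, 120)
        height = (
            100 + 0.9 * weight + rng.normal(0, 5)
            if height_from_weight
            else rng.uniform(150, 195)
        )
        age = rng.uniform(18, 60)
        s = Subject(f"s{i}", sex, age, weight, height)
        ree = ree_fn(s) if ree_fn else None
        subjects.append(
            Subject(f"s{i}", sex, age, weight, height, ree_measured=ree)
        )
    return subjects


class TestRandomSplit:
    def test_even_split_sizes_and_partition(self, study_cohort):
        split = random_split(study_cohort, seed=11)
        assert len(split.development) == len(split.validation) == 142
        dev_ids = {s.id for s in split.development}
        val_ids = {s.id for s in split.validation}
        assert dev_ids.isdisjoint(val_ids)
        assert dev_ids | val_ids == {s.id for s in study_cohort}

    def test_deterministic_for_fixed_seed(self, study_cohort):
        a = random_split(study_cohort, seed=5)
        b = random_split(study_cohort, seed=5)
        assert [s.id for s in a.development] == [s.id for s in b.development]

    def test_odd_cohort_sizes_differ_by_one(self, rng):
        cohort = _cohort(5, rng)
        split = random_split(cohort, seed=0)
        sizes = sorted([len(split.development), len(split.validation)])
        assert sizes == [2, 3]
        assert {s.id for s in split.development}.isdisjoint(
            {s.id for s in split.validation}
        )

    def test_undersized_cohort_rejected(self, rng):
        with pytest.raises(ValueError):
            random_split(_cohort(3, rng), seed=0)

    def test_each_subject_in_development_half_the_time(self, rng):
        """Over many seeds the split is symmetric per subject (binomial)."""
        cohort = _cohort(10, rng)
        n_seeds = 1000
        counts = {s.id: 0 for s in cohort}
        for seed in range(n_seeds):
            for s in random_split(cohort, seed=seed).development:
                counts[s.id] += 1
        # binomial(1000, 0.5): SE ~ 0.0158, allow 4 SEs
        for sid, c in counts.items():
            assert abs(c / n_seeds - 0.5) < 0.065, sid


class TestCompareGroups:
    def test_identical_groups_give_p_one(self, rng):
        cohort = tuple(_cohort(30, rng, ree_fn=lambda s: 1500.0 + s.weight))
        split = SplitResult(development=cohort, validation=cohort, seed=0)
        comp = compare_groups(split)
        assert (comp.continuous["p"] > 0.999).all()

    def test_injected_weight_shift_detected(self, rng):
        dev = tuple(_cohort(142, rng, ree_fn=lambda s: 1500.0))
        val = tuple(
            Subject(s.id + "v", s.sex, s.age, s.weight + 20.0, s.height, 1500.0)
            for s in _cohort(142, rng, ree_fn=lambda s: 1500.0)
        )
        comp = compare_groups(SplitResult(development=dev, validation=val, seed=0))
        assert comp.continuous.loc["weight", "p"] < 0.001
        # textbook two-sample t on the same arrays agrees
        a = np.array([s.weight for s in dev])
        b = np.array([s.weight for s in val])
        assert comp.continuous.loc["weight", "p"] == pytest.approx(
            stats.ttest_ind(a, b).pvalue
        )

    def test_sex_chi_square_matches_pearson(self):
        """74/68 vs 84/58 females/males of 142: Pearson chi-square p = 0.23."""
        def block(n_f, n_m, tag):
            subs = []
            for i in range(n_f):
                subs.append(Subject(f"{tag}f{i}", "female", 30, 60, 165, 1400))
            for i in range(n_m):
                subs.append(Subject(f"{tag}m{i}", "male", 30, 75, 178, 1700))
            return tuple(subs)

        split = SplitResult(block(74, 68, "d"), block(84, 58, "v"), seed=0)
        comp = compare_groups(split)
        assert comp.sex_counts["development"].tolist() == [74, 68]
        assert comp.sex_counts["validation"].tolist() == [84, 58]
        assert comp.sex_p == pytest.approx(0.2323, abs=0.001)
        assert comp.sex_p > 0.05


class TestStepwise:
    def test_exact_recovery_in_noise_free_limit(self, rng):
        cohort = _cohort(
            200, rng,
            ree_fn=lambda s: 2.0 * s.weight + 300.0 * s.is_male + 100.0,
            height_from_weight=True,
        )
        fit = stepwise_regression(cohort)
        assert set(fit.included_predictors) == {"weight", "sex"}
        assert fit.coefficients["weight"] == pytest.approx(2.0, abs=1e-6)
        assert fit.coefficients["sex"] == pytest.approx(300.0, abs=1e-6)
        assert fit.intercept == pytest.approx(100.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_thresholds_reduce_to_full_ols(self, rng):
        cohort = _cohort(
            150, rng,
            ree_fn=lambda s: 9 * s.weight + 280 * s.is_male - 8 * s.age
            + 1040 + rng.normal(0, 250),
        )
        fit = stepwise_regression(cohort, p_enter=1.0, p_remove=1.0001)
        assert set(fit.included_predictors) == {"weight", "sex", "age", "height"}
        frame = cohort_frame(cohort)
        X = sm.add_constant(frame[["weight", "sex", "age", "height"]])
        oracle = sm.OLS(frame["ree_measured"], X).fit()
        for name in ("weight", "sex", "age", "height"):
            assert fit.coefficients[name] == pytest.approx(
                oracle.params[name], abs=1e-8
            )
        assert fit.intercept == pytest.approx(oracle.params["const"], abs=1e-8)

    def test_pure_noise_gives_empty_model(self, rng):
        # measured REE unrelated to any candidate
        noise = iter(rng.normal(1500, 100, size=500))
        cohort = _cohort(60, rng, ree_fn=lambda s: next(noise))
        fit = stepwise_regression(cohort, candidates=["height"])
        if not fit.included_predictors:  # almost always at p_enter=0.05
            y = [s.ree_measured for s in cohort]
            assert fit.intercept == pytest.approx(np.mean(y))
            assert fit.r_squared == 0.0

    def test_r_squared_equals_squared_corr_of_fitted_and_observed(self, rng):
        cohort = _cohort(
            120, rng,
            ree_fn=lambda s: 9 * s.weight + 300 * s.is_male + rng.normal(900, 220),
        )
        fit = stepwise_regression(cohort)
        y = np.array([s.ree_measured for s in cohort])
        r = stats.pearsonr(np.array(fit.fitted_values), y).statistic
        assert fit.r_squared == pytest.approx(r**2, abs=1e-10)
        assert fit.adj_r_squared <= fit.r_squared <= 1.0

    def test_collinear_candidates_rejected(self, rng):
        cohort = [
            Subject(f"s{i}", "male", 30 + i % 20, 60.0 + i, 60.0 + i, 1500.0 + i)
            for i in range(40)
        ]  # height == weight exactly
        with pytest.raises(CollinearityError):
            stepwise_regression(cohort)

    def test_p_remove_must_exceed_p_enter(self, rng):
        with pytest.raises(ValueError):
            stepwise_regression(_cohort(50, rng, ree_fn=lambda s: 1500.0),
                                p_enter=0.05, p_remove=0.05)


class TestFitToEquation:
    def test_published_coefficients_round_trip(self):
        from reekit.development import RegressionFit

        fit = RegressionFit(
            included_predictors=("weight", "sex", "age"),
            coefficients={"weight": 8.957, "sex": 280.613, "age": -7.795},
            intercept=1039.837,
            std_errors={}, p_values={}, r=0.64, r_squared=0.42,
            adj_r_squared=0.40, n=142, excluded_predictors={"height": 0.5},
        )
        spec = fit_to_equation(fit)
        s = make_subject(sex="female", age=40, weight=60)
        assert predict(spec, s).ree_predicted == pytest.approx(
            8.957 * 60 - 7.795 * 40 + 1039.837, abs=1e-9
        )
        m = make_subject(sex="male", age=40, weight=60)
        assert predict(spec, m).ree_predicted - predict(spec, s).ree_predicted == (
            pytest.approx(280.613)
        )

    def test_wrapped_fit_reproduces_fitted_values(self, rng):
        cohort = _cohort(
            100, rng,
            ree_fn=lambda s: 10 * s.weight + 250 * s.is_male + rng.normal(800, 200),
        )
        fit = stepwise_regression(cohort)
        spec = fit_to_equation(fit)
        for s, fitted in zip(cohort, fit.fitted_values):
            assert predict(spec, s).ree_predicted == pytest.approx(fitted, abs=1e-8)

    def test_intercept_only_fit_is_constant(self):
        from reekit.development import RegressionFit

        fit = RegressionFit(
            included_predictors=(), coefficients={}, intercept=1500.0,
            std_errors={}, p_values={}, r=0.0, r_squared=0.0,
            adj_r_squared=0.0, n=50, excluded_predictors={},
        )
        spec = fit_to_equation(fit)
        for subject in (make_subject(), make_subject(sex="female", weight=50)):
            assert predict(spec, subject).ree_predicted == 1500.0
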