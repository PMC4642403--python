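"""Age-band mapping and the per-condition ANCOVA drug screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_dataset
from crowdrx.data_model import Review
from crowdrx.preprocess import ConditionDataset, DrugGroup
from crowdrx.screen import (
    AgeParseError,
    ConditionModel,
    ScreenResult,
    ScreenSkip,
    age_to_numeric,
    ancova_drug_test,
    bonferroni_screen,
)
from crowdrx.synthdata import ConditionSpec, DrugSpec, SynthConfig, generate
from crowdrx.preprocess import group_reviews, filter_eligible


class TestAgeToNumeric:
    @pytest.mark.parametrize(
        "band,years",
        [
            ("25-34", 29.5),
            ("45-54", 49.5),
            ("75 or over", 79.5),
            ("75+", 79.5),
            ("under 18", 15.0),
            ("18 or under", 15.0),
            ("42", 42.0),
            (" 35-44 ", 39.5),
        ],
    )
    def test_band_midpoints(self, band, years):
        assert age_to_numeric(band) == years

    @pytest.mark.parametrize("bad", ["", "unknown", "34-25", "old"])
    def test_unparseable_bands_raise(self, bad):
        with pytest.raises(AgeParseError):
            age_to_numeric(bad)


def _dataset_from_synth(drug_means, n=30, noise_sd=0.8, seed=7, **cond_kw):
    config = SynthConfig(
        conditions=[
            ConditionSpec(
                condition="c",
                drugs=[DrugSpec(k, m, n) for k, m in drug_means.items()],
                noise_sd=noise_sd,
                **cond_kw,
            )
        ],
        seed=seed,
    )
    datasets = filter_eligible(group_reviews(generate(config), []), min_reviews=1)
    assert len(datasets) == 1
    return datasets[0]


def _oracle_partial_f(dataset):
    """Independent normal-equations oracle for the drug partial F-test.

    Builds one-hot designs with pandas and solves X'Xb = X'y via pinv,
    sharing no code with ConditionModel.
    """
    rows = []
    for g in dataset.drug_groups:
        for r in g.reviews:
            rows.append((g.group_key, r.gender, age_to_numeric(r.age_range), r.rating))
    df = pd.DataFrame(rows, columns=["drug", "gender", "age", "y"])

    def sse(formula_cols):
        X = np.column_stack([np.ones(len(df))] + formula_cols + [df["age"].to_numpy(float)])
        beta = np.linalg.pinv(X.T @ X) @ X.T @ df["y"].to_numpy(float)
        resid = df["y"].to_numpy(float) - X @ beta
        return float(resid @ resid), int(np.linalg.matrix_rank(X))

    gender_cols = [
        (df["gender"] == lv).to_numpy(float) for lv in sorted(df["gender"].unique())[1:]
    ]
    drug_cols = [(df["drug"] == lv).to_numpy(float) for lv in sorted(df["drug"].unique())[1:]]
    sse_full, rank_full = sse(drug_cols + gender_cols)
    sse_red, rank_red = sse(gender_cols)
    df_num = rank_full - rank_red
    df_den = len(df) - rank_full
    f = ((sse_red - sse_full) / df_num) / (sse_full / df_den)
    return f, df_num, df_den, float(stats.f.sf(f, df_num, df_den))


class TestAncova:
    def test_identical_ratings_give_f_zero_p_one(self):
        ds = make_dataset("c", {"a": [3] * 12, "b": [3] * 12})
        res = ancova_drug_test(ds)
        assert res.f_statistic == 0.0 and res.p_raw == 1.0

    def test_matches_normal_equations_oracle(self):
        ds = _dataset_from_synth(
            {"a": 3.0, "b": 3.6, "c": 2.7}, n=10, age_slope=0.01, gender_effect=0.2
        )
        res = ancova_drug_test(ds)
        f, df_num, df_den, p = _oracle_partial_f(ds)
        assert res.df_num == df_num and res.df_den == df_den
        assert res.f_statistic == pytest.approx(f, abs=1e-8)
        assert res.p_raw == pytest.approx(p, abs=1e-10)

    def test_matches_statsmodels_model_comparison(self):
        sm = pytest.importorskip("statsmodels.api")
        smf = pytest.importorskip("statsmodels.formula.api")
        ds = _dataset_from_synth({"a": 3.2, "b": 2.6}, n=25, gender_effect=0.3)
        rows = [
            (g.group_key, r.gender, age_to_numeric(r.age_range), r.rating)
            for g in ds.drug_groups
            for r in g.reviews
        ]
        df = pd.DataFrame(rows, columns=["drug", "gender", "age", "y"])
        full = smf.ols("y ~ C(drug) + C(gender) + age", df).fit()
        red = smf.ols("y ~ C(gender) + age", df).fit()
        table = sm.stats.anova_lm(red, full)
        res = ancova_drug_test(ds)
        assert res.f_statistic == pytest.approx(float(table["F"].iloc[1]), rel=1e-8)
        assert res.p_raw == pytest.approx(float(table["Pr(>F)"].iloc[1]), rel=1e-6)

    def test_invariant_to_drug_relabeling(self):
        ds = _dataset_from_synth({"a": 3.4, "b": 2.8, "c": 3.0}, n=15)
        res1 = ancova_drug_test(ds)
        for g in ds.drug_groups:  # swap which level is the reference
            g.ingredient_key = {"a": "zzz", "b": "mmm", "c": "aaa"}[g.ingredient_key]
        res2 = ancova_drug_test(ds)
        assert res2.f_statistic == pytest.approx(res1.f_statistic, rel=1e-9)

    def test_f_invariant_to_shift_and_scale(self):
        ds = _dataset_from_synth({"a": 3.4, "b": 2.8}, n=20)
        f0 = ancova_drug_test(ds).f_statistic
        for g in ds.drug_groups:
            for r in g.reviews:
                r.rating = r.rating * 2.5 + 7  # ratings held as plain numbers
        assert ancova_drug_test(ds).f_statistic == pytest.approx(f0, rel=1e-9)

    def test_unparseable_ages_excluded_from_model(self):
        ds = make_dataset("c", {"a": [1, 2, 3] * 4, "b": [3, 4, 5] * 4})
        for g in ds.drug_groups:
            g.reviews[0].age_range = "unknown"
        model = ConditionModel(ds)
        assert model.n_modeled == 22 and model.n_excluded == 2

    def test_insufficient_residual_df_skips(self):
        ds = make_dataset(
            "c", {"a": [3], "b": [4]}, ages=["25-34"], genders=["female"]
        )
        with pytest.raises(ScreenSkip):
            ancova_drug_test(ds)

    def test_single_drug_condition_rejected(self):
        ds = make_dataset("c", {"a": [1, 2, 3]})
        with pytest.raises(ValueError):
            ancova_drug_test(ds)

    def test_permutation_null_p_is_uniform(self):
        """Permuting drug labels destroys the effect; p<.05 should occur at
        ~5% of replicates (binomial tolerance at 1000 reps)."""
        ds = _dataset_from_synth({"a": 3.8, "b": 2.6, "c": 3.2}, n=15, seed=11)
        groups = ds.drug_groups
        reviews = [r for g in groups for r in g.reviews]
        sizes = [g.n_reviews for g in groups]
        rng = np.random.default_rng(2024)
        hits = 0
        reps = 1000
        for _ in range(reps):
            perm = rng.permutation(len(reviews))
            shuffled, start = [], 0
            for g, size in zip(groups, sizes):
                g.reviews = [reviews[i] for i in perm[start : start + size]]
                start += size
            if ancova_drug_test(ds).p_raw < 0.05:
                hits += 1
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(hits / reps - 0.05) < 3 * se + 1e-9

    def test_power_for_half_point_effect(self):
        """A 0.5-latent-point drug effect at n=200/drug is flagged in >=90%
        of 200 seeded replicates."""
        flagged = 0
        for seed in range(200):
            ds = _dataset_from_synth({"a": 3.0, "b": 3.5}, n=200, noise_sd=0.8, seed=seed)
            results = bonferroni_screen([ancova_drug_test(ds)], alpha=0.05)
            flagged += results[0].significant
        assert flagged / 200 >= 0.90


class TestBonferroni:
    @pytest.mark.parametrize(
        "p_raw,n,expected,significant",
        [(0.0001, 249, 0.0249, True), (0.001, 249, 0.249, False), (0.9, 249, 1.0, False)],
    )
    def test_adjustment_arithmetic(self, p_raw, n, expected, significant):
        results = [
            ScreenResult(condition=f"c{i}", f_statistic=1, df_num=1, df_den=10, p_raw=p_raw)
            for i in range(n)
        ]
        out = bonferroni_screen(results, alpha=0.05)
        assert out[0].p_adjusted == pytest.approx(expected)
        assert out[0].significant is significant

    def test_empty_input_gives_empty_output(self):
        assert bonferroni_screen([]) == []

    def test_p_ordering_invariant(self):
        out = bonferroni_screen(
            [ScreenResult("c", 1.0, 1, 5, p_raw=0.3), ScreenResult("d", 1.0, 1, 5, p_raw=0.9)]
        )
        for r in out:
            assert 0 <= r.p_raw <= r.p_adjusted <= 1
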