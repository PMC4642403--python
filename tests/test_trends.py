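"""Adjusted ratings, Mann-Whitney rank test, and trend-pair deduction."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from conftest import make_dataset, make_reviews
from crowdrx.data_model import Review
from crowdrx.preprocess import ConditionDataset, DrugGroup
from crowdrx.screen import ConditionModel
from crowdrx.trends import (
    AdjustedRating,
    adjusted_rating,
    adjusted_ratings,
    deduce_trends,
    mann_whitney,
    modal_covariates,
)


class TestModalCovariates:
    def test_strict_majority(self):
        ds = make_dataset(
            "c",
            {"a": [3] * 5},
            ages=["25-34", "25-34", "25-34", "35-44", "35-44"],
            genders=["female", "female", "female", "female", "male"],
        )
        ds.drug_groups.append(ds.drug_groups[0])  # satisfy >=2 groups shape; content irrelevant
        assert modal_covariates(ds) == (29.5, "female")

    def test_age_tie_breaks_younger(self):
        ds = make_dataset(
            "c", {"a": [3] * 4}, ages=["35-44", "25-34", "35-44", "25-34"]
        )
        age, _ = modal_covariates(ds)
        assert age == 29.5

    def test_gender_tie_breaks_lexicographic(self):
        ds = make_dataset("c", {"a": [3] * 4}, genders=["male", "female"])
        _, gender = modal_covariates(ds)
        assert gender == "female"

    def test_no_parseable_ages_is_an_error(self):
        ds = make_dataset("c", {"a": [3, 4]}, ages=["unknown"])
        with pytest.raises(ValueError):
            modal_covariates(ds)


def _linear_dataset(coeffs, n_per_cell=2):
    """Noise-free dataset whose ratings follow an exact linear model, so the
    least-squares fit recovers the planted coefficients exactly."""
    intercept, drug_b, age_slope = coeffs
    reviews_a, reviews_b = [], []
    for band, years in [("25-34", 29.5), ("35-44", 39.5), ("45-54", 49.5)]:
        for _ in range(n_per_cell):
            reviews_a.append(Review("a", "c", intercept + age_slope * years, band, "male"))
            reviews_b.append(
                Review("b", "c", intercept + drug_b + age_slope * years, band, "male")
            )
    groups = [
        DrugGroup("a", "", "c", {"a"}, reviews_a),
        DrugGroup("b", "", "c", {"b"}, reviews_b),
    ]
    return ConditionDataset("c", groups)


class TestAdjustedRating:
    def test_planted_coefficients_recovered_in_prediction(self):
        # intercept 3.0, drug-b effect +0.7, age slope 0.01 -> prediction at
        # the modal age 29.5 is 3.0 + 0.7 + 0.01*29.5 = 3.995, the value an
        # independent dot product of the planted coefficients gives
        ds = _linear_dataset((3.0, 0.7, 0.01))
        model = ConditionModel(ds)
        adj = adjusted_rating(model, "b", 29.5, "male", 6)
        assert adj.adjusted_score == pytest.approx(3.995, abs=1e-9)

    def test_zero_covariate_model_predicts_group_mean(self):
        ds = make_dataset(
            "c", {"a": [2, 3, 4, 3], "b": [4, 5, 4, 5]}, ages=["25-34"], genders=["female"]
        )
        # single age band and gender: covariate columns are constant, so the
        # prediction at those covariates is the raw group mean
        model = ConditionModel(ds)
        assert model.predict("a", 29.5, "female") == pytest.approx(3.0, abs=1e-9)
        assert model.predict("b", 29.5, "female") == pytest.approx(4.5, abs=1e-9)

    def test_identical_distributions_get_equal_scores(self):
        ratings = [1, 2, 3, 4, 5] * 6
        ds = make_dataset("c", {"a": list(ratings), "b": list(ratings)})
        model = ConditionModel(ds)
        adj = adjusted_ratings(ds, model)
        assert abs(adj[0].adjusted_score - adj[1].adjusted_score) < 1e-9

    def test_all_ratings_share_modal_covariates(self):
        ds = make_dataset("c", {"a": [1, 2, 3] * 4, "b": [3, 4, 5] * 4})
        adj = adjusted_ratings(ds, ConditionModel(ds))
        assert len({(a.modal_age, a.modal_gender) for a in adj}) == 1

    def test_unknown_drug_rejected(self):
        ds = make_dataset("c", {"a": [1, 2, 3] * 4, "b": [3, 4, 5] * 4})
        with pytest.raises(KeyError):
            ConditionModel(ds).predict("zzz", 29.5, "female")


class TestMannWhitney:
    def test_exact_enumeration_small_sample(self):
        # all C(4,2)=6 label assignments: U in {0(x1), 2(x4), 4(x1)};
        # observed U=0, so 2 of 6 assignments are as extreme -> p = 1/3
        u, p = mann_whitney([1, 1], [5, 5])
        assert u == 0.0
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_samples_give_p_one(self):
        _, p = mann_whitney([1, 2, 3, 3, 5] * 10, [1, 2, 3, 3, 5] * 10)
        assert p == pytest.approx(1.0, abs=1e-9)
        _, p_small = mann_whitney([2, 2, 3], [2, 3, 2])
        assert p_small == pytest.approx(1.0, abs=1e-12)

    def test_matches_permutation_oracle_with_ties(self, rng):
        """Tie-corrected normal approximation vs a 20,000-draw Monte-Carlo
        permutation oracle on 1-5 rating samples (n=40 each)."""
        x = rng.integers(1, 6, size=40)
        y = np.clip(rng.integers(1, 6, size=40) + 1, 1, 5)
        u_obs, p = mann_whitney(x, y)
        pooled = np.concatenate([x, y]).astype(float)
        ranks = stats.rankdata(pooled)
        mu = 40 * 40 / 2.0
        draws = 20_000
        perm = np.argsort(rng.random((draws, 80)), axis=1)[:, :40]
        u = ranks[perm].sum(axis=1) - 40 * 41 / 2.0
        p_mc = float(np.mean(np.abs(u - mu) >= abs(u_obs - mu) - 1e-9))
        assert p == pytest.approx(p_mc, abs=0.01)

    def test_tie_group_convolution_agrees_with_enumeration(self, rng):
        """The exact DP path (pooled n=13, 5 distinct values) reproduces
        brute-force enumeration over all C(13,6) label assignments."""
        from itertools import combinations

        from math import comb as _comb

        x = rng.integers(1, 6, size=6).astype(float)
        y = rng.integers(1, 6, size=7).astype(float)
        _, p = mann_whitney(x, y, exact_limit=12)  # 13 pooled -> DP path
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        mu = 6 * 7 / 2.0
        dev = abs((ranks[:6].sum() - 6 * 7 / 2.0) - mu)
        hits = sum(
            1
            for idx in combinations(range(13), 6)
            if abs((ranks[list(idx)].sum() - 21.0) - mu) >= dev - 1e-9
        )
        assert p == pytest.approx(hits / _comb(13, 6), abs=1e-12)

    def test_matches_scipy_on_untied_data(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 1, 25)
        u, p = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue), abs=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])


def _adj(cond, key, score):
    return AdjustedRating(key, cond, score, 29.5, "female", 40)


class TestDeduceTrends:
    def test_passing_pair_mirrors_published_example(self):
        # one drug 0.7 adjusted points above the other with clearly different
        # rating distributions -> a single passing trend
        ds = make_dataset("hbp", {"amlodipine": [2, 2, 3, 3] * 10, "felodipine": [3, 3, 4, 3] * 10})
        ratings = [_adj("hbp", "amlodipine", 2.5), _adj("hbp", "felodipine", 3.2)]
        (pair,) = deduce_trends(ds, ratings)
        assert pair.drug_hi == "felodipine" and pair.drug_lo == "amlodipine"
        assert pair.diff == pytest.approx(0.7)
        assert pair.mw_p < 0.01 and pair.passes

    def test_below_half_point_fails_despite_significance(self):
        ds = make_dataset("c", {"a": [1] * 40, "b": [5] * 40})
        ratings = [_adj("c", "a", 2.51), _adj("c", "b", 3.0)]
        (pair,) = deduce_trends(ds, ratings)
        assert pair.mw_p < 1e-6 and pair.diff == pytest.approx(0.49)
        assert not pair.passes

    def test_nonsignificant_rank_test_fails_despite_gap(self):
        same = [1, 2, 3, 4, 5] * 8
        ds = make_dataset("c", {"a": list(same), "b": list(same)})
        ratings = [_adj("c", "a", 2.5), _adj("c", "b", 3.3)]
        (pair,) = deduce_trends(ds, ratings)
        assert pair.diff == pytest.approx(0.8) and pair.mw_p >= 0.01
        assert not pair.passes

    def test_swapping_labels_flips_orientation_only(self):
        ds = make_dataset("c", {"a": [2, 3, 2, 3] * 10, "b": [4, 5, 4, 4] * 10})
        r1 = [_adj("c", "a", 2.5), _adj("c", "b", 4.2)]
        (p1,) = deduce_trends(ds, r1)
        ds2 = make_dataset("c", {"b": [2, 3, 2, 3] * 10, "a": [4, 5, 4, 4] * 10})
        r2 = [_adj("c", "b", 2.5), _adj("c", "a", 4.2)]
        (p2,) = deduce_trends(ds2, r2)
        assert (p1.drug_hi, p1.drug_lo) == ("b", "a") and (p2.drug_hi, p2.drug_lo) == ("a", "b")
        assert p1.diff == pytest.approx(p2.diff) and p1.mw_p == pytest.approx(p2.mw_p)

    def test_thresholds_zero_and_one_yield_all_pairs(self):
        ds = make_dataset(
            "c", {k: [1 + i % 5] * 12 for i, k in enumerate("abcd")}
        )
        ratings = [_adj("c", k, 2.0 + i * 0.1) for i, k in enumerate("abcd")]
        pairs = deduce_trends(ds, ratings, diff_threshold=0.0, p_threshold=1.0)
        assert len(pairs) == len(list(combinations("abcd", 2)))
        assert all(p.passes for p in pairs)
        assert all(p.diff >= 0 for p in pairs)
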