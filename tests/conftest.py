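import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from crowdrx.data_model import Review
from crowdrx.preprocess import ConditionDataset, DrugGroup


def make_reviews(drug, condition, ratings, ages=None, genders=None, comments=None):
    """Build Review lists with cycling demographics for unit tests."""
    ages = ages or ["25-34", "35-44", "45-54"]
    genders = genders or ["female", "male"]
    comments = comments or [""]
    return [
        Review(
            drug_name=drug,
            condition=condition,
            rating=r,
            age_range=ages[i % len(ages)],
            gender=genders[i % len(genders)],
            comment=comments[i % len(comments)],
        )
        for i, r in enumerate(ratings)
    ]


def make_dataset(condition, drug_ratings: dict, **kw):
    """ConditionDataset from {drug: ratings list}."""
    groups = [
        DrugGroup(
            ingredient_key=drug,
            delivery_mode="",
            condition=condition,
            member_brands={drug},
            reviews=make_reviews(drug, condition, ratings, **kw),
        )
        for drug, ratings in drug_ratings.items()
    ]
    return ConditionDataset(condition=condition, drug_groups=groups)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fixture_bundle():
    from crowdrx.synthdata import make_paper_fixture

    return make_paper_fixture()
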