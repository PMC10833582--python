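import pytest
from hypothesis import settings

from cbpricer import (
    CostStructure,
    DrugProfile,
    EligibilityCascade,
    IndicationSpec,
    flat_population,
    packaged_population,
    packaged_profiles,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pop():
    return packaged_population()


@pytest.fixture(scope="session")
def dara(pop):
    return packaged_profiles()[0]


@pytest.fixture(scope="session")
def pembro(pop):
    return packaged_profiles()[1]


@pytest.fixture(scope="session")
def flat_pop():
    return flat_population(1_000_000.0)


def make_profile(
    *,
    name="test-drug",
    launch=2020,
    expiry=2025,
    vial=1.0,
    dose=2.0,
    crd=1.0e9,
    cex=1.0e8,
    cman=50.0,
    mp=0.2,
    msm=0.3,
    indications=None,
):
    """Small profile builder with all-ones cascades unless specified."""
    if indications is None:
        indications = [dict(approval_year=launch, incidence_per_100k=10.0)]
    specs = []
    for i, ind in enumerate(indications, start=1):
        ind = dict(ind)
        specs.append(
            IndicationSpec(
                label=ind.pop("label", f"ind-{i}"),
                grams_per_treatment=ind.pop("grams_per_treatment", dose),
                cascade=ind.pop("cascade", EligibilityCascade()),
                **ind,
            )
        )
    return DrugProfile(
        name=name,
        launch_year=launch,
        patent_expiry=expiry,
        vial_grams=vial,
        cost=CostStructure(
            initial_rd=crd,
            rd_per_new_indication=cex,
            manufacturing_per_gram=cman,
            profit_margin=mp,
            sales_marketing_margin=msm,
        ),
        indications=tuple(specs),
    )
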