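"""Core pricing operations: closed-form examples, invariants, and a
brute-force patient-year oracle."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cbpricer import (
    DomainError,
    EligibilityCascade,
    PatentExpiredError,
    UnpriceableError,
    cumulative_price_by_indication,
    cumulative_price_by_year,
    decompose_per_vial,
    flat_population,
    indication_based_price,
    per_vial_price,
    price_per_treatment,
    price_series,
)
from cbpricer.population import CascadeProvider

from conftest import make_profile


class TestPricePerTreatment:
    @pytest.mark.parametrize(
        "crd, patients, cman_tx, mp, expected",
        [
            (0.0, 10.0, 100.0, 0.2, 120.0),                      # zero R&D: margin on manufacturing
            (4_937_400_000.0, 1_000_000.0, 100.0, 0.2, 6_044.88),  # hand arithmetic
            (100.0, 4.0, 0.0, 0.0, 25.0),                        # pure amortization
        ],
    )
    def test_examples(self, crd, patients, cman_tx, mp, expected):
        assert price_per_treatment(crd, patients, cman_tx, mp) == pytest.approx(expected)

    def test_rejects_empty_population(self):
        with pytest.raises(DomainError, match="patients"):
            price_per_treatment(1e9, 0.0, 10.0, 0.2)


class TestPerVial:
    def test_published_intro_price_composition(self):
        # R&D already expressed per vial-equivalent: one 1.8 g vial per treatment
        price = per_vial_price(21_217.3, 42.61, 1.8, 1.8, 1.5)
        assert price == pytest.approx(31_941, abs=1.0)

    def test_vial_equals_treatment_dose(self):
        assert per_vial_price(500.0, 40.0, 2.0, 2.0, 1.5) == pytest.approx((500 + 80) * 1.5)

    def test_rd_share_halves_when_dose_doubles(self):
        lo = per_vial_price(600.0, 0.0, 2.0, 1.0, 1.0)
        hi = per_vial_price(600.0, 0.0, 4.0, 1.0, 1.0)
        assert hi == pytest.approx(lo / 2)

    def test_dose_below_vial_content_rejected(self):
        with pytest.raises(DomainError):
            per_vial_price(100.0, 10.0, 0.5, 1.0, 1.5)


class TestDecompose:
    @pytest.mark.parametrize(
        "per_vial, vial, cman, expected_rd, expected_manuf",
        [
            (31_941.0, 1.8, 42.61, 21_217.302, 76.698),
            (885.0, 0.1, 35.55, 586.445, 3.555),
        ],
    )
    def test_printed_price_decomposition(self, per_vial, vial, cman, expected_rd, expected_manuf):
        rd, manuf = decompose_per_vial(per_vial, vial, cman, 0.2, 0.3)
        assert rd == pytest.approx(expected_rd, abs=5e-3)
        assert manuf == pytest.approx(expected_manuf, abs=5e-3)

    @given(
        rd=st.floats(1e-3, 1e6), manuf=st.floats(1e-3, 1e4),
        mp=st.floats(0, 1), msm=st.floats(0, 1),
    )
    def test_round_trip(self, rd, manuf, mp, msm):
        mult = 1 + mp + msm
        per_vial = (rd + manuf) * mult
        got_rd, got_manuf = decompose_per_vial(per_vial, 1.0, manuf, mp, msm)
        assert got_rd == pytest.approx(rd, rel=1e-9, abs=1e-12)
        assert got_manuf == pytest.approx(manuf, rel=1e-9)

    def test_price_below_manufacturing_floor(self):
        with pytest.raises(DomainError, match="manufacturing floor"):
            decompose_per_vial(10.0, 1.8, 42.61, 0.2, 0.3)


class TestCumulativeByYear:
    def test_reduces_to_single_indication_formula(self, flat_pop):
        # one indication, one patent year, no sales & marketing margin
        profile = make_profile(launch=2020, expiry=2021, msm=0.0, cman=50.0, dose=2.0)
        b = cumulative_price_by_year(profile, 2020, flat_pop)
        patients = 1_000_000 * 10.0 / 1e5  # one year of incident cases
        expected = price_per_treatment(profile.cost.initial_rd, patients, 2.0 * 50.0, 0.2)
        assert b.per_treatment == pytest.approx(expected, rel=1e-12)
        assert b.total_patients == pytest.approx(patients, rel=1e-12)

    def test_patent_expired(self, flat_pop):
        profile = make_profile(launch=2020, expiry=2025)
        with pytest.raises(PatentExpiredError):
            cumulative_price_by_year(profile, 2025, flat_pop)

    def test_before_launch(self, flat_pop):
        profile = make_profile(launch=2020, expiry=2025)
        with pytest.raises(DomainError):
            cumulative_price_by_year(profile, 2019, flat_pop)

    def test_zero_patients_raises_or_flags(self, flat_pop):
        dead = EligibilityCascade(untreated_fraction=1.0)
        profile = make_profile(
            indications=[dict(approval_year=2020, incidence_per_100k=10.0, cascade=dead)]
        )
        with pytest.raises(UnpriceableError):
            cumulative_price_by_year(profile, 2020, flat_pop)
        b = cumulative_price_by_year(profile, 2020, flat_pop, allow_unpriceable=True)
        assert b.unpriceable and math.isnan(b.per_vial)

    def test_rd_accumulates_per_new_indication(self, flat_pop):
        profile = make_profile(
            indications=[
                dict(approval_year=2020, incidence_per_100k=10.0),
                dict(approval_year=2022, incidence_per_100k=10.0),
            ]
        )
        b_pre = cumulative_price_by_year(profile, 2021, flat_pop)
        b_post = cumulative_price_by_year(profile, 2022, flat_pop)
        assert b_pre.n_indications == 1
        assert b_post.n_indications == 2
        rd_total_post = b_post.rd_component * b_post.total_patients
        assert rd_total_post == pytest.approx(
            profile.cost.initial_rd + profile.cost.rd_per_new_indication, rel=1e-9
        )


class TestMonotonicity:
    """Per-treatment price falls with more patients, rises in every cost input."""

    def base(self):
        return make_profile(
            indications=[
                dict(approval_year=2020, incidence_per_100k=10.0),
                dict(approval_year=2021, incidence_per_100k=20.0),
            ]
        )

    def test_decreasing_in_patients(self, flat_pop):
        profile = self.base()
        base = cumulative_price_by_year(profile, 2021, CascadeProvider(flat_pop))
        more = cumulative_price_by_year(profile, 2021, CascadeProvider(flat_pop, patient_scale=2.0))
        assert more.per_treatment < base.per_treatment

    @pytest.mark.parametrize(
        "field, factor",
        [
            ("initial_rd", 1.5),
            ("rd_per_new_indication", 1.5),
            ("manufacturing_per_gram", 1.5),
            ("profit_margin", 1.5),
            ("sales_marketing_margin", 1.5),
        ],
    )
    def test_increasing_in_cost_inputs(self, flat_pop, field, factor):
        profile = self.base()
        bumped = profile.model_copy(
            update={"cost": profile.cost.model_copy(update={field: getattr(profile.cost, field) * factor})}
        )
        assert (
            cumulative_price_by_year(bumped, 2021, flat_pop).per_treatment
            > cumulative_price_by_year(profile, 2021, flat_pop).per_treatment
        )

    @given(scale=st.floats(0.1, 100.0))
    def test_patient_scaling_divides_rd_component(self, scale):
        flat = flat_population(1_000_000.0)
        profile = self.base()
        base = cumulative_price_by_year(profile, 2021, CascadeProvider(flat))
        scaled = cumulative_price_by_year(profile, 2021, CascadeProvider(flat, patient_scale=scale))
        assert scaled.rd_component == pytest.approx(base.rd_component / scale, rel=1e-9)
        assert scaled.manuf_component == pytest.approx(base.manuf_component, rel=1e-12)


class TestByIndicationAndIbp:
    def test_first_indication_identities(self, flat_pop):
        profile = make_profile()
        by_year = cumulative_price_by_year(profile, 2020, flat_pop)
        by_ind = cumulative_price_by_indication(profile, 1, flat_pop)
        ibp = indication_based_price(profile, 1, flat_pop)
        assert by_ind.per_vial == by_year.per_vial
        assert ibp.per_vial == by_ind.per_vial
        assert ibp.per_treatment == by_year.per_treatment

    def test_large_second_indication_lowers_cumulative_price(self, flat_pop):
        profile = make_profile(
            indications=[
                dict(approval_year=2020, incidence_per_100k=1.0),
                dict(approval_year=2021, incidence_per_100k=500.0),
            ]
        )
        k1 = cumulative_price_by_indication(profile, 1, flat_pop)
        k2 = cumulative_price_by_indication(profile, 2, flat_pop)
        assert k2.per_treatment < k1.per_treatment

    def test_second_indication_with_no_patients(self, flat_pop):
        dead = EligibilityCascade(trial_fraction=1.0)
        profile = make_profile(
            indications=[
                dict(approval_year=2020, incidence_per_100k=10.0),
                dict(approval_year=2021, incidence_per_100k=10.0, cascade=dead),
            ]
        )
        with pytest.raises(UnpriceableError):
            indication_based_price(profile, 2, flat_pop)

    def test_ibp_uses_only_incremental_rd(self, flat_pop):
        profile = make_profile(
            cex=0.0,
            cman=0.0,
            indications=[
                dict(approval_year=2020, incidence_per_100k=10.0),
                dict(approval_year=2021, incidence_per_100k=10.0),
            ],
        )
        b = indication_based_price(profile, 2, flat_pop)
        assert b.per_treatment == 0.0

    @pytest.mark.parametrize("k", [0, 3])
    def test_index_out_of_range(self, flat_pop, k):
        profile = make_profile(
            indications=[
                dict(approval_year=2020, incidence_per_100k=10.0),
                dict(approval_year=2021, incidence_per_100k=10.0),
            ]
        )
        with pytest.raises(DomainError):
            cumulative_price_by_indication(profile, k, flat_pop)
        with pytest.raises(DomainError):
            indication_based_price(profile, k, flat_pop)


def brute_force_breakdown(profile, eval_year, pop):
    """Independent patient-year enumeration: direct loops, no model code."""
    share_table = {0: 1.0, 1: 0.5}
    total_p = 0.0
    total_g = 0.0
    n_active = 0
    for ind in profile.indications:
        if ind.approval_year > eval_year:
            continue
        n_active += 1
        for year in range(ind.approval_year, profile.patent_expiry):
            c = ind.cascade
            patients = (
                pop.persons(year)
                * ind.incidence_per_100k
                / 100_000
                * c.subtype_share
                * c.stage_share
                * c.line_share
                * c.symptomatic_share
                * c.eligible_share
                * (1 - c.untreated_fraction)
                * (1 - c.trial_fraction)
            )
            n_comp = 0
            for entry_year, count in ind.competitor_schedule:
                if entry_year <= year:
                    n_comp = count
            patients *= share_table.get(n_comp, 0.33)
            total_p += patients
            total_g += patients * ind.grams_per_treatment
    rd_total = profile.cost.initial_rd + (n_active - 1) * profile.cost.rd_per_new_indication
    mult = 1 + profile.cost.profit_margin + profile.cost.sales_marketing_margin
    per_treatment = (rd_total / total_p + (total_g / total_p) * profile.cost.manufacturing_per_gram) * mult
    per_vial = (
        rd_total * profile.vial_grams / total_g
        + profile.vial_grams * profile.cost.manufacturing_per_gram
    ) * mult
    return total_p, per_treatment, per_vial


class TestBruteForceOracle:
    @pytest.mark.parametrize("seed", [1, 7, 23])
    def test_synthetic_profiles_match_enumeration(self, seed):
        from cbpricer import SyntheticSpec, synthetic_profile

        profile = synthetic_profile(SyntheticSpec(seed=seed, n_indications=3))
        pop = flat_population(5_000_000.0, 2000, 2045)
        for year in profile.pricing_years():
            expected_p, expected_tx, expected_vial = brute_force_breakdown(profile, year, pop)
            b = cumulative_price_by_year(profile, year, pop)
            assert b.total_patients == pytest.approx(expected_p, rel=1e-9)
            assert b.per_treatment == pytest.approx(expected_tx, rel=1e-9)
            assert b.per_vial == pytest.approx(expected_vial, rel=1e-9)


class TestPriceSeries:
    def test_modes_and_shape(self, dara, pop):
        years = price_series(dara, pop, "year")
        inds = price_series(dara, pop, "indication")
        ibp = price_series(dara, pop, "ibp")
        assert list(years["index"]) == list(range(2015, 2025))
        assert list(inds["index"]) == list(range(1, 7))
        assert ibp.loc[0, "per_vial"] == years.loc[0, "per_vial"]

    def test_unknown_mode(self, dara, pop):
        with pytest.raises(DomainError):
            price_series(dara, pop, "weekly")
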