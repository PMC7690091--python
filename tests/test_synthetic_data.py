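"""Synthetic evidence generator, life table, and the parameter fixture."""

import io
import math

import numpy as np
import pytest

from ptcl_cua import distributions as dist
from ptcl_cua.ipd_reconstruction import IPDSample, km_estimator, median_survival
from ptcl_cua.synthetic_data import (
    MONTHS_TO_WEEKS,
    TrueSurvivalSpec,
    default_parameters,
    digitize_emulate,
    generate_ipd,
    make_life_table,
    weighted_regimen_cost,
)


class TestGenerateIPD:
    def test_exponential_sample_median(self):
        """Exponential with rate ln2/week has median one week."""
        spec = TrueSurvivalSpec(
            "exponential", (math.log(2),), n_subjects=10_000,
            max_followup=math.inf, censor_rate=0.0, seed=7,
        )
        ipd = generate_ipd(spec)
        assert np.median(ipd.time) == pytest.approx(1.0, rel=0.02)

    def test_no_censoring_means_all_events(self):
        spec = TrueSurvivalSpec(
            "weibull", (1.5, 10.0), n_subjects=500,
            max_followup=math.inf, censor_rate=0.0, seed=3,
        )
        assert generate_ipd(spec).event.all()

    def test_gompertz_km_median_recovers_truth(self):
        """Truth calibrated to median 17.70 wk via the closed form
        t = (1/a) ln(1 + (a/b) ln 2)."""
        a = 0.05
        params = dist.calibrate_to_median("gompertz", 17.70, (a,))
        spec = TrueSurvivalSpec(
            "gompertz", tuple(params), n_subjects=5000,
            max_followup=math.inf, censor_rate=0.0, seed=11,
        )
        med = median_survival(km_estimator(generate_ipd(spec)))
        assert med == pytest.approx(17.70, rel=0.05)

    def test_seeded_reproducibility_byte_for_byte(self):
        spec = TrueSurvivalSpec("gompertz", (0.05, 0.03), n_subjects=80, seed=5)
        a, b = generate_ipd(spec), generate_ipd(spec)
        sa, sb = io.StringIO(), io.StringIO()
        a.to_csv(sa), b.to_csv(sb)
        assert sa.getvalue() == sb.getvalue()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            TrueSurvivalSpec("nope", (1.0,), n_subjects=10)
        with pytest.raises(ValueError):
            TrueSurvivalSpec("exponential", (-1.0,), n_subjects=10)
        with pytest.raises(ValueError):
            TrueSurvivalSpec("exponential", (1.0,), n_subjects=1)
        with pytest.raises(ValueError):
            TrueSurvivalSpec("exponential", (1.0,), n_subjects=10, censor_rate=1.0)


class TestDigitizeEmulate:
    def _hand_ipd(self):
        # 1 event at t=1, 2 events at t=2, 2 censored at t=2 (n=5)
        return IPDSample(
            np.array([1.0, 2.0, 2.0, 2.0, 2.0]),
            np.array([True, True, True, False, False]),
        )

    def test_jitter_zero_reproduces_exact_km(self):
        """KM product-limit: 1*(1-1/5)=0.8 at t=1, 0.8*(1-2/4)=0.4 at t=2."""
        curve = digitize_emulate(self._hand_ipd(), grid_step=1.0, jitter_sd=0.0)
        lookup = dict(zip(curve.times, curve.survival))
        assert lookup[0.0] == 1.0
        assert lookup[1.0] == pytest.approx(0.8, abs=1e-12)
        assert lookup[2.0] == pytest.approx(0.4, abs=1e-12)

    @pytest.mark.parametrize("jitter", [0.005, 0.05, 0.3])
    def test_jittered_output_is_monotone_and_bounded(self, jitter):
        spec = TrueSurvivalSpec("weibull", (1.2, 20.0), n_subjects=60, seed=9)
        curve = digitize_emulate(generate_ipd(spec), jitter_sd=jitter, seed=4)
        assert curve.survival[0] == 1.0
        assert np.all(np.diff(curve.survival) <= 0)
        assert np.all((curve.survival >= 0) & (curve.survival <= 1))

    def test_risk_table_counts_subjects_still_observed(self):
        curve = digitize_emulate(self._hand_ipd(), jitter_sd=0.0)
        rt = dict(zip(curve.risk_table["time_weeks"], curve.risk_table["n_at_risk"]))
        assert rt[0.0] == 5 and rt[1.0] == 5 and rt[2.0] == 4

    def test_empty_or_bad_arguments(self):
        ipd = self._hand_ipd()
        with pytest.raises(ValueError):
            digitize_emulate(ipd, grid_step=0.0)
        with pytest.raises(ValueError):
            digitize_emulate(ipd, jitter_sd=-0.1)


class TestLifeTable:
    def test_weekly_conversion_compounds_to_annual(self):
        """p_week = 1 - (1 - p_year)^(1/52.1): 52.1 weekly survivals must
        compound back to the annual survival implied by the hazard."""
        A, B, C = 5e-4, 3e-5, 0.09
        lt = make_life_table(A, B, C)
        for age in (0, 48, 63, 90):
            p_year = 1.0 - math.exp(-(A + B * math.exp(C * age)))
            assert (1.0 - lt.weekly_prob(age)) ** 52.1 == pytest.approx(
                1.0 - p_year, rel=1e-12
            )
        zero = make_life_table(makeham_a=0.0, gompertz_b=1e-300)
        assert zero.weekly_prob(50) == pytest.approx(0.0, abs=1e-12)

    def test_adult_mortality_is_monotone(self):
        lt = make_life_table()
        assert lt.weekly_prob(63) > lt.weekly_prob(48)
        probs = [lt.weekly_prob(a) for a in range(30, 101)]
        assert np.all(np.diff(probs) > 0)

    def test_csv_round_trip(self, tmp_path):
        lt = make_life_table()
        lt.to_csv(tmp_path / "lt.csv")
        back = type(lt).from_csv(tmp_path / "lt.csv")
        assert back.weekly_prob(48.5) == pytest.approx(lt.weekly_prob(48.5))


# printed parameter fixture, audited literal by literal
FIXTURE_VALUES = [
    ("response_split_initial.pralatrexate.CR", 0.126),
    ("response_split_initial.pralatrexate.PR", 0.211),
    ("response_split_initial.pralatrexate.SD", 0.221),
    ("response_split_initial.pralatrexate.PD", 0.442),
    ("response_split_initial.cc.CR", 0.198),
    ("response_split_initial.cc.PR", 0.214),
    ("response_split_initial.cc.SD", 0.032),
    ("response_split_initial.cc.PD", 0.556),
    ("response_split_subsequent.CR", 0.123),
    ("response_split_subsequent.PR", 0.158),
    ("response_split_subsequent.SD", 0.035),
    ("response_split_subsequent.PD", 0.684),
    ("sct_prob_initial", 0.529),
    ("sct_prob_subsequent", 0.458),
    ("sct_success", 0.663),
    ("medication_weekly.pralatrexate_initial", 2465.0),
    ("medication_weekly.cc_initial", 240.0),
    ("medication_weekly.cc_subsequent", 238.0),
    ("concomitant_weekly.pralatrexate_initial_first_cycle", 4.0),
    ("concomitant_weekly.pralatrexate_initial_last_cycle", 3.0),
    ("concomitant_weekly.cc_initial", 207.0),
    ("concomitant_weekly.cc_subsequent", 198.0),
    ("monitoring_weekly.pralatrexate_initial_first_cycle", 106.0),
    ("monitoring_weekly.pralatrexate_initial_other_cycles", 17.0),
    ("monitoring_weekly.cc_initial_first_cycle", 129.0),
    ("monitoring_weekly.cc_initial_other_cycles", 40.0),
    ("monitoring_weekly.cc_subsequent_first_cycle", 123.0),
    ("monitoring_weekly.cc_subsequent_other_cycles", 38.0),
    ("sct_cost", 27343.0),
    ("utilities.CR", 0.885),
    ("utilities.PR", 0.784),
    ("utilities.SD", 0.746),
    ("utilities.PD", 0.567),
    ("discount_annual", 0.05),
    ("start_age", 48.0),
    ("horizon_years", 15.0),
    ("weeks_per_year", 52.1),
]

AE_VALUES = [
    ("mucositis", 0.0172, 0.0365, 0.0393, 1288.0, -0.075),
    ("thrombocytopenia", 0.0267, 0.1122, 0.0839, 2859.0, -0.095),
    ("anemia", 0.0118, 0.0257, 0.0279, 2877.0, -0.085),
    ("neutropenia", 0.0172, 0.1250, 0.1011, 2760.0, -0.107),
    ("nausea_vomiting", 0.0026, 0.0053, 0.0070, 707.0, -0.059),
    ("peripheral_neuropathy", 0.0000, 0.0063, 0.0053, 643.0, -0.42),
]


class TestDefaultParameters:
    @pytest.mark.parametrize("path, expected", FIXTURE_VALUES, ids=[p for p, _ in FIXTURE_VALUES])
    def test_fixture_literals(self, path, expected):
        obj = default_parameters()
        for part in path.split("."):
            obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
        assert obj == expected

    @pytest.mark.parametrize("name, p_pi, p_ci, p_cs, cost, dis", AE_VALUES,
                             ids=[a[0] for a in AE_VALUES])
    def test_ae_fixture_literals(self, name, p_pi, p_ci, p_cs, cost, dis):
        items = {it.name: it for it in default_parameters().ae_items}
        it = items[name]
        assert it.weekly_prob["pralatrexate_initial"] == p_pi
        assert it.weekly_prob["cc_initial"] == p_ci
        assert it.weekly_prob["cc_subsequent"] == p_cs
        assert it.cost == cost
        assert it.disutility == dis

    def test_sct_success_utility_bands(self):
        p = default_parameters()
        assert p.sct_success_utility(48.0) == 0.976
        assert p.sct_success_utility(52.3) == 0.971
        assert p.sct_success_utility(59.9) == 0.966
        assert p.sct_success_utility(63.0) == 0.936
        assert p.sct_success_utility(80.0) == 0.936  # clamped beyond 64

    def test_splits_sum_to_one(self):
        p = default_parameters()
        for split in p.response_split_initial.values():
            assert sum(split.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(p.response_split_subsequent.values()) == pytest.approx(1.0, abs=1e-9)

    def test_cycle_count_and_month_conversion(self):
        p = default_parameters()
        assert p.cycles == 782  # 365 d / 7 d x 15 yr
        assert MONTHS_TO_WEEKS == pytest.approx(4.3482, abs=5e-5)
        assert 15.24 * MONTHS_TO_WEEKS == pytest.approx(66.27, abs=0.01)
        assert 4.07 * MONTHS_TO_WEEKS == pytest.approx(17.70, abs=0.01)

    def test_yaml_round_trip(self, tmp_path):
        p = default_parameters()
        p.to_yaml(tmp_path / "params.yaml")
        back = type(p).from_yaml(tmp_path / "params.yaml")
        assert back.to_dict() == p.to_dict()

    def test_validation_catches_bad_values(self):
        p = default_parameters()
        p.sct_success = 1.4
        with pytest.raises(ValueError):
            p.validate()


def test_weighted_regimen_cost_renormalizes():
    mix = {"DHAP": 0.153, "ESHAP": 0.099, "ICE": 0.748}
    costs = {"DHAP": 54.0, "ESHAP": 64.0, "ICE": 100.0}
    expected = 0.153 * 54 + 0.099 * 64 + 0.748 * 100
    assert weighted_regimen_cost(mix, costs) == pytest.approx(expected)
    # unpriced regimens are dropped and weights renormalized
    mix2 = dict(mix, BSC=0.0)
    assert weighted_regimen_cost(mix2, costs) == pytest.approx(expected)
    with pytest.raises(ValueError):
        weighted_regimen_cost({"X": 1.0}, costs)
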