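"""PBPK engine: analytic oracles, conservation, inhibition mechanics, DDI runs."""

import numpy as np
import pytest

from transporter_ddi.pbpk import (
    DosingSchedule,
    DrugModel,
    DrugRegimen,
    PBPKScenario,
    apply_inhibition,
    build_model,
    ddi_ratios,
    ddi_scenario,
    load_drug,
    pk_summary,
    simulate,
    worst_case_single_transporter,
)
from transporter_ddi.synth import generate_pk_observations


def one_compartment_drug(**overrides) -> DrugModel:
    params = dict(name="test", mw=400.0, fu_p=0.5, rb=1.0, ka=1.5, fa=1.0, fg=1.0,
                  model="one_compartment", vc_l=10.0, cl_plasma=9.0)
    params.update(overrides)
    return DrugModel(**params)


def pure_uptake_victim(**overrides) -> DrugModel:
    """Oral victim eliminated exclusively through hepatic OATP1B1 uptake."""
    params = dict(name="pure", mw=400.0, fu_p=0.1, rb=1.0, ka=1.0, fa=1.0, fg=1.0,
                  model="full", vc_l=20.0, cl_renal=0.0,
                  hepatic_uptake_clint=100.0,
                  hepatic_uptake_fractions={"OATP1B1": 1.0},
                  cl_met_int=1e5, intestinal_efflux_clint=0.0)
    params.update(overrides)
    return DrugModel(**params)


def single_dose(drug: DrugModel, dose_mg: float) -> PBPKScenario:
    return PBPKScenario(victim=DrugRegimen(drug=drug,
                                           dosing=DosingSchedule(dose_mg=dose_mg)))


class TestApplyInhibition:
    def test_conc_equal_ki_halves_clearance(self):
        assert apply_inhibition(80.0, 5.0, 5.0) == pytest.approx(40.0)

    def test_zero_conc_leaves_clearance_unchanged(self):
        assert apply_inhibition(80.0, 0.0, 5.0) == 80.0

    def test_nine_fold_ki_leaves_ten_percent(self):
        assert apply_inhibition(80.0, 45.0, 5.0) == pytest.approx(8.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            apply_inhibition(80.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            apply_inhibition(80.0, -1.0, 5.0)


class TestEngineOracles:
    def test_oral_one_compartment_matches_bateman_closed_form(self):
        drug = one_compartment_drug()
        result = simulate(single_dose(drug, 100.0), t_end=12.0, rtol=1e-8)
        dose = 100.0 * 1000.0 / drug.mw
        ka, k, v = drug.ka, drug.cl_plasma / drug.vc_l, drug.vc_l
        t = result.time
        bateman = dose * ka / (v * (ka - k)) * (np.exp(-k * t) - np.exp(-ka * t))
        err = np.max(np.abs(result.victim_plasma - bateman)) / bateman.max()
        assert err <= 1e-7  # 10 * rtol

    def test_zero_dose_state_stays_zero(self):
        sc = single_dose(one_compartment_drug(), 1e-30)
        result = simulate(sc, t_end=4.0)
        assert np.all(result.victim_plasma < 1e-25)

    def test_mass_balance_within_tolerance(self):
        sc = ddi_scenario("rosuvastatin_surrogate", "dicloxacillin", 20.0)
        result = simulate(sc, t_end=24.0)
        assert result.mass_balance_rel_error <= 1e-3

    def test_linearity_in_dose(self):
        drug = load_drug("rosuvastatin_surrogate")
        low = simulate(single_dose(drug, 10.0), t_end=48.0)
        high = simulate(single_dose(drug, 20.0), t_end=48.0)
        assert high.auc / low.auc == pytest.approx(2.0, rel=1e-6)
        np.testing.assert_allclose(high.victim_plasma, 2.0 * low.victim_plasma,
                                   rtol=1e-6, atol=1e-12)

    def test_constant_inhibition_matches_static_closed_form(self):
        """For a pure-uptake-cleared oral victim the AUC ratio under constant
        inhibitor exposure is exactly 1 + I/Ki (well-stirred identity
        AUC_po = D/(fu*CLint), independent of hepatic flow)."""
        drug = pure_uptake_victim()
        base = simulate(single_dose(drug, 10.0), t_end=200.0)
        for ratio in (0.5, 2.0):
            sc = single_dose(drug, 10.0).model_copy(
                update={"constant_inhibition": {"OATP1B1": ratio}})
            inhibited = simulate(sc, t_end=200.0)
            assert inhibited.auc / base.auc == pytest.approx(1.0 + ratio, rel=1e-3)


class TestDosingAndEvents:
    def test_repeated_dosing_accumulates(self):
        drug = one_compartment_drug(cl_plasma=2.0)
        multi = PBPKScenario(victim=DrugRegimen(
            drug=drug, dosing=DosingSchedule(dose_mg=100.0, interval_h=8.0, n_doses=3)))
        result = simulate(multi, t_end=30.0)
        # trough before each later dose is above the first-dose trough
        c8 = result.victim_plasma[np.searchsorted(result.time, 8.0) - 1]
        c16 = result.victim_plasma[np.searchsorted(result.time, 16.0) - 1]
        assert c16 > c8
        assert result.dosed_victim_umol == pytest.approx(3 * 100.0 * 1000.0 / drug.mw)

    def test_scenario_round_trips_through_dict(self):
        sc = ddi_scenario("rosuvastatin_surrogate", "dicloxacillin", 20.0)
        rebuilt = build_model(sc.model_dump())
        assert rebuilt == sc

    def test_fraction_split_validation(self):
        with pytest.raises(ValueError, match="sum"):
            DrugModel(name="bad", mw=400, fu_p=0.5, rb=1.0, ka=1.0, fa=1.0, fg=1.0,
                      vc_l=10.0, hepatic_uptake_clint=10.0,
                      hepatic_uptake_fractions={"OATP1B1": 0.5, "passive": 0.3},
                      cl_met_int=1.0)


class TestDDIRatios:
    def test_infinite_ki_means_no_interaction(self):
        prec = load_drug("dicloxacillin").model_copy(
            update={"ki_map": {t: 1e12 for t in load_drug("dicloxacillin").ki_map}})
        sc = ddi_scenario("rosuvastatin_surrogate", prec, 20.0)
        result = ddi_ratios(sc, t_end=24.0)
        assert result.auc_ratio == pytest.approx(1.0, abs=1e-6)
        assert result.cmax_ratio == pytest.approx(1.0, abs=1e-6)

    def test_auc_ratio_approaches_one_as_dose_vanishes(self):
        deviations = []
        for dose in (1000.0, 100.0, 10.0):
            sc = ddi_scenario("rosuvastatin_surrogate", "dicloxacillin", 20.0,
                              precipitant_dose_mg=dose, precipitant_n_doses=3)
            deviations.append(abs(ddi_ratios(sc, t_end=24.0).auc_ratio - 1.0))
        assert deviations[0] > deviations[1] > deviations[2]
        assert deviations[2] < 0.01

    def test_missing_precipitant_is_an_error(self):
        sc = single_dose(load_drug("rosuvastatin_surrogate"), 20.0)
        with pytest.raises(ValueError, match="no precipitant"):
            ddi_ratios(sc, t_end=8.0)

    def test_inhibition_traces_bounded_and_positive(self):
        sc = ddi_scenario("rosuvastatin_surrogate", "dicloxacillin", 20.0)
        result = ddi_ratios(sc, t_end=24.0)
        traces = result.percent_inhibition_traces
        values = traces.drop(columns="time_h").to_numpy()
        assert np.all(values >= 0.0) and np.all(values < 100.0)
        assert max(result.max_inhibition().values()) > 10.0


class TestWorstCase:
    def test_rejects_non_hepatic_transporter(self):
        sc = ddi_scenario("rosuvastatin_surrogate", "dicloxacillin", 20.0)
        with pytest.raises(ValueError, match="hepatic"):
            worst_case_single_transporter(sc, "BCRP")

    def test_reassigned_fractions_sum_to_one(self):
        sc = ddi_scenario("rosuvastatin_surrogate", "dicloxacillin", 20.0)
        result = worst_case_single_transporter(sc, "OATP1B3", t_end=12.0)
        fractions = result.combined.inhibition_traces  # run executed fine
        victim = sc.victim.drug  # original untouched
        assert sum(victim.hepatic_uptake_fractions.values()) == pytest.approx(1.0)
        assert "hepatic_uptake_OATP1B3" in fractions.columns

    def test_without_inhibitor_ratios_are_one(self):
        prec = load_drug("dicloxacillin").model_copy(update={"ki_map": {}})
        sc = ddi_scenario("rosuvastatin_surrogate", prec, 20.0)
        result = worst_case_single_transporter(sc, "OATP1B1", t_end=12.0)
        assert result.auc_ratio == pytest.approx(1.0, abs=1e-6)
        assert result.cmax_ratio == pytest.approx(1.0, abs=1e-6)


class TestPKSummary:
    def test_constant_curve_auc(self):
        t = np.linspace(0.0, 10.0, 101)
        summary = pk_summary(t, np.full_like(t, 3.0))
        assert summary["auc"] == pytest.approx(30.0)

    def test_monoexponential_half_life(self):
        t = np.linspace(0.0, 20.0, 2001)
        k = 0.35
        summary = pk_summary(t, 10.0 * np.exp(-k * t))
        assert summary["half_life"] == pytest.approx(np.log(2) / k, rel=0.01)

    def test_cmax_stable_under_grid_refinement(self):
        drug = one_compartment_drug()
        coarse = simulate(single_dose(drug, 100.0), t_end=12.0, grid_dt=0.02)
        fine = simulate(single_dose(drug, 100.0), t_end=12.0, grid_dt=0.005)
        assert coarse.cmax == pytest.approx(fine.cmax, rel=0.005)

    def test_all_zero_curve_is_an_error(self):
        with pytest.raises(ValueError):
            pk_summary(np.linspace(0, 1, 10), np.zeros(10))


class TestPKObservations:
    def test_noiseless_observations_lie_on_curve(self):
        drug = one_compartment_drug()
        sc = single_dose(drug, 100.0)
        times = [0.5, 1.0, 2.0, 4.0, 8.0]
        obs = generate_pk_observations(sc, times, cv=0.0, seed=0)
        curve = simulate(sc, t_end=8.0)
        expected = np.interp(times, curve.time, curve.victim_plasma)
        np.testing.assert_allclose(obs.concentration_uM, expected, rtol=1e-9)

    def test_dose_doubling_doubles_noiseless_observations(self):
        drug = one_compartment_drug()
        times = [1.0, 4.0]
        low = generate_pk_observations(single_dose(drug, 50.0), times, cv=0.0, seed=0)
        high = generate_pk_observations(single_dose(drug, 100.0), times, cv=0.0, seed=0)
        np.testing.assert_allclose(high.concentration_uM,
                                   2.0 * low.concentration_uM, rtol=1e-6)

    def test_fixed_seed_reproducible(self):
        sc = single_dose(one_compartment_drug(), 100.0)
        a = generate_pk_observations(sc, [1.0, 2.0, 3.0], cv=0.2, seed=5)
        b = generate_pk_observations(sc, [1.0, 2.0, 3.0], cv=0.2, seed=5)
        assert a.equals(b)

    def test_empty_sample_times_error(self):
        with pytest.raises(ValueError, match="empty"):
            generate_pk_observations(single_dose(one_compartment_drug(), 1.0), [],
                                     cv=0.1, seed=0)
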