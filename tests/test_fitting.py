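"""Data reduction and nonlinear fits: oracles, recovery, calibration, errors."""

import numpy as np
import pandas as pd
import pytest

from transporter_ddi.curves import activity_percent, competitive_rate, ic50_from_ki
from transporter_ddi.fitting import (
    FitResult,
    fit_ic50,
    fit_ki_competitive,
    fit_mm,
    net_uptake_rates,
    percent_activity,
    vesicle_net_transport,
)
from transporter_ddi.synth import (
    NoiseModel,
    TrueParams,
    generate_inhibition_dataset,
    generate_kinetics_dataset,
)

from conftest import INHIBITOR_CONCS


def activity_table(concs, ic50):
    return pd.DataFrame({
        "inhibitor_conc_uM": concs,
        "percent_activity": activity_percent(np.asarray(concs), ic50),
    })


class TestPercentActivity:
    def test_vehicle_row_is_exactly_100(self):
        data = generate_inhibition_dataset(
            TrueParams(ic50=5.0), [1.0, 10.0],
            noise=NoiseModel(cv=0.1, background_fraction=0.2, seed=2),
        )
        act = percent_activity(data)
        assert act.set_index("inhibitor_conc_uM").loc[0.0, "percent_activity"] == \
            pytest.approx(100.0)

    def test_transporter_equal_control_gives_zero(self):
        rows = []
        for conc in (0.0, 50.0):
            for cl in ("transporter", "control"):
                sig = 100.0 if (cl == "transporter" and conc == 0.0) else 10.0
                rows.append((1, cl, f"{cl}{conc}", conc, 2.5, sig))
        data = pd.DataFrame(rows, columns=["experiment_id", "cell_line", "well_id",
                                           "inhibitor_conc_uM", "substrate_conc_uM",
                                           "signal"])
        act = percent_activity(data).set_index("inhibitor_conc_uM")
        assert act.loc[50.0, "percent_activity"] == pytest.approx(0.0)

    def test_noiseless_pass_through_of_generating_curve(self):
        data = generate_inhibition_dataset(
            TrueParams(ic50=10.0), [10.0],
            noise=NoiseModel(cv=0.0, background_fraction=0.1, seed=0),
        )
        act = percent_activity(data).set_index("inhibitor_conc_uM")
        assert act.loc[10.0, "percent_activity"] == pytest.approx(50.0)

    def test_invariant_to_signal_rescaling(self):
        data = generate_inhibition_dataset(
            TrueParams(ic50=5.0), INHIBITOR_CONCS,
            noise=NoiseModel(cv=0.1, background_fraction=0.1, seed=9),
        )
        scaled = data.assign(signal=data.signal * 7.3)
        pd.testing.assert_frame_equal(percent_activity(data), percent_activity(scaled))

    def test_missing_vehicle_raises(self):
        data = generate_inhibition_dataset(
            TrueParams(ic50=5.0), [1.0, 10.0], noise=NoiseModel(0.0, 0.0, 0)
        )
        with pytest.raises(ValueError, match="vehicle"):
            percent_activity(data[data.inhibitor_conc_uM > 0])

    def test_nonpositive_vehicle_net_raises(self):
        data = generate_inhibition_dataset(
            TrueParams(ic50=5.0), [1.0], noise=NoiseModel(0.0, 0.0, 0)
        )
        dead = data.assign(signal=0.0)
        with pytest.raises(ValueError, match="non-functional"):
            percent_activity(dead)


class TestFitIC50:
    def test_exact_recovery_from_noiseless_curve(self):
        fit = fit_ic50(activity_table(INHIBITOR_CONCS, 3.86))
        assert fit.params["ic50"] == pytest.approx(3.86, rel=1e-3)
        assert fit.converged

    def test_half_activity_point_is_the_ic50(self):
        table = activity_table([1.0, 4.0, 16.0], 4.0)
        assert table.percent_activity.iloc[1] == pytest.approx(50.0)
        assert fit_ic50(table).params["ic50"] == pytest.approx(4.0, rel=1e-6)

    def test_matches_grid_search_oracle_on_noisy_data(self):
        """Exhaustive search over log10(IC50) agrees within one grid step."""
        data = generate_inhibition_dataset(
            TrueParams(ic50=3.86), INHIBITOR_CONCS,
            noise=NoiseModel(cv=0.1, background_fraction=0.1, seed=5),
        )
        act = percent_activity(data)
        conc = act.inhibitor_conc_uM.to_numpy()
        y = act.percent_activity.to_numpy()
        mask = conc > 0
        logc = np.log10(conc[mask])
        grid = np.arange(-2.0, 4.0, 0.001)
        sse = [np.sum((100.0 / (1.0 + 10.0 ** (logc - g)) - y[mask]) ** 2) for g in grid]
        best = grid[int(np.argmin(sse))]
        fitted = np.log10(fit_ic50(act).params["ic50"])
        assert abs(fitted - best) <= 0.001

    def test_ci_calibration_and_median_recovery(self):
        """200 seeded replicates of the study design: median within 10% of
        truth and >= 90% of replicates bracket truth in their own 95% CI."""
        true = 3.86
        estimates, covered = [], 0
        for seed in range(200):
            data = generate_inhibition_dataset(
                TrueParams(ic50=true), INHIBITOR_CONCS, n_replicates=3,
                n_experiments=2,
                noise=NoiseModel(cv=0.1, background_fraction=0.1, seed=seed),
            )
            fit = fit_ic50(percent_activity(data))
            estimates.append(fit.params["ic50"])
            low, high = fit.ci95["ic50"]
            covered += low <= true <= high
        assert abs(np.median(estimates) / true - 1.0) <= 0.10
        assert covered / 200 >= 0.90

    def test_flat_data_flagged_nonconvergent(self):
        table = pd.DataFrame({"inhibitor_conc_uM": [1.0, 10.0, 100.0],
                              "percent_activity": [101.0, 99.0, 100.5]})
        fit = fit_ic50(table)
        assert not fit.converged
        assert "decline" in fit.message or "boundary" in fit.message

    def test_too_few_concentrations_raise(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_ic50(activity_table([1.0, 10.0], 3.0))


class TestFitMM:
    CONCS = [0.5, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0]

    def test_noiseless_recovery(self):
        table = pd.DataFrame({
            "substrate_conc_uM": self.CONCS,
            "net_rate": [100.0 * s / (3.0 + s) for s in self.CONCS],
        })
        fit = fit_mm(table)
        assert fit.params["km"] == pytest.approx(3.0, rel=1e-3)
        assert fit.params["vmax"] == pytest.approx(100.0, rel=1e-3)

    def test_matches_profiled_grid_search_oracle(self):
        """Km grid with Vmax profiled by linear least squares per Km."""
        data = generate_kinetics_dataset(
            TrueParams(km=3.0, vmax=100.0), self.CONCS,
            noise=NoiseModel(cv=0.1, background_fraction=0.1, seed=8),
        )
        net = net_uptake_rates(data)
        s = net.substrate_conc_uM.to_numpy()
        v = net.net_rate.to_numpy()
        km_grid = 10.0 ** np.arange(-1.0, 3.0, 0.001)
        best_sse, best_km = np.inf, None
        for km in km_grid:
            m = s / (km + s)
            vmax = (v @ m) / (m @ m)
            sse = np.sum((vmax * m - v) ** 2)
            if sse < best_sse:
                best_sse, best_km = sse, km
        fit = fit_mm(net)
        assert abs(np.log10(fit.params["km"]) - np.log10(best_km)) <= 0.001

    def test_exclusion_removes_saturation_bias(self):
        data = generate_kinetics_dataset(
            TrueParams(km=3.0, vmax=100.0), self.CONCS,
            noise=NoiseModel(cv=0.0, background_fraction=0.1, seed=0),
            saturation_deviation=(250.0, 0.5),
        )
        net = net_uptake_rates(data)
        biased = fit_mm(net)
        clean = fit_mm(net, exclusions=[300.0])
        assert clean.params["km"] == pytest.approx(3.0, rel=1e-3)
        # without the exclusion the deviation drags the whole fit off truth
        assert abs(biased.params["km"] / 3.0 - 1.0) > 0.3
        assert clean.excluded_points == [300.0]

    def test_too_few_points_after_exclusion(self):
        table = pd.DataFrame({"substrate_conc_uM": [1.0, 3.0, 10.0],
                              "net_rate": [25.0, 50.0, 77.0]})
        with pytest.raises(ValueError, match="exclusions"):
            fit_mm(table, exclusions=[10.0])


class TestFitKiCompetitive:
    @staticmethod
    def grid(km=3.0, vmax=100.0, ki=3.65):
        rows = [
            (s, i, float(competitive_rate(s, i, km, vmax, ki)))
            for s in (1.0, 3.0, 10.0, 30.0)
            for i in (0.0, 2.0, 5.0, 15.0, 50.0)
        ]
        return pd.DataFrame(rows, columns=["substrate_conc_uM", "inhibitor_conc_uM",
                                           "net_rate"])

    def test_noiseless_recovery(self):
        fit = fit_ki_competitive(self.grid())
        assert fit.params["ki"] == pytest.approx(3.65, rel=1e-3)
        assert fit.params["km"] == pytest.approx(3.0, rel=1e-3)
        assert fit.params["vmax"] == pytest.approx(100.0, rel=1e-3)

    def test_uninhibited_rows_reduce_to_mm_fit(self):
        grid = self.grid()
        base = grid[grid.inhibitor_conc_uM == 0.0]
        mm = fit_mm(base.rename(columns={})[["substrate_conc_uM", "net_rate"]])
        ki_fit = fit_ki_competitive(self.grid())
        assert ki_fit.params["km"] == pytest.approx(mm.params["km"], rel=1e-3)
        assert ki_fit.params["vmax"] == pytest.approx(mm.params["vmax"], rel=1e-3)

    def test_cheng_prusoff_consistency_with_half_inhibition_search(self):
        """IC50 from Ki*(1+S/Km) equals a brute-force half-inhibition scan
        of the fitted rate surface."""
        fit = fit_ki_competitive(self.grid())
        km, vmax, ki = (fit.params[k] for k in ("km", "vmax", "ki"))
        s = 2.5
        predicted = ic50_from_ki(ki, km, s)
        v0 = competitive_rate(s, 0.0, km, vmax, ki)
        i_scan = np.logspace(-2, 3, 200001)
        v_scan = competitive_rate(s, i_scan, km, vmax, ki)
        brute = i_scan[int(np.argmin(np.abs(v_scan - v0 / 2.0)))]
        assert predicted == pytest.approx(brute, rel=1e-3)

    def test_single_substrate_level_is_unidentifiable(self):
        grid = self.grid()
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_ki_competitive(grid[grid.substrate_conc_uM == 3.0])


class TestVesicleReduction:
    def test_vehicle_normalises_to_100(self):
        from transporter_ddi.synth import generate_vesicle_dataset
        data = generate_vesicle_dataset(
            100.0, 20.0, TrueParams(ic50=166.0), [10.0, 100.0],
            noise=NoiseModel(cv=0.0, background_fraction=0.0, seed=0),
        )
        out = vesicle_net_transport(data).set_index("inhibitor_conc_uM")
        assert out.loc[0.0, "percent_activity"] == pytest.approx(100.0)

    def test_atp_equal_amp_everywhere_yields_zero_and_fails_downstream(self):
        rows = [(1, src, f"{src}{c}{r}", c, 30.0)
                for c in (0.0, 10.0, 100.0, 1000.0)
                for src in ("ATP", "AMP") for r in range(3)]
        data = pd.DataFrame(rows, columns=["experiment_id", "energy_source",
                                           "well_id", "inhibitor_conc_uM", "signal"])
        with pytest.raises(ValueError, match="<= 0"):
            vesicle_net_transport(data)


class TestFitResultInvariants:
    def test_ci_must_bracket_estimate(self):
        with pytest.raises(ValueError, match="bracket"):
            FitResult(params={"ic50": 5.0}, ci95={"ic50": (6.0, 7.0)},
                      residual_sum_squares=0.0, n_points=5)
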