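"""ODE engine for the minimal PBPK DDI simulator.

The state vector holds, per drug, the amounts (μmol) in: gut lumen,
enterocyte, portal vein, liver extracellular, liver intracellular, systemic
central, peripheral, plus three accumulators (renal eliminated, hepatically
eliminated, unabsorbed gut loss). The precipitant's equations are
independent of the victim; the victim's inhibitable intrinsic clearances are
scaled at every solver step by the competitive factor ``1/(1 + I/Ki)`` with
the inhibitor concentration taken at the site of action:

* enterocyte (apical efflux BCRP/P-gp and apical uptake OATP2B1):
  ``I = ka * A_lumen / Q_villous``, the absorption flux diluted into the
  villous blood flow;
* hepatic sinusoidal uptake (OATPs): unbound portal concentration
  ``fu * (C_systemic + ka * A_lumen / (Qh * Rb))`` — the dynamic analogue of
  the static liver-inlet estimate;
* renal (not used by the shipped victims): unbound systemic concentration.

Flows between blood-side compartments are plasma-referenced
(``Q_blood * Rb``); hepatocyte uptake and elimination act on unbound
concentrations with ``fu_p`` used on both sides of the membrane (no
differential intracellular binding). Dose events restart the integrator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .models import (
    HEPATIC_TRANSPORTERS,
    DrugModel,
    DrugRegimen,
    PBPKScenario,
    Physiology,
)

__all__ = [
    "SimResult",
    "DDIResult",
    "apply_inhibition",
    "simulate",
    "ddi_ratios",
    "worst_case_single_transporter",
    "pk_summary",
]

N_STATES = 10
(LUMEN, ENT, PORTAL, LIV_EC, LIV_CELL, CENTRAL, PERIPH,
 ELIM_RENAL, ELIM_HEP, GUT_LOSS) = range(N_STATES)

COMPARTMENTS = [
    "gut_lumen", "enterocyte", "portal", "liver_ec", "liver_cell",
    "central", "peripheral", "eliminated_renal", "eliminated_hepatic",
    "gut_loss",
]


def apply_inhibition(victim_clint: float, inhibitor_unbound_conc: float, ki: float) -> float:
    """Competitively inhibited intrinsic clearance: ``clint / (1 + I/Ki)``."""
    if ki <= 0:
        raise ValueError("ki must be > 0")
    if inhibitor_unbound_conc < 0:
        raise ValueError("inhibitor concentration must be >= 0")
    return victim_clint / (1.0 + inhibitor_unbound_conc / ki)


@dataclass
class _Compiled:
    """Flattened per-drug parameters for fast evaluation inside the RHS."""

    drug: DrugModel
    one_compartment: bool
    ka: float
    k_loss: float
    qh_eff: float
    qvil_eff: float
    fu: float
    ps_passive: float
    hepatic_active: list  # (transporter, f*clint)
    efflux: list  # (transporter, f*clint)
    f_gut_oatp2b1: float
    volumes: np.ndarray  # per-state volumes where defined

    @classmethod
    def build(cls, drug: DrugModel, phys: Physiology) -> "_Compiled":
        vols = np.ones(N_STATES)
        vols[ENT] = phys.v_enterocyte
        vols[PORTAL] = phys.v_portal
        vols[LIV_EC] = phys.v_liver_ec
        vols[LIV_CELL] = phys.v_liver_cell
        vols[CENTRAL] = drug.vc_l
        vols[PERIPH] = drug.vp_l if drug.vp_l > 0 else 1.0
        hepatic_active = [
            (t, drug.hepatic_uptake_clint * f)
            for t, f in drug.hepatic_uptake_fractions.items()
            if t != "passive" and f > 0
        ]
        efflux = [
            (t, drug.intestinal_efflux_clint * f)
            for t, f in drug.intestinal_efflux_fractions.items()
            if f > 0 and drug.intestinal_efflux_clint > 0
        ]
        return cls(
            drug=drug,
            one_compartment=drug.model == "one_compartment",
            ka=drug.ka_absorption,
            k_loss=drug.k_gut_loss,
            qh_eff=phys.qh_blood * drug.rb,
            qvil_eff=phys.q_villous_blood * drug.rb,
            fu=drug.fu_p,
            ps_passive=drug.hepatic_uptake_clint
            * drug.hepatic_uptake_fractions.get("passive", 0.0),
            hepatic_active=hepatic_active,
            efflux=efflux,
            f_gut_oatp2b1=drug.gut_uptake_oatp2b1_fraction,
            volumes=vols,
        )


def _inhibition_ratios(
    scenario: PBPKScenario,
    prec: Optional[_Compiled],
    prec_state: Optional[np.ndarray],
    phys: Physiology,
) -> dict[str, dict[str, float]]:
    """Per-site ``I/Ki`` ratios for every transporter with a known Ki."""
    const = scenario.constant_inhibition
    sites: dict[str, dict[str, float]] = {"gut": {}, "portal": {}, "systemic": {}}
    conc = {"gut": 0.0, "portal": 0.0, "systemic": 0.0}
    ki_map: dict[str, float] = {}
    if prec is not None and prec_state is not None:
        a_lumen = prec_state[LUMEN]
        c_sys = prec_state[CENTRAL] / prec.drug.vc_l
        conc["gut"] = prec.ka * a_lumen / phys.q_villous_blood
        conc["portal"] = prec.fu * (
            c_sys + prec.ka * a_lumen / (phys.qh_blood * prec.drug.rb)
        )
        conc["systemic"] = prec.fu * c_sys
        ki_map = prec.drug.ki_map
    for t in set(ki_map) | set(const):
        for site in sites:
            dynamic = conc[site] / ki_map[t] if t in ki_map else 0.0
            sites[site][t] = dynamic + const.get(t, 0.0)
    return sites


def _drug_rhs(
    c: _Compiled,
    y: np.ndarray,
    ratios: dict[str, dict[str, float]],
) -> np.ndarray:
    """Time derivative of one drug's 10-state block."""
    dy = np.zeros(N_STATES)
    a_lumen = y[LUMEN]
    c_central = y[CENTRAL] / c.drug.vc_l
    c_per = y[PERIPH] / (c.drug.vp_l if c.drug.vp_l > 0 else 1.0)

    if c.one_compartment:
        absorbed = c.ka * a_lumen
        lost = c.k_loss * a_lumen
        eliminated = c.drug.cl_plasma * c_central
        dist = c.drug.cl_distribution * (c_central - c_per) if c.drug.vp_l > 0 else 0.0
        dy[LUMEN] = -absorbed - lost
        dy[CENTRAL] = absorbed - eliminated - dist
        dy[PERIPH] = dist
        dy[ELIM_RENAL] = eliminated
        dy[GUT_LOSS] = lost
        return dy

    gut = ratios["gut"]
    portal = ratios["portal"]

    # absorption: passive fraction + OATP2B1-mediated fraction (inhibitable)
    g_2b1 = 1.0 / (1.0 + gut.get("OATP2B1", 0.0))
    g_abs = (1.0 - c.f_gut_oatp2b1) + c.f_gut_oatp2b1 * g_2b1
    flux_abs = c.ka * a_lumen * g_abs
    flux_loss = c.k_loss * a_lumen

    c_ent = y[ENT] / c.volumes[ENT]
    cl_efflux = sum(
        clint / (1.0 + gut.get(t, 0.0)) for t, clint in c.efflux
    )
    flux_efflux = cl_efflux * c_ent
    flux_washout = c.qvil_eff * c_ent

    c_portal = y[PORTAL] / c.volumes[PORTAL]
    c_le = y[LIV_EC] / c.volumes[LIV_EC]
    c_li = y[LIV_CELL] / c.volumes[LIV_CELL]

    cl_active = sum(
        clint / (1.0 + portal.get(t, 0.0)) for t, clint in c.hepatic_active
    )
    uptake_in = (c.ps_passive + cl_active) * c.fu * c_le
    passive_out = c.ps_passive * c.fu * c_li
    hepatic_elim = c.drug.cl_met_int * c.fu * c_li
    renal_elim = c.drug.cl_renal * c_central
    dist = c.drug.cl_distribution * (c_central - c_per) if c.drug.vp_l > 0 else 0.0

    dy[LUMEN] = -flux_abs - flux_loss + flux_efflux
    dy[ENT] = flux_abs - flux_efflux - flux_washout
    dy[PORTAL] = c.qh_eff * c_central + flux_washout - c.qh_eff * c_portal
    dy[LIV_EC] = c.qh_eff * c_portal - c.qh_eff * c_le - uptake_in + passive_out
    dy[LIV_CELL] = uptake_in - passive_out - hepatic_elim
    dy[CENTRAL] = c.qh_eff * c_le - c.qh_eff * c_central - renal_elim - dist
    dy[PERIPH] = dist
    dy[ELIM_RENAL] = renal_elim
    dy[ELIM_HEP] = hepatic_elim
    dy[GUT_LOSS] = flux_loss
    return dy


@dataclass
class SimResult:
    """Simulation output on a fixed time grid.

    ``victim_amounts``/``precipitant_amounts`` are (n_states, n_time) arrays
    in the order of :data:`COMPARTMENTS`. ``mass_balance_rel_error`` is the
    largest relative deviation of (in-body + eliminated + unabsorbed) from
    the cumulative dose.
    """

    time: np.ndarray
    victim_plasma: np.ndarray
    victim_amounts: np.ndarray
    dosed_victim_umol: float
    mass_balance_rel_error: float
    precipitant_plasma: Optional[np.ndarray] = None
    precipitant_amounts: Optional[np.ndarray] = None
    dosed_precipitant_umol: float = 0.0
    inhibition_traces: Optional[pd.DataFrame] = None

    def summary(self) -> dict[str, float]:
        return pk_summary(self.time, self.victim_plasma)

    @property
    def auc(self) -> float:
        return float(np.trapezoid(self.victim_plasma, self.time))

    @property
    def cmax(self) -> float:
        return float(self.victim_plasma.max())

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, drug, compartment, amount) table."""
        frames = []
        for label, amounts in (
            ("victim", self.victim_amounts),
            ("precipitant", self.precipitant_amounts),
        ):
            if amounts is None:
                continue
            df = pd.DataFrame(amounts.T, columns=COMPARTMENTS)
            df.insert(0, "time_h", self.time)
            df.insert(1, "drug", label)
            frames.append(df.melt(id_vars=["time_h", "drug"],
                                  var_name="compartment", value_name="amount_umol"))
        return pd.concat(frames, ignore_index=True)


def _dose_events(regimen: DrugRegimen, t_end: float) -> list[tuple[float, float]]:
    dose_umol = regimen.dosing.dose_mg * 1000.0 / regimen.drug.mw
    return [(t, dose_umol) for t in regimen.dosing.times() if t < t_end]


def simulate(
    scenario: PBPKScenario,
    t_end: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    grid_dt: float = 0.01,
) -> SimResult:
    """Integrate the scenario from 0 to ``t_end`` hours.

    Stiff integration (LSODA) restarted at every dose event; output on a
    fixed grid of spacing ``grid_dt`` h. Deterministic: no randomness is
    involved anywhere in the engine.
    """
    phys = scenario.physiology
    victim = _Compiled.build(scenario.victim.drug, phys)
    prec = (
        _Compiled.build(scenario.precipitant.drug, phys)
        if scenario.precipitant is not None
        else None
    )
    n = N_STATES * (2 if prec is not None else 1)

    events: dict[float, list[tuple[int, float]]] = {}
    for t, amount in _dose_events(scenario.victim, t_end):
        events.setdefault(t, []).append((LUMEN, amount))
    if prec is not None and scenario.precipitant is not None:
        for t, amount in _dose_events(scenario.precipitant, t_end):
            events.setdefault(t, []).append((N_STATES + LUMEN, amount))
    if not any(t <= 0.0 for t in events):
        events.setdefault(0.0, [])

    def rhs(t, y):
        prec_state = y[N_STATES:] if prec is not None else None
        ratios = _inhibition_ratios(scenario, prec, prec_state, phys)
        dy = np.empty_like(y)
        dy[:N_STATES] = _drug_rhs(victim, y[:N_STATES], ratios)
        if prec is not None:
            no_inhibition = {"gut": {}, "portal": {}, "systemic": {}}
            dy[N_STATES:] = _drug_rhs(prec, y[N_STATES:], no_inhibition)
        return dy

    grid = np.round(np.arange(0.0, t_end + grid_dt / 2, grid_dt), 10)
    segments = sorted(t for t in events if t < t_end) + [t_end]
    y = np.zeros(n)
    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    dosed_victim = dosed_prec = 0.0
    dosed_steps: list[tuple[float, float, float]] = []  # (t, cum_victim, cum_prec)

    for idx, t0 in enumerate(segments[:-1]):
        for state_idx, amount in events.get(t0, []):
            y[state_idx] += amount
            if state_idx < N_STATES:
                dosed_victim += amount
            else:
                dosed_prec += amount
        dosed_steps.append((t0, dosed_victim, dosed_prec))
        t1 = segments[idx + 1]
        seg_grid = grid[(grid >= t0) & (grid <= t1)]
        sol = solve_ivp(
            rhs, (t0, t1), y, method="LSODA", rtol=rtol, atol=atol,
            dense_output=True,
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE solver failed on segment [{t0}, {t1}] h: {sol.message}"
            )
        if seg_grid.size:
            seg_states = sol.sol(seg_grid)
            times_out.append(seg_grid)
            states_out.append(seg_states)
        y = sol.y[:, -1]

    time = np.concatenate(times_out)
    states = np.concatenate(states_out, axis=1)
    time, keep = np.unique(time, return_index=True)
    states = states[:, keep]

    victim_amounts = states[:N_STATES]
    victim_plasma = victim_amounts[CENTRAL] / scenario.victim.drug.vc_l

    # mass balance: everything in-body plus eliminated plus unabsorbed must
    # equal the cumulative administered dose at all times
    cum_victim = np.zeros_like(time)
    cum_prec = np.zeros_like(time)
    for t0, cv, cp in dosed_steps:
        # the stored state exactly at a dose time is the pre-dose state
        mask = time >= -1e-12 if t0 == 0.0 else time > t0 + 1e-12
        cum_victim[mask] = cv
        cum_prec[mask] = cp
    total_victim = victim_amounts.sum(axis=0)
    denom = np.maximum(cum_victim, 1e-30)
    mb_err = float(np.max(np.abs(total_victim - cum_victim) / denom))

    result = SimResult(
        time=time,
        victim_plasma=victim_plasma,
        victim_amounts=victim_amounts,
        dosed_victim_umol=dosed_victim,
        mass_balance_rel_error=mb_err,
    )
    if prec is not None:
        prec_amounts = states[N_STATES:]
        result.precipitant_amounts = prec_amounts
        result.precipitant_plasma = prec_amounts[CENTRAL] / prec.drug.vc_l
        result.dosed_precipitant_umol = dosed_prec
        total_prec = prec_amounts.sum(axis=0)
        denom_p = np.maximum(cum_prec, 1e-30)
        mb_p = float(np.max(np.abs(total_prec - cum_prec) / denom_p))
        result.mass_balance_rel_error = max(mb_err, mb_p)
    result.inhibition_traces = _traces(scenario, victim, prec, result)
    return result


def _traces(
    scenario: PBPKScenario,
    victim: _Compiled,
    prec: Optional[_Compiled],
    result: SimResult,
) -> pd.DataFrame:
    """Per-pathway percent inhibition, ``100*(1 - clint(t)/clint_baseline)``."""
    phys = scenario.physiology
    pathways: list[tuple[str, str, str]] = []  # (label, site, transporter)
    for t, _ in victim.hepatic_active:
        pathways.append((f"hepatic_uptake_{t}", "portal", t))
    for t, _ in victim.efflux:
        pathways.append((f"gut_efflux_{t}", "gut", t))
    if victim.f_gut_oatp2b1 > 0:
        pathways.append(("gut_uptake_OATP2B1", "gut", "OATP2B1"))

    data = {"time_h": result.time}
    n_t = result.time.size
    for label, site, transporter in pathways:
        ratio = np.full(n_t, scenario.constant_inhibition.get(transporter, 0.0))
        if prec is not None and result.precipitant_amounts is not None:
            ki = prec.drug.ki_map.get(transporter)
            if ki is not None:
                a_lumen = result.precipitant_amounts[LUMEN]
                c_sys = result.precipitant_amounts[CENTRAL] / prec.drug.vc_l
                if site == "gut":
                    conc = prec.ka * a_lumen / phys.q_villous_blood
                elif site == "portal":
                    conc = prec.fu * (
                        c_sys + prec.ka * a_lumen / (phys.qh_blood * prec.drug.rb)
                    )
                else:
                    conc = prec.fu * c_sys
                ratio = ratio + conc / ki
        data[label] = 100.0 * (1.0 - 1.0 / (1.0 + ratio))
    return pd.DataFrame(data)


@dataclass
class DDIResult:
    """Paired with/without-precipitant simulation and exposure ratios."""

    auc_ratio: float
    cmax_ratio: float
    baseline: SimResult
    combined: SimResult

    @property
    def percent_inhibition_traces(self) -> pd.DataFrame:
        return self.combined.inhibition_traces

    def max_inhibition(self) -> dict[str, float]:
        traces = self.combined.inhibition_traces
        return {
            c: float(traces[c].max()) for c in traces.columns if c != "time_h"
        }


def ddi_ratios(
    scenario: PBPKScenario,
    t_end: float = 48.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    grid_dt: float = 0.01,
) -> DDIResult:
    """AUC and Cmax ratios of the victim with vs. without the precipitant.

    The victim dosing is identical across the paired runs; AUC is the
    trapezoidal integral over the full simulated window.
    """
    if scenario.precipitant is None:
        raise ValueError("scenario has no precipitant")
    baseline_scenario = scenario.model_copy(
        update={"precipitant": None}, deep=True
    )
    baseline = simulate(baseline_scenario, t_end, rtol=rtol, atol=atol, grid_dt=grid_dt)
    combined = simulate(scenario, t_end, rtol=rtol, atol=atol, grid_dt=grid_dt)
    if baseline.time.shape != combined.time.shape or not np.allclose(
        baseline.time, combined.time
    ):
        raise RuntimeError("mismatched output grids between paired runs")
    return DDIResult(
        auc_ratio=combined.auc / baseline.auc,
        cmax_ratio=combined.cmax / baseline.cmax,
        baseline=baseline,
        combined=combined,
    )


def worst_case_single_transporter(
    scenario: PBPKScenario,
    transporter: str,
    t_end: float = 48.0,
    **kwargs,
) -> DDIResult:
    """Re-run the DDI with all hepatic uptake assigned to one transporter.

    99% of the victim's sinusoidal uptake intrinsic clearance is assigned to
    ``transporter`` and 1% to passive diffusion, representing a hypothetical
    victim fully dependent on that single uptake route.
    """
    if transporter not in HEPATIC_TRANSPORTERS:
        raise ValueError(
            f"{transporter!r} is not a hepatic uptake transporter "
            f"{HEPATIC_TRANSPORTERS}"
        )
    fractions = {transporter: 0.99, "passive": 0.01}
    victim_drug = scenario.victim.drug.model_copy(
        update={"hepatic_uptake_fractions": fractions}
    )
    new_scenario = scenario.model_copy(deep=True)
    new_scenario.victim.drug = victim_drug
    return ddi_ratios(new_scenario, t_end=t_end, **kwargs)


def pk_summary(time: np.ndarray, conc: np.ndarray) -> dict[str, float]:
    """Trapezoidal AUC, Cmax, tmax, and terminal half-life of a curve.

    The half-life comes from a log-linear regression over the terminal
    declining stretch spanning at most one decade of concentration (NaN when
    fewer than three usable points exist).
    """
    time = np.asarray(time, float)
    conc = np.asarray(conc, float)
    if time.size == 0 or np.all(conc <= 0):
        raise ValueError("empty or all-zero concentration curve")
    auc = float(np.trapezoid(conc, time))
    imax = int(np.argmax(conc))
    cmax = float(conc[imax])
    tmax = float(time[imax])

    half_life = float("nan")
    tail = conc[imax:]
    t_tail = time[imax:]
    positive = tail > 0
    if positive.sum() >= 3:
        c_end = tail[positive][-1]
        window = positive & (tail <= 10.0 * c_end) & (tail >= c_end)
        if window.sum() >= 3:
            slope = np.polyfit(t_tail[window], np.log(tail[window]), 1)[0]
            if slope < 0:
                half_life = float(np.log(2.0) / -slope)
    return {"auc": auc, "cmax": cmax, "tmax": tmax, "half_life": half_life}
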