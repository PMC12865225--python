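"""Seeded generators of synthetic transporter-assay datasets.

The generators emulate the statistical structure of HEK293 uptake assays
(transporter-expressing vs. control cells, vehicle wells, 7-point inhibitor
series, 7-8 point substrate series) and of inside-out membrane-vesicle efflux
assays (ATP vs. AMP triplicates), so the fitting and risk modules can be
exercised and calibrated without access to raw plate data.

Noise is multiplicative lognormal, parameterised by a fractional coefficient
of variation: a noisy signal is ``expected * exp(N(-sigma^2/2, sigma))`` with
``sigma^2 = ln(1 + cv^2)``, which has mean ``expected`` and coefficient of
variation ``cv``. Control-cell (background) uptake is modelled as
inhibitor-independent passive uptake, expressed as a fraction of the
transporter-cell vehicle signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .curves import activity_percent, michaelis_menten

__all__ = [
    "NoiseModel",
    "TrueParams",
    "generate_inhibition_dataset",
    "generate_kinetics_dataset",
    "generate_vesicle_dataset",
    "generate_pk_observations",
]

ASSAY_COLUMNS = [
    "experiment_id",
    "cell_line",
    "well_id",
    "inhibitor_conc_uM",
    "substrate_conc_uM",
    "signal",
]
VESICLE_COLUMNS = ["experiment_id", "energy_source", "well_id", "inhibitor_conc_uM", "signal"]


@dataclass(frozen=True)
class NoiseModel:
    """Replicate scatter and assay background.

    cv
        Fractional coefficient of variation of the multiplicative lognormal
        well-to-well noise (>= 0; 0 means noiseless).
    background_fraction
        Control-cell uptake as a fraction of the transporter-cell vehicle
        uptake, in [0, 1). Treated as passive, i.e. inhibitor-independent.
    seed
        RNG seed; identical seeds reproduce identical datasets.
    """

    cv: float = 0.1
    background_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if not 0 <= self.background_fraction < 1:
            raise ValueError("background_fraction must be in [0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def factors(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw n multiplicative noise factors with mean 1 and CV ``cv``."""
        if self.cv == 0:
            return np.ones(n)
        sigma = np.sqrt(np.log1p(self.cv**2))
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


@dataclass(frozen=True)
class TrueParams:
    """Generating ("true") kinetic parameters for a synthetic assay.

    Only the parameters relevant to a given generator need to be set:
    ``ic50`` for inhibition/vesicle series, ``km``/``vmax`` for kinetics,
    ``ki`` for competitive-inhibition grids. All concentrations in μM;
    ``vehicle_uptake`` and ``vmax`` in arbitrary amount(/min) units.
    """

    ic50: float | None = None
    km: float | None = None
    vmax: float | None = None
    ki: float | None = None
    vehicle_uptake: float = 100.0

    def __post_init__(self) -> None:
        for name in ("ic50", "km", "vmax", "ki", "vehicle_uptake"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(f"{name} must be > 0")


def _check_concs(concs: Sequence[float]) -> np.ndarray:
    concs = np.asarray(list(concs), dtype=float)
    if concs.size == 0:
        raise ValueError("concentration series is empty")
    if np.any(concs <= 0):
        raise ValueError("concentrations must be strictly positive (vehicle is implicit)")
    if np.any(np.diff(concs) <= 0):
        raise ValueError("concentrations must be sorted ascending without ties")
    return concs


def generate_inhibition_dataset(
    true: TrueParams,
    concs: Sequence[float],
    n_replicates: int = 3,
    n_experiments: int = 2,
    noise: NoiseModel = NoiseModel(),
    substrate_conc: float = 2.5,
) -> pd.DataFrame:
    """Simulate a cell-uptake inhibition assay across an inhibitor series.

    For each experiment, each inhibitor concentration (plus an implicit
    vehicle at 0 μM) is measured in ``n_replicates`` wells in both
    transporter-expressing and control cells. The expected transporter-cell
    signal is ``vehicle_uptake * activity(conc)/100 + background``; control
    wells carry background only. ``substrate_conc`` is the probe substrate
    concentration, recorded but constant across the series.
    """
    if true.ic50 is None:
        raise ValueError("TrueParams.ic50 is required for an inhibition dataset")
    if n_replicates < 1 or n_experiments < 1:
        raise ValueError("n_replicates and n_experiments must be >= 1")
    concs = _check_concs(concs)
    all_concs = np.concatenate([[0.0], concs])
    background = noise.background_fraction * true.vehicle_uptake

    rng = noise.rng()
    rows = []
    for exp in range(1, n_experiments + 1):
        for conc in all_concs:
            expected = true.vehicle_uptake * activity_percent(conc, true.ic50) / 100.0
            eps_t = noise.factors(rng, n_replicates)
            eps_c = noise.factors(rng, n_replicates)
            for rep in range(n_replicates):
                rows.append(
                    (exp, "transporter", f"T{conc:g}_{rep + 1}", conc, substrate_conc,
                     expected * eps_t[rep] + background)
                )
                rows.append(
                    (exp, "control", f"C{conc:g}_{rep + 1}", conc, substrate_conc,
                     background * eps_c[rep])
                )
    return pd.DataFrame(rows, columns=ASSAY_COLUMNS)


def generate_kinetics_dataset(
    true: TrueParams,
    concs: Sequence[float],
    n_replicates: int = 3,
    noise: NoiseModel = NoiseModel(),
    saturation_deviation: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Simulate a transport-kinetics assay across a substrate series.

    The expected transporter-minus-control rate follows Michaelis-Menten
    kinetics. ``saturation_deviation=(threshold_uM, multiplier)`` optionally
    scales the carrier-mediated rate by ``multiplier`` at concentrations
    above the threshold, emulating the systematic high-concentration
    deviations that are excluded from fits in practice. Background (control)
    rate is ``background_fraction * vmax``.
    """
    if true.km is None or true.vmax is None:
        raise ValueError("TrueParams.km and .vmax are required for a kinetics dataset")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    concs = _check_concs(concs)
    background = noise.background_fraction * true.vmax

    rng = noise.rng()
    rows = []
    for conc in concs:
        rate = float(michaelis_menten(conc, true.km, true.vmax))
        if saturation_deviation is not None and conc > saturation_deviation[0]:
            rate *= saturation_deviation[1]
        eps_t = noise.factors(rng, n_replicates)
        eps_c = noise.factors(rng, n_replicates)
        for rep in range(n_replicates):
            rows.append(
                (1, "transporter", f"T{conc:g}_{rep + 1}", 0.0, conc,
                 rate * eps_t[rep] + background)
            )
            rows.append(
                (1, "control", f"C{conc:g}_{rep + 1}", 0.0, conc, background * eps_c[rep])
            )
    return pd.DataFrame(rows, columns=ASSAY_COLUMNS)


def generate_vesicle_dataset(
    net_transport: float,
    amp_background: float,
    inhibition_curve: TrueParams,
    concs: Sequence[float],
    n_replicates: int = 3,
    noise: NoiseModel = NoiseModel(),
) -> pd.DataFrame:
    """Simulate an inside-out membrane-vesicle efflux inhibition assay.

    ATP-energised wells measure ``amp_background + net_transport *
    activity(conc)/100``; AMP wells (no active transport) measure the
    background alone. Both are measured in ``n_replicates`` wells per
    concentration, vehicle (0 μM) included.
    """
    if net_transport < 0 or amp_background < 0:
        raise ValueError("net_transport and amp_background must be >= 0")
    if inhibition_curve.ic50 is None:
        raise ValueError("inhibition_curve.ic50 is required")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    concs = _check_concs(concs)
    all_concs = np.concatenate([[0.0], concs])

    rng = noise.rng()
    rows = []
    for conc in all_concs:
        expected_net = net_transport * activity_percent(conc, inhibition_curve.ic50) / 100.0
        eps_atp = noise.factors(rng, n_replicates)
        eps_amp = noise.factors(rng, n_replicates)
        for rep in range(n_replicates):
            rows.append(
                (1, "ATP", f"ATP{conc:g}_{rep + 1}", conc,
                 (amp_background + expected_net) * eps_atp[rep])
            )
            rows.append(
                (1, "AMP", f"AMP{conc:g}_{rep + 1}", conc, amp_background * eps_amp[rep])
            )
    return pd.DataFrame(rows, columns=VESICLE_COLUMNS)


def generate_pk_observations(
    scenario,
    sample_times: Sequence[float],
    cv: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate noisy plasma-concentration observations of the victim drug.

    Runs the PBPK scenario, samples the victim plasma curve at
    ``sample_times`` (h) and applies multiplicative lognormal error with
    coefficient of variation ``cv``. Stands in for sparse clinical PK data.
    """
    from .pbpk import simulate

    sample_times = np.asarray(list(sample_times), dtype=float)
    if sample_times.size == 0:
        raise ValueError("sample_times is empty")
    t_end = float(sample_times.max())
    result = simulate(scenario, t_end=t_end)
    conc = np.interp(sample_times, result.time, result.victim_plasma)
    noise = NoiseModel(cv=cv, background_fraction=0.0, seed=seed)
    conc = conc * noise.factors(noise.rng(), sample_times.size)
    return pd.DataFrame({"time_h": sample_times, "concentration_uM": conc})
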