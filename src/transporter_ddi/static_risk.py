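"""FDA static (R-value) assessment of transporter-mediated DDI risk.

Given a precipitant drug's exposure parameters and a set of in vitro IC50
values, this module computes the three regulatory exposure metrics and the
corresponding R-values with their decision thresholds:

* hepatic basolateral uptake (OATP1B1/1B3, hepatic OATP2B1):
  ``R = 1 + I_in,max,u / IC50``, cut-off 1.1, where ``I_in,max,u`` is the
  maximal unbound inhibitor concentration at the liver inlet,
  ``fu,p * (Cmax + Fa*Fg*ka*Dose / (Qh*Rb))``;
* intestinal apical transporters (BCRP, P-gp, intestinal OATP2B1):
  ``R = I_gut / IC50``, cut-off 10, with ``I_gut = dose / 0.25 L``;
* renal transporters: ``R = I_max,u / IC50`` with ``I_max,u = fu,p * Cmax``;
  cut-off 0.1 basolateral (OAT1/2/3) and 0.02 apical (OAT4, borrowing the
  MATE cut-off for an apically expressed renal transporter).

R-values are reported rounded to two significant figures; threshold flags
are always computed on the unrounded value. An IC50 known only as a lower
bound ("IC50 >= x") propagates to an R-value that is an upper bound, still
compared against the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import pandas as pd

__all__ = [
    "Mechanism",
    "PrecipitantProfile",
    "RValue",
    "StaticRiskReport",
    "DEFAULT_TRANSPORTER_MECHANISMS",
    "dose_umol",
    "i_in_max_u",
    "i_max_u",
    "i_gut",
    "r_value",
    "build_report",
    "round_sigfigs",
]


class Mechanism(str, Enum):
    """Inhibition site class; selects the exposure metric and FDA cut-off."""

    HEPATIC_BASOLATERAL = "hepatic_basolateral"
    GUT_APICAL = "gut_apical"
    RENAL_BASOLATERAL = "renal_basolateral"
    RENAL_APICAL = "renal_apical"


THRESHOLDS = {
    Mechanism.HEPATIC_BASOLATERAL: 1.1,
    Mechanism.GUT_APICAL: 10.0,
    Mechanism.RENAL_BASOLATERAL: 0.1,
    Mechanism.RENAL_APICAL: 0.02,
}

# Which mechanisms each transporter is evaluated under. OATP2B1 is expressed
# both at the hepatic basolateral membrane and at the intestinal apical
# membrane, OAT4 at the apical membrane of the proximal tubule.
DEFAULT_TRANSPORTER_MECHANISMS: dict[str, tuple[Mechanism, ...]] = {
    "OATP1B1": (Mechanism.HEPATIC_BASOLATERAL,),
    "OATP1B3": (Mechanism.HEPATIC_BASOLATERAL,),
    "OATP2B1": (Mechanism.HEPATIC_BASOLATERAL, Mechanism.GUT_APICAL),
    "OAT1": (Mechanism.RENAL_BASOLATERAL,),
    "OAT2": (Mechanism.RENAL_BASOLATERAL,),
    "OAT3": (Mechanism.RENAL_BASOLATERAL,),
    "OAT4": (Mechanism.RENAL_APICAL,),
    "BCRP": (Mechanism.GUT_APICAL,),
    "P-gp": (Mechanism.GUT_APICAL,),
}


@dataclass(frozen=True)
class PrecipitantProfile:
    """Exposure and PK parameters of the inhibitor (precipitant) drug.

    Units: ``cmax_total`` μM (total plasma), ``dose_mg`` mg, ``mw`` g/mol,
    ``ka`` 1/min, ``qh`` L/min (hepatic blood flow), fractions unitless.
    """

    name: str
    fu_p: float
    cmax_total: float
    dose_mg: float
    mw: float
    fa: float = 1.0
    fg: float = 1.0
    ka: float = 0.1
    qh: float = 1.62
    rb: float = 0.65

    def __post_init__(self) -> None:
        for name in ("fu_p", "cmax_total", "dose_mg", "mw", "fa", "fg", "ka", "qh", "rb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("fu_p", "fa", "fg"):
            if getattr(self, name) > 1:
                raise ValueError(f"{name} must be <= 1")


def round_sigfigs(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures, half away from zero."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    scale = 10.0 ** (exponent - sig + 1)
    value = math.floor(abs(x) / scale + 0.5) * scale * math.copysign(1.0, x)
    return round(value, sig - 1 - exponent)  # snap to the shortest decimal


def dose_umol(profile: PrecipitantProfile) -> float:
    """Oral dose converted from mg to μmol: ``dose_mg * 1000 / mw``."""
    return profile.dose_mg * 1000.0 / profile.mw


def i_in_max_u(profile: PrecipitantProfile) -> float:
    """Maximal unbound inhibitor concentration at the liver inlet (μM).

    ``fu,p * (Cmax + Fa*Fg*ka*Dose / (Qh*Rb))``, the worst-case systemic Cmax
    plus the absorption flux diluted into hepatic blood flow.
    """
    absorption_term = (
        profile.fa * profile.fg * profile.ka * dose_umol(profile) / (profile.qh * profile.rb)
    )
    return profile.fu_p * (profile.cmax_total + absorption_term)


def i_max_u(profile: PrecipitantProfile) -> float:
    """Maximal unbound systemic concentration (μM): ``Cmax * fu,p``."""
    return profile.cmax_total * profile.fu_p


def i_gut(profile: PrecipitantProfile) -> float:
    """Nominal intestinal luminal concentration (μM): dose dissolved in 250 mL."""
    return dose_umol(profile) / 0.25


@dataclass(frozen=True)
class RValue:
    """One R-value with its threshold comparison.

    ``r`` is the unrounded value; ``r_2sf`` the 2-significant-figure value
    used for reporting. ``is_upper_bound`` marks R-values derived from an
    IC50 lower bound. ``flagged`` uses the unrounded value.
    """

    r: float
    r_2sf: float
    threshold: float
    flagged: bool
    mechanism: Mechanism
    exposure_metric: str
    is_upper_bound: bool = False

    def __str__(self) -> str:
        prefix = "<= " if self.is_upper_bound else ""
        return f"{prefix}{self.r_2sf:g}" + (" *" if self.flagged else "")


_EXPOSURE_FOR_MECHANISM = {
    Mechanism.HEPATIC_BASOLATERAL: "I_in_max_u",
    Mechanism.GUT_APICAL: "I_gut",
    Mechanism.RENAL_BASOLATERAL: "I_max_u",
    Mechanism.RENAL_APICAL: "I_max_u",
}


def r_value(
    exposure: float,
    ic50: float,
    mechanism: Mechanism | str,
    ic50_is_lower_bound: bool = False,
) -> RValue:
    """Compute the R-value for one (exposure metric, IC50, mechanism) triple.

    Hepatic basolateral uses ``1 + exposure/IC50``; the other mechanisms use
    the plain ratio ``exposure/IC50``. When the IC50 is a lower bound, the
    returned R is an upper bound (``is_upper_bound=True``) and is still
    compared against the threshold, which preserves the conservative reading:
    a flagged upper bound means risk cannot be excluded.
    """
    mechanism = Mechanism(mechanism)
    if exposure <= 0 or ic50 <= 0:
        raise ValueError("exposure and ic50 must be > 0")
    ratio = exposure / ic50
    r = 1.0 + ratio if mechanism is Mechanism.HEPATIC_BASOLATERAL else ratio
    threshold = THRESHOLDS[mechanism]
    return RValue(
        r=r,
        r_2sf=round_sigfigs(r, 2),
        threshold=threshold,
        flagged=bool(r >= threshold),
        mechanism=mechanism,
        exposure_metric=_EXPOSURE_FOR_MECHANISM[mechanism],
        is_upper_bound=ic50_is_lower_bound,
    )


@dataclass(frozen=True)
class StaticRiskReport:
    """Per-(transporter, mechanism) R-values for one precipitant drug."""

    precipitant: str
    exposures: dict[str, float]
    table: pd.DataFrame

    def flagged_transporters(self) -> list[str]:
        return sorted(self.table.loc[self.table["flagged"], "transporter"].unique())


def build_report(
    profile: PrecipitantProfile,
    ic50s: Mapping[str, float | tuple],
    mechanisms: Mapping[str, tuple[Mechanism, ...]] | None = None,
) -> StaticRiskReport:
    """Assemble the full static risk table for one precipitant.

    ``ic50s`` maps transporter name to either an IC50 in μM or a tuple
    ``(ic50, "lower_bound")`` for values reported as ">= x". Transporters are
    assigned mechanisms by ``mechanisms`` (default:
    :data:`DEFAULT_TRANSPORTER_MECHANISMS`); a transporter absent from the
    mapping is an error. One row is emitted per (transporter, mechanism).
    """
    if not ic50s:
        raise ValueError("empty IC50 map")
    mechanisms = dict(mechanisms or DEFAULT_TRANSPORTER_MECHANISMS)
    exposures = {
        "I_in_max_u": i_in_max_u(profile),
        "I_gut": i_gut(profile),
        "I_max_u": i_max_u(profile),
    }
    rows = []
    for transporter, value in ic50s.items():
        if transporter not in mechanisms:
            raise ValueError(f"unknown transporter {transporter!r}: declare its mechanism")
        if isinstance(value, tuple):
            ic50, qualifier = value
            lower_bound = qualifier == "lower_bound"
        else:
            ic50, lower_bound = float(value), False
        for mechanism in mechanisms[transporter]:
            rv = r_value(exposures[_EXPOSURE_FOR_MECHANISM[mechanism]], ic50, mechanism,
                         ic50_is_lower_bound=lower_bound)
            rows.append({
                "transporter": transporter,
                "mechanism": mechanism.value,
                "ic50_uM": ic50,
                "ic50_is_lower_bound": lower_bound,
                "exposure_metric": rv.exposure_metric,
                "exposure_uM": exposures[rv.exposure_metric],
                "r_value": rv.r,
                "r_value_2sf": rv.r_2sf,
                "r_is_upper_bound": rv.is_upper_bound,
                "threshold": rv.threshold,
                "flagged": rv.flagged,
            })
    return StaticRiskReport(
        precipitant=profile.name, exposures=exposures, table=pd.DataFrame(rows)
    )
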