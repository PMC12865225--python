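"""Configuration schema for the PBPK DDI simulator.

The simulator uses a deliberately small whole-body topology — the smallest
that exposes every inhibition site of interest for organic-anion transporter
DDIs::

    gut lumen -> enterocyte (apical carrier uptake + apical efflux, both
    inhibitable) -> portal vein -> liver extracellular <-> liver
    intracellular (sinusoidal active uptake split across OATPs + passive
    diffusion; intracellular metabolic/biliary elimination) -> systemic
    central <-> peripheral; renal elimination from central.

A drug can alternatively be run as a classical one-compartment oral model
(``model: one_compartment``) when only its plasma profile matters, e.g. a
precipitant whose disposition is described empirically; its gut-lumen and
systemic states still drive the inhibition of a co-simulated victim.

Units: time h, volume L, flows/clearances L/h, amounts μmol,
concentrations μM, dose mg, molecular weight g/mol.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator

HEPATIC_TRANSPORTERS = ("OATP1B1", "OATP1B3", "OATP2B1")
EFFLUX_TRANSPORTERS = ("BCRP", "P-gp")


class DrugModel(BaseModel):
    """One drug: physicochemistry, absorption, disposition, interaction terms.

    ``hepatic_uptake_fractions`` splits the sinusoidal uptake intrinsic
    clearance across the hepatic OATPs plus a passive (non-inhibitable,
    bidirectional) component and must sum to 1.
    ``gut_uptake_oatp2b1_fraction`` is the fraction of the intestinal
    absorption flux carried by apical OATP2B1 (inhibitable); the remainder is
    passive. ``ki_map`` holds the drug's inhibition constants (μM) when it
    acts as a precipitant.
    """

    name: str
    mw: float = Field(gt=0, description="molecular weight, g/mol")
    fu_p: float = Field(gt=0, le=1)
    rb: float = Field(gt=0, description="blood-to-plasma concentration ratio")
    ka: float = Field(gt=0, description="absorption rate constant, 1/h")
    fa: float = Field(gt=0, le=1, description="fraction absorbed")
    fg: float = Field(gt=0, le=1, description="fraction escaping gut metabolism")
    model: Literal["full", "one_compartment"] = "full"
    vc_l: float = Field(gt=0, description="central volume, L (plasma-referenced)")
    vp_l: float = Field(ge=0, default=0.0, description="peripheral volume, L")
    cl_distribution: float = Field(ge=0, default=0.0, description="inter-compartment CL, L/h")
    cl_renal: float = Field(ge=0, default=0.0, description="renal plasma clearance, L/h")
    # full-model hepatic handling
    hepatic_uptake_clint: float = Field(ge=0, default=0.0,
                                        description="sinusoidal uptake CLint (unbound), L/h")
    hepatic_uptake_fractions: dict[str, float] = Field(
        default_factory=lambda: {"passive": 1.0}
    )
    cl_met_int: float = Field(ge=0, default=0.0,
                              description="intracellular elimination CLint (unbound), L/h")
    # full-model intestinal handling
    intestinal_efflux_clint: float = Field(ge=0, default=0.0,
                                           description="apical efflux CLint, L/h")
    intestinal_efflux_fractions: dict[str, float] = Field(
        default_factory=lambda: {"BCRP": 1.0}
    )
    gut_uptake_oatp2b1_fraction: float = Field(ge=0, le=1, default=0.0)
    # one-compartment disposition
    cl_plasma: float = Field(ge=0, default=0.0,
                             description="total plasma clearance, L/h (one_compartment)")
    # precipitant property
    ki_map: dict[str, float] = Field(default_factory=dict,
                                     description="transporter -> Ki (μM, unbound)")

    @model_validator(mode="after")
    def _check_fractions(self) -> "DrugModel":
        allowed = set(HEPATIC_TRANSPORTERS) | {"passive"}
        if set(self.hepatic_uptake_fractions) - allowed:
            raise ValueError(f"hepatic_uptake_fractions keys must be in {sorted(allowed)}")
        if self.hepatic_uptake_clint > 0:
            total = sum(self.hepatic_uptake_fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"hepatic_uptake_fractions sum to {total}, expected 1")
        if set(self.intestinal_efflux_fractions) - set(EFFLUX_TRANSPORTERS):
            raise ValueError(
                f"intestinal_efflux_fractions keys must be in {EFFLUX_TRANSPORTERS}"
            )
        if self.intestinal_efflux_clint > 0:
            total = sum(self.intestinal_efflux_fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"intestinal_efflux_fractions sum to {total}, expected 1")
        for ki in self.ki_map.values():
            if ki <= 0:
                raise ValueError("all Ki values must be > 0")
        if self.model == "one_compartment" and self.cl_plasma <= 0:
            raise ValueError("one_compartment model requires cl_plasma > 0")
        return self

    @property
    def ka_absorption(self) -> float:
        """Absorbed part of the first-order lumen disappearance: ``ka * fa * fg``."""
        return self.ka * self.fa * self.fg

    @property
    def k_gut_loss(self) -> float:
        """Unabsorbed part of the lumen disappearance: ``ka * (1 - fa*fg)``.

        ``ka`` is the observed lumen disappearance rate constant; splitting
        it this way gives baseline availability ``fa*fg`` while keeping the
        lumen residence time ``1/ka`` independent of availability.
        """
        return self.ka * (1.0 - self.fa * self.fg)


class DosingSchedule(BaseModel):
    """Repeated oral dosing: ``n_doses`` doses of ``dose_mg`` every ``interval_h``.

    A zero dose is allowed and means the drug is never administered.
    """

    dose_mg: float = Field(ge=0)
    interval_h: float = Field(gt=0, default=24.0)
    n_doses: int = Field(ge=1, default=1)
    start_h: float = Field(ge=0, default=0.0)
    route: Literal["oral"] = "oral"

    def times(self) -> list[float]:
        return [self.start_h + i * self.interval_h for i in range(self.n_doses)]


class Physiology(BaseModel):
    """Shared physiological flows and volumes (70 kg reference subject)."""

    body_weight_kg: float = Field(gt=0, default=70.0)
    qh_blood: float = Field(gt=0, default=97.2, description="hepatic blood flow, L/h")
    q_villous_blood: float = Field(gt=0, default=18.0,
                                   description="villous (mucosal) blood flow, L/h")
    v_enterocyte: float = Field(gt=0, default=0.3)
    v_portal: float = Field(gt=0, default=1.0)
    v_liver_ec: float = Field(gt=0, default=0.7,
                              description="liver extracellular (blood+interstitial), L")
    v_liver_cell: float = Field(gt=0, default=1.1)


class DrugRegimen(BaseModel):
    drug: DrugModel
    dosing: DosingSchedule


class PBPKScenario(BaseModel):
    """A victim drug, an optional precipitant, and shared physiology.

    ``constant_inhibition`` maps transporter names to a fixed ``I/Ki`` ratio
    applied throughout the simulation (in addition to any dynamic precipitant
    inhibition); it exists for reduced-model analyses where the inhibitor
    exposure is held constant.
    """

    victim: DrugRegimen
    precipitant: Optional[DrugRegimen] = None
    physiology: Physiology = Field(default_factory=Physiology)
    constant_inhibition: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_ratios(self) -> "PBPKScenario":
        for ratio in self.constant_inhibition.values():
            if ratio < 0:
                raise ValueError("constant_inhibition ratios must be >= 0")
        return self


def build_model(config: dict) -> PBPKScenario:
    """Validate a plain dict (e.g. parsed YAML) into a :class:`PBPKScenario`."""
    return PBPKScenario.model_validate(config)
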