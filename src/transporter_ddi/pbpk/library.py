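"""Built-in drug models shipped as editable YAML configuration files.

The precipitant models (dicloxacillin, flucloxacillin) carry clinically
anchored oral PK plus the in vitro inhibition constants; the victim models
are openly parameterised surrogates for proprietary compound files and are
labelled as such in their configs. Use :func:`load_drug` for the bundled
models or :func:`load_drug_file` for your own.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .models import DosingSchedule, DrugModel, DrugRegimen, PBPKScenario, Physiology

__all__ = ["available_drugs", "load_drug", "load_drug_file", "ddi_scenario"]

_DATA = resources.files("transporter_ddi") / "data"


def available_drugs() -> list[str]:
    """Names of the bundled drug models."""
    return sorted(p.name.removesuffix(".yaml") for p in _DATA.iterdir()
                  if p.name.endswith(".yaml"))


def load_drug(name: str) -> DrugModel:
    """Load a bundled drug model by name (see :func:`available_drugs`)."""
    path = _DATA / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(f"no bundled drug model {name!r}; "
                       f"available: {available_drugs()}") from None
    return DrugModel.model_validate(yaml.safe_load(text))


def load_drug_file(path: str | Path) -> DrugModel:
    """Load a drug model from a user-supplied YAML file."""
    with open(path) as fh:
        return DrugModel.model_validate(yaml.safe_load(fh))


def ddi_scenario(
    victim: DrugModel | str,
    precipitant: DrugModel | str | None,
    victim_dose_mg: float,
    precipitant_dose_mg: float = 1000.0,
    precipitant_interval_h: float = 8.0,
    precipitant_n_doses: int = 6,
    physiology: Physiology | None = None,
) -> PBPKScenario:
    """Assemble a single-victim-dose DDI scenario.

    The victim is dosed once at t=0 together with the first precipitant
    dose; the precipitant is dosed repeatedly (default 1000 mg every 8 h).
    """
    if isinstance(victim, str):
        victim = load_drug(victim)
    if isinstance(precipitant, str):
        precipitant = load_drug(precipitant)
    return PBPKScenario(
        victim=DrugRegimen(drug=victim, dosing=DosingSchedule(dose_mg=victim_dose_mg)),
        precipitant=(
            None
            if precipitant is None
            else DrugRegimen(
                drug=precipitant,
                dosing=DosingSchedule(
                    dose_mg=precipitant_dose_mg,
                    interval_h=precipitant_interval_h,
                    n_doses=precipitant_n_doses,
                ),
            )
        ),
        physiology=physiology or Physiology(),
    )
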