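"""Concentration-response and carrier-mediated transport rate laws.

These are the elementary curves everything else in the package is built on:
the fixed-slope log-logistic inhibition curve used for IC50 estimation, the
Michaelis-Menten uptake rate, and its competitive-inhibition extension.
Concentrations are in μM throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "inhibition_percent",
    "activity_percent",
    "michaelis_menten",
    "competitive_rate",
    "ic50_from_ki",
]


def inhibition_percent(conc, ic50):
    """Percent inhibition of carrier-mediated transport at inhibitor ``conc``.

    Log-logistic curve with the Hill slope fixed at 1 and asymptotes fixed at
    0% (no inhibitor) and 100% (complete inhibition)::

        inhibition = 100 - 100 / (1 + 10**(log10(I) - log10(IC50)))
                   = 100 * I / (IC50 + I)

    Exactly 50% at ``conc == ic50`` and strictly increasing in ``conc``.
    ``conc == 0`` (vehicle) maps to 0% inhibition.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("inhibitor concentrations must be >= 0")
    if ic50 <= 0:
        raise ValueError("ic50 must be > 0")
    return 100.0 * conc / (ic50 + conc)


def activity_percent(conc, ic50):
    """Percent of vehicle transport activity remaining at inhibitor ``conc``."""
    return 100.0 - inhibition_percent(conc, ic50)


def michaelis_menten(s, km, vmax):
    """Carrier-mediated uptake rate ``vmax * S / (km + S)`` at substrate conc S."""
    s = np.asarray(s, dtype=float)
    if km <= 0 or vmax <= 0:
        raise ValueError("km and vmax must be > 0")
    return vmax * s / (km + s)


def competitive_rate(s, i, km, vmax, ki):
    """Uptake rate under competitive inhibition.

    ``v = vmax * S / (km * (1 + I/ki) + S)``: the inhibitor raises the
    apparent Km by ``(1 + I/ki)`` and leaves Vmax untouched.
    """
    s = np.asarray(s, dtype=float)
    i = np.asarray(i, dtype=float)
    if ki <= 0:
        raise ValueError("ki must be > 0")
    if km <= 0 or vmax <= 0:
        raise ValueError("km and vmax must be > 0")
    return vmax * s / (km * (1.0 + i / ki) + s)


def ic50_from_ki(ki, km, s):
    """Cheng-Prusoff relation for a competitive inhibitor: IC50 = Ki*(1 + S/Km)."""
    if ki <= 0 or km <= 0 or s < 0:
        raise ValueError("ki, km must be > 0 and s >= 0")
    return ki * (1.0 + s / km)
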