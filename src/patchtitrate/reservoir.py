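"""Reservoir (permeate) composition and virtual-reaction equilibrium constants.

The permeate is an NaCl solution whose pH is adjusted with excess HCl (acidic
side) or NaOH (basic side).  Given target pH and salt concentration, the full
ion composition {H+, OH-, Na+, Cl-} follows from electroneutrality and the
water autoionization product; non-ideality is handled with the mean activity
coefficient from the empirical Davies equation, solved self-consistently with
the ionic strength.

The grand-canonical coupling to the simulation box uses electroneutral
ion-pair exchange reactions (NaCl, HCl, NaOH, HOH) whose equilibrium
constants are ``K_ij = gamma_pm^2 c_i c_j / c0^2``, with the water pair fixed
to the activity product ``K_w = 1e-14``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReservoirSpec",
    "davies_log10_gamma",
    "solve_reservoir",
    "composite_acid_constants",
    "K_WATER",
]

K_WATER = 1e-14  # water ion activity product at 298 K
DAVIES_A = 0.509  # Debye-Huckel coefficient at 25 C, (mol/L)^(-1/2)
DAVIES_LINEAR = 0.3

#: ion-pair exchange reactions coupling the box to the reservoir
PAIR_REACTIONS = ("NaCl", "HCl", "NaOH", "HOH")


class InfeasibleReservoirError(ValueError):
    """Requested (pH, c_salt) implies a negative ion concentration."""


def davies_log10_gamma(ionic_strength: float, z: int = 1) -> float:
    """Davies estimate of ``log10 gamma`` for an ion of valency ``z``.

    ``log10 gamma = -A z^2 (sqrt(I)/(1+sqrt(I)) - 0.3 I)`` with A = 0.509 at
    298 K; ``ionic_strength`` in mol/L.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be non-negative")
    s = np.sqrt(ionic_strength)
    return float(-DAVIES_A * z * z * (s / (1.0 + s) - DAVIES_LINEAR * ionic_strength))


@dataclass(frozen=True)
class ReservoirSpec:
    """Resolved permeate composition and derived reaction constants.

    ``conc`` maps ion names {"H", "OH", "Na", "Cl"} to mol/L; ``constants``
    maps pair-reaction names to dimensionless equilibrium constants.
    """

    pH: float
    c_salt: float
    conc: dict = field(default_factory=dict)
    ionic_strength: float = 0.0
    gamma_pm: float = 1.0
    constants: dict = field(default_factory=dict)
    activity_model: str = "davies"

    def ion_concentration(self, name: str) -> float:
        return self.conc[name]


def solve_reservoir(
    pH: float, c_salt: float, activity_model: str = "davies", tol: float = 1e-12
) -> ReservoirSpec:
    """Solve the permeate composition at prescribed pH and NaCl concentration.

    pH is interpreted on the activity scale, ``pH = -log10(gamma_pm c_H/c0)``.
    The composition is iterated to self-consistency between ionic strength
    and the Davies activity coefficient (``activity_model="ideal"`` forces
    ``gamma_pm = 1``, useful for comparison against ideal-gas theory).
    """
    if not 0.0 < pH < 14.0:
        raise ValueError("pH must be in (0, 14)")
    if c_salt < 0:
        raise ValueError("c_salt must be non-negative")
    if activity_model not in ("davies", "ideal"):
        raise ValueError(f"unknown activity model {activity_model!r}")

    a_H = 10.0 ** (-pH)
    a_OH = K_WATER / a_H
    gamma = 1.0
    for _ in range(200):
        c_H = a_H / gamma
        c_OH = a_OH / gamma
        if pH <= 7.0:
            c_Na = c_salt
            c_Cl = c_salt + c_H - c_OH
        else:
            c_Cl = c_salt
            c_Na = c_salt + c_OH - c_H
        if c_Cl < -1e-15 or c_Na < -1e-15:
            raise InfeasibleReservoirError(
                f"pH={pH}, c_salt={c_salt}: implied concentration negative"
            )
        ionic = 0.5 * (c_H + c_OH + c_Na + c_Cl)
        gamma_new = (
            1.0 if activity_model == "ideal" else 10.0 ** davies_log10_gamma(ionic, 1)
        )
        if abs(gamma_new - gamma) <= tol * gamma:
            gamma = gamma_new
            break
        gamma = gamma_new

    c_H = a_H / gamma
    c_OH = a_OH / gamma
    if pH <= 7.0:
        c_Na, c_Cl = c_salt, c_salt + c_H - c_OH
    else:
        c_Cl, c_Na = c_salt, c_salt + c_OH - c_H
    conc = {"H": c_H, "OH": c_OH, "Na": max(c_Na, 0.0), "Cl": max(c_Cl, 0.0)}
    ionic = 0.5 * sum(conc.values())
    g2 = gamma * gamma
    constants = {
        "HOH": K_WATER,
        "NaCl": g2 * conc["Na"] * conc["Cl"],
        "HCl": g2 * conc["H"] * conc["Cl"],
        "NaOH": g2 * conc["Na"] * conc["OH"],
    }
    return ReservoirSpec(
        pH=pH,
        c_salt=c_salt,
        conc=conc,
        ionic_strength=ionic,
        gamma_pm=gamma,
        constants=constants,
        activity_model=activity_model,
    )


def composite_acid_constants(res: ReservoirSpec, pKa: float) -> dict:
    """Equilibrium constants of the acid move and its composite variants.

    The plain dissociation ``HA -> A- + H+`` has ``K = K_A``.  Combining it
    with the reservoir pair reactions yields electroneutral alternatives that
    sample efficiently when free H+ is scarce:

    - ``HA -> A- + Na+``  with ``K = K_A K_NaCl / K_HCl``
    - ``HA + OH- -> A-``  with ``K = K_A / K_w``
    """
    K_A = 10.0 ** (-pKa)
    return {
        "acid_H": K_A,
        "acid_Na": K_A * res.constants["NaCl"] / res.constants["HCl"],
        "acid_OH": K_A / res.constants["HOH"],
    }
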