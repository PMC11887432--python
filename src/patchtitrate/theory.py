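"""Closed-form Donnan / Henderson-Hasselbalch reference theory.

Ideal-gas Donnan partitioning of monovalent ions across a semipermeable
membrane, the Henderson-Hasselbalch titration curve, and the coupled
self-consistent solution of the two (the analytic reference the simulations
are compared against).

Conventions: the nonexchangeable charges are anionic (acidic sites), so the
retentate is at lower pH than the permeate and ``Delta pH = -log10 D+ <= 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import Boltzmann, elementary_charge

__all__ = [
    "DonnanResult",
    "ionic_strength",
    "donnan_ideal",
    "hh_alpha",
    "coupled_hh_donnan",
    "donnan_potential",
    "permeate_composition_ideal",
]

ION_VALENCY = {"H": 1, "OH": -1, "Na": 1, "Cl": -1}


class ConvergenceError(RuntimeError):
    """Self-consistent HH+Donnan iteration failed to converge."""


@dataclass(frozen=True)
class DonnanResult:
    """Analytic Donnan prediction at one state point.

    ``D_plus``/``D_minus`` are retentate/permeate concentration ratios of
    monovalent cations/anions (``D_plus * D_minus = 1``); ``psi_don`` is the
    Donnan potential in volts; ``alpha`` the degree of ionization and
    ``pH_ret`` the retentate pH.
    """

    D_plus: float
    D_minus: float
    delta_pH: float
    psi_don: float
    alpha: float = float("nan")
    pH_ret: float = float("nan")


def ionic_strength(conc: dict) -> float:
    """``I = (1/2) sum_i c_i z_i^2`` over the small ions, in mol/L."""
    if any(c < 0 for c in conc.values()):
        raise ValueError("concentrations must be non-negative")
    return 0.5 * sum(c * ION_VALENCY.get(name, 1) ** 2 for name, c in conc.items())


def permeate_composition_ideal(pH: float, c_salt: float) -> dict:
    """Ideal permeate ion concentrations: NaCl plus excess HCl or NaOH."""
    c_H = 10.0 ** (-pH)
    c_OH = 1e-14 / c_H
    if pH <= 7.0:
        return {"H": c_H, "OH": c_OH, "Na": c_salt, "Cl": c_salt + c_H - c_OH}
    return {"H": c_H, "OH": c_OH, "Na": c_salt + c_OH - c_H, "Cl": c_salt}


def donnan_potential(D_plus: float, temperature: float = 298.0) -> float:
    """Donnan potential in volts: ``psi = -(kB T / e) ln D+``.

    The ideal distribution ratios obey ``D_± = exp(∓ e psi / kB T)``.
    """
    if D_plus <= 0:
        raise ValueError("D_plus must be positive")
    return -(Boltzmann * temperature / elementary_charge) * np.log(D_plus)


def donnan_ideal(c_A: float, ionic: float, temperature: float = 298.0) -> DonnanResult:
    """Ideal Donnan partitioning for nonexchangeable anion concentration c_A.

    Electroneutrality of the retentate with a common monovalent ratio D
    reads ``D I = I / D + c_A``, whose positive root is
    ``D+ = (c_A + sqrt(c_A^2 + 4 I^2)) / (2 I)``.  Limits: ``D+ -> 1`` for
    ``c_A << I`` and ``D+ -> c_A / I`` for ``c_A >> I``.
    """
    if ionic <= 0:
        raise ValueError("ionic strength must be positive")
    if c_A < 0:
        raise ValueError("c_A must be non-negative")
    D_plus = (c_A + np.sqrt(c_A * c_A + 4.0 * ionic * ionic)) / (2.0 * ionic)
    return DonnanResult(
        D_plus=float(D_plus),
        D_minus=float(1.0 / D_plus),
        delta_pH=float(-np.log10(D_plus)),
        psi_don=donnan_potential(D_plus, temperature),
    )


def hh_alpha(pH: float, pKa: float) -> float:
    """Henderson-Hasselbalch ionization degree ``1 / (1 + 10^(pKa - pH))``."""
    return float(1.0 / (1.0 + 10.0 ** (pKa - pH)))


def coupled_hh_donnan(
    pH_perm: float,
    pKa: float,
    c_acid_total: float,
    c_salt: float,
    include_water_ions: bool = True,
    damping: float = 0.5,
    tol: float = 1e-12,
    max_iter: int = 10_000,
    temperature: float = 298.0,
) -> DonnanResult:
    """Self-consistent Henderson-Hasselbalch + Donnan solution.

    Solves ``alpha = HH(pH_perm + Delta_pH(alpha))`` with
    ``Delta_pH = -log10 D+(alpha c_acid_total, I)``.  The permeate ionic
    strength includes the H+/OH- contributions by default (this produces the
    suppression of the Donnan effect at extreme pH, where the excess strong
    acid/base raises I even at constant salt).  Damped fixed-point iteration;
    raises :class:`ConvergenceError` with diagnostics if it fails.
    """
    if c_acid_total < 0 or c_salt < 0:
        raise ValueError("concentrations must be non-negative")
    if include_water_ions:
        ionic = ionic_strength(permeate_composition_ideal(pH_perm, c_salt))
    else:
        ionic = max(c_salt, 1e-300)
    if ionic <= 0:
        raise ValueError("permeate ionic strength must be positive")

    alpha = hh_alpha(pH_perm, pKa)
    for _ in range(max_iter):
        don = donnan_ideal(alpha * c_acid_total, ionic, temperature)
        target = hh_alpha(pH_perm + don.delta_pH, pKa)
        new_alpha = (1.0 - damping) * alpha + damping * target
        if abs(new_alpha - alpha) <= tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    else:
        raise ConvergenceError(
            f"HH+Donnan fixed point did not converge: pH={pH_perm}, pKa={pKa}, "
            f"c_acid={c_acid_total}, I={ionic}, last alpha={alpha}"
        )

    don = donnan_ideal(alpha * c_acid_total, ionic, temperature)
    return DonnanResult(
        D_plus=don.D_plus,
        D_minus=don.D_minus,
        delta_pH=don.delta_pH,
        psi_don=don.psi_don,
        alpha=float(alpha),
        pH_ret=float(pH_perm + don.delta_pH),
    )
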