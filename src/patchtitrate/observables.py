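"""Observables and error analysis: alpha, distribution ratios, blocking errors.

Simulation time series are reduced to equilibrium averages after discarding
an equilibration transient (30% of the run by default); statistical errors
of the mean are estimated by block averaging with block-size doubling until
the blocked standard error plateaus, which also yields an estimate of the
autocorrelation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from patchtitrate.geometry import AVOGADRO_PER_NM3_MOLAR

__all__ = [
    "ObservableSeries",
    "ionization_degree",
    "distribution_ratio",
    "delta_pH",
    "blocking_error",
    "BlockingResult",
]


class InsufficientDataError(ValueError):
    """Too few post-equilibration samples for a blocking analysis."""


def ionization_degree(n_A: int, n_HA: int) -> float:
    """Degree of ionization ``alpha = N_A- / (N_A- + N_HA)``."""
    total = n_A + n_HA
    if total < 1:
        raise ValueError("alpha undefined without ionizable sites")
    return n_A / total


def distribution_ratio(c_ret: float, c_perm: float) -> float:
    """Retentate/permeate concentration ratio ``D = c_ret / c_perm``."""
    if c_perm <= 0:
        raise ZeroDivisionError("permeate concentration must be positive")
    return c_ret / c_perm


def delta_pH(D_cation: float) -> float:
    """Retentate-minus-permeate pH: ``Delta pH = -log10 D+``.

    Negative when the confined particles are anionic (cations accumulate in
    the retentate, D+ > 1).
    """
    if D_cation <= 0:
        raise ValueError("distribution ratio must be positive")
    return float(-np.log10(D_cation))


@dataclass(frozen=True)
class BlockingResult:
    mean: float
    se: float
    tau: float  # autocorrelation time in units of the sampling interval
    block_size: int
    n_used: int


def blocking_error(
    series: np.ndarray,
    equilibration_fraction: float = 0.30,
    plateau_rtol: float = 0.05,
    min_samples: int = 64,
) -> BlockingResult:
    """Mean and standard error of a correlated series by block averaging.

    Discards the first ``equilibration_fraction`` of the series, then doubles
    the block size until the blocked standard error changes by less than
    ``plateau_rtol`` across two successive doublings (or fewer than 8 blocks
    remain).  The implied autocorrelation time is
    ``tau = (SE_plateau / SE_naive)^2 / 2`` in sampling intervals.
    """
    x = np.asarray(series, dtype=float)
    n0 = len(x)
    x = x[int(np.floor(equilibration_fraction * n0)):]
    n = len(x)
    if n < min_samples:
        raise InsufficientDataError(f"need >= {min_samples} post-equilibration samples, got {n}")

    mean = float(np.mean(x))
    var0 = float(np.var(x, ddof=1))
    if var0 == 0.0:
        return BlockingResult(mean=mean, se=0.0, tau=0.0, block_size=1, n_used=n)
    se_naive = np.sqrt(var0 / n)

    ses = []
    bs = 1
    y = x.copy()
    while len(y) >= 8:
        m = len(y)
        ses.append((bs, np.sqrt(np.var(y, ddof=1) / m)))
        # merge pairs into blocks of double size
        y = 0.5 * (y[: 2 * (m // 2) : 2] + y[1 : 2 * (m // 2) : 2])
        bs *= 2

    se_final, bs_final = ses[-1][1], ses[-1][0]
    for i in range(2, len(ses)):
        s2, s1, s0 = ses[i][1], ses[i - 1][1], ses[i - 2][1]
        if s0 > 0 and abs(s2 - s1) < plateau_rtol * s2 and abs(s1 - s0) < plateau_rtol * s1:
            se_final, bs_final = s2, ses[i][0]
            break

    tau = 0.5 * (se_final / se_naive) ** 2 if se_naive > 0 else 0.0
    return BlockingResult(mean=mean, se=float(se_final), tau=float(tau), block_size=bs_final, n_used=n)


@dataclass
class ObservableSeries:
    """Per-sample observables of one run plus reduction to means and errors.

    ``frame`` columns: cycle, alpha, N_Na, N_Cl, N_H, N_OH, U_total,
    U_coulomb.  ``volume`` is the box volume in nm^3 and ``reservoir_conc``
    the permeate composition used for distribution ratios.
    """

    frame: pd.DataFrame
    volume: float
    reservoir_conc: dict
    equilibration_fraction: float = 0.30
    metadata: dict = field(default_factory=dict)

    def block(self, column: str) -> BlockingResult:
        return blocking_error(
            self.frame[column].to_numpy(), self.equilibration_fraction
        )

    def concentration(self, species: str) -> BlockingResult:
        """Retentate concentration of an ion species in mol/L (box volume)."""
        counts = self.frame[f"N_{species}"].to_numpy() / (
            self.volume * AVOGADRO_PER_NM3_MOLAR
        )
        return blocking_error(counts, self.equilibration_fraction)

    def distribution(self, species: str) -> tuple[float, float]:
        """(D_i, SE) for one ion species against the reservoir."""
        c = self.concentration(species)
        c_perm = self.reservoir_conc[species]
        return c.mean / c_perm, c.se / c_perm

    def summary(self) -> dict:
        """Reduced observables: alpha, D_i, Delta pH, with standard errors."""
        out: dict = {"n_samples": int(len(self.frame))}
        a = self.block("alpha")
        out.update(alpha_mean=a.mean, alpha_SE=a.se, alpha_tau=a.tau)
        for sp in ("Na", "Cl", "H", "OH"):
            if self.reservoir_conc.get(sp, 0.0) > 0:
                D, se = self.distribution(sp)
                out[f"D_{sp}"] = D
                out[f"D_{sp}_SE"] = se
        if "D_Na" in out and out["D_Na"] > 0:
            out["delta_pH"] = delta_pH(out["D_Na"])
            out["delta_pH_SE"] = out["D_Na_SE"] / (out["D_Na"] * np.log(10.0))
            out["delta_pH_abs"] = abs(out["delta_pH"])
        out.update(self.metadata)
        return out
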