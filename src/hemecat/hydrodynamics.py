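"""Rotating-disc (Koutecky-Levich) analysis of catalytic O2 reduction.

For a disc rotating at angular velocity omega, the catalytic current obeys

    1/i = 1/i_K + 1/i_L(omega)

where i_L = 0.62 n F A D^{2/3} omega^{1/2} nu^{-1/6} [O2] is the Levich
(diffusion-limited) current and i_K the mass-transport-free kinetic
current.  A straight-line fit of 1/i against omega^{-1/2} therefore yields
the electron count n per O2 from its slope and i_K from its intercept.
For a surface-confined catalyst at coverage Gamma the kinetic current is
first order in substrate and catalyst,

    i_K = n F A [O2] Gamma k_ORR,

so the intercept also yields the second-order rate constant k_ORR and,
multiplied by the bulk O2 concentration, the pseudo-first-order turnover
rate.  Currents are sign-normalised to cathodic magnitudes before any
reciprocal transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .constants import MOLAR_TO_MOL_PER_CM3, ElectrochemConstants

__all__ = [
    "RotationSeries",
    "KLAnalysis",
    "levich_current",
    "kinetic_current",
    "kl_model_current",
    "kl_fit",
    "n_from_slope",
    "k2_from_kinetic_current",
    "pseudo_first_order",
]

LEVICH_PREFACTOR = 0.62


@dataclass(frozen=True)
class RotationSeries:
    """Catalytic current sampled at one held potential across rotation rates.

    ``entries`` holds (angular velocity rad s^-1, current A) pairs.
    """

    potential_hold: float
    entries: tuple[tuple[float, float], ...]
    constants: ElectrochemConstants = field(default_factory=ElectrochemConstants)

    def __post_init__(self) -> None:
        entries = tuple((float(w), float(i)) for w, i in self.entries)
        object.__setattr__(self, "entries", entries)
        if len(entries) < 3:
            raise ValueError(f"need >= 3 rotation rates, got {len(entries)}")
        omegas = [w for w, _ in entries]
        if any(w <= 0 for w in omegas):
            raise ValueError("angular velocities must be > 0")
        if len(set(omegas)) != len(omegas):
            raise ValueError("angular velocities must be distinct")
        if any(i == 0 for _, i in entries):
            raise ValueError("currents must be nonzero")

    @property
    def omega(self) -> np.ndarray:
        return np.array([w for w, _ in self.entries])

    @property
    def current(self) -> np.ndarray:
        return np.array([i for _, i in self.entries])


@dataclass(frozen=True)
class KLAnalysis:
    """Result of a Koutecky-Levich straight-line fit at one potential.

    ``kinetic_current``, ``k2`` and ``k1`` are ``None`` when the fitted
    intercept is non-positive (kinetic current undefined) or, for the rate
    constants, when no coverage was supplied.
    """

    slope: float              # A^-1 rad^{1/2} s^{-1/2}
    intercept: float          # A^-1
    r_squared: float
    n_estimate: float         # electrons per O2
    kinetic_current: Optional[float] = None   # A
    k2: Optional[float] = None                # M^-1 s^-1
    k1: Optional[float] = None                # s^-1

    @property
    def intercept_flagged(self) -> bool:
        """True when the intercept was non-positive and i_K is undefined."""
        return self.kinetic_current is None


def levich_current(n: float, omega: float, c: ElectrochemConstants) -> float:
    """Diffusion-limited (Levich) current i_L in A.

    i_L = 0.62 n F A D^{2/3} omega^{1/2} nu^{-1/6} [O2], with [O2] in
    mol cm^-3 and omega in rad s^-1.
    """
    if n <= 0:
        raise ValueError("electron count must be > 0")
    if omega <= 0:
        raise ValueError("angular velocity must be > 0 rad/s")
    return (
        LEVICH_PREFACTOR
        * n
        * c.faraday_constant
        * c.electrode_area
        * c.o2_diffusion ** (2.0 / 3.0)
        * np.sqrt(omega)
        * c.kinematic_viscosity ** (-1.0 / 6.0)
        * c.o2_concentration
    )


def kinetic_current(
    n: float, k2: float, coverage: float, c: ElectrochemConstants
) -> float:
    """Kinetic current i_K = n F A [O2] Gamma k_ORR in A.

    ``k2`` is the second-order rate constant in M^-1 s^-1; ``coverage`` is
    in mol cm^-2.
    """
    if min(n, k2, coverage) < 0:
        raise ValueError("n, k2 and coverage must be >= 0")
    k2_cm3 = k2 / MOLAR_TO_MOL_PER_CM3  # cm^3 mol^-1 s^-1
    return (
        n
        * c.faraday_constant
        * c.electrode_area
        * c.o2_concentration
        * coverage
        * k2_cm3
    )


def kl_model_current(
    i_k: float, n: float, omega: float, c: ElectrochemConstants
) -> float:
    """Koutecky-Levich composite current (1/i_K + 1/i_L)^-1 in A."""
    il = levich_current(n, omega, c)
    if i_k <= 0:
        return il
    return 1.0 / (1.0 / i_k + 1.0 / il)


def kl_fit(series: RotationSeries, coverage: float | None = None) -> KLAnalysis:
    """Ordinary least squares of 1/|i| on omega^{-1/2}.

    Populates slope, intercept and r^2; the electron count from the slope;
    and, when the intercept is positive, the kinetic current i_K = 1/b.
    With a surface coverage (mol cm^-2) supplied, also the second-order
    rate constant k2 (M^-1 s^-1) and the pseudo-first-order rate
    k1 = k2 [O2] (s^-1).
    """
    x = 1.0 / np.sqrt(series.omega)
    y = 1.0 / np.abs(series.current)
    fit = stats.linregress(x, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    r2 = float(fit.rvalue) ** 2
    n_est = n_from_slope(slope, series.constants)
    if intercept <= 0:
        return KLAnalysis(slope=slope, intercept=intercept, r_squared=r2, n_estimate=n_est)
    i_k = 1.0 / intercept
    k2 = k1 = None
    if coverage is not None:
        k2 = k2_from_kinetic_current(i_k, n_est, coverage, series.constants)
        k1 = pseudo_first_order(k2, series.constants)
    return KLAnalysis(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n_estimate=n_est,
        kinetic_current=i_k,
        k2=k2,
        k1=k1,
    )


def n_from_slope(slope: float, c: ElectrochemConstants) -> float:
    """Electrons per O2 from a Koutecky-Levich slope.

    n = 1 / (slope * 0.62 F A D^{2/3} nu^{-1/6} [O2]); the bulk O2
    concentration belongs in the slope because it enters the Levich
    current linearly.
    """
    if slope <= 0:
        raise ValueError("K-L slope must be > 0")
    levich_factor = (
        LEVICH_PREFACTOR
        * c.faraday_constant
        * c.electrode_area
        * c.o2_diffusion ** (2.0 / 3.0)
        * c.kinematic_viscosity ** (-1.0 / 6.0)
        * c.o2_concentration
    )
    return 1.0 / (slope * levich_factor)


def k2_from_kinetic_current(
    i_k: float, n: float, coverage: float, c: ElectrochemConstants
) -> float:
    """Second-order O2-reduction rate constant from a kinetic current.

    k_ORR = i_K / (n F A [O2] Gamma), returned in M^-1 s^-1.
    """
    if i_k < 0:
        raise ValueError("kinetic current magnitude must be >= 0")
    if n <= 0:
        raise ValueError("electron count must be > 0")
    if coverage <= 0:
        raise ValueError("surface coverage must be > 0")
    k2_cm3 = i_k / (
        n * c.faraday_constant * c.electrode_area * c.o2_concentration * coverage
    )
    return k2_cm3 * MOLAR_TO_MOL_PER_CM3


def pseudo_first_order(k2: float, c: ElectrochemConstants) -> float:
    """Pseudo-first-order turnover rate k1 = k2 [O2] in s^-1.

    ``k2`` in M^-1 s^-1; the bulk O2 concentration is taken from ``c`` in M.
    """
    if k2 < 0:
        raise ValueError("second-order rate constant must be >= 0")
    return k2 * c.o2_molar
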